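# Methods

This note documents the statistical and numerical methods implemented in
`pitsa`, the default parameters and their rationale, and the scope and
limitations of the synthetic-data generators.

## 1. Reporter-ion quantification (`pitsa.quantify`)

**Impurity correction.** TMT reagents carry isotopic impurities: a reporter
labeled with reagent *i* contributes signal to neighboring channels. Writing
the vendor matrix *M* with rows = source reagent and columns = observed
channel (rows sum to ≤ 1), the observed row vector for a PSM is
`obs = true · M`. We recover the true signal by solving the linear system
`Mᵀ x = obsᵀ` (LAPACK via `numpy.linalg.solve`) rather than applying a
truncated subtraction, so correction followed by mixing is exact to machine
precision. Matrices with condition number above 10⁸ are rejected. Small
negative values produced by noise are clamped to zero and counted in the log.

**Channel normalization.** Each channel's column is scaled so that all column
sums equal the mean column sum, separately per assay when the design mixes
abundance and PISA channels. This is the standard equal-loading correction;
see §6 for its compositional side effect.

**Aggregation and scaling.** PSMs are summed to features first and each
feature row is then scaled to a total of 100 across its channels
(sum-then-scale, not scale-then-sum), preserving PSM-level weighting by
signal. Phosphopeptide PSMs contribute their full signal to every site with a
localization score ≥ 13 (features are named `PROTEIN_S123` etc.); peptides
with no confidently localized site are dropped. The pre-scaling summed
signal-to-noise is retained per feature and used by the
limit-of-quantification filter (default: keep features with total S:N ≥ 100).

## 2. Fold changes, thermal shifts, categories (`pitsa.integrate`)

**log2FC.** For each replicate at timepoint *t*, the fold change is
`log2(v_t,r) − mean_r log2(v_0,r)` against the 0 h reference of the same
assay. Zeros are treated as missing replicates (no pseudocount); features
with an entirely missing reference are dropped. The SEM is the sample
standard deviation over replicates divided by √n.

**Thermal shift.** `TS = PISA log2FC − abundance log2FC`, computed per
feature and timepoint on the inner join of the two tables; SEMs combine in
quadrature (independent-error approximation, conservative because both
assays share biological samples), n = min of the two.

**Phospho−protein normalization.** Site-level fold changes (abundance or TS)
minus the parent protein's, to expose occupancy changes and site-specific
stability effects. Sites without a quantified parent pass through flagged
`normalized = False` (for Δphospho−protein TS they are omitted, since an
unnormalized TS difference is not interpretable the same way).

**Categorization.** Each axis is classed `up` (log2FC ≥ 1), `down` (≤ −1) or
`unchanged`; boundary values count as regulated. The joint category is
`"<abundance>|<thermal shift>"`, with `unknown` on a missing axis and a
`complete` flag. The cutoff of 1 (two-fold) is deliberately coarse: it makes
the 3×3 map robust to the normalization artifact of §6 and matches common
practice for multiplexed proteomics effect-size thresholds.

## 3. Timecourse statistics (`pitsa.timestats`)

For a feature with replicate-by-timepoint log2FC matrix (n × T), let
d₁…d_{T−1} be the successive timepoint differences per replicate and d̄ their
mean. The statistic is Hotelling's

&nbsp;&nbsp;T² = n · d̄ᵀ S̃⁻¹ d̄,  S̃ = λ·diag(S) + (1−λ)·S,

on p = T − 1 dimensions. Successive differences remove the (arbitrary)
reference-timepoint offset and make a flat series exactly T² = 0. When
n − 1 ≥ p, λ = 0 and under normality `(n−p)/(p(n−1))·T² ~ F(p, n−p)`; the
package's null rejection rate at the F-based 0.05 cut is ≈ 0.049 over 10⁴
simulations. When n − 1 < p the sample covariance is singular, so λ is set by
the Schäfer–Strimmer analytic shrinkage estimate (variance of the off-diagonal
entries over their squared magnitude), floored at 0.1; the resulting statistic
is then a ranking score, not F-distributed. The phospho/protein ratio
T²_site / T²_parent flags sites whose dynamics exceed their parent's; it is
undefined (NaN, `ratio_ok = False`) when the parent is missing or flat.

## 4. Network propagation (`pitsa.netprop`)

**Random walk with restart.** `w ← (1−r)·Wᵀw + r·w₀` with row-stochastic W
(isolated nodes get a self-transition), restart r = 0.5 and 40 steps.
r = 0.5 keeps weight local (half the mass restarts each step, so signal
decays geometrically with path length); 40 steps is far past the (1−r)⁴⁰ ≈
10⁻¹² convergence horizon, and the iterate matches the dense closed form
`w = r(I − (1−r)Wᵀ)⁻¹ w₀` to ~10⁻¹³. Total weight is conserved at Σw =
number of seeds.

**Significance.** Node weights are z-scored against 100 degree-preserving
randomizations (double edge swaps, 10·|E| attempts, self-loops and
multi-edges rejected; if a graph admits no legal swap it is returned
unchanged with a warning). z = (w_real − mean)/sd with sample sd. Nodes are
selected at z > 10 — deliberately strict because with only 100
randomizations the empirical sd of a hub's weight is noisy and the z values
for genuinely proximal nodes are enormous (≫ 10) anyway.

**Subgraph extraction.** The induced subgraph on {z > 10} ∪ seeds, then
iterative removal of degree-1 nodes that are neither seeds nor quantified,
to fixed point. Seeds are exempt from pruning: they are the evidence the
walk started from.

## 5. Kinase-motif enrichment (`pitsa.kinlib`)

**Scoring.** A kinase PSSM covers a contiguous window of positions around the
acceptor (default −5…+4, excluding 0); the site score is the sum of log₂
odds over the flank, with the acceptor at index `len(flank)//2` (even-length
10-mers are valid). Positions falling off a short flank and padding
characters (`X`, `_`) contribute 0 (odds 1, neutral).

**Percentiles and favorability.** Each kinase's scores are converted to
percentiles against the full site background: `100·|{background ≤ s}|/N`
(the "≤" convention, so the background maximum maps to exactly 100). For
each site the top-k kinases by percentile (default k = 15 for genome-scale
PSSM libraries; use k = 1–2 for small libraries) are "favorable"; percentile
ties are broken alphabetically by kinase name via a stable sort, making
results order-independent and reproducible.

**Enrichment.** For each kinase and direction, the 2×2 table counts
favorable/unfavorable sites among regulated (up: log2FC ≥ 1; down: ≤ −1;
boundary regulated) versus unregulated sites. The one-sided p-value is the
exact hypergeometric tail `P(X ≥ a)` (`scipy.stats.hypergeom.sf(a−1, …)`),
verified against full integer enumeration for every table with row margins
≤ 20 (53,360 tables, max |Δ| ≈ 3 × 10⁻¹⁶). The effect size is the
Haldane-corrected frequency factor
`log2[((a+½)/(a+b+1)) / ((c+½)/(c+d+1))]`, finite for zero cells. P-values
are Benjamini–Hochberg adjusted within each direction
(`statsmodels.stats.multitest.multipletests`), default α = 0.1. For each
kinase the more significant direction is flagged `selected_direction`;
kinases significant in both directions are flagged `dual_significant` (a sign
of background misspecification rather than biology).

## 6. Synthetic data (`pitsa.synthdata`)

The generators emulate the *structure* of a PITSA experiment, not mass
spectrometry physics:

- Per-protein lognormal baselines (ln-mean ln 500, σ = 1), soluble fraction
  U(0.3, 0.9), linear effect ramps from 0 h to the final timepoint,
  multiplicative lognormal noise with mean 1 at a given CV, Dirichlet splits
  of protein signal over PSMs, and the vendor-style impurity matrix (92 %
  main channel, 3 %/4 % to the −1/+1 neighbors). PISA channels observe
  `baseline · soluble_fraction · 2^TS`.
- Not modeled: peptide ionization efficiency, co-isolation interference,
  missing-value mechanisms correlated with intensity, temperature-gradient
  melting curves (PISA integrates over them by design), or ratio
  compression.
- Network fixtures use `networkx` planted-partition graphs and two-clique
  constructions; motif fixtures draw baseline PSSM odds lognormal(0, 0.25)
  (continuous scores avoid massive ties) and plant signature residues at
  three window positions with odds 8, at a chosen penetrance among
  upregulated sites.

Every generator returns a ground-truth manifest (JSON-serializable) so tests
and the acceptance script can score recovery without reference to how the
data were made.

**Known artifact: compositional shift.** Column-sum channel normalization
forces each timepoint's channels to the same total. If many features truly
change in one direction, the normalization subtracts the mean log-total
change from *every* feature's fold change. In the planted-category fixture
this shift is bounded (the planted effects are balanced across categories)
and stays inside the ±1 category margin; recovery at 10 % CV with 100
features per category is ≥ 96 %. On tiny, unbalanced fixtures (a handful of
features) the shift can dominate — zero-noise unit tests therefore skip
normalization, and real analyses should ensure the feature set is large
enough that the unchanged majority anchors the column sums. This is the
standard compositional caveat of equal-loading normalization, not specific
to this implementation.

## 7. Numerical and design choices

- All linear algebra is delegated to NumPy/SciPy (LAPACK); p-values to
  `scipy.stats`; multiple-testing to `statsmodels`; graph machinery to
  `networkx`. The package's own code is the experiment logic, not numerics.
- Edge-swap randomization is hand-rolled (≈ 20 lines) because the library
  equivalent raises on swap-poor graphs instead of degrading gracefully.
- All stochastic functions take explicit integer seeds or `Generator`
  objects; multi-randomization routines spawn child seeds via
  `numpy.random.SeedSequence` so results are reproducible and independent.
- APIs are plain functions over `pandas` DataFrames plus small frozen
  dataclasses for structured inputs (designs, impurity matrices, PSSMs);
  validation errors name the offending field, channel or site.

## 8. Limitations

- The F-calibration of T² holds only in the λ = 0 regime; shrunken
  statistics are rankings.
- SEM quadrature for thermal shifts ignores the covariance induced by shared
  samples (conservative).
- The z > 10 propagation threshold is tuned for ~100 randomizations; with
  many more randomizations a calibrated empirical p-value would be
  preferable.
- Percentile favorability is relative to the analyzed site set; enrichment
  conclusions depend on that background being representative.
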