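# pitsa

Analysis toolkit for **P**hosphorylation **I**ntegrated **T**hermal **S**hift
**A**ssays: paired TMT abundance / PISA (Proteome Integral Solubility
Alteration) experiments that follow a stimulation timecourse at both the
protein and the phosphosite level.

## Science

A PISA experiment heats aliquots of each sample across a temperature gradient,
pools them, and quantifies the remaining *soluble* protein by multiplexed
TMT reporter ions. A protein whose thermal stability changes on stimulation —
through ligand binding, complex assembly, or a phosphorylation event — changes
its soluble fraction even when its total abundance does not. Running an
abundance multiplex and a PISA multiplex on the same samples therefore
separates two regulatory axes:

- **abundance log2FC** — how much of the protein there is, relative to the
  unstimulated (0 h) reference, and
- **thermal-shift log2FC** — the PISA fold change *minus* the abundance fold
  change, isolating the solubility/stability component.

`pitsa` implements the full computational chain:

1. **`pitsa.quantify`** — reporter-ion processing: isotopic impurity
   correction (solve the reagent mixing matrix, not just subtract), channel
   normalization to equal column sums, aggregation of PSMs to proteins or
   localized phosphosites, scaling of each feature row to a total of 100, and
   a limit-of-quantification filter on the summed raw signal-to-noise.
2. **`pitsa.integrate`** — replicate-level log2 fold changes versus 0 h with
   SEMs, thermal shifts with error propagation in quadrature,
   phosphosite-minus-parent-protein normalization (both for abundance and for
   thermal shift), and a 3×3 categorization (up/unchanged/down on each axis,
   cutoff |log2FC| ≥ 1, with `unknown` when one axis is missing).
3. **`pitsa.timestats`** — a Hotelling T² statistic on successive timepoint
   differences, with analytic covariance shrinkage toward the diagonal when
   replicates are scarce, plus phospho-versus-protein T² ratios to find sites
   whose dynamics exceed their parent protein's.
4. **`pitsa.netprop`** — random-walk-with-restart propagation of a regulated
   seed set over a protein–protein interaction network, empirical z-scores
   against degree-preserving edge-swap randomizations, and extraction of the
   significant subgraph with pruning of peripheral unquantified nodes.
5. **`pitsa.kinlib`** — kinase position-specific scoring matrices (PSSMs)
   over site flanking sequences, percentile ranking against the site
   background, top-k favorability, and directional Fisher enrichment of each
   kinase's favorable set in up- versus down-regulated sites with
   Haldane-corrected frequency factors and Benjamini–Hochberg adjustment.
6. **`pitsa.synthdata`** — synthetic experiment generators with ground-truth
   manifests for every stage: planted abundance/thermal-shift categories,
   planted network communities, and planted kinase motifs. These drive the
   test suite and the acceptance script.

## Worked example

Simulate a small experiment with four proteins planted in each of the nine
abundance × thermal-shift categories, then run the quantification and
integration stages and recover the categories:

```python
from pitsa import quantify as q, integrate as it, synthdata as sd

truth, expected = sd.category_truth(n_per_category=4, effect_log2=2.0,
                                    noise_cv=0.1, rng_seed=11)
sim = sd.simulate_pitsa(truth)

tbl = q.correct_impurities(sim.protein_psms, sim.impurity)
tbl = q.normalize_channels(tbl, sim.design)
fq = q.aggregate_features(tbl, "protein")
print(fq.data.iloc[:3, :5].round(3))
```

```text
            ab_0h_r1  ab_0h_r2  ab_0h_r3  ab_0h_r4  ab_4h_r1
feature_id
PROT0000       4.495     4.499     4.635     4.558     3.693
PROT0001       6.042     5.248     5.278     5.532     4.000
PROT0002       3.804     3.713     3.532     3.834     2.981
```

Each feature row sums to 100 across its assay's channels. Now compute fold
changes, thermal shifts and categories at 24 h:

```python
ab = it.log2fc(fq, sim.design, "abundance")
ts = it.thermal_shift(it.log2fc(fq, sim.design, "pisa"), ab)
cats = it.categorize(ab, ts).query("timepoint_h == 24")
print(it.category_counts(cats))
```

```text
category
down|down              4
down|unchanged         4
down|up                4
unchanged|down         4
unchanged|unchanged    4
unchanged|up           4
up|down                4
up|unchanged           4
up|up                  4
```

All 36 planted proteins land in their true category at 10 % noise.

### Kinase enrichment

Plant one kinase's motif into 30 % of the upregulated sites of a 2,250-site
library and test every kinase's favorable set for directional enrichment:

```python
from pitsa import kinlib as kl

pssms, sites, truth = sd.simulate_motifs(n_background=2000, n_up=200,
                                         n_down=50, penetrance=0.3,
                                         rng_seed=11)
scores = kl.score_sites(pssms, sites["flank"])
pct, fav = kl.rank_kinases(scores, top_k=1)
enr = kl.enrich(fav, sites["logfc"], alpha_adj=0.1)
print(enr[enr.direction == "up"].sort_values("adjusted_p")
      [["kinase", "a", "b", "c", "d", "p_value", "adjusted_p",
        "frequency_factor"]].to_string(index=False))
```

```text
kinase  a   b   c    d      p_value   adjusted_p  frequency_factor
  KIN1 80 120 331 1669 1.008473e-13 5.042363e-13          1.273506
  KIN2 28 172 419 1581 9.939450e-01 9.999295e-01         -0.564183
  KIN3 35 165 400 1600 8.258405e-01 9.999295e-01         -0.180458
  KIN4 24 176 454 1546 9.999295e-01 9.999295e-01         -0.897973
  KIN5 33 167 396 1604 8.897632e-01 9.999295e-01         -0.249634
```

The planted kinase (`KIN1`) is recovered at adjusted p ≈ 5 × 10⁻¹³ with a
frequency factor of 1.27 (its motif is 2.4-fold over-represented among
upregulated sites); all other kinases are null.

### Command line

The same stages are available as a CLI:

```sh
pitsa simulate --n-per-category 25 --rng-seed 4 --out-dir fix/
pitsa quantify  --psms fix/protein_psms.tsv --design fix/design.tsv \
                --impurity fix/impurity.tsv --kind protein --out quant.tsv
pitsa integrate --protein-quant quant.tsv --design fix/design.tsv \
                --out-dir integrated/
```

`pitsa --help` lists all six subcommands (`quantify`, `integrate`,
`timestats`, `netprop`, `kinenrich`, `simulate`).

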