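"""Synthetic paired abundance/PISA experiments with recorded ground truth.

Generates every input the pipeline consumes — PSM reporter tables for a
protein run and a phospho-enriched run sharing one plex design, the
channel design, a vendor-like isotopic-impurity matrix, planted-partition
interaction networks, and synthetic kinase PSSMs with planted motifs — all
from a single seed, with the planted truth emitted as a manifest so every
downstream stage has a closed-loop test.

The default experiment mirrors a T-cell-activation-style design: five
timepoints (0, 4, 6, 8, 24 h) x four replicates x two assays in one plex,
log-normal multiplicative reporter noise, and effects that ramp in late in
the timecourse.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .kinlib import AMINO_ACIDS, KinasePssm
from .quantify import ImpurityMatrix, PhosphoSite, ReporterTable, SampleDesign

DEFAULT_TIMEPOINTS = (0.0, 4.0, 6.0, 8.0, 24.0)
DEFAULT_N_REPLICATES = 4
DEFAULT_NOISE_CV = 0.10


@dataclass(frozen=True)
class ProteinTruth:
    """Planted truth for one protein: baseline total S:N, PISA soluble
    fraction at 0 h, and per-timepoint true log2 fold changes in abundance
    and thermal shift."""

    baseline: float
    soluble_fraction: float
    abundance_fc: tuple[float, ...]
    ts_fc: tuple[float, ...]
    n_psms: int = 3


@dataclass(frozen=True)
class SiteTruth:
    """Planted truth for one phosphosite: parent protein, site identity,
    relative abundance, and per-timepoint occupancy / thermal-shift effects
    beyond the parent protein's."""

    protein: str
    residue: str
    position: int
    rel_abundance: float
    occupancy_fc: tuple[float, ...]
    delta_ts: tuple[float, ...]
    loc_score: float = 25.0


@dataclass
class TruthModel:
    """Complete generative description of a synthetic experiment."""

    proteins: dict[str, ProteinTruth]
    sites: dict[str, SiteTruth] = field(default_factory=dict)
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = DEFAULT_N_REPLICATES
    noise_cv: float = DEFAULT_NOISE_CV
    impurity: str = "vendor"  # "vendor" or "identity"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.impurity not in ("vendor", "identity"):
            raise ValueError(f"unknown impurity model {self.impurity!r}")
        if 0.0 not in self.timepoints:
            raise ValueError("timepoints must include the 0 h reference")
        T = len(self.timepoints)
        for name, p in self.proteins.items():
            for fld in ("abundance_fc", "ts_fc"):
                if len(getattr(p, fld)) != T:
                    raise ValueError(f"protein {name}: {fld} must have {T} entries")
            if not 0 < p.soluble_fraction <= 1:
                raise ValueError(f"protein {name}: soluble_fraction must lie in (0, 1]")
        for name, s in self.sites.items():
            if s.protein not in self.proteins:
                raise ValueError(f"site {name}: unknown parent protein {s.protein!r}")
            for fld in ("occupancy_fc", "delta_ts"):
                if len(getattr(s, fld)) != T:
                    raise ValueError(f"site {name}: {fld} must have {T} entries")

    def manifest(self) -> dict:
        """JSON-serializable record of every planted effect."""
        return {
            "timepoints": list(self.timepoints),
            "n_replicates": self.n_replicates,
            "noise_cv": self.noise_cv,
            "impurity": self.impurity,
            "rng_seed": self.rng_seed,
            "proteins": {k: dataclasses.asdict(v) for k, v in self.proteins.items()},
            "sites": {k: dataclasses.asdict(v) for k, v in self.sites.items()},
        }


@dataclass
class SimulatedExperiment:
    protein_psms: ReporterTable
    phospho_psms: ReporterTable
    design: SampleDesign
    impurity: ImpurityMatrix
    truth: TruthModel


def _ramp(final: float, timepoints) -> tuple[float, ...]:
    """Effect trajectory rising linearly with time to its 24 h value."""
    tmax = max(timepoints)
    return tuple(final * t / tmax for t in timepoints)


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def make_design(
    timepoints=DEFAULT_TIMEPOINTS, n_replicates: int = DEFAULT_N_REPLICATES
) -> SampleDesign:
    """One-plex design: a channel per (assay, timepoint, replicate)."""
    rows = [
        {
            "channel": f"{assay[:2]}_{t:g}h_r{r}",
            "timepoint_h": t,
            "assay": assay,
            "replicate": r,
        }
        for assay in ("abundance", "pisa")
        for t in timepoints
        for r in range(1, n_replicates + 1)
    ]
    return SampleDesign(pd.DataFrame(rows))


def vendor_impurity(channels) -> ImpurityMatrix:
    """Vendor-product-sheet-like impurity matrix: 92% of each reagent in
    its own channel, 3% spilling one channel down and 4% one up."""
    n = len(channels)
    m = np.zeros((n, n))
    for i in range(n):
        m[i, i] = 0.92
        if i > 0:
            m[i, i - 1] = 0.03
        if i < n - 1:
            m[i, i + 1] = 0.04
    return ImpurityMatrix(pd.DataFrame(m, index=list(channels), columns=list(channels)))


def simulate_pitsa(truth: TruthModel) -> SimulatedExperiment:
    """Generate the paired protein and phospho PSM tables for a truth model.

    Per channel, a protein's abundance value is
    ``baseline x 2^abundance_fc(t) x noise`` and its PISA value additionally
    carries ``soluble_fraction x 2^ts_fc(t)``; phosphosite peptides are
    modulated further by their occupancy and delta-TS trajectories. Each
    protein's total splits over its PSMs with fixed per-protein fractions,
    and the true signal is mixed through the impurity matrix to produce the
    observed reporter values. Same seed, byte-identical output.
    """
    rng = np.random.default_rng(truth.rng_seed)
    design = make_design(truth.timepoints, truth.n_replicates)
    channels = design.channels
    impurity = (
        vendor_impurity(channels)
        if truth.impurity == "vendor"
        else ImpurityMatrix.identity(channels)
    )
    meta = design.table.set_index("channel")
    tp_index = {t: i for i, t in enumerate(truth.timepoints)}
    ch_t = np.array([tp_index[t] for t in meta.loc[channels, "timepoint_h"]])
    ch_pisa = (meta.loc[channels, "assay"] == "pisa").to_numpy()

    def channel_values(base: float, fc, ts, soluble: float, n_rows: int) -> np.ndarray:
        """base x 2^fc(t), with PISA channels further scaled by the soluble
        fraction and 2^ts(t), times per-channel log-normal noise."""
        vals = base * np.exp2(np.asarray(fc)[ch_t])
        vals = np.where(ch_pisa, vals * soluble * np.exp2(np.asarray(ts)[ch_t]), vals)
        return vals[None, :] * _noise(rng, truth.noise_cv, (n_rows, len(channels)))

    prot_rows = []
    for name in truth.proteins:
        p = truth.proteins[name]
        vals = channel_values(p.baseline, p.abundance_fc, p.ts_fc, p.soluble_fraction, p.n_psms)
        frac = rng.dirichlet(np.full(p.n_psms, 5.0))
        for k in range(p.n_psms):
            prot_rows.append((f"PEP_{name}_{k + 1}", name, []) + tuple(vals[k] * frac[k]))

    phos_rows = []
    for site_id in truth.sites:
        s = truth.sites[site_id]
        p = truth.proteins[s.protein]
        vals = channel_values(
            p.baseline * s.rel_abundance,
            np.asarray(p.abundance_fc) + np.asarray(s.occupancy_fc),
            np.asarray(p.ts_fc) + np.asarray(s.delta_ts),
            p.soluble_fraction,
            1,
        )
        phos_rows.append(
            (
                f"PEP_{site_id}",
                s.protein,
                [PhosphoSite(s.residue, s.position, s.loc_score)],
            )
            + tuple(vals[0])
        )

    cols = ["peptide", "protein", "phosphosites"] + channels
    mix = impurity.matrix.loc[channels, channels].to_numpy()

    def to_table(rows) -> ReporterTable:
        df = pd.DataFrame(rows, columns=cols)
        df[channels] = df[channels].to_numpy() @ mix
        return ReporterTable(df, list(channels))

    return SimulatedExperiment(
        protein_psms=to_table(prot_rows),
        phospho_psms=to_table(phos_rows),
        design=design,
        impurity=impurity,
        truth=truth,
    )


def null_truth(
    n_proteins: int = 50,
    noise_cv: float = 0.0,
    rng_seed: int = 0,
    impurity: str = "vendor",
    timepoints=DEFAULT_TIMEPOINTS,
    n_replicates: int = DEFAULT_N_REPLICATES,
) -> TruthModel:
    """All effects zero: every downstream fold change is pure noise (and
    exactly 0 at CV = 0)."""
    rng = np.random.default_rng(rng_seed)
    zero = tuple(0.0 for _ in timepoints)
    proteins = {
        f"PROT{i:04d}": ProteinTruth(
            baseline=float(rng.lognormal(math.log(500.0), 1.0)),
            soluble_fraction=float(rng.uniform(0.3, 0.9)),
            abundance_fc=zero,
            ts_fc=zero,
        )
        for i in range(n_proteins)
    }
    return TruthModel(
        proteins=proteins,
        timepoints=timepoints,
        n_replicates=n_replicates,
        noise_cv=noise_cv,
        impurity=impurity,
        rng_seed=rng_seed + 1,
    )


CATEGORY_DIRECTIONS = [(a, t) for a in (-1, 0, 1) for t in (-1, 0, 1)]
_CLASS = {-1: "down", 0: "unchanged", 1: "up"}


def category_truth(
    n_per_category: int = 100,
    effect_log2: float = 2.0,
    noise_cv: float = DEFAULT_NOISE_CV,
    rng_seed: int = 0,
    impurity: str = "vendor",
    timepoints=DEFAULT_TIMEPOINTS,
    n_replicates: int = DEFAULT_N_REPLICATES,
) -> tuple[TruthModel, dict[str, str]]:
    """Proteins planted into each of the nine behaviour categories.

    Abundance and thermal-shift effects of +-``effect_log2`` (or 0) ramp to
    their full size at the last timepoint. Returns the truth model and the
    expected ``abundance_class|ts_class`` category per protein at 24 h.
    """
    rng = np.random.default_rng(rng_seed)
    proteins: dict[str, ProteinTruth] = {}
    expected: dict[str, str] = {}
    i = 0
    for a_dir, t_dir in CATEGORY_DIRECTIONS:
        for _ in range(n_per_category):
            name = f"PROT{i:04d}"
            proteins[name] = ProteinTruth(
                baseline=float(rng.lognormal(math.log(500.0), 1.0)),
                soluble_fraction=float(rng.uniform(0.3, 0.9)),
                abundance_fc=_ramp(a_dir * effect_log2, timepoints),
                ts_fc=_ramp(t_dir * effect_log2, timepoints),
            )
            expected[name] = f"{_CLASS[a_dir]}|{_CLASS[t_dir]}"
            i += 1
    truth = TruthModel(
        proteins=proteins,
        timepoints=timepoints,
        n_replicates=n_replicates,
        noise_cv=noise_cv,
        impurity=impurity,
        rng_seed=rng_seed + 1,
    )
    return truth, expected


def default_truth(
    n_proteins: int = 200,
    frac_late_up: float = 0.3,
    frac_ts: float = 0.1,
    n_sites: int = 100,
    frac_occupancy: float = 0.3,
    frac_delta_ts: float = 0.15,
    effect_log2: float = 2.0,
    noise_cv: float = DEFAULT_NOISE_CV,
    rng_seed: int = 0,
    impurity: str = "vendor",
    timepoints=DEFAULT_TIMEPOINTS,
    n_replicates: int = DEFAULT_N_REPLICATES,
) -> TruthModel:
    """A realistic mixed experiment: a late-rising upregulated fraction of
    the proteome, a sprinkling of thermal shifts, and phosphosites with
    planted occupancy changes and phospho-specific thermal shifts."""
    rng = np.random.default_rng(rng_seed)
    zero = tuple(0.0 for _ in timepoints)
    proteins: dict[str, ProteinTruth] = {}
    names = [f"PROT{i:04d}" for i in range(n_proteins)]
    for name in names:
        up = rng.random() < frac_late_up
        ts = rng.random() < frac_ts
        proteins[name] = ProteinTruth(
            baseline=float(rng.lognormal(math.log(500.0), 1.0)),
            soluble_fraction=float(rng.uniform(0.3, 0.9)),
            abundance_fc=_ramp(effect_log2, timepoints) if up else zero,
            ts_fc=_ramp(float(rng.choice([-1, 1])) * effect_log2, timepoints) if ts else zero,
        )
    sites: dict[str, SiteTruth] = {}
    for _ in range(n_sites):
        parent = str(rng.choice(names))
        res = str(rng.choice(list("STY"), p=[0.8, 0.15, 0.05]))
        pos = int(rng.integers(5, 500))
        site_id = f"{parent}_{res}{pos}"
        if site_id in sites:
            continue
        occ = rng.random() < frac_occupancy
        dts = rng.random() < frac_delta_ts
        sites[site_id] = SiteTruth(
            protein=parent,
            residue=res,
            position=pos,
            rel_abundance=float(rng.uniform(0.05, 0.5)),
            occupancy_fc=_ramp(float(rng.choice([-1, 1])) * effect_log2, timepoints)
            if occ
            else zero,
            delta_ts=_ramp(float(rng.choice([-1, 1])) * effect_log2, timepoints) if dts else zero,
        )
    return TruthModel(
        proteins=proteins,
        sites=sites,
        timepoints=timepoints,
        n_replicates=n_replicates,
        noise_cv=noise_cv,
        impurity=impurity,
        rng_seed=rng_seed + 1,
    )


def simulate_ppi(
    n_nodes: int = 120,
    n_communities: int = 4,
    p_in: float = 0.5,
    p_out: float = 0.02,
    rng_seed: int = 0,
    quantified_frac: float = 0.8,
) -> tuple[nx.Graph, dict]:
    """Planted-partition interaction network.

    Nodes split evenly into communities; within-community edges appear with
    probability ``p_in``, between-community edges with ``p_out``. Node
    attributes record the planted ``community`` and a random ``quantified``
    flag. Returns the graph and a truth dict (community members, params).
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    size = n_nodes // n_communities
    g = nx.planted_partition_graph(n_communities, size, p_in, p_out, seed=rng_seed)
    rng = np.random.default_rng(rng_seed)
    mapping = {i: f"GENE{i:04d}" for i in g.nodes}
    communities = {
        f"C{c}": [mapping[i] for i in g.nodes if g.nodes[i]["block"] == c]
        for c in range(n_communities)
    }
    g = nx.relabel_nodes(g, mapping)
    for n in g.nodes:
        g.nodes[n]["community"] = f"C{g.nodes[n].pop('block')}"
        g.nodes[n]["quantified"] = bool(rng.random() < quantified_frac)
    truth = {
        "communities": communities,
        "p_in": p_in,
        "p_out": p_out,
        "rng_seed": rng_seed,
        "quantified_frac": quantified_frac,
    }
    return g, truth


def two_clique_fixture(
    clique_size: int = 15, n_bridges: int = 2, rng_seed: int = 0
) -> tuple[nx.Graph, list[str], list[str]]:
    """Two dense cliques joined by a few bridge edges — the planted-
    community fixture for propagation tests. Returns (graph, clique-1
    members, clique-2 members); all nodes are marked quantified."""
    a = [f"A{i:02d}" for i in range(clique_size)]
    b = [f"B{i:02d}" for i in range(clique_size)]
    g = nx.Graph()
    for grp in (a, b):
        g.add_edges_from((x, y) for i, x in enumerate(grp) for y in grp[i + 1 :])
    rng = np.random.default_rng(rng_seed)
    for k in range(n_bridges):
        g.add_edge(a[int(rng.integers(clique_size))], b[int(rng.integers(clique_size))])
    nx.set_node_attributes(g, True, "quantified")
    return g, a, b


def simulate_motifs(
    n_background: int = 2000,
    n_up: int = 200,
    n_down: int = 50,
    n_kinases: int = 5,
    penetrance: float = 0.3,
    planted_kinase_index: int = 0,
    motif_odds: float = 8.0,
    window: tuple[int, int] = (-5, 4),
    rng_seed: int = 0,
) -> tuple[list[KinasePssm], pd.DataFrame, dict]:
    """Synthetic kinase PSSMs plus a site table with planted motifs.

    Each kinase prefers three distinct residues at fixed flank positions
    (odds ``motif_odds`` versus neutral 1). Background and regulated flanks
    draw residues uniformly, except that a ``penetrance`` fraction of the
    upregulated sites carries the planted kinase's preferred residues.
    Fold changes place sites at |logFC| ~ 2 (regulated) or within (-1, 1)
    (unregulated). Returns (pssms, sites, truth).
    """
    if not 0.0 <= penetrance <= 1.0:
        raise ValueError("penetrance must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    lo, hi = window
    positions = [p for p in range(lo, hi + 1) if p != 0]
    sig_positions = [lo + 2, -1, hi - 1]
    prefs = {
        k: [AMINO_ACIDS[(3 * k + 2 * j + 1) % 20] for j in range(len(sig_positions))]
        for k in range(n_kinases)
    }
    pssms = []
    for k in range(n_kinases):
        # log-normal baseline odds keep scores continuous (real matrices
        # have no exact ties); the signature residues stand far above it
        odds = pd.DataFrame(
            rng.lognormal(0.0, 0.25, size=(len(positions), 20)),
            index=positions,
            columns=list(AMINO_ACIDS),
        )
        for pos, res in zip(sig_positions, prefs[k]):
            odds.loc[pos, res] = motif_odds
        pssms.append(KinasePssm(f"KIN{k + 1}", odds))

    width = hi - lo + 1
    center = -lo

    def random_flank() -> str:
        res = rng.choice(list(AMINO_ACIDS), size=width)
        res[center] = "S"
        return "".join(res)

    def planted_flank(k: int) -> str:
        res = list(random_flank())
        for pos, aa in zip(sig_positions, prefs[k]):
            res[center + pos] = aa
        return "".join(res)

    n_planted = int(round(penetrance * n_up))
    rows = []
    for i in range(n_up):
        planted = i < n_planted
        flank = planted_flank(planted_kinase_index) if planted else random_flank()
        rows.append((f"UP{i:04d}", flank, float(np.clip(rng.normal(2.0, 0.3), 1.0, None)), planted))
    for i in range(n_down):
        rows.append(
            (f"DN{i:04d}", random_flank(), float(np.clip(rng.normal(-2.0, 0.3), None, -1.0)), False)
        )
    for i in range(n_background):
        rows.append((f"BG{i:04d}", random_flank(), float(rng.uniform(-0.9, 0.9)), False))
    sites = pd.DataFrame(rows, columns=["site_id", "flank", "logfc", "planted"]).set_index(
        "site_id"
    )
    truth = {
        "planted_kinase": pssms[planted_kinase_index].name,
        "penetrance": penetrance,
        "n_planted": n_planted,
        "signature_positions": sig_positions,
        "preferred_residues": prefs,
        "rng_seed": rng_seed,
    }
    return pssms, sites, truth
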