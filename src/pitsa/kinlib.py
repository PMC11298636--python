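"""Kinase substrate-motif scoring and directional enrichment.

Phosphosites are scored against kinase position-specific scoring matrices
(PSSMs) over the flanking sequence of the phosphoacceptor, percentile-ranked
against the detected-phosphoproteome background per kinase, and the top-k
kinases per site are called *favorable*. Enrichment of each kinase's
favored sites among up- or down-regulated phosphosites is tested with a
one-sided Fisher's exact test plus a Haldane-corrected log2 frequency
factor, with Benjamini-Hochberg adjustment across kinases per direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Characters that mean "no residue" (sequence terminus padding / unknown);
#: they contribute neutral odds of 1 to a motif score.
PADDING = frozenset("X_")

DEFAULT_TOP_K = 15
DEFAULT_FC_UP = 1.0
DEFAULT_FC_DOWN = -1.0
DEFAULT_ALPHA_ADJ = 0.1


@dataclass
class KinasePssm:
    """Positive odds weights over flank positions x residues.

    ``odds`` is indexed by integer positions relative to the
    phosphoacceptor (position 0 itself excluded; default window -5..+4)
    with the 20 amino acids as columns. Scoring sums log2 odds, so an
    entry of 1 is neutral.
    """

    name: str
    odds: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.odds.to_numpy(dtype=float) <= 0).any():
            raise ValueError(f"PSSM {self.name}: all odds must be > 0")
        pos = sorted(int(p) for p in self.odds.index)
        if 0 in pos:
            raise ValueError(f"PSSM {self.name}: position 0 (phosphoacceptor) must be excluded")
        expect = [p for p in range(pos[0], pos[-1] + 1) if p != 0]
        if pos != expect:
            raise ValueError(f"PSSM {self.name}: positions must be contiguous around 0, got {pos}")
        missing = sorted(set(AMINO_ACIDS) - set(self.odds.columns))
        if missing:
            raise ValueError(f"PSSM {self.name}: missing residue columns {missing}")
        self.odds = self.odds.loc[pos, list(AMINO_ACIDS)].astype(float)

    @property
    def positions(self) -> list[int]:
        return [int(p) for p in self.odds.index]

    @classmethod
    def from_long(cls, name: str, table: pd.DataFrame) -> "KinasePssm":
        """Build from long format (position, residue, odds); absent cells
        default to neutral odds 1."""
        wide = table.pivot(index="position", columns="residue", values="odds")
        pos = sorted(int(p) for p in wide.index)
        full = pd.DataFrame(1.0, index=pos, columns=list(AMINO_ACIDS))
        full.update(wide)
        return cls(name, full)


def score_site(pssm: KinasePssm, flank: str, site_id: str | None = None) -> float:
    """Log2-odds motif score of a flank sequence.

    The phosphoacceptor sits at index ``len(flank) // 2`` (for the default
    -5..+4 window that is a 10-mer with five residues before the acceptor
    and four after). Window positions falling off the flank, or covered by
    padding characters, contribute 0 (neutral odds). A non-padding residue
    outside the amino acid alphabet is an error naming the site.
    """
    center = len(flank) // 2
    logodds = np.log2(pssm.odds.to_numpy())
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    score = 0.0
    for row, pos in enumerate(pssm.positions):
        i = center + pos
        if not 0 <= i < len(flank):
            continue
        res = flank[i]
        if res in PADDING:
            continue
        if res not in aa_index:
            where = site_id or flank
            raise ValueError(f"residue {res!r} outside amino-acid alphabet in site {where}")
        score += logodds[row, aa_index[res]]
    return score


def score_sites(pssms: list[KinasePssm], flanks: pd.Series) -> pd.DataFrame:
    """Score every site against every kinase; sites x kinases DataFrame."""
    out = {}
    for pssm in pssms:
        logodds = np.log2(pssm.odds.to_numpy())
        aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
        scores = np.zeros(len(flanks))
        for k, (sid, flank) in enumerate(flanks.items()):
            center = len(flank) // 2
            s = 0.0
            for row, pos in enumerate(pssm.positions):
                i = center + pos
                if 0 <= i < len(flank):
                    res = flank[i]
                    if res in PADDING:
                        continue
                    if res not in aa_index:
                        raise ValueError(
                            f"residue {res!r} outside amino-acid alphabet in site {sid}"
                        )
                    s += logodds[row, aa_index[res]]
            scores[k] = s
        out[pssm.name] = scores
    return pd.DataFrame(out, index=flanks.index)


def percentile_scores(scores: pd.DataFrame, background: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-kinase percentile of each site's score within the background
    score distribution (default: the scored sites themselves).

    Percentile = 100 x |{background scores <= site score}| / |background|,
    so a site matching the background maximum scores 100 and tied scores
    share a percentile. Invariant under strictly monotone transforms of a
    kinase's scores.
    """
    if background is None:
        background = scores
    out = {}
    for kin in scores.columns:
        bg = np.sort(background[kin].to_numpy())
        ranks = np.searchsorted(bg, scores[kin].to_numpy(), side="right")
        out[kin] = 100.0 * ranks / len(bg)
    return pd.DataFrame(out, index=scores.index)


def favorability(percentiles: pd.DataFrame, top_k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """Boolean sites x kinases matrix: the ``top_k`` kinases by percentile
    are favorable for each site. Boundary ties break deterministically by
    kinase name (ascending), truncating the favorable set to exactly
    ``top_k``."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    kin_order = np.argsort(percentiles.columns.to_numpy())  # alphabetical tie-break
    cols = percentiles.columns.to_numpy()[kin_order]
    vals = percentiles.to_numpy()[:, kin_order]
    fav = np.zeros_like(vals, dtype=bool)
    # stable sort on negated percentile keeps alphabetical order within ties
    order = np.argsort(-vals, axis=1, kind="stable")[:, :top_k]
    np.put_along_axis(fav, order, True, axis=1)
    out = pd.DataFrame(fav, index=percentiles.index, columns=cols)
    return out[list(percentiles.columns)]


def rank_kinases(
    scores: pd.DataFrame,
    background: pd.DataFrame | None = None,
    top_k: int = DEFAULT_TOP_K,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentile-rank kinases per site and call the top-k favorable.

    Returns ``(percentiles, favorable)``, both sites x kinases.
    """
    pct = percentile_scores(scores, background)
    return pct, favorability(pct, top_k=top_k)


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment tail) Fisher's exact p for the 2x2 table
    [[a, b], [c, d]]: the hypergeometric probability of a or more favored
    sites among the regulated set given the margins."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("contingency cells must be non-negative integers")
    return float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def frequency_factor(a: int, b: int, c: int, d: int) -> float:
    """Haldane-corrected log2 ratio of favored-site fractions: regulated
    (a of a+b) versus unregulated (c of c+d), +0.5 per cell so zero cells
    stay finite."""
    return float(np.log2(((a + 0.5) / (a + b + 1.0)) / ((c + 0.5) / (c + d + 1.0))))


def enrich(
    favorable: pd.DataFrame,
    logfc: pd.Series,
    fc_up: float = DEFAULT_FC_UP,
    fc_down: float = DEFAULT_FC_DOWN,
    alpha_adj: float = DEFAULT_ALPHA_ADJ,
) -> pd.DataFrame:
    """Directional kinase-motif enrichment among regulated phosphosites.

    Sites partition by ``logfc``: up (>= ``fc_up``), down (<= ``fc_down``)
    and unregulated (strictly between). Per kinase and direction a 2x2
    table (a = regulated & favored, b = regulated & not, c = unregulated &
    favored, d = unregulated & not) yields a one-sided Fisher p on the raw
    integer counts and a Haldane-corrected log2 frequency factor; p-values
    are BH-adjusted across kinases within each direction. Per kinase the
    more significant direction is selected; ``dual_significant`` marks
    kinases significant (adjusted p <= ``alpha_adj``) in both directions.
    """
    fc = logfc.reindex(favorable.index)
    if fc.isna().any():
        missing = list(fc.index[fc.isna()])[:5]
        raise ValueError(f"sites without fold changes, e.g. {missing}")
    groups = {
        "up": fc >= fc_up,
        "down": fc <= fc_down,
    }
    unreg = (fc > fc_down) & (fc < fc_up)
    if int(unreg.sum()) == 0:
        raise ValueError("unregulated site set is empty")
    rows = []
    for direction, reg in groups.items():
        if int(reg.sum()) == 0:
            raise ValueError(f"regulated ({direction}) site set is empty")
        for kin in favorable.columns:
            fav = favorable[kin]
            a = int((reg & fav).sum())
            b = int((reg & ~fav).sum())
            c = int((unreg & fav).sum())
            d = int((unreg & ~fav).sum())
            rows.append(
                {
                    "kinase": kin,
                    "direction": direction,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "frequency_factor": frequency_factor(a, b, c, d),
                    "p_value": fisher_one_sided(a, b, c, d),
                }
            )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = np.nan
    for direction in groups:
        sel = out["direction"] == direction
        out.loc[sel, "adjusted_p"] = multipletests(
            out.loc[sel, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    # per kinase: pick the more significant direction (ties favor "up")
    best = (
        out.sort_values(["adjusted_p", "direction"], ascending=[True, False])
        .groupby("kinase")
        .head(1)[["kinase", "direction"]]
    )
    best_pairs = set(map(tuple, best.to_numpy()))
    out["selected_direction"] = [
        (k, dr) in best_pairs for k, dr in zip(out["kinase"], out["direction"])
    ]
    sig = out[out["adjusted_p"] <= alpha_adj].groupby("kinase")["direction"].nunique()
    dual = set(sig[sig == 2].index)
    out["dual_significant"] = out["kinase"].isin(dual)
    return out.sort_values(["direction", "adjusted_p", "kinase"], ignore_index=True)
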