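"""Hotelling-T2 timecourse statistics.

Scores how dynamically a feature (protein or phosphosite) changes across a
timecourse: the successive timepoint differences of each replicate series
form a (T-1)-dimensional observation, and a one-sample Hotelling T2 on
their mean — against a covariance shrunk toward its diagonal when the
replicate count is too small — measures departure from a flat trajectory.
The ratio of a phosphosite's T2 to its parent protein's T2 separates
stoichiometry changes (site dynamics beyond the protein's) from
abundance-driven phosphorylation changes (ratio near 1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .integrate import parent_accession
from .quantify import FeatureQuant, SampleDesign

logger = logging.getLogger(__name__)

#: Shrinkage floor applied when the difference dimension exceeds the
#: replicate degrees of freedom (guarantees an invertible covariance).
MIN_LAMBDA_UNDERDETERMINED = 0.1


def hotelling_t2(series: np.ndarray, shrinkage: float | str = "auto") -> tuple[float, float]:
    """One-sample Hotelling T2 on successive timepoint differences.

    Parameters
    ----------
    series:
        Replicate-by-timepoint matrix (n x T, n >= 2, T >= 2) of log2
        values or log2 fold changes; no missing cells.
    shrinkage:
        ``"auto"``: lambda = 0 in the classical regime (n - 1 >= T - 1),
        otherwise an analytic estimate toward the diagonal (Schafer-Strimmer
        style), floored at 0.1. A float in [0, 1] fixes lambda.

    Returns
    -------
    (t2, lam):
        ``t2 = n * dbar' S~^-1 dbar`` with ``S~ = lam*diag(S) + (1-lam)*S``
        the shrunken sample covariance of the differences; ``t2`` is NaN
        when the shrunken covariance is numerically singular.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n x T matrix with n >= 2 replicates and T >= 2 timepoints")
    if np.isnan(x).any():
        raise ValueError("timecourse matrix must have no missing cells")
    d = np.diff(x, axis=1)  # n x p successive differences
    n, p = d.shape
    dbar = d.mean(axis=0)
    s = np.atleast_2d(np.cov(d, rowvar=False, ddof=1))

    if shrinkage == "auto":
        lam = 0.0 if n - 1 >= p else max(MIN_LAMBDA_UNDERDETERMINED, _analytic_lambda(d))
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage lambda must lie in [0, 1]")
    s_shrunk = lam * np.diag(np.diag(s)) + (1.0 - lam) * s

    if not dbar.any():  # perfectly flat mean trajectory
        return 0.0, lam
    try:
        sol = np.linalg.solve(s_shrunk, dbar)
    except np.linalg.LinAlgError:
        return float("nan"), lam
    if not np.all(np.isfinite(sol)):
        return float("nan"), lam
    t2 = float(n * dbar @ sol)
    # a flat series gives dbar = 0 exactly; tiny negatives from roundoff clip to 0
    return max(t2, 0.0), lam


def _analytic_lambda(d: np.ndarray) -> float:
    """Analytic shrinkage intensity toward diag(S): ratio of the summed
    sampling variance of the off-diagonal covariances to their summed
    squares, clipped to [0, 1]."""
    n, p = d.shape
    dc = d - d.mean(axis=0)
    # w[k,i,j] = dc[k,i] * dc[k,j]; s_ij = n/(n-1) * mean_k w
    w = dc[:, :, None] * dc[:, None, :]
    wbar = w.mean(axis=0)
    var_s = n / (n - 1) ** 3 * ((w - wbar) ** 2).sum(axis=0)
    s = n / (n - 1) * wbar
    off = ~np.eye(p, dtype=bool)
    denom = (s[off] ** 2).sum()
    if denom <= 0:
        return 1.0
    return float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))


def timecourse_matrices(
    fq: FeatureQuant, design: SampleDesign, assay: str
) -> dict[str, np.ndarray]:
    """Per-feature replicate x timepoint matrices of log2FC versus 0 h.

    Replicate r's fold change at timepoint t is log2 of its channel value
    minus the mean log2 of the 0 h reference channels, so the reference
    anchors every series. Features with any unquantified (zero) cell are
    excluded and counted.
    """
    tps = design.timepoints
    cols = [design.channels_for(timepoint=t, assay=assay) for t in tps]
    n_reps = {len(c) for c in cols}
    if len(n_reps) != 1:
        raise ValueError("timecourse matrices need equal replicate counts at every timepoint")
    mats: dict[str, np.ndarray] = {}
    n_excluded = 0
    ref_cols = design.channels_for(timepoint=0.0, assay=assay)
    for fid, row in fq.data.iterrows():
        vals = np.array([[row[c] for c in cs] for cs in cols], dtype=float).T  # n x T
        if (vals <= 0).any():
            n_excluded += 1
            continue
        ref_mean = np.mean([np.log2(row[c]) for c in ref_cols])
        mats[fid] = np.log2(vals) - ref_mean
    if n_excluded:
        logger.info("timecourse: excluded %d features with missing cells", n_excluded)
    return mats


def timecourse_t2(
    matrices: dict[str, np.ndarray], shrinkage: float | str = "auto"
) -> pd.DataFrame:
    """Hotelling T2 for every feature; columns feature_id, t2, lam, ok."""
    rows = []
    for fid, mat in matrices.items():
        t2, lam = hotelling_t2(mat, shrinkage=shrinkage)
        rows.append((fid, t2, lam, np.isfinite(t2)))
    out = pd.DataFrame(rows, columns=["feature_id", "t2", "lam", "ok"])
    n_bad = int((~out["ok"]).sum()) if len(out) else 0
    if n_bad:
        logger.warning("Hotelling T2 singular for %d features (flagged)", n_bad)
    return out.sort_values("feature_id", ignore_index=True)


def t2_ratio(site_stats: pd.DataFrame, protein_stats: pd.DataFrame) -> pd.DataFrame:
    """Phosphosite T2 / parent-protein T2.

    Ratios far above 1 mark sites whose dynamics exceed the parent
    protein's (stoichiometry change). The ratio is NaN (flagged) when the
    parent is missing or its T2 is zero.
    """
    site = site_stats.copy()
    site["_parent"] = site["feature_id"].map(parent_accession)
    prot = protein_stats.rename(columns={"feature_id": "_parent", "t2": "_prot_t2"})
    merged = site.merge(prot[["_parent", "_prot_t2"]], on="_parent", how="left")
    denom_ok = merged["_prot_t2"].notna() & (merged["_prot_t2"] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom_ok, merged["t2"] / merged["_prot_t2"], np.nan)
    n_flagged = int((~denom_ok).sum())
    if n_flagged:
        logger.info("T2 ratio undefined for %d sites (missing or zero protein T2)", n_flagged)
    out = site_stats.copy()
    out["protein_t2"] = merged["_prot_t2"].to_numpy()
    out["ratio"] = ratio
    out["ratio_ok"] = denom_ok.to_numpy()
    return out
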