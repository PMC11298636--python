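"""Fold-change readouts and behavioural categorization.

The four readouts of a paired abundance/PISA experiment, all on the log2
scale versus the 0 h reference:

* protein abundance fold change,
* protein thermal shift (PISA fold change minus abundance fold change —
  solubility change with the abundance change normalized out),
* protein-normalized phosphosite abundance (site minus parent protein),
* phosphosite thermal shift and its difference from the bulk protein
  (delta phospho-protein TS), which flags phospho-subpopulations whose
  thermal stability differs from the protein pool.

Fold-change tables are long-format DataFrames with columns ``feature_id``,
``measure``, ``timepoint_h``, ``log2fc``, ``sem``, ``n`` (and, where
relevant, a ``normalized`` flag).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .quantify import FeatureQuant, SampleDesign

logger = logging.getLogger(__name__)

FC_COLUMNS = ["feature_id", "measure", "timepoint_h", "log2fc", "sem", "n"]

ABUNDANCE_CLASSES = ("down", "unchanged", "up")


def parent_accession(site_id: str) -> str:
    """Parent protein accession of an ``ACCESSION_ResiduePosition`` site id."""
    acc, _, _ = site_id.rpartition("_")
    if not acc:
        raise ValueError(f"{site_id!r} is not an accession_site feature id")
    return acc


def log2fc(fq: FeatureQuant, design: SampleDesign, assay: str, measure: str | None = None) -> pd.DataFrame:
    """Per-feature mean log2 fold change versus the 0 h reference.

    For replicate *r* at timepoint *t*, ``fc_r = log2(value_{t,r}) - m0``
    where ``m0`` is the mean of the log2 reference-channel (0 h) values.
    Channel values of zero mean "not quantified" and are excluded from the
    replicate count rather than pseudocounted. Features with no positive
    reference value are dropped (warned). Reported per timepoint: mean
    log2FC, SEM over replicates (sample sd / sqrt(n)), and n.
    """
    if measure is None:
        measure = assay
    vals = fq.data[fq.channels].to_numpy(dtype=float)
    mask = vals > 0
    with np.errstate(divide="ignore"):
        logv = np.where(mask, np.log2(np.where(mask, vals, 1.0)), np.nan)
    col_idx = {c: i for i, c in enumerate(fq.channels)}

    ref_cols = [col_idx[c] for c in design.channels_for(timepoint=0.0, assay=assay)]
    ref = logv[:, ref_cols]
    ref_n = (~np.isnan(ref)).sum(axis=1)
    ref_mean = np.where(ref_n > 0, np.nansum(ref, axis=1) / np.maximum(ref_n, 1), np.nan)
    usable = ref_n > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning("dropping %d features with all-zero 0 h reference (%s)", n_dropped, assay)

    records = []
    ids = np.asarray(fq.feature_ids)
    for t in design.timepoints:
        cols = [col_idx[c] for c in design.channels_for(timepoint=t, assay=assay)]
        fc = logv[:, cols] - ref_mean[:, None]
        n = (~np.isnan(fc)).sum(axis=1)
        mean = np.nansum(fc, axis=1) / np.maximum(n, 1)
        resid = np.where(np.isnan(fc), 0.0, fc - mean[:, None])
        var = np.where(n > 1, (resid**2).sum(axis=1) / np.maximum(n - 1, 1), np.nan)
        sem = np.sqrt(var / np.maximum(n, 1))
        keep = usable & (n > 0)
        records.append(
            pd.DataFrame(
                {
                    "feature_id": ids[keep],
                    "measure": measure,
                    "timepoint_h": float(t),
                    "log2fc": mean[keep],
                    "sem": sem[keep],
                    "n": n[keep],
                }
            )
        )
    out = pd.concat(records, ignore_index=True) if records else pd.DataFrame(columns=FC_COLUMNS)
    return out.sort_values(["feature_id", "timepoint_h"], ignore_index=True)


def thermal_shift(pisa_fc: pd.DataFrame, abundance_fc: pd.DataFrame, measure: str = "thermal_shift") -> pd.DataFrame:
    """Thermal shift = PISA log2FC minus abundance log2FC, per feature and
    timepoint; SEMs combine in quadrature. Features or timepoints present in
    only one input are omitted (counted in the log)."""
    merged = pisa_fc.merge(
        abundance_fc, on=["feature_id", "timepoint_h"], suffixes=("_pisa", "_ab")
    )
    n_lost = len(pisa_fc) + len(abundance_fc) - 2 * len(merged)
    if n_lost:
        logger.info("thermal shift: %d one-sided rows omitted", n_lost)
    return pd.DataFrame(
        {
            "feature_id": merged["feature_id"],
            "measure": measure,
            "timepoint_h": merged["timepoint_h"],
            "log2fc": merged["log2fc_pisa"] - merged["log2fc_ab"],
            "sem": np.sqrt(merged["sem_pisa"] ** 2 + merged["sem_ab"] ** 2),
            "n": merged[["n_pisa", "n_ab"]].min(axis=1),
        }
    ).sort_values(["feature_id", "timepoint_h"], ignore_index=True)


def phospho_protein_normalize(site_fc: pd.DataFrame, protein_fc: pd.DataFrame) -> pd.DataFrame:
    """Normalize phosphosite fold changes to the parent protein.

    Protein-normalized site log2FC = site log2FC - parent-protein log2FC at
    the same timepoint (same assay). A constant normalized trajectory means
    the site only tracks protein abundance; a changing one means altered
    phosphorylation stoichiometry. Sites whose parent protein is
    unquantified pass through unnormalized with ``normalized=False``.
    """
    site = site_fc.copy()
    site["_parent"] = site["feature_id"].map(parent_accession)
    prot = protein_fc.rename(
        columns={"feature_id": "_parent", "log2fc": "_p_fc", "sem": "_p_sem", "n": "_p_n"}
    )[["_parent", "timepoint_h", "_p_fc", "_p_sem", "_p_n"]]
    merged = site.merge(prot, on=["_parent", "timepoint_h"], how="left")
    normalized = merged["_p_fc"].notna()
    n_pass = int((~normalized).sum())
    if n_pass:
        logger.info("phospho normalization: %d site rows passed through (parent unquantified)", n_pass)
    out = pd.DataFrame(
        {
            "feature_id": merged["feature_id"],
            "measure": "phospho_abundance_norm",
            "timepoint_h": merged["timepoint_h"],
            "log2fc": np.where(normalized, merged["log2fc"] - merged["_p_fc"], merged["log2fc"]),
            "sem": np.where(
                normalized, np.sqrt(merged["sem"] ** 2 + merged["_p_sem"] ** 2), merged["sem"]
            ),
            "n": np.where(normalized, merged[["n", "_p_n"]].min(axis=1), merged["n"]).astype(int),
            "normalized": normalized,
        }
    )
    return out.sort_values(["feature_id", "timepoint_h"], ignore_index=True)


def delta_phospho_protein_ts(site_ts: pd.DataFrame, protein_ts: pd.DataFrame) -> pd.DataFrame:
    """Delta phospho-protein TS = site thermal shift minus the parent
    protein's bulk thermal shift. Sites without a parent-protein thermal
    shift are omitted (a difference cannot be formed); counts are logged.
    An absolute delta >= 1 (2-fold) marks a site as differentially stable
    versus the bulk protein."""
    site = site_ts.copy()
    site["_parent"] = site["feature_id"].map(parent_accession)
    prot = protein_ts.rename(
        columns={"feature_id": "_parent", "log2fc": "_p_fc", "sem": "_p_sem", "n": "_p_n"}
    )[["_parent", "timepoint_h", "_p_fc", "_p_sem", "_p_n"]]
    merged = site.merge(prot, on=["_parent", "timepoint_h"], how="inner")
    n_lost = len(site) - len(merged)
    if n_lost:
        logger.info("delta phospho-protein TS: %d site rows omitted (no parent TS)", n_lost)
    return pd.DataFrame(
        {
            "feature_id": merged["feature_id"],
            "measure": "delta_phospho_protein_ts",
            "timepoint_h": merged["timepoint_h"],
            "log2fc": merged["log2fc"] - merged["_p_fc"],
            "sem": np.sqrt(merged["sem"] ** 2 + merged["_p_sem"] ** 2),
            "n": merged[["n", "_p_n"]].min(axis=1),
        }
    ).sort_values(["feature_id", "timepoint_h"], ignore_index=True)


def _classify(fc: float, cutoff: float) -> str:
    if np.isnan(fc):
        return "unknown"
    if fc >= cutoff:
        return "up"
    if fc <= -cutoff:
        return "down"
    return "unchanged"


def categorize(
    abundance_fc: pd.DataFrame, ts_fc: pd.DataFrame, cutoff_log2: float = 1.0
) -> pd.DataFrame:
    """3x3 behavioural categorization of features by abundance and thermal
    shift, using a symmetric log2 cutoff in both dimensions (default 1.0 =
    2-fold).

    A dimension is ``up`` when log2FC >= cutoff, ``down`` when <= -cutoff
    (boundary values count as regulated), else ``unchanged``. Features seen
    in only one dimension get ``unknown`` in the other and ``complete=False``
    so they can be excluded from 3x3 summaries. The same function applies to
    phosphosites with (abundance, delta phospho-protein TS) inputs.
    """
    if cutoff_log2 <= 0:
        raise ValueError("cutoff must be > 0")
    ab = abundance_fc[["feature_id", "timepoint_h", "log2fc"]].rename(columns={"log2fc": "_ab"})
    ts = ts_fc[["feature_id", "timepoint_h", "log2fc"]].rename(columns={"log2fc": "_ts"})
    merged = ab.merge(ts, on=["feature_id", "timepoint_h"], how="outer")
    out = pd.DataFrame(
        {
            "feature_id": merged["feature_id"],
            "timepoint_h": merged["timepoint_h"],
            "abundance_class": [_classify(v, cutoff_log2) for v in merged["_ab"]],
            "ts_class": [_classify(v, cutoff_log2) for v in merged["_ts"]],
        }
    )
    out["category"] = out["abundance_class"] + "|" + out["ts_class"]
    out["complete"] = (out["abundance_class"] != "unknown") & (out["ts_class"] != "unknown")
    return out.sort_values(["feature_id", "timepoint_h"], ignore_index=True)


def category_counts(assignment: pd.DataFrame, timepoint: float | None = None) -> pd.Series:
    """Counts over the 9 categories, restricted to fully observed features."""
    sel = assignment[assignment["complete"]]
    if timepoint is not None:
        sel = sel[sel["timepoint_h"] == float(timepoint)]
    return sel.groupby("category").size()
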