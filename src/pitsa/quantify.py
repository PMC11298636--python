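"""PSM-level TMT reporter quantification.

Takes tables of peptide-spectrum matches with per-channel signal-to-noise
(S:N) values and turns them into per-protein or per-phosphosite feature
tables: isotopic-impurity correction, channel (loading) normalization,
aggregation by summing S:N over matching PSMs, scaling of each feature row
to a total of 100, and a limit-of-quantitation filter on the summed raw S:N.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ASSAYS = ("abundance", "pisa")

#: Default phosphosite localization-score cutoff (AScore-style; 13 ~ p<0.05
#: confidence that the phosphate is on the stated residue).
DEFAULT_MIN_LOCALIZATION = 13.0

#: Default limit-of-quantitation: minimum summed raw S:N across all channels
#: for a feature to be considered quantified.
DEFAULT_MIN_TOTAL_SN = 100.0

_SITE_TOKEN = re.compile(r"^([STY])(\d+):([0-9.eE+-]+)$")


@dataclass(frozen=True)
class PhosphoSite:
    """A localized phosphosite on a peptide: residue, 1-based protein
    position, and localization confidence score."""

    residue: str
    position: int
    score: float

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(f"phosphosite residue must be S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError(f"phosphosite position must be 1-based positive, got {self.position}")

    @property
    def label(self) -> str:
        return f"{self.residue}{self.position}"


class SampleDesign:
    """Mapping from TMT channels to (timepoint, assay, replicate).

    Parameters
    ----------
    table:
        DataFrame with columns ``channel``, ``timepoint_h``, ``assay``
        (``abundance`` or ``pisa``) and ``replicate`` (positive int).

    The reference timepoint (0 h) must be present for both assays, every
    (timepoint, assay, replicate) triple must map to exactly one channel,
    and every (timepoint, assay) cell needs at least two replicates so a
    standard error can be computed downstream.
    """

    REQUIRED = ("channel", "timepoint_h", "assay", "replicate")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"sample design missing columns: {missing}")
        tbl = table.loc[:, list(self.REQUIRED)].copy()
        tbl["timepoint_h"] = tbl["timepoint_h"].astype(float)
        tbl["replicate"] = tbl["replicate"].astype(int)
        bad = sorted(set(tbl["assay"]) - set(ASSAYS))
        if bad:
            raise ValueError(f"unknown assay labels {bad}; expected one of {ASSAYS}")
        if (tbl["timepoint_h"] < 0).any():
            raise ValueError("timepoints must be non-negative hours")
        if (tbl["replicate"] < 1).any():
            raise ValueError("replicate indices must be positive")
        if tbl["channel"].duplicated().any():
            dups = tbl.loc[tbl["channel"].duplicated(), "channel"].tolist()
            raise ValueError(f"duplicate channels in design: {dups}")
        trip = tbl[["timepoint_h", "assay", "replicate"]]
        if trip.duplicated().any():
            raise ValueError("each (timepoint, assay, replicate) must map to exactly one channel")
        for assay in ASSAYS:
            if assay in set(tbl["assay"]) and 0.0 not in set(
                tbl.loc[tbl["assay"] == assay, "timepoint_h"]
            ):
                raise ValueError(f"reference timepoint 0 h missing for assay {assay!r}")
        counts = tbl.groupby(["timepoint_h", "assay"])["replicate"].nunique()
        if (counts < 2).any():
            low = counts[counts < 2].index.tolist()
            raise ValueError(f"need >=2 replicates per (timepoint, assay); too few at {low}")
        self.table = tbl.reset_index(drop=True)

    @property
    def channels(self) -> list[str]:
        return self.table["channel"].tolist()

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.table["timepoint_h"].unique())

    def channels_for(self, timepoint: float | None = None, assay: str | None = None) -> list[str]:
        """Channels matching the given timepoint and/or assay, replicate order."""
        sel = self.table
        if timepoint is not None:
            sel = sel[sel["timepoint_h"] == float(timepoint)]
        if assay is not None:
            sel = sel[sel["assay"] == assay]
        return sel.sort_values("replicate")["channel"].tolist()

    @classmethod
    def read_tsv(cls, path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


class ImpurityMatrix:
    """TMT reagent isotopic-impurity matrix.

    Row ``i``, column ``j`` holds the fraction of reagent *i*'s signal that
    is observed in channel *j* (vendor product-sheet convention). Rows sum
    to at most 1, the diagonal is the row maximum, and all entries are
    non-negative.
    """

    def __init__(self, matrix: pd.DataFrame):
        if matrix.shape[0] != matrix.shape[1]:
            raise ValueError("impurity matrix must be square")
        if list(matrix.index) != list(matrix.columns):
            raise ValueError("impurity matrix row and column channel labels must match")
        vals = matrix.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("impurity matrix entries must be >= 0")
        if (vals.sum(axis=1) > 1 + 1e-9).any():
            raise ValueError("impurity matrix rows must sum to <= 1")
        if not np.allclose(np.diag(vals), vals.max(axis=1)):
            raise ValueError("impurity matrix diagonal must be the row maximum")
        self.matrix = matrix.astype(float)

    @property
    def channels(self) -> list[str]:
        return list(self.matrix.index)

    @classmethod
    def identity(cls, channels) -> "ImpurityMatrix":
        n = len(channels)
        return cls(pd.DataFrame(np.eye(n), index=channels, columns=channels))

    @classmethod
    def read_tsv(cls, path) -> "ImpurityMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


@dataclass
class ReporterTable:
    """PSM-level reporter S:N table.

    ``data`` has one PSM per row with columns ``peptide``, ``protein``,
    ``phosphosites`` (list of :class:`PhosphoSite`, possibly empty) and one
    float column per channel in ``channels``.
    """

    data: pd.DataFrame
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ("peptide", "protein", "phosphosites"):
            if col not in self.data.columns:
                raise ValueError(f"reporter table missing column {col!r}")
        missing = [c for c in self.channels if c not in self.data.columns]
        if missing:
            raise ValueError(f"reporter table missing channel columns: {missing}")
        vals = self.data[self.channels].to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("S:N values must be non-negative")

    def __len__(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data[self.channels].to_numpy(dtype=float)

    def with_values(self, vals: np.ndarray) -> "ReporterTable":
        out = self.data.copy()
        out[self.channels] = vals
        return ReporterTable(out, list(self.channels))

    @classmethod
    def read_tsv(cls, path, channels: list[str] | None = None) -> "ReporterTable":
        df = pd.read_csv(path, sep="\t")
        if channels is None:
            channels = [c for c in df.columns if c not in ("peptide", "protein", "phosphosites")]
        df["phosphosites"] = [
            parse_site_tokens(s) for s in df.get("phosphosites", pd.Series([""] * len(df))).fillna("")
        ]
        return cls(df, channels)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out["phosphosites"] = [format_site_tokens(s) for s in out["phosphosites"]]
        out.to_csv(path, sep="\t", index=False)


def parse_site_tokens(text: str) -> list[PhosphoSite]:
    """Parse semicolon-separated ``S140:0.99`` tokens into site records."""
    sites = []
    for tok in str(text).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        m = _SITE_TOKEN.match(tok)
        if m is None:
            raise ValueError(f"malformed phosphosite token {tok!r}")
        sites.append(PhosphoSite(m.group(1), int(m.group(2)), float(m.group(3))))
    return sites


def format_site_tokens(sites) -> str:
    return ";".join(f"{s.residue}{s.position}:{s.score:g}" for s in sites)


@dataclass
class FeatureQuant:
    """Per-feature scaled channel intensities.

    ``data`` is indexed by ``feature_id`` (protein accession, or
    ``ACCESSION_ResiduePosition`` for phosphosites) with one column per
    channel plus ``total_sn``, the summed raw S:N before scaling. After
    scaling every channel row sums to 100.
    """

    data: pd.DataFrame
    channels: list[str]
    kind: str  # 'protein' or 'phosphosite'

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "phosphosite"):
            raise ValueError(f"feature kind must be protein/phosphosite, got {self.kind!r}")
        vals = self.data[self.channels].to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("scaled intensities must be non-negative")
        if len(vals) and not np.allclose(vals.sum(axis=1), 100.0, atol=1e-6):
            raise ValueError("every feature row must sum to 100 after scaling")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @classmethod
    def read_tsv(cls, path, kind: str) -> "FeatureQuant":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        channels = [c for c in df.columns if c != "total_sn"]
        return cls(df, channels, kind)

    def to_tsv(self, path) -> None:
        self.data.rename_axis("feature_id").to_csv(path, sep="\t")


def correct_impurities(
    raw: ReporterTable, impurity: ImpurityMatrix, cond_limit: float = 1e8
) -> ReporterTable:
    """Undo isotopic cross-channel contamination of TMT reporter signal.

    With ``M[i][j]`` the fraction of reagent *i* observed in channel *j*,
    the observed row is ``obs = true @ M``; the true signal is recovered by
    solving the linear system per PSM. Negative solutions (noise) are
    clamped to zero and counted.
    """
    if set(raw.channels) != set(impurity.channels):
        raise ValueError(
            "channel mismatch between reporter table and impurity matrix: "
            f"{sorted(set(raw.channels) ^ set(impurity.channels))}"
        )
    m = impurity.matrix.loc[raw.channels, raw.channels].to_numpy()
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > cond_limit:
        raise ValueError(f"impurity matrix is singular or ill-conditioned (cond={cond:.3g})")
    obs = raw.values()
    # obs = true @ M  <=>  M.T @ true.T = obs.T
    true = np.linalg.solve(m.T, obs.T).T
    n_clamped = int((true < 0).sum())
    if n_clamped:
        logger.info("impurity correction clamped %d negative values to 0", n_clamped)
        true = np.clip(true, 0.0, None)
    return raw.with_values(true)


def normalize_channels(
    tbl: ReporterTable,
    design: SampleDesign | None = None,
    per_assay: bool = False,
) -> ReporterTable:
    """Equalize channel loading: scale every channel column so all column
    sums equal the mean column sum.

    With ``per_assay=True`` (requires ``design``) normalization is computed
    separately within the abundance and PISA channel subsets.
    """
    if len(tbl) == 0:
        raise ValueError("cannot normalize an empty reporter table")
    if per_assay:
        if design is None:
            raise ValueError("per-assay normalization requires a sample design")
        groups = [design.channels_for(assay=a) for a in ASSAYS]
        groups = [g for g in groups if g]
    else:
        groups = [list(tbl.channels)]
    vals = tbl.values().copy()
    idx = {c: i for i, c in enumerate(tbl.channels)}
    for group in groups:
        cols = [idx[c] for c in group]
        sums = vals[:, cols].sum(axis=0)
        zero = [group[i] for i in range(len(cols)) if sums[i] <= 0]
        if zero:
            raise ValueError(f"channels with zero total S:N cannot be normalized: {zero}")
        vals[:, cols] *= sums.mean() / sums
    return tbl.with_values(vals)


def aggregate_features(
    tbl: ReporterTable,
    kind: str,
    min_localization: float = DEFAULT_MIN_LOCALIZATION,
) -> FeatureQuant:
    """Sum PSM S:N into protein or phosphosite features and scale rows to 100.

    Protein features sum over all PSMs of an accession. Phosphosite features
    sum over all phosphopeptides carrying that localized site (localization
    score >= ``min_localization``); a peptide with several localized sites
    contributes its full S:N to each site feature. Feature ids are
    ``ACCESSION`` or ``ACCESSION_ResiduePosition``.
    """
    if kind == "protein":
        frame = tbl.data[["protein"] + tbl.channels].rename(columns={"protein": "feature_id"})
    elif kind == "phosphosite":
        rows = []
        for rec in tbl.data.itertuples(index=False):
            for site in rec.phosphosites:
                if site.score >= min_localization:
                    rows.append(
                        (f"{rec.protein}_{site.label}",)
                        + tuple(getattr(rec, c) for c in tbl.channels)
                    )
        frame = pd.DataFrame(rows, columns=["feature_id"] + tbl.channels)
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    summed = frame.groupby("feature_id", sort=True)[tbl.channels].sum()
    total = summed.sum(axis=1)
    empty = int((total <= 0).sum())
    if empty:
        logger.info("dropping %d features with zero total S:N after aggregation", empty)
    summed = summed[total > 0]
    total = total[total > 0]
    scaled = summed.div(total, axis=0) * 100.0
    scaled["total_sn"] = total
    return FeatureQuant(scaled, list(tbl.channels), kind)


def filter_low_quant(
    fq: FeatureQuant, min_total_sn: float = DEFAULT_MIN_TOTAL_SN
) -> FeatureQuant:
    """Drop features below the limit of quantitation.

    A feature is kept when its summed raw S:N across all channels (before
    the scale-to-100 step) is at least ``min_total_sn``.
    """
    if min_total_sn < 0:
        raise ValueError("min_total_sn must be >= 0")
    keep = fq.data["total_sn"] >= min_total_sn
    removed = int((~keep).sum())
    if removed:
        logger.info("limit-of-quantitation filter removed %d of %d features", removed, len(fq))
    if keep.sum() == 0:
        logger.warning("limit-of-quantitation filter removed every feature")
    return FeatureQuant(fq.data[keep].copy(), list(fq.channels), fq.kind)
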