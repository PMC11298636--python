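import numpy as np
import pandas as pd
import pytest

from pitsa.quantify import (
    ImpurityMatrix,
    PhosphoSite,
    ReporterTable,
    SampleDesign,
)


@pytest.fixture
def design2() -> SampleDesign:
    """Minimal two-timepoint, two-replicate, two-assay design."""
    rows = []
    for assay in ("abundance", "pisa"):
        for t in (0.0, 24.0):
            for r in (1, 2):
                rows.append(
                    {
                        "channel": f"{assay[:2]}_{t:g}_{r}",
                        "timepoint_h": t,
                        "assay": assay,
                        "replicate": r,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


def make_reporter(rows, channels) -> ReporterTable:
    """Assemble a ReporterTable from (peptide, protein, sites, *values) rows."""
    df = pd.DataFrame(
        [
            {
                "peptide": pep,
                "protein": prot,
                "phosphosites": sites,
                **dict(zip(channels, vals)),
            }
            for pep, prot, sites, *vals in [(r[0], r[1], r[2], *r[3]) for r in rows]
        ]
    )
    return ReporterTable(df, list(channels))


@pytest.fixture
def toy_reporter(design2) -> ReporterTable:
    ch = design2.channels
    return make_reporter(
        [
            ("PEP1", "P1", [], [10.0] * len(ch)),
            ("PEP2", "P1", [], [20.0, 10.0, 5.0, 2.0, 8.0, 4.0, 2.0, 1.0]),
            ("PEP3", "P2", [PhosphoSite("S", 10, 30.0)], [4.0] * len(ch)),
        ],
        ch,
    )


@pytest.fixture
def impurity2x2() -> ImpurityMatrix:
    return ImpurityMatrix(
        pd.DataFrame([[0.9, 0.1], [0.2, 0.8]], index=["c1", "c2"], columns=["c1", "c2"])
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
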