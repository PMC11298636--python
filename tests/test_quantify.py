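"""Unit tests for PSM-level quantification: impurity correction, channel
normalization, feature aggregation and the limit-of-quantitation filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_reporter
from pitsa import quantify as q


def simple_table(values, channels=("c1", "c2")):
    return make_reporter([("PEP", "P", [], list(v)) for v in values], list(channels))


class TestImpurityCorrection:
    def test_identity_matrix_is_noop(self):
        tbl = simple_table([(90.0, 10.0), (5.0, 7.0)])
        out = q.correct_impurities(tbl, q.ImpurityMatrix.identity(["c1", "c2"]))
        np.testing.assert_allclose(out.values(), tbl.values())

    def test_hand_solved_2x2(self, impurity2x2):
        # x @ M = (90, 10) with M = [[.9,.1],[.2,.8]] solves to x = (100, 0)
        out = q.correct_impurities(simple_table([(90.0, 10.0)]), impurity2x2)
        np.testing.assert_allclose(out.values(), [[100.0, 0.0]], atol=1e-12)

    def test_zero_row_stays_zero(self, impurity2x2):
        out = q.correct_impurities(simple_table([(0.0, 0.0)]), impurity2x2)
        np.testing.assert_allclose(out.values(), [[0.0, 0.0]])

    def test_round_trip_recovers_truth(self, rng):
        channels = [f"c{i}" for i in range(10)]
        m = np.eye(10) * 0.9
        for i in range(9):
            m[i, i + 1] = 0.06
            m[i + 1, i] = 0.04
        imp = q.ImpurityMatrix(pd.DataFrame(m, index=channels, columns=channels))
        true = rng.uniform(1.0, 100.0, size=(200, 10))
        observed = true @ m
        tbl = simple_table(observed, channels)
        out = q.correct_impurities(tbl, imp)
        np.testing.assert_allclose(out.values(), true, rtol=1e-9)

    def test_singular_matrix_rejected(self):
        imp = q.ImpurityMatrix(
            pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["c1", "c2"], columns=["c1", "c2"])
        )
        with pytest.raises(ValueError, match="ill-conditioned"):
            q.correct_impurities(simple_table([(1.0, 1.0)]), imp)

    def test_channel_mismatch_rejected(self, impurity2x2):
        tbl = simple_table([(1.0, 2.0)], channels=("x1", "x2"))
        with pytest.raises(ValueError, match="channel mismatch"):
            q.correct_impurities(tbl, impurity2x2)

    def test_negative_solutions_clamped(self, impurity2x2):
        # observed (0, 10) would solve to a negative c1 component
        out = q.correct_impurities(simple_table([(0.0, 10.0)]), impurity2x2)
        assert (out.values() >= 0).all()


class TestChannelNormalization:
    def test_column_sums_equalized(self):
        tbl = simple_table([(200.0, 100.0)])
        out = q.normalize_channels(tbl)
        np.testing.assert_allclose(out.values(), [[150.0, 150.0]])

    def test_three_channel_factors(self):
        tbl = simple_table([(10.0, 20.0, 30.0)], channels=("c1", "c2", "c3"))
        out = q.normalize_channels(tbl)
        np.testing.assert_allclose(out.values(), [[20.0, 20.0, 20.0]])

    def test_idempotent(self, rng):
        tbl = simple_table(rng.uniform(0.1, 50.0, size=(20, 4)), channels=list("abcd"))
        once = q.normalize_channels(tbl)
        twice = q.normalize_channels(once)
        np.testing.assert_allclose(twice.values(), once.values(), rtol=1e-12)

    def test_equal_columns_unchanged(self):
        tbl = simple_table([(5.0, 5.0), (3.0, 3.0)])
        out = q.normalize_channels(tbl)
        np.testing.assert_allclose(out.values(), tbl.values())

    def test_zero_channel_is_error(self):
        tbl = simple_table([(5.0, 0.0)])
        with pytest.raises(ValueError, match="c2"):
            q.normalize_channels(tbl)


class TestAggregation:
    def test_protein_psms_summed(self, toy_reporter, design2):
        fq = q.aggregate_features(toy_reporter, "protein")
        assert set(fq.feature_ids) == {"P1", "P2"}
        # P1 = PEP1 + PEP2 raw sums before scaling
        ch0 = design2.channels[0]
        raw = toy_reporter.data.groupby("protein")[ch0].sum()
        scaled = fq.data.loc["P1", ch0]
        assert scaled == pytest.approx(100.0 * raw["P1"] / fq.data.loc["P1", "total_sn"])

    def test_rows_scale_to_100(self, toy_reporter):
        for kind in ("protein", "phosphosite"):
            fq = q.aggregate_features(toy_reporter, kind, min_localization=0.0)
            sums = fq.data[fq.channels].sum(axis=1)
            np.testing.assert_allclose(sums, 100.0, atol=1e-6)

    def test_normalize_to_100_values(self):
        tbl = simple_table([(2.0, 3.0, 5.0)], channels=("c1", "c2", "c3"))
        fq = q.aggregate_features(tbl, "protein")
        np.testing.assert_allclose(
            fq.data[["c1", "c2", "c3"]].to_numpy(), [[20.0, 30.0, 50.0]]
        )

    def test_multisite_peptide_contributes_to_both_sites(self):
        ch = ("c1", "c2")
        s10 = q.PhosphoSite("S", 10, 30.0)
        s14 = q.PhosphoSite("S", 14, 30.0)
        tbl = make_reporter(
            [
                ("PEPa", "P", [s10, s14], [6.0, 2.0]),
                ("PEPb", "P", [s10], [2.0, 2.0]),
                ("PEPc", "P", [s14], [10.0, 30.0]),
            ],
            list(ch),
        )
        fq = q.aggregate_features(tbl, "phosphosite", min_localization=0.0)
        # hand-summed raw totals: S10 = (6+2, 2+2) = (8,4); S14 = (16,32)
        assert fq.data.loc["P_S10", "total_sn"] == pytest.approx(12.0)
        assert fq.data.loc["P_S14", "total_sn"] == pytest.approx(48.0)
        np.testing.assert_allclose(
            fq.data.loc["P_S10", ["c1", "c2"]].to_numpy(dtype=float), [800 / 12, 400 / 12]
        )

    def test_localization_filter_drops_low_scores(self):
        lo = q.PhosphoSite("S", 5, 5.0)
        hi = q.PhosphoSite("T", 9, 20.0)
        tbl = make_reporter([("PEP", "P", [lo, hi], [1.0, 1.0])], ["c1", "c2"])
        fq = q.aggregate_features(tbl, "phosphosite", min_localization=13.0)
        assert fq.feature_ids == ["P_T9"]

    def test_psm_order_invariance(self, toy_reporter):
        fq1 = q.aggregate_features(toy_reporter, "protein")
        shuffled = q.ReporterTable(
            toy_reporter.data.iloc[::-1].reset_index(drop=True), toy_reporter.channels
        )
        fq2 = q.aggregate_features(shuffled, "protein")
        pd.testing.assert_frame_equal(fq1.data, fq2.data)


class TestLowQuantFilter:
    def _fq(self, totals):
        rows = [(f"PEP{i}", f"P{i}", [], [t / 2, t / 2]) for i, t in enumerate(totals)]
        return q.aggregate_features(make_reporter(rows, ["c1", "c2"]), "protein")

    def test_zero_threshold_keeps_all(self):
        fq = self._fq([50.0, 150.0, 500.0])
        assert len(q.filter_low_quant(fq, 0.0)) == 3

    def test_threshold_removes_below(self):
        fq = self._fq([50.0, 150.0, 500.0])
        out = q.filter_low_quant(fq, 100.0)
        assert len(out) == 2 and "P0" not in out.feature_ids

    def test_all_removed_is_empty_not_error(self):
        out = q.filter_low_quant(self._fq([50.0, 150.0]), 1e6)
        assert len(out) == 0


class TestIO:
    def test_reporter_tsv_round_trip(self, toy_reporter, tmp_path):
        p = tmp_path / "psms.tsv"
        toy_reporter.to_tsv(p)
        back = q.ReporterTable.read_tsv(p, channels=toy_reporter.channels)
        np.testing.assert_allclose(back.values(), toy_reporter.values())
        assert list(back.data["phosphosites"].map(len)) == list(
            toy_reporter.data["phosphosites"].map(len)
        )

    def test_site_token_parsing(self):
        sites = q.parse_site_tokens("S140:0.99;T22:13")
        assert [(s.residue, s.position, s.score) for s in sites] == [
            ("S", 140, 0.99),
            ("T", 22, 13.0),
        ]
        with pytest.raises(ValueError, match="malformed"):
            q.parse_site_tokens("Q7:1.0")

    def test_design_validation(self, design2):
        bad = design2.table.copy()
        bad.loc[bad["timepoint_h"] == 0.0, "timepoint_h"] = 2.0
        with pytest.raises(ValueError, match="reference timepoint"):
            q.SampleDesign(bad)


@settings(deadline=None, max_examples=25)
@given(
    vals=st.lists(
        st.tuples(*(st.floats(0.1, 1e4) for _ in range(3))), min_size=1, max_size=8
    )
)
def test_feature_rows_always_sum_to_100(vals):
    """Property: any positive PSM table aggregates to rows summing to 100."""
    tbl = simple_table(vals, channels=("c1", "c2", "c3"))
    fq = q.aggregate_features(tbl, "protein")
    np.testing.assert_allclose(fq.data[["c1", "c2", "c3"]].sum(axis=1), 100.0, atol=1e-6)
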