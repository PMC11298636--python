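"""Unit tests for kinase-motif scoring, percentile favorability, and
directional Fisher enrichment with Haldane-corrected frequency factors."""

import math

import numpy as np
import pandas as pd
import pytest

from pitsa import kinlib as kl


def toy_pssm(name="K", entries=None, window=(-1, 1)):
    lo, hi = window
    positions = [p for p in range(lo, hi + 1) if p != 0]
    odds = pd.DataFrame(1.0, index=positions, columns=list(kl.AMINO_ACIDS))
    for (pos, res), v in (entries or {}).items():
        odds.loc[pos, res] = v
    return kl.KinasePssm(name, odds)


def hypergeom_tail_oracle(a, b, c, d):
    """Exact integer enumeration of P(X >= a) for the 2x2 margins."""
    n_pop, n_succ, n_draw = a + b + c + d, a + c, a + b
    total = math.comb(n_pop, n_draw)
    acc = 0
    for k in range(a, min(n_draw, n_succ) + 1):
        acc += math.comb(n_succ, k) * math.comb(n_pop - n_succ, n_draw - k)
    return acc / total


class TestScoreSite:
    def test_neutral_pssm_scores_zero(self):
        pssm = toy_pssm(window=(-5, 4))
        assert kl.score_site(pssm, "AAAAASAAAA") == pytest.approx(0.0)

    def test_hand_summed_toy(self):
        pssm = toy_pssm(entries={(-1, "R"): 4.0, (1, "P"): 2.0})
        assert kl.score_site(pssm, "RSP") == pytest.approx(3.0)  # log2 4 + log2 2

    def test_terminal_padding_is_neutral(self):
        pssm = toy_pssm(entries={(-1, "R"): 4.0, (1, "P"): 2.0})
        assert kl.score_site(pssm, "_SP") == pytest.approx(1.0)
        # positions falling off a short flank are also neutral
        wide = toy_pssm(entries={(-5, "R"): 4.0, (1, "P"): 2.0}, window=(-5, 4))
        assert kl.score_site(wide, "AASPA") == pytest.approx(1.0)

    def test_unknown_residue_is_error(self):
        pssm = toy_pssm()
        with pytest.raises(ValueError, match="site7"):
            kl.score_site(pssm, "BSP", site_id="site7")

    def test_additive_over_disjoint_windows(self):
        left = toy_pssm(entries={(-2, "K"): 8.0, (-1, "R"): 4.0}, window=(-2, -1))
        right = toy_pssm(entries={(1, "P"): 2.0, (2, "L"): 16.0}, window=(1, 2))
        both = toy_pssm(
            entries={(-2, "K"): 8.0, (-1, "R"): 4.0, (1, "P"): 2.0, (2, "L"): 16.0},
            window=(-2, 2),
        )
        flank = "KRSPL"
        assert kl.score_site(both, flank) == pytest.approx(
            kl.score_site(left, flank) + kl.score_site(right, flank)
        )

    def test_pssm_validation(self):
        with pytest.raises(ValueError, match="> 0"):
            toy_pssm(entries={(-1, "R"): 0.0})
        bad = pd.DataFrame(1.0, index=[-2, 1], columns=list(kl.AMINO_ACIDS))
        with pytest.raises(ValueError, match="contiguous"):
            kl.KinasePssm("B", bad)


class TestPercentilesAndFavorability:
    def test_background_maximum_scores_percentile_100(self):
        scores = pd.DataFrame({"K": [1.0, 2.0, 5.0]}, index=["s1", "s2", "s3"])
        pct = kl.percentile_scores(scores)
        assert pct.loc["s3", "K"] == pytest.approx(100.0)

    def test_monotone_transform_invariance(self, rng):
        scores = pd.DataFrame(
            {"K": rng.normal(size=50), "L": rng.normal(size=50)},
            index=[f"s{i}" for i in range(50)],
        )
        pct1 = kl.percentile_scores(scores)
        pct2 = kl.percentile_scores(np.exp(scores) * 3 + 1)
        pd.testing.assert_frame_equal(pct1, pct2)

    def test_tie_broken_alphabetically(self):
        pct = pd.DataFrame(
            {"KB": [90.0], "KA": [90.0], "KC": [10.0]}, index=["s1"]
        )
        fav = kl.favorability(pct, top_k=1)
        assert fav.loc["s1", "KA"] and not fav.loc["s1", "KB"] and not fav.loc["s1", "KC"]

    def test_favorable_set_size_is_top_k(self, rng):
        pct = pd.DataFrame(
            rng.uniform(0, 100, size=(20, 7)),
            index=[f"s{i}" for i in range(20)],
            columns=[f"K{j}" for j in range(7)],
        )
        fav = kl.favorability(pct, top_k=3)
        assert (fav.sum(axis=1) == 3).all()

    def test_matches_sort_based_oracle(self, rng):
        """20 sites x 5 kinases favorability equals an independent
        recomputation by explicit sorting."""
        sites = [f"s{i:02d}" for i in range(20)]
        kinases = [f"K{j}" for j in range(5)]
        scores = pd.DataFrame(
            rng.normal(size=(20, 5)), index=sites, columns=kinases
        )
        pct, fav = kl.rank_kinases(scores, top_k=2)
        for s in sites:
            # oracle: percentile by counting <=, rank by (-pct, name)
            expect_pct = {
                k: 100.0 * (scores[k] <= scores.loc[s, k]).sum() / len(sites)
                for k in kinases
            }
            order = sorted(kinases, key=lambda k: (-expect_pct[k], k))
            assert set(fav.columns[fav.loc[s]]) == set(order[:2])
            for k in kinases:
                assert pct.loc[s, k] == pytest.approx(expect_pct[k])


class TestEnrichment:
    def test_equal_proportions_null(self):
        assert kl.frequency_factor(5, 5, 50, 50) == pytest.approx(0.0)
        p = kl.fisher_one_sided(5, 5, 50, 50)
        assert p == pytest.approx(hypergeom_tail_oracle(5, 5, 50, 50), abs=1e-12)

    def test_enriched_table_hand_values(self):
        a, b, c, d = 8, 2, 10, 90
        assert kl.fisher_one_sided(a, b, c, d) == pytest.approx(
            hypergeom_tail_oracle(a, b, c, d), abs=1e-12
        )
        ff = kl.frequency_factor(a, b, c, d)
        assert ff == pytest.approx(math.log2((8.5 / 11) / (10.5 / 101)))
        assert ff == pytest.approx(2.894, abs=1e-3)

    def test_haldane_keeps_zero_cells_finite(self):
        ff = kl.frequency_factor(0, 10, 0, 90)
        assert np.isfinite(ff)
        assert ff == pytest.approx(math.log2((0.5 / 11) / (0.5 / 91)))
        assert kl.fisher_one_sided(0, 10, 0, 90) == pytest.approx(1.0)

    def test_fisher_matches_oracle_on_margin_grid(self):
        """Spot grid of 2x2 tables against exact enumeration."""
        for a in range(0, 8, 2):
            for b in range(0, 8, 3):
                for c in range(0, 8, 2):
                    for d in range(0, 8, 3):
                        if a + b == 0 or c + d == 0:
                            continue
                        assert kl.fisher_one_sided(a, b, c, d) == pytest.approx(
                            hypergeom_tail_oracle(a, b, c, d), abs=1e-12
                        )

    def _run_enrich(self, fav_up_rate=0.8, fav_bg_rate=0.2, rng=None):
        idx = [f"u{i}" for i in range(50)] + [f"d{i}" for i in range(20)] + [
            f"b{i}" for i in range(200)
        ]
        logfc = pd.Series([2.0] * 50 + [-2.0] * 20 + [0.0] * 200, index=idx)
        fav = pd.DataFrame(index=idx, columns=["KA", "KB"], dtype=bool)
        draws = rng.random(len(idx))
        fav["KA"] = [
            (draws[i] < fav_up_rate) if s.startswith("u") else (draws[i] < fav_bg_rate)
            for i, s in enumerate(idx)
        ]
        fav["KB"] = rng.random(len(idx)) < fav_bg_rate
        return kl.enrich(fav, logfc)

    def test_planted_direction_selected(self, rng):
        out = self._run_enrich(rng=rng)
        ka_up = out[(out.kinase == "KA") & (out.direction == "up")].iloc[0]
        assert ka_up.adjusted_p < 0.01
        assert bool(ka_up.selected_direction)
        assert not bool(ka_up.dual_significant)

    def test_bh_monotone_and_at_least_raw(self, rng):
        out = self._run_enrich(rng=rng)
        for _, grp in out.groupby("direction"):
            grp = grp.sort_values("p_value")
            assert (grp["adjusted_p"].to_numpy() >= grp["p_value"].to_numpy() - 1e-15).all()
            assert (np.diff(grp["adjusted_p"].to_numpy()) >= -1e-12).all()

    def test_contingency_margins_partition_sites(self, rng):
        out = self._run_enrich(rng=rng)
        up = out[out.direction == "up"].iloc[0]
        assert up.a + up.b == 50  # upregulated sites
        assert up.c + up.d == 200  # unregulated sites

    def test_empty_regulated_set_is_error(self):
        fav = pd.DataFrame({"K": [True, False]}, index=["s1", "s2"])
        logfc = pd.Series([0.0, 0.5], index=["s1", "s2"])
        with pytest.raises(ValueError, match="regulated"):
            kl.enrich(fav, logfc)

    def test_boundary_logfc_counts_as_regulated(self):
        fav = pd.DataFrame(
            {"K": [True, True, False, False]}, index=["s1", "s2", "s3", "s4"]
        )
        logfc = pd.Series([1.0, -1.0, 0.0, 0.5], index=fav.index)
        out = kl.enrich(fav, logfc)
        up = out[out.direction == "up"].iloc[0]
        assert up.a + up.b == 1 and up.c + up.d == 2
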