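"""Main-effects ANOVA and Fisher-LSD against independent oracles.

Expected sums of squares and p-values for the reference experiment were
frozen from a standalone brute-force recomputation (level totals and
scipy distribution tails) made before this module was written.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ivtflow as iv
from conftest import glm_anova_oracle, random_balanced_design


class TestAnovaReference:
    def test_sums_of_squares(self, ref_anova):
        assert ref_anova.ss["d_sa_mm"] == pytest.approx(7.598, abs=1e-3)
        assert ref_anova.ss["a_lt_deg"] == pytest.approx(81.903, abs=1e-3)
        assert ref_anova.ss["r_tt_mm"] == pytest.approx(77.751, abs=1e-3)
        assert ref_anova.ss_err == pytest.approx(23.490, abs=1e-3)
        assert ref_anova.ms_err == pytest.approx(1.9575, abs=1e-4)
        assert ref_anova.df_err == 12 and ref_anova.df_total == 24

    def test_distance_not_significant(self, ref_anova):
        assert ref_anova.p["d_sa_mm"] == pytest.approx(0.459, abs=5e-4)

    def test_radius_significant(self, ref_anova):
        assert ref_anova.p["r_tt_mm"] < 0.05

    def test_decomposition_conserved(self, ref_anova):
        total = sum(ref_anova.ss.values()) + ref_anova.ss_err
        assert total == pytest.approx(ref_anova.ss_total, rel=1e-9)


class TestAnovaEdgeCases:
    def test_constant_responses_flagged(self, ref_design):
        flat = ref_design.with_responses(np.full(25, 3.0))
        table = iv.anova_main_effects(flat)
        assert table.zero_variance
        assert all(p == 1.0 for p in table.p.values())

    def test_unbalanced_design_rejected(self, ref_design):
        runs = pd.concat(
            [ref_design.runs.iloc[:-1], ref_design.runs.iloc[[0]]],
            ignore_index=True,
        )
        broken = iv.Design(
            factors=ref_design.factors,
            runs=runs,
            responses=ref_design.responses,
        )
        with pytest.raises(iv.UnbalancedDesignError):
            iv.anova_main_effects(broken)

    def test_missing_responses_rejected(self, ref_design):
        bare = iv.Design(factors=ref_design.factors, runs=ref_design.runs)
        with pytest.raises(ValueError, match="responses"):
            iv.anova_main_effects(bare)


class TestGlmOracleAgreement:
    def test_reference_matches_glm(self, ref_design, ref_anova):
        oracle = glm_anova_oracle(ref_design)
        for name in ref_anova.factors:
            row = oracle.loc[f"C({name})"]
            assert ref_anova.ss[name] == pytest.approx(row.sum_sq, rel=1e-10)
            assert ref_anova.f[name] == pytest.approx(row.F, rel=1e-10)
            assert ref_anova.p[name] == pytest.approx(row["PR(>F)"], rel=1e-10)

    def test_random_designs_match_glm(self):
        rng = np.random.default_rng(20260922)
        for _ in range(20):
            design = random_balanced_design(rng)
            table = iv.anova_main_effects(design)
            oracle = glm_anova_oracle(design)
            for name in table.factors:
                row = oracle.loc[f"C({name})"]
                assert table.ss[name] == pytest.approx(row.sum_sq, rel=1e-8)
                assert table.p[name] == pytest.approx(row["PR(>F)"], rel=1e-8)


class TestLsdPairwise:
    # frozen from the brute-force recomputation of the reference data
    EXPECTED_RTT = {
        (0.0, 2.5): 0.0044,
        (0.0, 5.0): 0.0007,
        (0.0, 7.5): 0.0002,
        (0.0, 10.0): 0.0001,
        (2.5, 5.0): 0.3323,
        (2.5, 7.5): 0.1074,
        (2.5, 10.0): 0.0722,
        (5.0, 7.5): 0.4794,
        (5.0, 10.0): 0.3557,
        (7.5, 10.0): 0.8216,
    }

    def test_radius_pairwise_p_values(self, ref_design):
        table = iv.lsd_pairwise(ref_design, "r_tt_mm")
        for pair, expected in self.EXPECTED_RTT.items():
            assert table.p_value(*pair) == pytest.approx(expected, abs=5e-5)

    def test_pooled_se_constant_across_pairs(self, ref_design):
        table = iv.lsd_pairwise(ref_design, "r_tt_mm")
        assert table.table.se.nunique() == 1
        assert table.table.se.iloc[0] == pytest.approx(
            np.sqrt(2 * 1.9575 / 5), abs=1e-4
        )

    def test_pair_order_symmetry(self, ref_design):
        table = iv.lsd_pairwise(ref_design, "r_tt_mm")
        assert table.p_value(2.5, 0.0) == table.p_value(0.0, 2.5)

    def test_identical_group_means_give_p_one(self, ref_design):
        # responses that depend only on the other two factors
        d = ref_design.runs["d_sa_mm"].to_numpy()
        a = ref_design.runs["a_lt_deg"].to_numpy()
        y = d + a  # integer-valued: radius group sums are exactly equal
        table = iv.lsd_pairwise(ref_design.with_responses(y), "r_tt_mm")
        assert np.all(table.table.t == 0.0)
        assert np.all(table.table.p_value == 1.0)

    def test_unknown_factor_rejected(self, ref_design):
        with pytest.raises(KeyError):
            iv.lsd_pairwise(ref_design, "bore_mm")


class TestPermutationCrossCheck:
    def test_radius_permutation_p_brackets_parametric(self, ref_design):
        """Permutation null of the radius F statistic (10,000 shuffles)
        agrees with the parametric F(4,12) tail within Monte-Carlo error."""
        rng = np.random.default_rng(12345)
        y = ref_design.responses
        idx = {
            name: ref_design.level_index(name)
            for name in ("d_sa_mm", "a_lt_deg", "r_tt_mm")
        }
        onehots = {
            name: np.eye(5)[ix] for name, ix in idx.items()
        }  # 25 x 5 indicators
        n_perm = 10_000
        perms = np.array([rng.permutation(25) for _ in range(n_perm)])
        Y = y[perms]  # n_perm x 25
        grand = Y.sum(axis=1)
        ss_total = (Y**2).sum(axis=1) - grand**2 / 25
        ss = {
            name: ((Y @ oh) ** 2).sum(axis=1) / 5 - grand**2 / 25
            for name, oh in onehots.items()
        }
        ss_err = ss_total - sum(ss.values())
        f_rtt = (ss["r_tt_mm"] / 4) / (ss_err / 12)
        obs = iv.anova_main_effects(ref_design)
        p_perm = float(np.mean(f_rtt >= obs.f["r_tt_mm"]))
        p_param = obs.p["r_tt_mm"]
        mc_err = 3 * np.sqrt(max(p_param, p_perm, 1e-4) / n_perm)
        assert abs(p_perm - p_param) < max(0.003, mc_err)


class TestSignificanceReport:
    def test_reference_ranking_and_flags(self, ref_anova):
        ranking = iv.significance_report(ref_anova)
        frame = ranking.table.set_index("factor")
        assert frame.loc["r_tt_mm", "significant"]
        assert not frame.loc["d_sa_mm", "significant"]
        # ordered by explained sum of squares, descending
        assert list(frame.sum_sq) == sorted(frame.sum_sq, reverse=True)

    def test_null_data_rarely_flagged(self, ref_design):
        rng = np.random.default_rng(99)
        flags = 0
        n = 200
        for _ in range(n):
            table = iv.anova_main_effects(
                ref_design.with_responses(rng.normal(0, 1, 25))
            )
            flags += sum(
                r.significant
                for r in iv.significance_report(table).table.itertuples()
            )
        rate = flags / (3 * n)
        assert 0.01 < rate < 0.10


@given(st.integers(0, 2**31 - 1))
def test_decomposition_conservation_property(seed):
    rng = np.random.default_rng(seed)
    design = random_balanced_design(rng)
    table = iv.anova_main_effects(design)
    assert sum(table.ss.values()) + table.ss_err == pytest.approx(
        table.ss_total, rel=1e-9, abs=1e-9
    )
    assert all(s >= 0 for s in table.ss.values())
    assert all(0 <= p <= 1 for p in table.p.values())
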