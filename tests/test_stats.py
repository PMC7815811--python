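"""Clinical scoring and the statistical stage."""

import numpy as np
import pandas as pd
import pytest

from dfcpipe.stats import (
    DEFAULT_CIS20R_MAP,
    RegressionBlocks,
    assess_normality,
    classify_severe_fatigue,
    hierarchical_forward_regression,
    paired_compare,
    score_cis20r,
    spearman_profile,
    three_group_compare,
    two_group_compare,
)


class TestScoreCis20r:
    def test_floor_and_ceiling(self):
        lo = score_cis20r([1] * 20)
        assert (
            lo.subjective_complaints,
            lo.motivation,
            lo.physical_activity,
            lo.concentration,
        ) == (8, 4, 3, 5)
        assert lo.total == 20
        assert score_cis20r([7] * 20).total == 140

    def test_subscale_sizes_partition_the_instrument(self):
        sizes = [len(v) for v in DEFAULT_CIS20R_MAP.values()]
        assert sorted(sizes) == [3, 4, 5, 8]
        assert sum(sizes) == 20

    def test_reverse_keying(self):
        items = [1] * 20
        score = score_cis20r(items, reverse_items=(0,))
        assert score.subjective_complaints == 7 + 7  # 8-1 for item 0, 7x1 rest

    @pytest.mark.parametrize("bad", [[0] + [1] * 19, [8] + [1] * 19, [1] * 19])
    def test_invalid_items_rejected(self, bad):
        with pytest.raises(ValueError):
            score_cis20r(bad)


class TestClassifySevereFatigue:
    @pytest.mark.parametrize(
        "total,expected", [(76, "severe"), (75, "non-severe"), (140, "severe"), (20, "non-severe")]
    )
    def test_cutoff_boundary(self, total, expected):
        assert classify_severe_fatigue(total) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_severe_fatigue(10)


class TestAssessNormality:
    def test_gaussian_samples_classified_normal(self):
        hits = 0
        for seed in range(50):
            x = np.random.default_rng(seed).normal(0, 1, 500)
            hits += assess_normality(x) == "normal"
        assert hits >= 45

    def test_skewed_samples_classified_non_normal(self):
        hits = 0
        for seed in range(50):
            x = np.random.default_rng(seed).exponential(1.0, 100)
            hits += assess_normality(x) == "non-normal"
        assert hits >= 45

    def test_constant_sample_degenerate(self):
        assert assess_normality(np.ones(10)) == "non-normal"


class TestTwoGroupCompare:
    def test_identical_samples_null(self, rng):
        x = rng.normal(size=30)
        res = two_group_compare(x, x.copy())
        assert res.p == pytest.approx(1.0) or abs(res.statistic) < 1e-12

    def test_detects_one_sd_shift_at_study_sizes(self):
        hits = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            res = two_group_compare(g.normal(1, 1, 35), g.normal(0, 1, 19))
            hits += res.p < 0.05
        assert hits >= 85  # ~0.9 power once the normality gate is in the loop

    def test_normality_gate_switches_to_mann_whitney(self):
        g = np.random.default_rng(0)
        res = two_group_compare(g.exponential(1, 100), g.exponential(2, 100))
        assert res.name == "mann-whitney"

    def test_welch_fallback_on_variance_ratio(self):
        g = np.random.default_rng(1)
        res = two_group_compare(g.normal(0, 1, 40), g.normal(0, 3, 40))
        assert res.name == "t-test"
        assert res.df != pytest.approx(78)  # fractional Welch df


class TestPairedCompare:
    def test_no_change_detected(self, rng):
        x = rng.normal(size=20)
        res = paired_compare(x, x.copy())
        assert res.p == 1.0 and res.statistic == 0.0

    def test_detects_constant_shift(self):
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            before = g.normal(0, 1, 30)
            after = before + 1 + 0.5 * g.normal(size=30)
            res = paired_compare(before, after)
            hits += res.p < 0.05 and res.statistic > 0
        assert hits >= 18

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1.0], [2.0])


class TestHierarchicalForwardRegression:
    def test_perfect_predictor_selected_alone(self, rng):
        n = 50
        x1 = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "x1": x1,
                "x2": rng.normal(size=n),
                "x3": rng.normal(size=n),
                "y": 2.0 * x1,
            }
        )
        blocks = RegressionBlocks(block1=("x1", "x2"), block3=("x3",), outcome="y")
        res = hierarchical_forward_regression(df, blocks)
        assert res.selected[0] == "x1"
        assert res.r2 == pytest.approx(1.0, abs=1e-6)
        assert res.standardized_beta["x1"] == pytest.approx(1.0, abs=1e-6)

    def test_blocks_enter_in_hierarchical_order(self, rng):
        n = 60
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        df = pd.DataFrame({"a": a, "b": b, "y": a + b + 0.3 * rng.normal(size=n)})
        blocks = RegressionBlocks(block1=("a",), block3=("b",), outcome="y")
        res = hierarchical_forward_regression(df, blocks)
        assert res.selected == ["a", "b"]
        assert res.r2_steps[0] < res.r2_steps[1]
        assert res.delta_r2[1] == pytest.approx(res.r2_steps[1] - res.r2_steps[0])

    def test_pure_noise_outcome_mostly_selects_nothing(self):
        empty = 0
        for seed in range(40):
            g = np.random.default_rng(seed)
            df = pd.DataFrame(
                {"x1": g.normal(size=40), "x2": g.normal(size=40), "y": g.normal(size=40)}
            )
            blocks = RegressionBlocks(block1=("x1", "x2"), outcome="y")
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = hierarchical_forward_regression(df, blocks)
            empty += not res.selected
        assert empty >= 32  # two candidates at p_enter 0.05

    def test_standardized_beta_invariant_to_rescaling(self, rng):
        n = 60
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = x - z + 0.5 * rng.normal(size=n)
        df1 = pd.DataFrame({"x": x, "z": z, "y": y})
        df2 = pd.DataFrame({"x": 1000 * x + 5, "z": 0.01 * z - 3, "y": y})
        blocks = RegressionBlocks(block1=("x", "z"), outcome="y")
        r1 = hierarchical_forward_regression(df1, blocks)
        r2 = hierarchical_forward_regression(df2, blocks)
        for k in ("x", "z"):
            assert r1.standardized_beta[k] == pytest.approx(
                r2.standardized_beta[k], abs=1e-10
            )

    def test_listwise_deletion_and_small_n_guard(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=5), "y": rng.normal(size=5)})
        df.loc[0, "x"] = np.nan
        blocks = RegressionBlocks(block1=("x",), outcome="y")
        res = hierarchical_forward_regression(df, blocks)  # 4 complete cases
        assert res.n == 4


class TestSpearmanProfile:
    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        preds1 = pd.DataFrame({"p": x})
        preds2 = pd.DataFrame({"p": np.exp(3 * x)})
        fat = pd.DataFrame({"total": y})
        r1 = spearman_profile(preds1, fat)
        r2 = spearman_profile(preds2, fat)
        assert r1.loc[0, "rho"] == pytest.approx(r2.loc[0, "rho"], abs=1e-12)

    def test_anti_monotone_pair(self):
        x = np.arange(10.0)
        res = spearman_profile(pd.DataFrame({"p": x}), pd.DataFrame({"t": -x}))
        assert res.loc[0, "rho"] == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_profile(
                pd.DataFrame({"p": [1, 2, 3]}), pd.DataFrame({"t": [1, 2, 3]})
            )


class TestThreeGroupCompare:
    def test_identical_groups_null(self):
        vals = np.ones(10)
        omnibus, pairwise = three_group_compare(
            {"a": vals, "b": vals.copy(), "c": vals.copy()}
        )
        assert omnibus.p == pytest.approx(1.0)
        assert (pairwise["p"] == 1.0).all()

    def test_shifted_group_detected_at_study_sizes(self):
        hits = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            groups = {
                "control": g.normal(0, 1, 19),
                "non-fatigued": g.normal(1.2, 1, 15),
                "fatigued": g.normal(0, 1, 18),
            }
            omnibus, _ = three_group_compare(groups)
            hits += omnibus.p < 0.05
        assert hits >= 80

    def test_pairwise_pattern_matches_shift_structure(self):
        g = np.random.default_rng(7)
        groups = {
            "control": g.normal(0, 1, 60),
            "non-fatigued": g.normal(1.2, 1, 60),
            "fatigued": g.normal(0, 1, 60),
        }
        omnibus, pairwise = three_group_compare(groups)
        assert omnibus.p < 0.05
        lookup = {
            frozenset((r.group_a, r.group_b)): r.p for r in pairwise.itertuples()
        }
        assert lookup[frozenset(("control", "non-fatigued"))] < 0.05
        assert lookup[frozenset(("control", "fatigued"))] > 0.05
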