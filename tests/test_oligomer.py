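"""Distributions, GFP-background correction, averages, comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simpull import (
    CorrectionModel,
    OligomerDistribution,
    OligomerModel,
    average_step,
    build_distribution,
    compare_conditions,
    correct_gfp_background,
    dissolution_difference,
)

TOL = 1e-9


def dist(freqs, n=100, condition="x"):
    return OligomerDistribution(condition=condition, frequencies=freqs, n_traces=n)


@st.composite
def distributions(draw):
    kmax = draw(st.integers(min_value=1, max_value=6))
    raw = [draw(st.floats(min_value=0.0, max_value=1.0)) for _ in range(kmax)]
    if sum(raw) == 0:
        raw[0] = 1.0
    total = sum(raw)
    return dist({k + 1: v / total for k, v in enumerate(raw)})


class TestBuildDistribution:
    def test_single_bin(self):
        d = build_distribution([1, 1, 1])
        assert d.frequencies == {1: 1.0}
        assert d.n_traces == 3

    def test_gfp_control_frequencies(self):
        d = build_distribution([1] * 700 + [2] * 300)
        assert d.frequencies[1] == pytest.approx(0.70)
        assert d.frequencies[2] == pytest.approx(0.30)

    def test_simple_arithmetic(self):
        d = build_distribution([1, 2, 2, 3])
        assert d.frequencies == {1: 0.25, 2: 0.5, 3: 0.25}

    def test_zero_step_traces_excluded(self):
        d = build_distribution([0, 0, 1, 2])
        assert d.n_traces == 2
        assert d.frequencies == {1: 0.5, 2: 0.5}

    def test_invalid_rows_excluded_from_table(self):
        t = pd.DataFrame(
            {"step_count": [1, 2, 9], "valid": [True, True, False]}
        )
        d = build_distribution(t)
        assert d.n_traces == 2

    def test_no_valid_traces_is_error(self):
        with pytest.raises(ValueError):
            build_distribution([0, 0])


class TestCorrection:
    def test_gfp_control_becomes_pure_monomer(self):
        out = correct_gfp_background(dist({1: 0.70, 2: 0.30}), CorrectionModel(0.30))
        assert out.frequencies == {1: 1.0}

    def test_bin2_clipped_at_zero(self):
        out = correct_gfp_background(
            dist({1: 0.50, 2: 0.20, 3: 0.30}), CorrectionModel(0.30)
        )
        assert out.frequencies[1] == pytest.approx(0.70)
        assert out.frequencies.get(2, 0.0) == pytest.approx(0.0)
        assert out.frequencies[3] == pytest.approx(0.30)

    def test_zero_fraction_is_identity(self):
        d = dist({1: 0.6, 2: 0.4})
        out = correct_gfp_background(d, CorrectionModel(0.0))
        assert out.frequencies == d.frequencies

    def test_mode_none_is_identity(self):
        d = dist({1: 0.5, 3: 0.5})
        out = correct_gfp_background(d, CorrectionModel(0.30, mode="none"))
        assert out.frequencies == d.frequencies

    def test_deconvolve_inverts_increment_model_exactly(self):
        # observed(k) = 0.7 d(k) + 0.3 d(k-1) for d = {1:.4,2:.3,3:.2,4:.1}
        d_true = {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
        obs = {}
        for k in range(1, 6):
            obs[k] = 0.7 * d_true.get(k, 0.0) + 0.3 * d_true.get(k - 1, 0.0)
        out = correct_gfp_background(
            dist(obs), CorrectionModel(0.30, mode="deconvolve")
        )
        for k, p in d_true.items():
            assert out.frequencies[k] == pytest.approx(p, abs=1e-12)

    @given(distributions())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mass_conserved_by_every_mode(self, d):
        for mode in ("bin_shift", "none", "deconvolve"):
            out = correct_gfp_background(d, CorrectionModel(0.30, mode=mode))
            assert abs(sum(out.frequencies.values()) - 1.0) <= TOL


class TestAverageStep:
    def test_pure_monomer(self):
        s = average_step(dist({1: 1.0}), n_boot=0)
        assert s.average_step == 1.0

    def test_even_split(self):
        s = average_step(dist({1: 0.5, 2: 0.5}), n_boot=0)
        assert s.average_step == 1.5

    def test_gfp_control_chain(self):
        d = dist({1: 0.7, 2: 0.3})
        assert average_step(d, n_boot=0).average_step == pytest.approx(1.3)
        corrected = correct_gfp_background(d, CorrectionModel(0.30))
        assert average_step(corrected, n_boot=0).average_step == pytest.approx(1.0)

    def test_rightward_mass_shift_increases_average(self):
        base = dist({1: 0.5, 2: 0.3, 3: 0.2})
        shifted = dist({1: 0.4, 2: 0.4, 3: 0.2})  # 0.1 moved from bin 1 to 2
        assert (
            average_step(shifted, n_boot=0).average_step
            > average_step(base, n_boot=0).average_step
        )

    def test_bootstrap_sem_scales_inverse_sqrt_n(self):
        rng = np.random.default_rng(0)
        sems = []
        for n in (250, 1000, 4000):
            counts = rng.choice([1, 2, 3], size=n, p=[0.5, 0.3, 0.2])
            d = build_distribution(counts)
            sems.append(average_step(d, n_boot=400, seed=1).sem)
        assert sems[0] > sems[1] > sems[2]
        assert sems[0] / sems[1] == pytest.approx(2.0, rel=0.35)
        assert sems[1] / sems[2] == pytest.approx(2.0, rel=0.35)

    def test_sem_reproducible_with_seed(self):
        d = build_distribution([1, 2, 2, 3, 1, 1, 2])
        a = average_step(d, n_boot=200, seed=5)
        b = average_step(d, n_boot=200, seed=5)
        assert a.sem == b.sem


class TestDissolutionDifference:
    def test_identical_distributions_give_zeros(self):
        d = dist({1: 0.4, 2: 0.6})
        out = dissolution_difference(d, d)
        assert np.allclose(out["difference"], 0.0)

    def test_signed_difference(self):
        out = dissolution_difference(dist({1: 0.4, 2: 0.6}), dist({1: 0.9, 2: 0.1}))
        assert list(out["difference"]) == pytest.approx([0.5, -0.5])

    def test_union_bins_zero_filled(self):
        out = dissolution_difference(dist({1: 1.0}), dist({1: 0.5, 3: 0.5}))
        assert list(out["step"]) == [1, 3]
        assert out["difference"].sum() == pytest.approx(0.0, abs=TOL)

    @given(distributions(), distributions())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_differences_always_sum_to_zero(self, a, b):
        out = dissolution_difference(a, b)
        assert abs(out["difference"].sum()) <= TOL

    def test_bootstrap_ci_brackets_difference(self):
        rng = np.random.default_rng(2)
        before = build_distribution(rng.choice([1, 2], size=400, p=[0.4, 0.6]))
        after = build_distribution(rng.choice([1, 2], size=400, p=[0.9, 0.1]))
        out = dissolution_difference(before, after, n_boot=300, seed=3)
        assert (out["ci_low"] <= out["difference"]).all()
        assert (out["difference"] <= out["ci_high"]).all()


class TestCompareConditions:
    def test_identical_groups_not_significant(self):
        g = np.array([1, 1, 2, 2, 3, 1, 2])
        out = compare_conditions({"a": g, "b": g.copy()}, test="ttest")
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["pvalue"] == pytest.approx(1.0)

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(4)
        a = rng.normal(1.5, 0.8, size=500)
        b = rng.normal(3.0, 0.8, size=500)
        out = compare_conditions({"a": a, "b": b}, test="ttest")
        assert out["pvalue"] < 0.001
        out2 = compare_conditions({"a": a, "b": b}, test="anova")
        assert out2["pvalue"] < 0.001

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            compare_conditions({"a": np.ones(5)})

    def test_pairwise_adjustment_recorded(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(2, 1, 60) for k in "abc"}
        out = compare_conditions(groups, test="anova", adjust="bonferroni")
        assert out["adjustment"] == "bonferroni"
        assert len(out["pairwise"]) == 3

    def test_two_way_anova_reports_factor_pvalues(self):
        rng = np.random.default_rng(6)
        factors = pd.DataFrame(
            {"a": ["wt", "wt", "mut", "mut"], "b": ["-", "+", "-", "+"]},
            index=["wt-", "wt+", "mut-", "mut+"],
        )
        groups = {
            "wt-": rng.normal(1.5, 0.5, 80),
            "wt+": rng.normal(1.5, 0.5, 80),
            "mut-": rng.normal(3.0, 0.5, 80),
            "mut+": rng.normal(3.0, 0.5, 80),
        }
        out = compare_conditions(groups, test="anova2", factors=factors)
        assert out["pvalue"]["C(a)"] < 0.001
        assert out["pvalue"]["C(b)"] > 0.01


class TestOligomerModel:
    def test_fit_reports_raw_and_corrected(self):
        counts = [1] * 70 + [2] * 30
        res = OligomerModel(counts, condition="GFP").fit(n_boot=200, seed=0)
        assert res.summary_raw.average_step == pytest.approx(1.3)
        assert res.average_step == pytest.approx(1.0)
        assert res.sem >= 0
        text = res.summary()
        assert "GFP" in text and "corrected" in text

    def test_invariants_on_distribution_type(self):
        with pytest.raises(ValueError):
            OligomerDistribution("x", {1: 0.5, 2: 0.4}, 10)  # not normalized
        with pytest.raises(ValueError):
            OligomerDistribution("x", {0: 1.0}, 10)  # bin 0
        with pytest.raises(ValueError):
            OligomerDistribution("x", {1: 1.0}, 0)  # no traces

    def test_pooled_display_bins(self):
        d = dist({1: 0.5, 2: 0.2, 7: 0.2, 8: 0.1})
        pooled = d.pooled(cap=6)
        assert pooled["6+"] == pytest.approx(0.3)
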