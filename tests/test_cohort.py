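"""Method comparison and cohort trend statistics against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipdesq.cohort import (
    compare_to_va,
    find_inflection,
    group_summary,
    local_trend,
    normalize_rates,
    trend_tests,
    validate_cohort,
)
from lipdesq.synthetic import SyntheticCohortSpec, generate_trend_cohort


def _cohort(ages, rates, sex="female"):
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(len(ages))],
        "age": ages, "sex": sex, "rate": rates,
    })


class TestNormalize:
    def test_minmax_scaling(self):
        np.testing.assert_allclose(normalize_rates([0.2, 0.6, 1.0]), [0, 0.5, 1])

    def test_idempotence_on_unit_range(self):
        x = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(normalize_rates(x), x)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.floats(0.1, 50), st.floats(-100, 100))
    def test_affine_invariance(self, a, b):
        x = np.array([0.1, 0.9, 0.4, 0.7])
        np.testing.assert_allclose(normalize_rates(a * x + b), normalize_rates(x),
                                   atol=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_rates([1.0, 1.0, 1.0])


class TestCompareToVA:
    def test_exact_linear_relation(self):
        va = np.array([0.0, 1, 2, 3, 4])
        mc = compare_to_va(0.1 + 0.2 * va, va)
        assert mc.r == pytest.approx(1.0)
        assert mc.mse == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formulas_on_random_fixture(self, rng):
        va = rng.uniform(0, 4, 10)
        rates = rng.uniform(0, 2, 10)
        mc = compare_to_va(rates, va, normalize=False)
        x, y = va, rates
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        r = sxy / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        beta = sxy / ((x - x.mean()) ** 2).sum()
        alpha = y.mean() - beta * x.mean()
        mse = np.mean((y - alpha - beta * x) ** 2)
        assert mc.r == pytest.approx(r, abs=1e-9)
        assert mc.slope == pytest.approx(beta, abs=1e-9)
        assert mc.mse == pytest.approx(mse, abs=1e-9)

    def test_subject_order_invariance(self, rng):
        va = rng.uniform(0, 4, 12)
        rates = rng.uniform(0, 2, 12)
        perm = rng.permutation(12)
        a = compare_to_va(rates, va)
        b = compare_to_va(rates[perm], va[perm])
        assert (a.r, a.mse) == pytest.approx((b.r, b.mse))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_to_va([1.0, 1.0, 1.0], [0, 1, 2])


class TestGroupSummary:
    def test_separated_groups_are_significant(self, rng):
        ages = [25] * 20 + [65] * 20
        rates = np.r_[rng.normal(0.3, 0.05, 20), rng.normal(5.0, 0.05, 20)]
        gs = group_summary(_cohort(ages, rates))
        assert gs.kruskal_p < 1e-3
        assert (gs.pairwise["p_raw"] < 1e-3).all()

    def test_single_group_is_an_error(self, rng):
        with pytest.raises(ValueError):
            group_summary(_cohort([25] * 10, rng.uniform(0, 1, 10)))

    def test_type_one_error_rate_is_calibrated(self):
        # two decade groups drawn from the same distribution
        rej = 0
        n_sim = 200
        rng = np.random.default_rng(7)
        for _ in range(n_sim):
            rates = rng.normal(0.4, 0.1, 60)
            gs = group_summary(_cohort([25] * 30 + [35] * 30, rates))
            rej += gs.kruskal_p < 0.05
        assert 0.02 <= rej / n_sim <= 0.09

    def test_holm_adjustment_is_monotone(self, rng):
        ages = np.repeat([25, 35, 45, 55], 15)
        rates = rng.normal(0.4, 0.1, 60) + 0.02 * (ages == 55)
        gs = group_summary(_cohort(ages, rates))
        assert (gs.pairwise["p_holm"] >= gs.pairwise["p_raw"] - 1e-12).all()


class TestTrendTests:
    def test_exact_linear_trend(self):
        ages = np.arange(20, 70)
        tt = trend_tests(_cohort(ages, 0.01 * ages))
        assert tt.slope == pytest.approx(0.01)
        assert tt.spearman_rho == pytest.approx(1.0)

    def test_reversed_ages_negate_rho(self, rng):
        ages = np.arange(20, 60)
        rates = rng.uniform(0, 1, 40)
        a = trend_tests(_cohort(ages, rates))
        b = trend_tests(_cohort(ages[::-1], rates))
        assert a.spearman_rho == pytest.approx(-b.spearman_rho)

    def test_null_slope_ci_covers_zero(self):
        from scipy import stats
        rng = np.random.default_rng(3)
        covered = 0
        for _ in range(100):
            ages = rng.integers(20, 70, 50)
            rates = rng.normal(0.4, 0.1, 50)  # independent of age
            lr = stats.linregress(ages.astype(float), rates)
            tcrit = stats.t.ppf(0.975, 48)
            covered += abs(lr.slope) <= tcrit * lr.stderr
        assert covered >= 90

    def test_constant_rates_reported_missing(self):
        tt = trend_tests(_cohort(np.arange(20, 40), np.full(20, 0.4)))
        assert np.isnan(tt.spearman_rho)


class TestLocalTrend:
    def test_reproduces_exactly_linear_data(self):
        ages = np.arange(20, 70)
        curve = local_trend(_cohort(ages, 0.01 * ages), span=0.75)
        interior = curve[(curve["age"] > 25) & (curve["age"] < 64)]
        np.testing.assert_allclose(interior["fitted"], 0.01 * interior["age"],
                                   atol=1e-6)

    def test_recovers_planted_peak_location(self):
        rng = np.random.default_rng(42)
        ages = np.repeat(np.arange(20, 70), 10)
        mu = np.where(ages <= 40, 0.2 + 0.02 * (ages - 20), 0.6 - 0.01 * (ages - 40))
        curve = local_trend(_cohort(ages, mu + rng.normal(0, 0.05, ages.size)),
                            span=0.4)
        peak_age = curve.loc[curve["fitted"].idxmax(), "age"]
        assert abs(peak_age - 40) <= 3

    def test_larger_span_is_smoother(self, rng):
        ages = np.repeat(np.arange(20, 70), 4)
        rates = rng.normal(0.4, 0.2, ages.size)
        def roughness(span):
            c = local_trend(_cohort(ages, rates), span=span)["fitted"].to_numpy()
            return np.sum(np.diff(c, 2) ** 2)
        assert roughness(1.0) <= roughness(0.3)

    def test_span_validation(self):
        with pytest.raises(ValueError):
            local_trend(_cohort(np.arange(20, 60), np.ones(40)), span=1.5)


class TestFindInflection:
    def test_noiseless_v_shape_recovered_exactly(self):
        ages = np.repeat(np.arange(20, 70), 2)
        rates = np.abs(ages - 45) * -0.01 + 1.0  # vertex at 45
        r = find_inflection(_cohort(ages, rates), min_side_n=10)
        assert r.breakpoint_age == 45
        assert r.significant

    def test_record_order_invariance(self):
        df = generate_trend_cohort(SyntheticCohortSpec(seed=1))
        shuffled = df.sample(frac=1.0, random_state=0)
        a = find_inflection(df, sex="female")
        b = find_inflection(shuffled, sex="female")
        assert a.breakpoint_age == b.breakpoint_age
        assert a.p_min == pytest.approx(b.p_min)

    def test_affine_rate_rescaling_leaves_breakpoint(self):
        df = generate_trend_cohort(SyntheticCohortSpec(seed=2))
        scaled = df.assign(rate=df["rate"] * 7.5 + 3.0)
        a = find_inflection(df, sex="female")
        b = find_inflection(scaled, sex="female")
        assert a.breakpoint_age == b.breakpoint_age
        assert a.p_min == pytest.approx(b.p_min, rel=1e-9)

    def test_two_fit_method_agrees_on_strong_break(self):
        df = generate_trend_cohort(SyntheticCohortSpec(seed=3))
        a = find_inflection(df, sex="female", method="interaction")
        b = find_inflection(df, sex="female", method="two_fit")
        assert abs(a.breakpoint_age - b.breakpoint_age) <= 2

    def test_min_side_n_constrains_candidates(self):
        df = generate_trend_cohort(SyntheticCohortSpec(seed=4))
        r = find_inflection(df, sex="female", min_side_n=30)
        ages = df.loc[df.sex == "female", "age"]
        for a in r.p_by_age:
            assert (ages <= a).sum() >= 30 and (ages > a).sum() >= 30

    def test_too_few_records_is_an_error(self):
        with pytest.raises(ValueError):
            find_inflection(_cohort([25, 30, 35], [0.1, 0.2, 0.3]), min_side_n=30)

    def test_summary_mentions_breakpoint(self):
        df = generate_trend_cohort(SyntheticCohortSpec(seed=5))
        text = find_inflection(df, sex="female").summary()
        assert "breakpoint age" in text


def test_validate_cohort_rejects_bad_rows():
    with pytest.raises(ValueError):
        validate_cohort(_cohort([25, 99], [0.1, 0.2]))
    with pytest.raises(ValueError):
        validate_cohort(_cohort([25, 30], [0.1, -0.2]))
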