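import numpy as np
import pytest

from tigrisim import (
    EffectConfig,
    TreatmentEffect,
    VarianceSample,
    generate_experiment_dataset,
    permutation_variance_test,
    trait_variances,
    welch_log_variance_test,
)


def welch_oracle(x, y):
    """Textbook Welch statistic and Welch-Satterthwaite df, coded from the
    formulas independently of the implementation under test."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx)**2 / (nx - 1) + (vy / ny)**2 / (ny - 1))
    return t, df


class TestTraitVariances:
    def test_degenerate_distribution_has_zero_variance(self):
        assert trait_variances([0.03, 0.03, 0.03]) == 0.0

    def test_two_point_sample(self):
        assert trait_variances([0.02, 0.04]) == pytest.approx(2e-4)

    def test_order_invariance(self, rng):
        values = rng.uniform(6.25, 12.5, 50)
        assert trait_variances(values) == pytest.approx(
            trait_variances(values[::-1]), abs=1e-15)

    def test_single_value_is_undefined(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            trait_variances([0.03])


class TestWelchLogVariance:
    def test_identical_samples_give_null_result(self):
        t, df, p = welch_log_variance_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swapping_samples_negates_t(self):
        t1, df1, p1 = welch_log_variance_test([1, 2, 3, 4], [2, 4, 8])
        t2, df2, p2 = welch_log_variance_test([2, 4, 8], [1, 2, 3, 4])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        assert df1 == pytest.approx(df2)

    def test_fixed_vectors_match_hand_computation(self):
        a, b = [1, 2, 3, 4], [2, 4, 8]
        t, df, _ = welch_log_variance_test(a, b)
        t_ref, df_ref = welch_oracle(np.log(a), np.log(b))
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert df == pytest.approx(df_ref, abs=1e-12)

    def test_agrees_with_oracle_on_random_pairs(self, rng):
        for _ in range(100):
            a = rng.lognormal(0, 1, rng.integers(2, 40))
            b = rng.lognormal(0.5, 2, rng.integers(2, 40))
            t, df, _ = welch_log_variance_test(a, b)
            t_ref, df_ref = welch_oracle(np.log(a), np.log(b))
            assert abs(t - t_ref) < 1e-10
            assert abs(df - df_ref) < 1e-10

    def test_missing_values_dropped_via_variance_sample(self):
        a = VarianceSample("slow", np.array([1.0, np.nan, 2.0, 3.0]))
        b = VarianceSample("fast", np.array([0.5, 0.7, np.nan]))
        t, df, p = welch_log_variance_test(a, b)
        t2, _, _ = welch_log_variance_test([1.0, 2.0, 3.0], [0.5, 0.7])
        assert t == pytest.approx(t2)

    def test_non_positive_variances_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            welch_log_variance_test([1.0, 0.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match=">= 2"):
            welch_log_variance_test([1.0], [1.0, 2.0])


def _measurements(dataset, treatment, trait="f"):
    return dataset.replicate_measurements(treatment, trait)


class TestPermutationTest:
    def test_contract_and_reproducibility(self):
        ds = generate_experiment_dataset(rng=0)
        kwargs = dict(
            measurements_a=_measurements(ds, "deterministic_fast"),
            measurements_b=_measurements(ds, "deterministic_slow"),
            pool=_measurements(ds, "stochastic_slow"),
            n_permutations=2000,
        )
        r1 = permutation_variance_test(rng=7, **kwargs)
        r2 = permutation_variance_test(rng=7, **kwargs)
        assert 0.0 <= r1.p_value <= 1.0
        assert len(r1.null_distribution) == 2000
        assert len(r1.universal_pdf) == 8 + 8
        np.testing.assert_array_equal(r1.null_distribution, r2.null_distribution)
        np.testing.assert_array_equal(r1.universal_pdf, r2.universal_pdf)
        assert r1.p_value == r2.p_value

    def test_group_size_larger_than_pool_rejected(self):
        ds = generate_experiment_dataset(rng=1)
        with pytest.raises(ValueError, match="group_size"):
            permutation_variance_test(
                _measurements(ds, "deterministic_fast"),
                _measurements(ds, "deterministic_slow"),
                group_size=10_000, n_permutations=100, rng=0)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            permutation_variance_test([[1, 2, 3]], [[1, 2], [3, 4]],
                                      group_size=2, n_permutations=10, rng=0)

    def test_inflated_variance_detected(self):
        inflate = EffectConfig(treatments={
            "stochastic_slow": TreatmentEffect(maturity_var=4.0, interval_var=4.0)})
        ds = generate_experiment_dataset(effect_config=inflate, rng=3)
        res = permutation_variance_test(
            _measurements(ds, "deterministic_fast"),
            _measurements(ds, "stochastic_slow"),
            pool=_measurements(ds, "deterministic_slow"),
            n_permutations=2000, rng=4)
        assert res.observed_difference > 0
        assert res.p_value < 0.05

    def test_null_rejection_rate_near_nominal(self):
        # small-n calibration check; the full 500-dataset calibration runs
        # with the acceptance suite
        rejections = 0
        for i in range(100):
            ds = generate_experiment_dataset(rng=500 + i)
            res = permutation_variance_test(
                _measurements(ds, "deterministic_fast"),
                _measurements(ds, "deterministic_slow"),
                pool=_measurements(ds, "stochastic_slow"),
                n_permutations=1000, rng=900 + i)
            rejections += res.p_value < 0.05
        assert rejections <= 15

    def test_pool_scope_and_oversampling_options(self):
        ds = generate_experiment_dataset(rng=11)
        a = _measurements(ds, "deterministic_fast")
        b = _measurements(ds, "deterministic_slow")
        pairwise = permutation_variance_test(
            a, b, pool=_measurements(ds, "stochastic_slow"),
            pool_scope="pairwise", n_permutations=500, rng=1)
        oversampled = permutation_variance_test(
            a, b, pdf_oversample=10, n_permutations=500, rng=1)
        redrawn = permutation_variance_test(
            a, b, redraw_universal_pdf=True, n_permutations=200, rng=1)
        assert len(oversampled.universal_pdf) == 160
        for res in (pairwise, oversampled, redrawn):
            assert 0.0 <= res.p_value <= 1.0

    def test_single_measurement_replicate_feeds_pool_only(self):
        rng = np.random.default_rng(0)
        reps_a = [rng.normal(0, 1, 30) for _ in range(3)] + [np.array([0.2])]
        reps_b = [rng.normal(0, 1, 30) for _ in range(3)]
        res = permutation_variance_test(reps_a, reps_b, group_size=20,
                                        n_permutations=200, rng=1)
        assert np.isfinite(res.observed_difference)
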