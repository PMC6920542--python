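"""Frequentist estimators: marginal OLS, ratio/weighted-median, bootstrap CI, Egger."""

import numpy as np
import pytest

from bayesmr import (
    EstimateWithInterval,
    InstrumentSummary,
    ObservedData,
    egger_regression,
    per_instrument_associations,
    ratio_estimates,
    weighted_median,
    wme_with_ci,
)
from bayesmr.frequentist import read_summary, write_summary


from _oracles import brute_force_weighted_median


class TestPerInstrumentAssociations:
    def test_perfect_line_and_flat_response(self):
        d = ObservedData(Y=[5.0, 5.0, 5.0], X=[0.0, 1.0, 2.0], Z=np.array([[0], [1], [2]]))
        s = per_instrument_associations(d)
        assert s.beta_X[0] == pytest.approx(1.0)
        assert s.beta_Y[0] == pytest.approx(0.0)

    def test_hand_ols_on_four_points(self):
        Z = np.array([[0], [0], [1], [2]])
        X = np.array([1.0, 2.0, 2.0, 4.0])
        d = ObservedData(Y=X, X=X, Z=Z)
        s = per_instrument_associations(d)
        z = Z[:, 0]
        expected = ((z - z.mean()) @ (X - X.mean())) / ((z - z.mean()) @ (z - z.mean()))
        assert s.beta_X[0] == pytest.approx(expected, rel=1e-12)

    def test_matches_statsmodels(self, scenario3_dataset):
        import statsmodels.api as sm

        _, d = scenario3_dataset
        s = per_instrument_associations(d)
        for j in (0, 17, 59):
            fit = sm.OLS(d.X, sm.add_constant(d.Z[:, j].astype(float))).fit()
            assert s.beta_X[j] == pytest.approx(fit.params[1], rel=1e-10)
            assert s.se_X[j] == pytest.approx(fit.bse[1], rel=1e-10)

    def test_constant_column_names_offender(self):
        Z = np.array([[1, 0], [1, 1], [1, 2], [1, 0]])
        d = ObservedData(Y=np.arange(4.0), X=np.arange(4.0), Z=Z)
        with pytest.raises(ValueError, match=r"\[0\]"):
            per_instrument_associations(d)


class TestRatioEstimates:
    def test_arithmetic(self):
        s = InstrumentSummary(
            beta_X=[0.5], se_X=[0.1], beta_Y=[1.0], se_Y=[0.1]
        )
        ratios, weights = ratio_estimates(s)
        assert ratios[0] == pytest.approx(2.0)
        assert weights[0] == pytest.approx(25.0)

    def test_zero_exposure_association_errors(self):
        s = InstrumentSummary(beta_X=[0.0], se_X=[0.1], beta_Y=[1.0], se_Y=[0.1])
        with pytest.raises(ValueError, match="ratio undefined"):
            ratio_estimates(s)

    def test_noise_free_structural_recovery(self, clean_iv_dataset):
        params, d = clean_iv_dataset
        ratios, _ = ratio_estimates(per_instrument_associations(d))
        assert np.allclose(ratios, 2.0, atol=1e-6)


class TestWeightedMedian:
    def test_singleton(self):
        assert weighted_median([3.7], [0.2]) == pytest.approx(3.7)

    def test_equal_weights_hits_middle(self):
        assert weighted_median([1, 2, 3], [1, 1, 1]) == pytest.approx(2.0)

    def test_dominant_weight_interpolation(self):
        # p = (0.495, 0.995); interpolate at 0.5 between values 1 and 100
        assert weighted_median([1, 100], [0.99, 0.01]) == pytest.approx(1.99)

    def test_empty_and_nonpositive_weights(self):
        with pytest.raises(ValueError):
            weighted_median([], [])
        with pytest.raises(ValueError):
            weighted_median([1.0, 2.0], [1.0, 0.0])

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            J = int(rng.integers(1, 10))
            vals = rng.normal(size=J) * 10
            vals += 1e-6 * np.arange(J)  # keep values distinct
            w = rng.uniform(0.05, 3.0, size=J)
            assert weighted_median(vals, w) == pytest.approx(
                brute_force_weighted_median(vals, w), abs=1e-9
            )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=7)
        w = rng.uniform(0.1, 2.0, size=7)
        ref = weighted_median(vals, w)
        for _ in range(20):
            perm = rng.permutation(7)
            assert weighted_median(vals[perm], w[perm]) == pytest.approx(ref)


class TestWmeWithCi:
    def test_degenerate_noise_free_bootstrap(self, clean_iv_dataset):
        _, d = clean_iv_dataset
        est = wme_with_ci(d, n_boot=200, rng=0)
        assert est.point == pytest.approx(2.0, abs=1e-6)
        assert est.upper - est.lower < 1e-6

    def test_deterministic_given_seed(self, scenario3_dataset):
        _, d = scenario3_dataset
        a = wme_with_ci(d, n_boot=200, rng=42)
        b = wme_with_ci(d, n_boot=200, rng=42)
        assert (a.point, a.lower, a.upper) == (b.point, b.lower, b.upper)

    def test_summary_scheme_runs(self, scenario3_dataset):
        _, d = scenario3_dataset
        est = wme_with_ci(d, n_boot=300, rng=1, scheme="summary")
        assert est.lower < est.point < est.upper

    def test_n_boot_floor(self, scenario3_dataset):
        _, d = scenario3_dataset
        with pytest.raises(ValueError):
            wme_with_ci(d, n_boot=50, rng=0)

    def test_percentile_endpoints_definition(self, scenario3_dataset):
        from bayesmr.frequentist import _bootstrap_wme

        _, d = scenario3_dataset
        boots, _ = _bootstrap_wme(d.X, d.Y, d.Z.astype(float), 500, np.random.default_rng(9))
        est = wme_with_ci(d, n_boot=500, rng=np.random.default_rng(9), level=0.95)
        assert est.lower == pytest.approx(np.quantile(boots, 0.025))
        assert est.upper == pytest.approx(np.quantile(boots, 0.975))


def test_wme_consistency_with_half_invalid_weight():
    """Median consistency: >=50% valid instruments, bias vanishes at large n."""
    from bayesmr import draw_structural_params, simulate_dataset, simulate_genotypes, benchmark_scenario

    spec = benchmark_scenario(3)
    rng = np.random.default_rng(77)
    G = simulate_genotypes(20_000, 60, seed=rng)
    points = []
    for _ in range(50):
        params = draw_structural_params(spec, "alternative", rng)
        d = simulate_dataset(params, G, rng)
        ratios, weights = ratio_estimates(per_instrument_associations(d))
        points.append(weighted_median(ratios, weights))
    assert abs(np.mean(points) - 0.35) < 0.02


class TestEgger:
    def test_exact_fit(self):
        bx = np.array([0.2, 0.5, 1.0, 1.5])
        s = InstrumentSummary(
            beta_X=bx, se_X=np.full(4, 0.1), beta_Y=0.35 * bx, se_Y=np.full(4, 0.1)
        )
        slope, intercept = egger_regression(s)
        assert slope.point == pytest.approx(0.35, abs=1e-12)
        assert intercept.point == pytest.approx(0.0, abs=1e-12)

    def test_sign_recoding_three_points(self):
        s = InstrumentSummary(
            beta_X=[-1.0, 2.0, 1.0], se_X=[0.1] * 3, beta_Y=[-2.0, 4.0, 2.0], se_Y=[1.0] * 3
        )
        slope, intercept = egger_regression(s)
        assert slope.point == pytest.approx(2.0, abs=1e-12)
        assert intercept.point == pytest.approx(0.0, abs=1e-12)

    def test_recoding_is_involution_and_allele_coding_invariant(self, scenario3_dataset):
        _, d = scenario3_dataset
        s = per_instrument_associations(d)
        base_slope, base_int = egger_regression(s)
        # flip the allele coding of a few instruments: dose -> 2 - dose
        Z2 = d.Z.copy()
        for j in (0, 5, 41):
            Z2[:, j] = 2 - Z2[:, j]
        d2 = ObservedData(Y=d.Y, X=d.X, Z=Z2)
        slope2, int2 = egger_regression(per_instrument_associations(d2))
        assert slope2.point == pytest.approx(base_slope.point, rel=1e-9)
        assert int2.point == pytest.approx(base_int.point, rel=1e-9)

    def test_needs_three_instruments(self):
        s = InstrumentSummary(beta_X=[1.0, 2.0], se_X=[0.1] * 2, beta_Y=[1.0, 2.0], se_Y=[0.1] * 2)
        with pytest.raises(ValueError):
            egger_regression(s)

    def test_matches_statsmodels_wls(self, scenario3_dataset):
        import statsmodels.api as sm

        _, d = scenario3_dataset
        s = per_instrument_associations(d)
        sign = np.where(s.beta_X < 0, -1.0, 1.0)
        bx, by = s.beta_X * sign, s.beta_Y * sign
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / s.se_Y**2).fit()
        slope, intercept = egger_regression(s)
        assert slope.point == pytest.approx(fit.params[1], rel=1e-10)
        ci = fit.conf_int(alpha=0.05)
        assert slope.lower == pytest.approx(ci[1][0], rel=1e-8)
        assert slope.upper == pytest.approx(ci[1][1], rel=1e-8)

    def test_balanced_pleiotropy_large_j_recovers_theta(self):
        # needs strong instrument-strength variance (sigma_alpha >> slope SE),
        # otherwise the Egger slope suffers regression-dilution attenuation
        from bayesmr import draw_structural_params, simulate_dataset, simulate_genotypes, benchmark_scenario
        from dataclasses import replace

        spec = replace(benchmark_scenario(11), n_individuals=5000, J=200)
        rng = np.random.default_rng(88)
        G = simulate_genotypes(5000, 200, seed=rng)
        params = draw_structural_params(spec, "alternative", rng)
        d = simulate_dataset(params, G, rng)
        slope, _ = egger_regression(per_instrument_associations(d))
        assert slope.point == pytest.approx(0.35, abs=0.05)


class TestEstimatorPermutationInvariance:
    def test_instrument_order_irrelevant(self, scenario3_dataset):
        _, d = scenario3_dataset
        rng = np.random.default_rng(4)
        perm = rng.permutation(d.J)
        d2 = ObservedData(Y=d.Y, X=d.X, Z=d.Z[:, perm])
        s1 = per_instrument_associations(d)
        s2 = per_instrument_associations(d2)
        r1, w1 = ratio_estimates(s1)
        r2, w2 = ratio_estimates(s2)
        assert weighted_median(r1, w1) == pytest.approx(weighted_median(r2, w2))
        e1, _ = egger_regression(s1)
        e2, _ = egger_regression(s2)
        assert e1.point == pytest.approx(e2.point)


def test_summary_round_trip(tmp_path, scenario3_dataset):
    _, d = scenario3_dataset
    s = per_instrument_associations(d)
    path = tmp_path / "summary.tsv"
    write_summary(s, path)
    back = read_summary(path)
    assert np.allclose(back.beta_X, s.beta_X)
    assert np.allclose(back.se_Y, s.se_Y)


def test_interval_container_validates_order():
    with pytest.raises(ValueError):
        EstimateWithInterval(point=0.0, lower=1.0, upper=-1.0)
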