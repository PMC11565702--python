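import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit import estimators
from mrkit.exceptions import DegenerateInstrumentError, InsufficientInstrumentsError

from conftest import make_harmonized


def random_instance(rng, n):
    """Random well-conditioned harmonized set."""
    return make_harmonized(
        beta_exp=rng.uniform(0.2, 1.5, n) * rng.choice([-1, 1], n),
        se_exp=rng.uniform(0.01, 0.1, n),
        beta_out=rng.normal(0, 0.3, n),
        se_out=rng.uniform(0.01, 0.1, n),
    )


class TestWaldRatio:
    def test_direct_division(self):
        est = estimators.wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)

    def test_null_outcome_gives_p_one(self):
        est = estimators.wald_ratio(1.0, 0.1, 0.0, 0.1)
        assert est.beta == 0.0
        assert est.pval == pytest.approx(1.0)

    def test_sign_law(self):
        est = estimators.wald_ratio(-0.5, 0.05, 0.1, 0.02)
        assert est.beta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.04)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(DegenerateInstrumentError):
            estimators.wald_ratio(0.0, 0.05, 0.1, 0.02)


class TestIvw:
    def test_two_snp_closed_form(self):
        h = make_harmonized([1.0, 2.0], [0.01, 0.01], [0.2, 0.4], [0.1, 0.1])
        est = estimators.ivw(h, "fixed")
        assert est.beta == pytest.approx(0.2, abs=1e-15)
        assert est.se == pytest.approx(1 / math.sqrt(500), abs=1e-15)
        assert est.extra["Q"] == pytest.approx(0.0, abs=1e-12)

    def test_null_outcome_effects(self):
        h = make_harmonized([1.0, 2.0, 0.5], [0.01] * 3, [0.0] * 3, [0.1] * 3)
        assert estimators.ivw(h, "fixed").beta == 0.0

    def test_matches_weighted_mean_of_ratios(self, rng):
        for _ in range(50):
            h = random_instance(rng, int(rng.integers(2, 30)))
            est = estimators.ivw(h, "fixed")
            ratios = h.beta_out / h.beta_exp
            w = h.beta_exp**2 / h.se_out**2
            assert est.beta == pytest.approx(
                float(np.sum(w * ratios) / np.sum(w)), abs=1e-12
            )

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(20):
            h = random_instance(rng, 10)
            fe = estimators.ivw(h, "fixed")
            re = estimators.ivw(h, "random")
            assert re.se >= fe.se
            assert re.beta == pytest.approx(fe.beta)

    def test_auto_gates_on_heterogeneity(self):
        homogeneous = make_harmonized(
            [1.0, 2.0, 1.5], [0.01] * 3, [0.2, 0.4, 0.3], [0.1] * 3
        )
        assert estimators.ivw(homogeneous, "auto").extra["model_used"] == "fixed"
        heterogeneous = make_harmonized(
            [1.0, 1.0, 1.0], [0.01] * 3, [0.0, 0.5, -0.5], [0.01] * 3
        )
        est = estimators.ivw(heterogeneous, "auto")
        assert est.extra["Q_pval"] < 0.05
        assert est.extra["model_used"] == "random"

    def test_single_snp_raises(self):
        h = make_harmonized([1.0], [0.01], [0.2], [0.1])
        with pytest.raises(InsufficientInstrumentsError):
            estimators.ivw(h)


class TestEgger:
    def test_exact_collinear_fit(self):
        h = make_harmonized(
            [1.0, 2.0, 3.0], [0.01] * 3, [0.2, 0.4, 0.6], [0.1] * 3
        )
        est = estimators.egger(h)
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.extra["egger_intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_affine_shift_moves_intercept_only(self):
        h = make_harmonized(
            [1.0, 2.0, 3.0], [0.01] * 3,
            [0.25, 0.45, 0.65], [0.1] * 3,  # +0.05 vertical shift
        )
        est = estimators.egger(h)
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.extra["egger_intercept"] == pytest.approx(0.05, abs=1e-12)

    def test_invariant_to_flipping_one_snp(self, rng):
        h = random_instance(rng, 12)
        est = estimators.egger(h)
        flipped = make_harmonized(
            h.beta_exp * np.where(np.arange(12) == 3, -1, 1),
            h.se_exp,
            h.beta_out * np.where(np.arange(12) == 3, -1, 1),
            h.se_out,
        )
        est_f = estimators.egger(flipped)
        assert est_f.beta == pytest.approx(est.beta, abs=1e-12)
        assert est_f.extra["egger_intercept"] == pytest.approx(
            est.extra["egger_intercept"], abs=1e-12
        )

    def test_too_few_snps_raises(self):
        h = make_harmonized([1.0, 2.0], [0.01] * 2, [0.2, 0.4], [0.1] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            estimators.egger(h)


class TestWeightedMedian:
    def test_equal_weights_lands_on_middle_ratio(self):
        h = make_harmonized(
            [1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.2, 0.9], [0.1] * 3
        )
        est = estimators.weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_identical_ratios_small_bootstrap_se(self):
        h = make_harmonized(
            [1.0, 2.0, 0.5], [0.001] * 3, [0.3, 0.6, 0.15], [0.001] * 3
        )
        est = estimators.weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.3)
        assert est.se < 0.01

    def test_equal_weights_odd_n_equals_sample_median(self, rng):
        for _ in range(10):
            n = int(rng.choice([3, 5, 7, 9]))
            ratios = rng.normal(0, 1, n)
            h = make_harmonized(np.ones(n), np.full(n, 0.01), ratios, np.ones(n))
            est = estimators.weighted_median(h, n_boot=10, seed=0)
            assert est.beta == pytest.approx(float(np.median(ratios)), abs=1e-12)

    def test_seeded_bootstrap_reproducible(self, small_harmonized):
        a = estimators.weighted_median(small_harmonized, n_boot=100, seed=7)
        b = estimators.weighted_median(small_harmonized, n_boot=100, seed=7)
        assert a.se == b.se


class TestWeightedMode:
    def test_majority_cluster_wins(self):
        h = make_harmonized(
            [1.0] * 4, [0.01] * 4, [0.2, 0.2, 0.2, 0.9], [0.05] * 4
        )
        est = estimators.weighted_mode(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2, abs=0.05)

    def test_tight_cluster_recovered_within_grid(self):
        h = make_harmonized(
            [1.0, 1.0, 1.0], [0.01] * 3, [0.5, 0.5001, 0.4999], [0.05] * 3
        )
        est = estimators.weighted_mode(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-3)

    def test_bimodal_sixty_forty_lands_in_major_mode(self, rng):
        ratios = np.concatenate([np.full(6, 0.1), np.full(4, 0.8)])
        ratios = ratios + rng.normal(0, 0.005, 10)
        h = make_harmonized(np.ones(10), np.full(10, 0.01), ratios, np.ones(10))
        est = estimators.weighted_mode(h, n_boot=10, seed=0)
        assert abs(est.beta - 0.1) < abs(est.beta - 0.8)
        # dense-grid brute force agrees
        w = np.ones(10)
        dense = estimators._weighted_mode(ratios, w, phi=1.0, grid_size=200_000)
        assert est.beta == pytest.approx(dense, abs=1e-3)


class TestInvariants:
    def test_outcome_scale_equivariance(self, rng):
        c = 2.5
        for method, kwargs in [
            (estimators.ivw, {}),
            (estimators.egger, {}),
            (estimators.weighted_median, {"n_boot": 50, "seed": 3}),
            (estimators.weighted_mode, {"n_boot": 50, "seed": 3}),
        ]:
            h = random_instance(rng, 10)
            scaled = make_harmonized(
                h.beta_exp, h.se_exp, c * h.beta_out, c * h.se_out
            )
            base = method(h, **kwargs)
            scl = method(scaled, **kwargs)
            assert scl.beta == pytest.approx(c * base.beta, rel=1e-6), method
            assert scl.se == pytest.approx(c * base.se, rel=0.3), method

    @given(
        beta=st.floats(-3, 3, allow_nan=False),
        se=st.floats(0.01, 2, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_estimate_invariants(self, beta, se):
        est = estimators.MREstimate("m", beta, se, 0.5, n_snps=2)
        assert est.ci_low <= est.beta <= est.ci_high
        assert est.odds_ratio == pytest.approx(math.exp(beta))
        assert est.or_ci_low <= est.odds_ratio <= est.or_ci_high
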