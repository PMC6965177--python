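"""Tests for the closed-form correlation, attenuation and regime analysis."""

import math

import numpy as np
import pytest

from corrnoise import (
    ErrorSpec,
    Regime,
    TrueSignal,
    attenuation_coeff,
    classify_regime,
    error_ratios,
    expected_corr,
    expected_corr_raw,
    limiting_surface,
    null_corr,
    sample_corr,
    simulate_bivariate,
)
from corrnoise.analytic import expected_corr_grid
from conftest import MODEL_KINDS, random_error, random_signal


def symmetric_signal(rho0: float, mu: float = 0.0) -> TrueSignal:
    return TrueSignal(mu_x=mu, mu_y=mu, var_x=1.0, var_y=1.0, rho0=rho0)


class TestErrorRatios:
    def test_round_trip(self):
        sig = TrueSignal(3.0, -2.0, 4.0, 1.0, 0.2)
        err = ErrorSpec.realistic(var_au_x=1.0, var_au_y=0.25, var_ac=0.09)
        ratios = error_ratios(sig, err)
        assert ratios.xi2_x == pytest.approx(1.0 / 4.0)
        assert ratios.xi2_y == pytest.approx(0.25)
        assert ratios.gamma_x == pytest.approx(0.3 / 2.0)
        assert ratios.delta_x == pytest.approx(1.5)
        assert ratios.delta_y == pytest.approx(-2.0)
        # reconstruct the absolute variances from the ratios
        assert ratios.xi2_x * sig.var_x == pytest.approx(err.var_au_x)
        assert ratios.gamma2_y * sig.var_y == pytest.approx(err.var_ac_y)


class TestAttenuation:
    def test_spearman_value(self):
        sig = symmetric_signal(0.8)
        err = ErrorSpec.additive(0.75)
        assert attenuation_coeff(sig, err) == pytest.approx(1.0 / 1.75, abs=1e-14)

    def test_no_error_is_one(self):
        assert attenuation_coeff(symmetric_signal(0.3), ErrorSpec.none()) == 1.0

    def test_multiplicative_value(self):
        sig = symmetric_signal(0.0, mu=1.0)
        err = ErrorSpec.multiplicative(var_mu_x=0.1, var_mu_y=0.1)
        assert attenuation_coeff(sig, err) == pytest.approx(1.0 / 1.2, abs=1e-14)

    def test_strictly_decreasing_in_each_variance(self):
        sig = TrueSignal(1.0, 2.0, 1.5, 0.8, 0.4)
        base = dict(var_au_x=0.1, var_au_y=0.1, var_ac_x=0.05, var_ac_y=0.05,
                    var_mu_x=0.02, var_mu_y=0.02, var_mc_x=0.01, var_mc_y=0.01)
        a0 = attenuation_coeff(sig, ErrorSpec.generalized(**base))
        for key in base:
            bumped = dict(base)
            bumped[key] = base[key] + 0.05
            assert attenuation_coeff(sig, ErrorSpec.generalized(**bumped)) < a0

    def test_vanishes_as_uncorrelated_error_grows(self):
        sig = symmetric_signal(0.8)
        big = ErrorSpec.additive(1e8, 1e8, var_ac=0.25)
        assert abs(expected_corr(sig, big).rho) < 1e-6


class TestExpectedCorr:
    def test_symmetric_additive_value(self):
        # rho0=0.8, xi^2 = gamma^2 = 0.25, positive sign -> (0.8+0.25)/1.5
        sig = symmetric_signal(0.8)
        err = ErrorSpec.additive(0.25, var_ac=0.25, sign=+1)
        assert expected_corr(sig, err).rho == pytest.approx(0.7, abs=1e-14)

    def test_no_error_identity(self):
        for rho0 in (-0.6, 0.0, 0.45):
            assert expected_corr(symmetric_signal(rho0), ErrorSpec.none()).rho == rho0

    def test_multiplicative_null_value(self):
        sig = symmetric_signal(0.0, mu=1.0)
        err = ErrorSpec.multiplicative(var_mc=0.1)
        assert expected_corr(sig, err).rho == pytest.approx(0.1 / 1.2, abs=1e-14)

    def test_realistic_value(self):
        sig = symmetric_signal(0.5, mu=1.0)
        err = ErrorSpec.realistic(var_ac=0.25, var_mc=0.1, sign=+1)
        assert expected_corr(sig, err).rho == pytest.approx(0.9 / 1.45, abs=1e-14)

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_agrees_with_raw_moment_form(self, kind):
        master = np.random.default_rng(7)
        for _ in range(50):
            sig = random_signal(master)
            err = random_error(master, kind)
            assert expected_corr(sig, err).rho == pytest.approx(
                expected_corr_raw(sig, err), abs=1e-12
            )

    def test_bounded_by_one_over_sweep(self):
        master = np.random.default_rng(11)
        kinds = MODEL_KINDS * 2000
        for kind in kinds:
            sig = random_signal(master, mu_max=10.0)
            err = random_error(master, kind, scale=1.5)
            assert abs(expected_corr(sig, err).rho) <= 1.0 + 1e-12

    @pytest.mark.parametrize("kind", ["additive", "multiplicative", "realistic"])
    def test_monte_carlo_oracle(self, kind):
        """Closed form matches the simulated sample correlation (subset of
        the full acceptance sweep)."""
        n = 300_000
        master = np.random.default_rng(23)
        for i in range(3):
            sig = random_signal(master)
            err = random_error(master, kind)
            rho = expected_corr(sig, err).rho
            r = sample_corr(simulate_bivariate(sig, err, n, seed=3000 + i).data)
            assert r == pytest.approx(rho, abs=5.0 * (1.0 - rho**2) / math.sqrt(n))

    def test_vectorized_matches_scalar(self):
        master = np.random.default_rng(40)
        for _ in range(30):
            sig = random_signal(master, mu_max=5.0)
            pi = float(master.choice([-1.0, 1.0]))
            kw = dict(var_au_x=master.uniform(0, 0.4), var_au_y=master.uniform(0, 0.4),
                      var_ac=master.uniform(0, 0.3), var_mu_x=master.uniform(0, 0.1),
                      var_mu_y=master.uniform(0, 0.1), var_mc=master.uniform(0, 0.1))
            err = ErrorSpec.realistic(
                var_au_x=kw["var_au_x"], var_au_y=kw["var_au_y"], var_ac=kw["var_ac"],
                var_mu_x=kw["var_mu_x"], var_mu_y=kw["var_mu_y"], var_mc=kw["var_mc"],
                sign=int(pi),
            )
            vec = expected_corr_grid(
                sig.mu_x, sig.mu_y, sig.var_x, sig.var_y, sig.rho0, pi=pi, **kw
            )
            assert float(vec) == pytest.approx(expected_corr(sig, err).rho, abs=1e-12)


class TestReductions:
    def test_generalized_reduces_to_special_models(self):
        master = np.random.default_rng(31)
        for _ in range(100):
            sig = random_signal(master)
            sign = int(master.choice([-1, 1]))
            vau = (master.uniform(0, 0.5), master.uniform(0, 0.5))
            vmu = (master.uniform(0, 0.2), master.uniform(0, 0.2))
            vac, vmc = master.uniform(0, 0.4), master.uniform(0, 0.1)
            special = ErrorSpec.realistic(
                var_au_x=vau[0], var_au_y=vau[1], var_ac=vac,
                var_mu_x=vmu[0], var_mu_y=vmu[1], var_mc=vmc, sign=sign,
            )
            gen = ErrorSpec.generalized(
                var_au_x=vau[0], var_au_y=vau[1],
                var_ac_x=vac, var_ac_y=vac,
                var_mu_x=vmu[0], var_mu_y=vmu[1],
                var_mc_x=vmc, var_mc_y=vmc,
                pi_ac=float(sign), pi_mc=float(sign),
            )
            assert expected_corr(sig, gen).rho == pytest.approx(
                expected_corr(sig, special).rho, abs=1e-14
            )
            assert attenuation_coeff(sig, gen) == pytest.approx(
                attenuation_coeff(sig, special), abs=1e-14
            )

    def test_uncorrelated_additive_reduces_to_spearman(self):
        master = np.random.default_rng(37)
        for _ in range(100):
            sig = random_signal(master)
            vau_x, vau_y = master.uniform(0, 1.0, 2)
            err = ErrorSpec.additive(vau_x, vau_y, var_ac=0.0)
            spearman_a = 1.0 / math.sqrt(
                (1.0 + vau_x / sig.var_x) * (1.0 + vau_y / sig.var_y)
            )
            assert attenuation_coeff(sig, err) == pytest.approx(spearman_a, abs=1e-14)
            assert expected_corr(sig, err).rho == pytest.approx(
                spearman_a * sig.rho0, abs=1e-14
            )


class TestNullCorr:
    def test_additive_value(self):
        sig = symmetric_signal(0.3)
        err = ErrorSpec.additive(0.0, var_ac=0.25)
        # A = 1/1.25, gamma_x*gamma_y = 0.25 -> 0.2
        assert null_corr(sig, err) == pytest.approx(0.2, abs=1e-14)

    def test_zero_without_error(self):
        assert null_corr(symmetric_signal(0.5), ErrorSpec.none()) == 0.0

    def test_negative_sign_negates(self):
        sig = symmetric_signal(0.7, mu=2.0)
        pos = ErrorSpec.realistic(var_au_x=0.1, var_ac=0.2, var_mu_x=0.02, var_mc=0.05, sign=+1)
        neg = ErrorSpec.realistic(var_au_x=0.1, var_ac=0.2, var_mu_x=0.02, var_mc=0.05, sign=-1)
        assert null_corr(sig, neg) == pytest.approx(-null_corr(sig, pos), abs=1e-14)

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_matches_expected_corr_at_zero(self, kind):
        master = np.random.default_rng(43)
        for _ in range(20):
            sig = random_signal(master).with_rho0(0.0)
            err = random_error(master, kind)
            assert null_corr(sig, err) == pytest.approx(
                expected_corr(sig, err).rho, abs=1e-14
            )


class TestRegime:
    def test_uncorrelated_additive_attenuates(self):
        sig = symmetric_signal(0.8)
        report = classify_regime(sig, ErrorSpec.additive(0.75))
        assert report.regime is Regime.ATTENUATED
        assert report.surface_S is None

    def test_no_error_unbiased(self):
        assert classify_regime(symmetric_signal(0.5), ErrorSpec.none()).regime \
            is Regime.UNBIASED

    def test_sign_flip(self):
        # rho0 = -0.2, gamma_x = gamma_y = 0.5 -> rho = A*(-0.2 + 0.25) > 0
        sig = symmetric_signal(-0.2)
        report = classify_regime(sig, ErrorSpec.additive(0.0, var_ac=0.25, sign=+1))
        assert report.regime is Regime.SIGN_FLIPPED
        assert report.rho > 0

    def test_sign_flip_monte_carlo(self):
        sig = symmetric_signal(-0.2)
        err = ErrorSpec.additive(0.0, var_ac=0.25, sign=+1)
        r = sample_corr(simulate_bivariate(sig, err, 200_000, seed=77).data)
        assert r > 0

    def test_sign_flip_condition_for_positive_correlated_error(self):
        """With rho0 < 0 the sign flips exactly when |rho0| < gamma_x*gamma_y."""
        for gamma2 in (0.09, 0.25, 0.49):
            for rho0 in np.linspace(-0.95, -0.01, 25):
                sig = symmetric_signal(float(rho0))
                err = ErrorSpec.additive(0.1, var_ac=gamma2, sign=+1)
                flipped = classify_regime(sig, err).regime is Regime.SIGN_FLIPPED
                assert flipped == (abs(rho0) < gamma2)

    def test_surface_boundary_unbiased(self):
        err = ErrorSpec.additive(0.75, var_ac=0.25, sign=+1)
        sig = symmetric_signal(0.25)  # S = 0.25 for xi^2=0.75, gamma^2=0.25
        report = classify_regime(sig, err)
        assert report.regime is Regime.UNBIASED
        assert report.surface_S == pytest.approx(0.25, abs=1e-12)


class TestLimitingSurface:
    def test_pure_correlated(self):
        assert limiting_surface(0.0, 0.25, "pos") == pytest.approx(1.0)

    def test_mixed(self):
        assert limiting_surface(0.75, 0.25, "pos") == pytest.approx(0.25)

    def test_pure_uncorrelated(self):
        assert limiting_surface(0.5, 0.0, "pos") == 0.0

    def test_negative_sign(self):
        assert limiting_surface(0.75, 0.25, "neg") == pytest.approx(-0.25)

    def test_no_error_rejected(self):
        with pytest.raises(ValueError):
            limiting_surface(0.0, 0.0, "pos")

    @pytest.mark.parametrize("sign", ["pos", "neg"])
    def test_regime_flips_across_surface(self, sign):
        """classify_regime switches attenuated/inflated as rho0 crosses S.

        For positively correlated error rho is inflated below S and
        attenuated above; for negatively correlated error (S < 0) the
        sides swap.
        """
        eps = 1e-6
        pi = +1 if sign == "pos" else -1
        for xi2 in (0.1, 0.5, 1.0):
            for gamma2 in (0.05, 0.2, 0.6):
                s = limiting_surface(xi2, gamma2, sign)
                assert abs(s) < 1.0 - eps
                err = ErrorSpec.additive(xi2, var_ac=gamma2, sign=pi)
                below = classify_regime(symmetric_signal(s - eps), err).regime
                above = classify_regime(symmetric_signal(s + eps), err).regime
                if sign == "pos":
                    assert below is Regime.INFLATED
                    assert above is Regime.ATTENUATED
                else:
                    assert below is Regime.ATTENUATED
                    assert above is Regime.INFLATED
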