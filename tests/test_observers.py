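"""Observer models: worked examples, identities, symmetry, oracle checks."""

import numpy as np
import pytest
from scipy import stats

import headingci.observers as obs
from headingci import ObserverParams, SensoryMeasurement
from headingci.generative import InvalidParameterError

from conftest import random_measurement, random_observer_params, random_sds


class TestCueSummary:
    def test_constant_structure(self, unit_params, unit_meas, unit_sds):
        s = obs.cue_summary(unit_params, unit_meas, unit_sds, structure=1)
        assert (s.mu_K, s.sigma2_K) == (pytest.approx(1.0), pytest.approx(1.5))

    def test_changed_structure(self, unit_params, unit_meas, unit_sds):
        s = obs.cue_summary(unit_params, unit_meas, unit_sds, structure=2)
        assert (s.mu_K, s.sigma2_K) == (pytest.approx(1.0), pytest.approx(2.0))

    def test_covariance_interpolates_structures(self, rng):
        for _ in range(20):
            p = random_observer_params(rng)
            m = random_measurement(rng)
            sds = random_sds(rng, p.sigma_vest)
            p.rho = 1.0
            cov1 = obs.cue_summary(p, m, sds, variant="cov")
            cci1 = obs.cue_summary(p, m, sds, structure=1)
            assert cov1.mu_K == pytest.approx(cci1.mu_K)
            assert cov1.sigma2_K == pytest.approx(cci1.sigma2_K)
            p.rho = 0.0
            cov2 = obs.cue_summary(p, m, sds, variant="cov")
            cci2 = obs.cue_summary(p, m, sds, structure=2)
            assert cov2.mu_K == pytest.approx(cci2.mu_K)
            assert cov2.sigma2_K == pytest.approx(cci2.sigma2_K)

    def test_invalid_sds_rejected(self, unit_params, unit_meas):
        with pytest.raises(InvalidParameterError):
            obs.cue_summary(unit_params, unit_meas, (1.0, 0.0, 1.0), structure=1)


class TestStructureInference:
    def test_likelihood_worked_values(self, unit_params, unit_meas, unit_sds):
        l1 = obs.structure_likelihood(unit_params, unit_meas, unit_sds, 1)
        l2 = obs.structure_likelihood(unit_params, unit_meas, unit_sds, 2)
        assert l1 == pytest.approx(1 / (4 * np.pi) * np.exp(-2.5 / 8), rel=1e-12)
        assert l2 == pytest.approx(1 / (2 * np.pi * np.sqrt(5)) * np.exp(-0.3), rel=1e-12)

    def test_log_and_linear_forms_agree(self, unit_params, unit_meas, unit_sds):
        ll = obs.log_structure_likelihood(unit_params, unit_meas, unit_sds, 1)
        assert np.exp(ll) == pytest.approx(
            obs.structure_likelihood(unit_params, unit_meas, unit_sds, 1)
        )

    def test_posterior_worked_value(self, unit_params, unit_meas, unit_sds):
        post = obs.posterior_constant(unit_params, unit_meas, unit_sds)
        assert post.p_c1 == pytest.approx(0.5247477, rel=1e-5)
        assert post.p_c1 + post.p_c2 == pytest.approx(1.0)

    @pytest.mark.parametrize("p_constant, expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_prior_certainty(self, unit_params, unit_meas, unit_sds, p_constant, expected):
        unit_params.p_constant = p_constant
        post = obs.posterior_constant(unit_params, unit_meas, unit_sds)
        assert float(post.p_c1) == expected

    def test_posterior_unimodal_in_x_vis0(self, unit_params, unit_sds):
        """p(C=1|...) falls off monotonically away from its peak in x_vis0."""
        grid = np.linspace(-20, 20, 401)
        m = SensoryMeasurement(x_vest=1.0, x_vis=1.0, x_vis0=grid)
        p_c1 = np.asarray(obs.posterior_constant(unit_params, m, unit_sds).p_c1)
        k = int(np.argmax(p_c1))
        assert np.all(np.diff(p_c1[: k + 1]) >= -1e-12)
        assert np.all(np.diff(p_c1[k:]) <= 1e-12)

    def test_likelihood_matches_quadrature(self, rng):
        """Analytic marginal (x K0) equals numerical double integration."""
        for _ in range(10):
            p = random_observer_params(rng)
            m = random_measurement(rng, scale=2.0)
            sds = random_sds(rng, p.sigma_vest)
            for structure in (1, 2):
                analytic = float(
                    obs.structure_likelihood(p, m, sds, structure)
                ) * _k0(p, m, sds)
                numeric = _marginal_by_quadrature(p, m, sds, structure)
                assert analytic == pytest.approx(numeric, rel=1e-6)


def _k0(p, m, sds):
    return stats.norm.pdf(m.x_vis0, 0.0, np.hypot(sds[2], p.sigma_env))


def _marginal_by_quadrature(p, m, sds, structure, n=1501, k=9.0):
    """Dense-trapezoid double integration of the cue marginal given C.

    Trapezoid sums on wide Gaussian-support windows are spectrally
    accurate here (cross-checked against scipy adaptive quadrature to
    ~1e-12 relative); the windows cover every factor's mean +/- k SDs.
    """
    sv, svis, svis0 = sds

    def span(*pairs):
        lo = min(mu - k * s for mu, s in pairs)
        hi = max(mu + k * s for mu, s in pairs)
        return np.linspace(lo, hi, n)

    g_self = span((0.0, p.sigma_self), (m.x_vest, sv))
    g_env = span((0.0, p.sigma_env), (-m.x_vis0, svis0))
    S, E = np.meshgrid(g_self, g_env, indexing="ij", sparse=True)
    w = (
        stats.norm.pdf(m.x_vest, S, sv)
        * stats.norm.pdf(m.x_vis, S - E, svis)
        * stats.norm.pdf(S, 0, p.sigma_self)
        * stats.norm.pdf(E, 0, p.sigma_env)
    )
    if structure == 1:
        w = w * stats.norm.pdf(m.x_vis0, -E, svis0)
        return float(np.trapezoid(np.trapezoid(w, g_env, axis=1), g_self))
    base = np.trapezoid(np.trapezoid(w, g_env, axis=1), g_self)
    g0 = span((0.0, p.sigma_env), (-m.x_vis0, svis0))
    env0_factor = np.trapezoid(
        stats.norm.pdf(m.x_vis0, -g0, svis0) * stats.norm.pdf(g0, 0, p.sigma_env), g0
    )
    return float(base * env0_factor)


class TestEstimators:
    def test_worked_examples(self, unit_params, unit_meas, unit_sds):
        assert obs.estimate_integration(unit_params, unit_meas, unit_sds).s_hat == pytest.approx(0.625)
        assert obs.estimate_segregation(unit_params, unit_meas, unit_sds).s_hat == pytest.approx(0.6)
        assert obs.estimate_cci(unit_params, unit_meas, unit_sds).s_hat == pytest.approx(0.6131187, rel=1e-5)
        assert obs.estimate_wta(unit_params, unit_meas, unit_sds).s_hat == pytest.approx(0.625)

    def test_covariance_worked_example(self):
        p = ObserverParams(model_id="covariance", sigma_self=1.0, sigma_env=1.0,
                           sigma_vest=1.0, w_vis=0.2, rho=0.5)
        m = SensoryMeasurement(1.0, 1.0, 2.0)
        assert obs.estimate_covariance(p, m, (1.0, 1.0, 1.0)).s_hat == pytest.approx(0.5)

    def test_mci_worked_examples(self):
        p = ObserverParams(model_id="mci", sigma_self=1.0, sigma_vest=1.0,
                           w_vis=0.2, p_common=0.5)
        m = SensoryMeasurement(1.0, 1.0, 0.0)
        assert obs.estimate_mci(p, m, (1.0, 1.0, 1.0)).s_hat == pytest.approx(0.59617, rel=1e-4)
        p.p_common = 1.0
        assert obs.estimate_mci(p, m, (1.0, 1.0, 1.0)).s_hat == pytest.approx(2.0 / 3.0)

    def test_fixed_weight_arithmetic(self):
        p = ObserverParams(model_id="fixed", alpha_vest=0.5, alpha_mom=0.3, alpha_cont=0.2)
        assert obs.estimate_fixed(p, SensoryMeasurement(1.0, 1.0, 0.0)).s_hat == pytest.approx(1.0)
        p2 = ObserverParams(model_id="fixed", alpha_vest=1.0, alpha_mom=0.0, alpha_cont=0.0)
        assert obs.estimate_fixed(p2, SensoryMeasurement(3.2, -1.0, 5.0)).s_hat == pytest.approx(3.2)

    def test_heuristic_tie_and_branching(self, unit_params, unit_sds):
        # tie: both conflicts equal -> C=1 branch
        m = SensoryMeasurement(1.0, 1.0, 0.0)
        assert obs.estimate_heuristic(unit_params, m, unit_sds).s_hat == pytest.approx(0.625)
        # x_vis0=2: mu_K1 = 0 -> conflict 1 > conflict 0 -> C=1 branch fires
        m2 = SensoryMeasurement(1.0, 1.0, 2.0)
        e = obs.estimate_heuristic(unit_params, m2, unit_sds)
        assert e.s_hat == pytest.approx(float(np.asarray(e.s_hat_c1)))
        inv = obs.estimate_heuristic(unit_params, m2, unit_sds, as_printed=False)
        assert inv.s_hat == pytest.approx(float(np.asarray(inv.s_hat_c2)))

    def test_heuristic_ignores_structure_prior(self, unit_params, unit_sds, rng):
        m = random_measurement(rng)
        unit_params.p_constant = 0.9
        a = obs.estimate_heuristic(unit_params, m, unit_sds).s_hat
        unit_params.p_constant = 0.1
        b = obs.estimate_heuristic(unit_params, m, unit_sds).s_hat
        assert float(np.asarray(a)) == float(np.asarray(b))

    def test_zero_measurements_zero_estimate(self, unit_params, unit_sds):
        m = SensoryMeasurement(0.0, 0.0, 0.0)
        for mid in ("cci", "integration", "segregation", "covariance", "wta", "mci"):
            p = random_observer_params(np.random.default_rng(0))
            e = obs.estimate(mid, p, m, unit_sds)
            assert float(np.asarray(e.s_hat)) == pytest.approx(0.0, abs=1e-12)

    def test_segregation_and_mci_ignore_x_vis0(self, unit_params, rng):
        p = random_observer_params(rng)
        sds = random_sds(rng, p.sigma_vest)
        base = SensoryMeasurement(1.3, -0.7, 0.0)
        ref_seg = float(np.asarray(obs.estimate_segregation(p, base, sds).s_hat))
        ref_mci = float(np.asarray(obs.estimate_mci(p, base, sds).s_hat))
        for x0 in (-100.0, -3.0, 42.0, 100.0):
            m = SensoryMeasurement(1.3, -0.7, x0)
            assert float(np.asarray(obs.estimate_segregation(p, m, sds).s_hat)) == ref_seg
            assert float(np.asarray(obs.estimate_mci(p, m, sds).s_hat)) == ref_mci


class TestModelIdentities:
    """Special cases collapse onto each other exactly."""

    def test_cci_limits_and_covariance_limits(self, rng):
        for _ in range(100):
            p = random_observer_params(rng)
            m = random_measurement(rng)
            sds = random_sds(rng, p.sigma_vest)
            p.p_constant = 1.0
            cci = float(np.asarray(obs.estimate_cci(p, m, sds).s_hat))
            integ = float(np.asarray(obs.estimate_integration(p, m, sds).s_hat))
            assert cci == pytest.approx(integ, rel=1e-12, abs=1e-12)
            p.p_constant = 0.0
            cci0 = float(np.asarray(obs.estimate_cci(p, m, sds).s_hat))
            seg = float(np.asarray(obs.estimate_segregation(p, m, sds).s_hat))
            assert cci0 == pytest.approx(seg, rel=1e-12, abs=1e-12)
            p.rho = 1.0
            assert float(np.asarray(obs.estimate_covariance(p, m, sds).s_hat)) == pytest.approx(integ, rel=1e-12, abs=1e-12)
            p.rho = 0.0
            assert float(np.asarray(obs.estimate_covariance(p, m, sds).s_hat)) == pytest.approx(seg, rel=1e-12, abs=1e-12)


class TestInvariants:
    @pytest.mark.parametrize("mid", ["cci", "integration", "segregation", "covariance", "wta", "mci", "heuristic"])
    def test_odd_symmetry(self, mid, rng):
        """Negating all cues negates the estimate (zero-mean priors)."""
        for _ in range(20):
            p = random_observer_params(rng)
            m = random_measurement(rng)
            sds = random_sds(rng, p.sigma_vest)
            neg = SensoryMeasurement(-m.x_vest, -m.x_vis, -m.x_vis0)
            a = float(np.asarray(obs.estimate(mid, p, m, sds).s_hat))
            b = float(np.asarray(obs.estimate(mid, p, neg, sds).s_hat))
            assert a == pytest.approx(-b, rel=1e-10, abs=1e-12)

    @pytest.mark.parametrize("mid", ["cci", "mci"])
    def test_average_lies_between_structure_estimates(self, mid, rng):
        for _ in range(50):
            p = random_observer_params(rng)
            m = random_measurement(rng)
            sds = random_sds(rng, p.sigma_vest)
            e = obs.estimate(mid, p, m, sds)
            lo = min(float(np.asarray(e.s_hat_c1)), float(np.asarray(e.s_hat_c2)))
            hi = max(float(np.asarray(e.s_hat_c1)), float(np.asarray(e.s_hat_c2)))
            assert lo - 1e-12 <= float(np.asarray(e.s_hat)) <= hi + 1e-12

    def test_wta_selects_one_structure_estimate(self, rng):
        for _ in range(50):
            p = random_observer_params(rng)
            m = random_measurement(rng)
            sds = random_sds(rng, p.sigma_vest)
            e = obs.estimate_wta(p, m, sds)
            s = float(np.asarray(e.s_hat))
            assert s in (float(np.asarray(e.s_hat_c1)), float(np.asarray(e.s_hat_c2)))

    @pytest.mark.parametrize("mid", ["cci", "integration", "segregation", "covariance", "wta"])
    def test_prior_shrinkage(self, mid, rng):
        """Proper priors pull the estimate toward zero."""
        for _ in range(30):
            p = random_observer_params(rng)
            m = random_measurement(rng)
            sds = random_sds(rng, p.sigma_vest)
            mu1 = np.abs(np.asarray(obs.cue_summary(p, m, sds, structure=1).mu_K))
            mu2 = np.abs(np.asarray(obs.cue_summary(p, m, sds, structure=2).mu_K))
            bound = abs(m.x_vest) + max(float(mu1), float(mu2))
            assert abs(float(np.asarray(obs.estimate(mid, p, m, sds).s_hat))) <= bound + 1e-12


class TestQuadratureOracle:
    @pytest.mark.parametrize("mid", ["cci", "integration", "segregation", "covariance", "mci"])
    def test_closed_form_matches_posterior_mean(self, mid, rng):
        """Closed forms equal the brute-force posterior mean of s_self."""
        for _ in range(20):
            p = random_observer_params(rng)
            m = random_measurement(rng)
            sds = random_sds(rng, p.sigma_vest)
            closed = float(np.asarray(obs.estimate(mid, p, m, sds).s_hat))
            n_grid = 181 if mid == "covariance" else 401
            oracle = obs.numeric_posterior_mean(p, m, sds, mid, n_grid=n_grid)
            assert closed == pytest.approx(oracle, abs=1e-3)
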