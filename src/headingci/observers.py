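"""Closed-form heading estimators for the eight observer models.

All models estimate the lateral self-motion component ``s_self`` from the
three noisy cues ``(x_vest, x_vis, x_vis0)``. The contextual models differ
in how visual information enters, summarized by an effective visual cue
with mean ``mu_K`` and variance ``sigma2_K``:

* **C=1** (environmental motion constant): the pre-motion retinal signal
  is used to infer the environmental motion and subtract it out,
  ``mu_K = x_vis - sigma_env^2/(sigma_env^2 + sigma_vis0^2) * x_vis0``.
* **C=2** (environmental motion changed): the pre-motion signal is
  disregarded and the slow-speed prior stands in for the unknown
  environmental motion, ``mu_K = x_vis`` with inflated variance
  ``sigma_vis^2 + sigma_env^2``.

Every per-structure estimate is the same precision-weighted combination of
the vestibular cue, the effective visual cue, and the zero-mean prior::

    s_hat_C = (x_vest/sv^2 + mu_K/sK^2) / (1/sv^2 + 1/sK^2 + 1/ss^2)

The models:

``cci``           model averaging over C with posterior weights
``integration``   always C=1 (p_constant = 1)
``segregation``   always C=2 (p_constant = 0)
``covariance``    bivariate Gaussian prior on (s_env0, s_env) with
                  correlation rho; rho=1 -> integration, rho=0 -> segregation
``fixed``         descriptive fixed-weight sum of the three cues
``heuristic``     non-Bayesian structure choice by cue-conflict comparison
``wta``           model selection: commit to the a-posteriori likelier C
``mci``           conventional momentary causal inference on (x_vest, x_vis)

All functions are vectorized: measurement and SD fields may be arrays and
broadcast together. Likelihood arithmetic is done in log space.

``numeric_posterior_mean`` is a brute-force quadrature oracle over the full
latent space, independent of the closed forms; it exists for testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import math

from .generative import (
    CausalStructure,
    InvalidParameterError,
    ObserverParams,
    SensoryMeasurement,
)

__all__ = [
    "CueSummary",
    "StructurePosterior",
    "HeadingEstimate",
    "cue_summary",
    "estimate_given_structure",
    "log_structure_likelihood",
    "structure_likelihood",
    "posterior_constant",
    "estimate_cci",
    "estimate_integration",
    "estimate_segregation",
    "estimate_covariance",
    "estimate_fixed",
    "estimate_heuristic",
    "estimate_wta",
    "estimate_mci",
    "estimate_varweight",
    "estimate",
    "numeric_posterior_mean",
]


@dataclass
class CueSummary:
    """Effective visual cue: mean and variance of the visual contribution."""

    mu_K: np.ndarray | float
    sigma2_K: np.ndarray | float


@dataclass
class StructurePosterior:
    """Posterior over the causal structure of environmental motion."""

    p_c1: np.ndarray | float

    @property
    def p_c2(self) -> np.ndarray | float:
        return 1.0 - self.p_c1


@dataclass
class HeadingEstimate:
    """Self-motion estimate with per-structure diagnostics (deg/s)."""

    s_hat: np.ndarray | float
    s_hat_c1: Optional[np.ndarray | float] = None
    s_hat_c2: Optional[np.ndarray | float] = None
    structure_posterior: Optional[StructurePosterior] = None


def _as_sds(sds) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sigma_vest, sigma_vis, sigma_vis0 = (
        np.asarray(s) if np.issubdtype(np.asarray(s).dtype, np.floating)
        else np.asarray(s, dtype=float)
        for s in sds
    )
    if np.any(sigma_vest <= 0) or np.any(sigma_vis <= 0) or np.any(sigma_vis0 <= 0):
        raise InvalidParameterError("measurement SDs must be strictly positive")
    return sigma_vest, sigma_vis, sigma_vis0


# ---------------------------------------------------------------------------
# Effective visual cue and per-structure estimate


def cue_summary(
    params: ObserverParams,
    meas: SensoryMeasurement,
    sds,
    structure: CausalStructure | int | None = None,
    variant: str = "cci",
) -> CueSummary:
    """Effective visual mean/variance ``(mu_K, sigma2_K)``.

    ``variant="cci"`` uses the causal ``structure``; ``variant="cov"`` uses
    the correlation ``params.rho`` (rho=1 reproduces C=1, rho=0 C=2).
    """
    _, sigma_vis, sigma_vis0 = _as_sds(sds)
    if params.sigma_env is None or not params.sigma_env > 0:
        raise InvalidParameterError("sigma_env must be > 0")
    v_env = params.sigma_env**2
    v_vis = sigma_vis**2
    v_vis0 = sigma_vis0**2
    x_vis = np.asarray(meas.x_vis)
    x_vis0 = np.asarray(meas.x_vis0)
    if variant == "cov":
        if params.rho is None:
            raise InvalidParameterError("variant='cov' requires rho")
        rho = params.rho
        gain = rho * v_env / (v_env + v_vis0)
        mu = x_vis - gain * x_vis0
        s2 = v_vis + v_env * (1.0 - rho**2 * v_env / (v_env + v_vis0))
        return CueSummary(mu, s2)
    if variant != "cci":
        raise ValueError(f"unknown variant {variant!r}")
    if int(structure) == int(CausalStructure.CONSTANT):
        gain = v_env / (v_env + v_vis0)
        mu = x_vis - gain * x_vis0
        s2 = v_vis + v_env * v_vis0 / (v_env + v_vis0)
    elif int(structure) == int(CausalStructure.CHANGED):
        mu = x_vis + np.zeros_like(v_vis0)
        s2 = v_vis + v_env + np.zeros_like(v_vis0)
    else:
        raise ValueError(f"causal structure must be 1 or 2, got {structure}")
    return CueSummary(mu, s2)


def estimate_given_structure(
    params: ObserverParams, meas: SensoryMeasurement, summary: CueSummary
) -> np.ndarray | float:
    """Precision-weighted estimate of ``s_self`` given an effective cue."""
    if params.sigma_self is None or params.sigma_vest is None:
        raise InvalidParameterError("sigma_self and sigma_vest are required")
    v_vest = params.sigma_vest**2
    v_self = params.sigma_self**2
    s2 = np.asarray(summary.sigma2_K)
    if np.any(s2 <= 0):
        raise InvalidParameterError("sigma2_K must be > 0")
    num = np.asarray(meas.x_vest) / v_vest + summary.mu_K / s2
    den = 1.0 / v_vest + 1.0 / s2 + 1.0 / v_self
    return num / den


# ---------------------------------------------------------------------------
# Structure likelihood and posterior


def log_structure_likelihood(
    params: ObserverParams,
    meas: SensoryMeasurement,
    sds,
    structure: CausalStructure | int,
) -> np.ndarray:
    """Log marginal likelihood of the cues given C (common K0 factor omitted).

    The analytic marginal over the latent velocities is, up to a factor K0
    independent of C::

        (2 pi sqrt(D))^-1 exp(-[(x_vest-mu_K)^2 ss^2 + x_vest^2 sK^2
                                 + mu_K^2 sv^2] / (2 D))

    with D = sv^2 sK^2 + sv^2 ss^2 + sK^2 ss^2 and (mu_K, sK^2) the
    structure's effective visual cue.
    """
    summ = cue_summary(params, meas, sds, structure=structure, variant="cci")
    sigma_vest, _, _ = _as_sds(sds)
    return _log_lik_from_summary(params, meas, sigma_vest, summ)


def _log_lik_from_summary(
    params: ObserverParams,
    meas: SensoryMeasurement,
    sigma_vest: np.ndarray,
    summ: CueSummary,
) -> np.ndarray:
    v_vest = sigma_vest**2
    v_self = params.sigma_self**2
    s2 = np.asarray(summ.sigma2_K)
    x_vest = np.asarray(meas.x_vest)
    mu = np.asarray(summ.mu_K)
    det = v_vest * s2 + v_vest * v_self + s2 * v_self
    quad = ((x_vest - mu) ** 2 * v_self + x_vest**2 * s2 + mu**2 * v_vest) / det
    return -math.log(2.0 * math.pi) - 0.5 * np.log(det) - 0.5 * quad


def structure_likelihood(
    params: ObserverParams,
    meas: SensoryMeasurement,
    sds,
    structure: CausalStructure | int,
) -> np.ndarray:
    """Unnormalized marginal likelihood of the cues given C (K0 omitted)."""
    return np.exp(log_structure_likelihood(params, meas, sds, structure))


def posterior_constant(
    params: ObserverParams, meas: SensoryMeasurement, sds
) -> StructurePosterior:
    """Posterior probability that environmental motion remained constant.

    Computed in log space; the prior is ``params.p_constant``.
    """
    p = params.p_constant
    if p is None or not 0.0 <= p <= 1.0:
        raise InvalidParameterError("p_constant must be in [0, 1]")
    if p == 1.0:
        ll1 = log_structure_likelihood(params, meas, sds, 1)
        return StructurePosterior(np.ones_like(np.asarray(ll1, dtype=float)))
    if p == 0.0:
        ll2 = log_structure_likelihood(params, meas, sds, 2)
        return StructurePosterior(np.zeros_like(np.asarray(ll2, dtype=float)))
    ll1 = log_structure_likelihood(params, meas, sds, 1) + np.log(p)
    ll2 = log_structure_likelihood(params, meas, sds, 2) + np.log1p(-p)
    if not (np.all(np.isfinite(ll1)) or np.all(np.isfinite(ll2))):
        raise FloatingPointError("degenerate input: both structure likelihoods zero")
    # stable softmax over the two structures
    p_c1 = np.exp(ll1 - np.logaddexp(ll1, ll2))
    return StructurePosterior(p_c1)


# ---------------------------------------------------------------------------
# Observer models


def _both_structure_estimates(params, meas, sds):
    s1 = estimate_given_structure(
        params, meas, cue_summary(params, meas, sds, structure=1)
    )
    s2 = estimate_given_structure(
        params, meas, cue_summary(params, meas, sds, structure=2)
    )
    return s1, s2


def _cci_parts(params, meas, sds):
    """Shared internals of the averaging/selection models (computed once)."""
    summ1 = cue_summary(params, meas, sds, structure=1)
    summ2 = cue_summary(params, meas, sds, structure=2)
    s1 = estimate_given_structure(params, meas, summ1)
    s2 = estimate_given_structure(params, meas, summ2)
    p = params.p_constant
    if p is None or not 0.0 <= p <= 1.0:
        raise InvalidParameterError("p_constant must be in [0, 1]")
    if p == 1.0:
        p_c1 = np.ones_like(np.asarray(s1, dtype=float))
    elif p == 0.0:
        p_c1 = np.zeros_like(np.asarray(s1, dtype=float))
    else:
        sigma_vest, _, _ = _as_sds(sds)
        ll1 = _log_lik_from_summary(params, meas, sigma_vest, summ1) + math.log(p)
        ll2 = _log_lik_from_summary(params, meas, sigma_vest, summ2) + math.log1p(-p)
        p_c1 = np.exp(ll1 - np.logaddexp(ll1, ll2))
    return s1, s2, StructurePosterior(p_c1)


def estimate_cci(
    params: ObserverParams, meas: SensoryMeasurement, sds
) -> HeadingEstimate:
    """Contextual causal inference: posterior-weighted model averaging."""
    s1, s2, post = _cci_parts(params, meas, sds)
    return HeadingEstimate(post.p_c1 * s1 + post.p_c2 * s2, s1, s2, post)


def estimate_integration(
    params: ObserverParams, meas: SensoryMeasurement, sds
) -> HeadingEstimate:
    """Mandatory integration: always assume constant environmental motion."""
    s1 = estimate_given_structure(
        params, meas, cue_summary(params, meas, sds, structure=1)
    )
    ones = np.ones_like(np.asarray(s1, dtype=float))
    return HeadingEstimate(s1, s1, None, StructurePosterior(ones))


def estimate_segregation(
    params: ObserverParams, meas: SensoryMeasurement, sds
) -> HeadingEstimate:
    """Full segregation: disregard the pre-motion visual signal."""
    s2 = estimate_given_structure(
        params, meas, cue_summary(params, meas, sds, structure=2)
    )
    zeros = np.zeros_like(np.asarray(s2, dtype=float))
    return HeadingEstimate(s2, None, s2, StructurePosterior(zeros))


def estimate_covariance(
    params: ObserverParams, meas: SensoryMeasurement, sds
) -> HeadingEstimate:
    """Correlated-environment prior: linear integration of all three cues."""
    summ = cue_summary(params, meas, sds, variant="cov")
    return HeadingEstimate(estimate_given_structure(params, meas, summ))


def estimate_fixed(params: ObserverParams, meas: SensoryMeasurement) -> HeadingEstimate:
    """Descriptive fixed-weight sum of vestibular, momentary and contextual cues."""
    for name in ("alpha_vest", "alpha_mom", "alpha_cont"):
        if getattr(params, name) is None:
            raise InvalidParameterError(f"fixed-weight model requires {name}")
    x_vest = np.asarray(meas.x_vest)
    x_vis = np.asarray(meas.x_vis)
    x_vis0 = np.asarray(meas.x_vis0)
    s = (
        params.alpha_vest * x_vest
        + params.alpha_mom * x_vis
        + params.alpha_cont * (x_vis - x_vis0)
    )
    return HeadingEstimate(s)


def estimate_heuristic(
    params: ObserverParams,
    meas: SensoryMeasurement,
    sds,
    as_printed: bool = True,
) -> HeadingEstimate:
    """Non-Bayesian structure choice by comparing cue conflicts.

    Picks the C=1 estimate when ``|x_vest - mu_K,C=1| >= |x_vest -
    mu_K,C=2|`` (ties to C=1). That inequality direction is the model's
    defining rule; ``as_printed=False`` inverts it (pick the structure with
    the *smaller* conflict), for sensitivity analysis.
    """
    mu1 = np.asarray(cue_summary(params, meas, sds, structure=1).mu_K)
    mu2 = np.asarray(cue_summary(params, meas, sds, structure=2).mu_K)
    x_vest = np.asarray(meas.x_vest)
    take_c1 = np.abs(x_vest - mu1) >= np.abs(x_vest - mu2)
    if not as_printed:
        take_c1 = ~take_c1 | (np.abs(x_vest - mu1) == np.abs(x_vest - mu2))
    s1, s2 = _both_structure_estimates(params, meas, sds)
    return HeadingEstimate(np.where(take_c1, s1, s2), s1, s2, None)


def estimate_wta(
    params: ObserverParams, meas: SensoryMeasurement, sds
) -> HeadingEstimate:
    """Winner-take-all: commit to the a-posteriori likelier structure."""
    s1, s2, post = _cci_parts(params, meas, sds)
    s = np.where(np.asarray(post.p_c1) >= 0.5, s1, s2)
    return HeadingEstimate(s, s1, s2, post)


def estimate_mci(
    params: ObserverParams, meas: SensoryMeasurement, sds
) -> HeadingEstimate:
    """Momentary causal inference on (x_vest, x_vis); ignores x_vis0.

    Both latent sources share the prior N(0, sigma_self^2). Under a common
    cause the cues are fused with the prior; otherwise only the vestibular
    cue informs self-motion. The posterior over the structure uses the
    analytic Gaussian marginals of the two hypotheses.
    """
    p = params.p_common
    if p is None or not 0.0 <= p <= 1.0:
        raise InvalidParameterError("mci requires p_common in [0, 1]")
    if params.sigma_self is None or params.sigma_vest is None:
        raise InvalidParameterError("mci requires sigma_self and sigma_vest")
    sigma_vest, sigma_vis, _ = _as_sds(sds)
    v_vest = sigma_vest**2
    v_vis = sigma_vis**2
    v_self = params.sigma_self**2
    x_vest = np.asarray(meas.x_vest)
    x_vis = np.asarray(meas.x_vis)

    det1 = v_vest * v_vis + v_vest * v_self + v_vis * v_self
    ll1 = (
        -math.log(2 * math.pi)
        - 0.5 * np.log(det1)
        - 0.5
        * ((x_vest - x_vis) ** 2 * v_self + x_vest**2 * v_vis + x_vis**2 * v_vest)
        / det1
    )
    ll2 = (
        -math.log(2 * math.pi)
        - 0.5 * np.log((v_vest + v_self) * (v_vis + v_self))
        - 0.5 * (x_vest**2 / (v_vest + v_self) + x_vis**2 / (v_vis + v_self))
    )
    if p == 1.0:
        p_c1 = np.ones_like(ll1)
    elif p == 0.0:
        p_c1 = np.zeros_like(ll1)
    else:
        a = ll1 + math.log(p)
        b = ll2 + math.log1p(-p)
        p_c1 = np.exp(a - np.logaddexp(a, b))

    s1 = (x_vest / v_vest + x_vis / v_vis) / (1 / v_vest + 1 / v_vis + 1 / v_self)
    s2 = (x_vest / v_vest) / (1 / v_vest + 1 / v_self)
    s = p_c1 * s1 + (1.0 - p_c1) * s2
    return HeadingEstimate(s, s1, s2, StructurePosterior(p_c1))


def estimate_varweight(
    params: ObserverParams,
    meas: SensoryMeasurement,
    sds,
    env_constant: np.ndarray | bool,
) -> HeadingEstimate:
    """Diagnostic variable-weight rule (not an observer model).

    The structure posterior is replaced by a fixed weight that depends on
    the *true* causal state: weight ``alpha_1`` on the C=1 estimate when
    ``s_env0 == s_env`` actually held, ``alpha_2`` otherwise.
    """
    if params.alpha_1 is None or params.alpha_2 is None:
        raise InvalidParameterError("variable-weight rule requires alpha_1, alpha_2")
    s1, s2 = _both_structure_estimates(params, meas, sds)
    alpha = np.where(np.asarray(env_constant, dtype=bool), params.alpha_1, params.alpha_2)
    return HeadingEstimate(alpha * s1 + (1.0 - alpha) * s2, s1, s2, None)


_ESTIMATORS = {
    "cci": estimate_cci,
    "integration": estimate_integration,
    "segregation": estimate_segregation,
    "covariance": estimate_covariance,
    "heuristic": estimate_heuristic,
    "wta": estimate_wta,
    "mci": estimate_mci,
}


def estimate(
    model_id: str, params: ObserverParams, meas: SensoryMeasurement, sds=None, **kw
) -> HeadingEstimate:
    """Dispatch to a model's estimator (shared vectorized signature)."""
    if model_id == "fixed":
        return estimate_fixed(params, meas)
    if model_id == "varweight":
        return estimate_varweight(params, meas, sds, **kw)
    try:
        fn = _ESTIMATORS[model_id]
    except KeyError:
        raise ValueError(f"unknown model_id {model_id!r}") from None
    return fn(params, meas, sds, **kw)


# ---------------------------------------------------------------------------
# Brute-force quadrature oracle


def _norm_logpdf(x, mu, sigma):
    return -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def _grid(center: float, half_width: float, n: int) -> np.ndarray:
    return np.linspace(center - half_width, center + half_width, n)


def numeric_posterior_mean(
    params: ObserverParams,
    meas: SensoryMeasurement,
    sds,
    model_id: str,
    n_grid: int = 401,
    n_sigmas: float = 9.0,
) -> float:
    """Posterior mean of ``s_self`` by dense grid quadrature (test oracle).

    Integrates the full generative joint over the latent velocities and the
    causal structure on a trapezoid grid, entirely independent of the
    closed-form estimators. Scalar measurements only.
    """
    sigma_vest, sigma_vis, sigma_vis0 = (float(np.asarray(s)) for s in sds)
    x_vest = float(np.asarray(meas.x_vest))
    x_vis = float(np.asarray(meas.x_vis))
    x_vis0 = float(np.asarray(meas.x_vis0))
    ss = params.sigma_self

    def span(*pairs):
        lo = min(m - n_sigmas * s for m, s in pairs)
        hi = max(m + n_sigmas * s for m, s in pairs)
        return np.linspace(lo, hi, n_grid)

    if model_id == "mci":
        v = params.sigma_self
        g_self = span((0.0, v), (x_vest, sigma_vest), (x_vis, sigma_vis))
        # C=1: x_vis measures s_self directly
        lw1 = (
            _norm_logpdf(g_self, 0.0, v)
            + _norm_logpdf(x_vest, g_self, sigma_vest)
            + _norm_logpdf(x_vis, g_self, sigma_vis)
        )
        w1 = np.exp(lw1 - lw1.max())
        mass1 = np.trapezoid(w1, g_self)
        mean1 = np.trapezoid(g_self * w1, g_self) / mass1
        log_mass1 = np.log(mass1) + lw1.max()
        # C=2: separable; the x_vis factor integrates over its own source
        lwa = _norm_logpdf(g_self, 0.0, v) + _norm_logpdf(x_vest, g_self, sigma_vest)
        wa = np.exp(lwa - lwa.max())
        mass_a = np.trapezoid(wa, g_self)
        mean2 = np.trapezoid(g_self * wa, g_self) / mass_a
        g_env = span((0.0, v), (x_vis, sigma_vis))
        lwb = _norm_logpdf(g_env, 0.0, v) + _norm_logpdf(x_vis, g_env, sigma_vis)
        wb = np.exp(lwb - lwb.max())
        log_mass2 = (
            np.log(mass_a) + lwa.max() + np.log(np.trapezoid(wb, g_env)) + lwb.max()
        )
        p = params.p_common
        if p is None:
            raise InvalidParameterError("mci oracle requires p_common")
        la = np.log(p) + log_mass1 if p > 0 else -np.inf
        lb = np.log1p(-p) + log_mass2 if p < 1 else -np.inf
        w_c1 = np.exp(la - np.logaddexp(la, lb))
        return float(w_c1 * mean1 + (1 - w_c1) * mean2)

    se = params.sigma_env
    g_self = span((0.0, ss), (x_vest, sigma_vest))
    g_env = span((0.0, se), (-x_vis0, sigma_vis0))

    if model_id == "covariance":
        rho = params.rho
        if rho is None:
            raise InvalidParameterError("covariance oracle requires rho")
        # 3-D grid: cap the per-axis resolution to bound memory
        n_grid = min(n_grid, 201)
        g_self = span((0.0, ss), (x_vest, sigma_vest))
        g_env = span((0.0, se), (-x_vis0, sigma_vis0))
        g_env0 = span((0.0, se), (-x_vis0, sigma_vis0))
        S, E, E0 = np.meshgrid(g_self, g_env, g_env0, indexing="ij", sparse=True)
        if rho >= 1.0:
            # degenerate bivariate prior: s_env0 == s_env exactly
            S2, E2 = np.meshgrid(g_self, g_env, indexing="ij", sparse=True)
            lw = (
                _norm_logpdf(S2, 0.0, ss)
                + _norm_logpdf(E2, 0.0, se)
                + _norm_logpdf(x_vest, S2, sigma_vest)
                + _norm_logpdf(x_vis, S2 - E2, sigma_vis)
                + _norm_logpdf(x_vis0, -E2, sigma_vis0)
            )
            w = np.exp(lw - lw.max())
            mass = np.trapezoid(np.trapezoid(w, g_env, axis=1), g_self)
            num = np.trapezoid(
                g_self * np.trapezoid(w, g_env, axis=1), g_self
            )
            return float(num / mass)
        cond_sd = se * np.sqrt(1.0 - rho**2)
        lw = (
            _norm_logpdf(S, 0.0, ss)
            + _norm_logpdf(E, 0.0, se)
            + _norm_logpdf(E0, rho * E, cond_sd)
            + _norm_logpdf(x_vest, S, sigma_vest)
            + _norm_logpdf(x_vis, S - E, sigma_vis)
            + _norm_logpdf(x_vis0, -E0, sigma_vis0)
        )
        w = np.exp(lw - lw.max())
        w2 = np.trapezoid(w, g_env0, axis=2)
        w1 = np.trapezoid(w2, g_env, axis=1)
        mass = np.trapezoid(w1, g_self)
        num = np.trapezoid(g_self * w1, g_self)
        return float(num / mass)

    # cci family: integration (p=1), segregation (p=0), cci (0<p<1)
    if model_id == "cci":
        p = params.p_constant
    elif model_id == "integration":
        p = 1.0
    elif model_id == "segregation":
        p = 0.0
    else:
        raise ValueError(f"no oracle for model_id {model_id!r}")
    if p is None:
        raise InvalidParameterError("cci oracle requires p_constant")

    S, E = np.meshgrid(g_self, g_env, indexing="ij", sparse=True)
    # C=1: s_env0 == s_env
    lw1 = (
        _norm_logpdf(S, 0.0, ss)
        + _norm_logpdf(E, 0.0, se)
        + _norm_logpdf(x_vest, S, sigma_vest)
        + _norm_logpdf(x_vis, S - E, sigma_vis)
        + _norm_logpdf(x_vis0, -E, sigma_vis0)
    )
    m1 = lw1.max()
    w1 = np.exp(lw1 - m1)
    w1s = np.trapezoid(w1, g_env, axis=1)
    mass1 = np.trapezoid(w1s, g_self)
    mean1 = np.trapezoid(g_self * w1s, g_self) / mass1
    log_mass1 = np.log(mass1) + m1
    # C=2: independent s_env0; its factor affects the mass, not the mean
    lw2 = (
        _norm_logpdf(S, 0.0, ss)
        + _norm_logpdf(E, 0.0, se)
        + _norm_logpdf(x_vest, S, sigma_vest)
        + _norm_logpdf(x_vis, S - E, sigma_vis)
    )
    m2 = lw2.max()
    w2 = np.exp(lw2 - m2)
    w2s = np.trapezoid(w2, g_env, axis=1)
    mass2 = np.trapezoid(w2s, g_self)
    mean2 = np.trapezoid(g_self * w2s, g_self) / mass2
    g_env0 = span((0.0, se), (-x_vis0, sigma_vis0))
    lwk = _norm_logpdf(g_env0, 0.0, se) + _norm_logpdf(x_vis0, -g_env0, sigma_vis0)
    mk = lwk.max()
    log_k0 = np.log(np.trapezoid(np.exp(lwk - mk), g_env0)) + mk
    log_mass2 = np.log(mass2) + m2 + log_k0

    if p >= 1.0:
        return float(mean1)
    if p <= 0.0:
        return float(mean2)
    la = np.log(p) + log_mass1
    lb = np.log1p(-p) + log_mass2
    w_c1 = np.exp(la - np.logaddexp(la, lb))
    return float(w_c1 * mean1 + (1 - w_c1) * mean2)
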