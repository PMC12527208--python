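"""Model fitting: Monte-Carlo/KDE likelihood, MAP search, AIC comparison.

Each observer model maps sensory measurements deterministically to a
heading estimate, but the measurements themselves are unobservable. The
response likelihood therefore marginalizes over them: for every stimulus
condition we draw ``n_mc`` measurement triples from the generative
measurement distributions, push them through the model estimator, and
evaluate the observed responses under a Gaussian kernel density estimate
of the simulated estimates (Silverman bandwidth, density floored to keep
the objective finite).

The MAP objective adds independent log-normal priors on the noise
parameters (log-means 1 for sigma_self, sigma_env, sigma_vest and -2 for
w_vis, log-SDs 1) and flat priors on the naturally bounded parameters.
Because the Monte-Carlo objective is stochastic, the search uses common
random numbers (one frozen set of standard-normal draws per fit) so that
an off-the-shelf direct-search optimizer (bounded Powell) sees a smooth
deterministic surface; multiple Latin-hypercube restarts guard against
local optima. The reported log likelihood is the average of ``n_final_evals``
fresh evaluations at the optimum, with the log prior subtracted, and
``AIC = 2k - 2 logL`` with k the model's free-parameter count.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from . import observers
from .generative import (
    DEFAULT_NOISE_FLOOR,
    DEFAULT_REFERENCE_SPEED,
    ObserverParams,
    SensoryMeasurement,
    TrialStimulus,
    heading_to_lateral,
    lateral_to_heading,
    measurement_sds,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "FREE_PARAMS",
    "free_param_names",
    "log_prior",
    "response_loglik",
    "total_log_posterior",
    "fit_model",
    "compare_models",
    "model_r2",
    "r_squared",
]


# ---------------------------------------------------------------------------
# Free-parameter registry


@dataclass(frozen=True)
class _FreeParam:
    name: str
    low: float
    high: float
    log_scale: bool = False
    prior_log_mean: Optional[float] = None  # log-normal prior (log-SD 1); None = flat
    init_low: float = 0.0  # initialization window (natural scale)
    init_high: float = 1.0


def _sigma(name: str) -> _FreeParam:
    return _FreeParam(name, 1e-3, 50.0, True, 1.0, float(np.exp(-0.5)), float(np.exp(2.5)))


_W_VIS = _FreeParam("w_vis", 1e-3, 2.0, True, -2.0, float(np.exp(-3.5)), float(np.exp(-0.5)))
_PROB = lambda name: _FreeParam(name, 0.0, 1.0, False, None, 0.05, 0.95)
_ALPHA_FIX = lambda name: _FreeParam(name, -2.0, 2.0, False, None, -0.5, 1.2)

FREE_PARAMS: dict[str, tuple[_FreeParam, ...]] = {
    "cci": (_sigma("sigma_self"), _sigma("sigma_env"), _sigma("sigma_vest"), _W_VIS, _PROB("p_constant")),
    "wta": (_sigma("sigma_self"), _sigma("sigma_env"), _sigma("sigma_vest"), _W_VIS, _PROB("p_constant")),
    "integration": (_sigma("sigma_self"), _sigma("sigma_env"), _sigma("sigma_vest"), _W_VIS),
    "segregation": (_sigma("sigma_self"), _sigma("sigma_env"), _sigma("sigma_vest"), _W_VIS),
    "heuristic": (_sigma("sigma_self"), _sigma("sigma_env"), _sigma("sigma_vest"), _W_VIS),
    "covariance": (_sigma("sigma_self"), _sigma("sigma_env"), _sigma("sigma_vest"), _W_VIS, _PROB("rho")),
    "fixed": (_sigma("sigma_vest"), _W_VIS, _ALPHA_FIX("alpha_vest"), _ALPHA_FIX("alpha_mom"), _ALPHA_FIX("alpha_cont")),
    "mci": (_sigma("sigma_self"), _sigma("sigma_vest"), _W_VIS, _PROB("p_common")),
    "varweight": (_sigma("sigma_self"), _sigma("sigma_env"), _sigma("sigma_vest"), _W_VIS, _PROB("alpha_1"), _PROB("alpha_2")),
}


def free_param_names(model_id: str) -> tuple[str, ...]:
    return tuple(fp.name for fp in FREE_PARAMS[model_id])


@dataclass
class FitConfig:
    """Configuration of one fitting run."""

    n_mc: int = 1000  # Monte-Carlo samples per condition
    n_final_evals: int = 100  # objective evaluations averaged at the MAP
    n_restarts: int = 5
    seed: int = 0
    kde_bandwidth_rule: str = "silverman"
    density_floor: float = 1e-9
    kde_min_bandwidth: float = 1e-3  # fallback kernel width (deg/s)
    noise_floor: float = DEFAULT_NOISE_FLOOR
    reference_speed: float = DEFAULT_REFERENCE_SPEED
    optimizer: str = "powell"
    max_evals: int = 1000  # per restart
    xtol: float = 1e-3
    ftol: float = 1e-4
    bounds: dict = field(default_factory=dict)  # per-parameter overrides

    def __post_init__(self) -> None:
        if self.n_mc < 10:
            raise ValueError("n_mc must be >= 10")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class FitResult:
    """Outcome of a MAP fit."""

    model_id: str
    map_params: ObserverParams
    log_posterior: float
    log_likelihood: float  # averaged over n_final_evals, prior subtracted
    aic: float
    n_free: int
    seed: int
    converged: bool
    restarts: list = field(default_factory=list)  # per-restart (x, fun, nfev)
    r_squared: Optional[float] = None
    config_hash: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["map_params"] = asdict(self.map_params)
        return d


# ---------------------------------------------------------------------------
# Parameter vector <-> ObserverParams


def _theta_to_params(model_id: str, theta: np.ndarray) -> ObserverParams:
    kw: dict = {"model_id": model_id if model_id != "varweight" else "cci"}
    for fp, t in zip(FREE_PARAMS[model_id], theta):
        kw[fp.name] = float(np.exp(t)) if fp.log_scale else float(t)
    p = ObserverParams(**kw)
    p.model_id = model_id
    return p


def _params_to_theta(model_id: str, params: ObserverParams) -> np.ndarray:
    out = []
    for fp in FREE_PARAMS[model_id]:
        v = getattr(params, fp.name)
        if v is None:
            raise ValueError(f"params missing {fp.name}")
        out.append(np.log(v) if fp.log_scale else v)
    return np.asarray(out, dtype=float)


def _theta_bounds(model_id: str, config: FitConfig) -> list[tuple[float, float]]:
    bounds = []
    for fp in FREE_PARAMS[model_id]:
        lo, hi = config.bounds.get(fp.name, (fp.low, fp.high))
        if fp.log_scale:
            bounds.append((np.log(lo), np.log(hi)))
        else:
            bounds.append((lo, hi))
    return bounds


def log_prior(model_id: str, params: ObserverParams) -> float:
    """Log prior density of a model's free parameters.

    Log-normal on the noise SDs and the Weber fraction (log-SD 1, putting
    ~95% of mass between 1/7 and 7 times the median); flat (0) on the
    naturally bounded parameters.
    """
    total = 0.0
    for fp in FREE_PARAMS[model_id]:
        v = getattr(params, fp.name)
        if v is None:
            raise ValueError(f"params missing {fp.name}")
        if fp.prior_log_mean is not None:
            if v <= 0:
                return -np.inf
            z = np.log(v) - fp.prior_log_mean
            total += -np.log(v) - 0.5 * np.log(2 * np.pi) - 0.5 * z**2
    return float(total)


# ---------------------------------------------------------------------------
# Condition table and vectorized KDE likelihood


@dataclass
class _ConditionData:
    s_self: np.ndarray  # (C,)
    s_env: np.ndarray
    s_env0: np.ndarray
    env_constant: np.ndarray  # (C,) bool
    responses: np.ndarray  # (C, R) lateral units, NaN-padded
    keys: pd.DataFrame  # condition labels, aligned with rows


_COND_KEYS = ["condition", "visual_velocity", "heading_angle"]


def _condition_data(dataset: pd.DataFrame, config: FitConfig) -> _ConditionData:
    required = set(_COND_KEYS + ["s_self", "s_env", "s_env0", "reported_heading"])
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    grouped = dataset.groupby(_COND_KEYS, sort=True)
    keys, rows, latents = [], [], []
    max_r = 0
    for key, g in grouped:
        keys.append(key)
        lat = heading_to_lateral(g["reported_heading"].to_numpy(), config.reference_speed)
        rows.append(np.asarray(lat, dtype=float))
        latents.append(
            (g["s_self"].iloc[0], g["s_env"].iloc[0], g["s_env0"].iloc[0])
        )
        max_r = max(max_r, len(g))
    resp = np.full((len(rows), max_r), np.nan)
    for i, r in enumerate(rows):
        resp[i, : len(r)] = r
    lat_arr = np.asarray(latents, dtype=float)
    return _ConditionData(
        s_self=lat_arr[:, 0],
        s_env=lat_arr[:, 1],
        s_env0=lat_arr[:, 2],
        env_constant=lat_arr[:, 2] == lat_arr[:, 1],
        responses=resp,
        keys=pd.DataFrame(keys, columns=_COND_KEYS),
    )


def _kde_loglik(sim: np.ndarray, resp: np.ndarray, config: FitConfig) -> float:
    """Summed log KDE density of responses under simulated estimates.

    ``sim`` is (C, M) simulated estimates, ``resp`` (C, R) observed
    responses (NaN = missing). Gaussian kernel, Silverman's rule per
    condition with a floor acting as the narrow-kernel fallback when the
    simulated estimates are (nearly) identical.
    """
    m = sim.shape[1]
    sim32 = sim.astype(np.float32, copy=False)
    sd = sim32.std(axis=1, ddof=1, dtype=np.float64)
    q75, q25 = np.percentile(sim32, [75.0, 25.0], axis=1)
    spread = np.minimum(sd, (q75 - q25) / 1.349)
    spread = np.where(spread > 0, spread, sd)
    bw = 0.9 * spread * m ** (-0.2)
    bw = np.maximum(bw, config.kde_min_bandwidth)
    # (C, R, M) kernel matrix in float32; exponents are <= 0, so plain
    # exp-sum-log is overflow-safe, and underflow is caught by the floor
    resp32 = resp.astype(np.float32, copy=False)
    bw32 = bw.astype(np.float32)
    z = (resp32[:, :, None] - sim32[:, None, :]) / bw32[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        kernel_sum = np.exp(-0.5 * z * z).sum(axis=2, dtype=np.float64)
        log_f = np.log(kernel_sum) - np.log(m * bw[:, None]) - 0.5 * np.log(2 * np.pi)
    log_f = np.maximum(log_f, np.log(config.density_floor))
    return float(np.nansum(np.where(np.isnan(resp), 0.0, log_f)))


def _simulate_estimates(
    model_id: str,
    params: ObserverParams,
    cond: _ConditionData,
    z: np.ndarray,
    config: FitConfig,
) -> np.ndarray:
    """Map frozen standard-normal draws ``z`` (3, C, M) to model estimates."""
    stim = TrialStimulus(
        s_self=cond.s_self[:, None],
        s_env=cond.s_env[:, None],
        s_env0=cond.s_env0[:, None],
    )
    sds64 = measurement_sds(params, stim, config.noise_floor)
    # single precision in the Monte-Carlo hot path: estimates only feed a
    # kernel density whose bandwidth is orders of magnitude above eps(f32)
    sds = tuple(s.astype(np.float32) for s in sds64)
    z32 = z if z.dtype == np.float32 else z.astype(np.float32)
    meas = SensoryMeasurement(
        x_vest=stim.s_self.astype(np.float32) + sds[0] * z32[0],
        x_vis=(stim.s_self - stim.s_env).astype(np.float32) + sds[1] * z32[1],
        x_vis0=(-stim.s_env0).astype(np.float32) + sds[2] * z32[2],
    )
    kw = {}
    if model_id == "varweight":
        kw["env_constant"] = cond.env_constant[:, None]
    est = observers.estimate(model_id, params, meas, sds, **kw)
    return np.asarray(est.s_hat)


def _dataset_loglik(
    model_id: str,
    params: ObserverParams,
    cond: _ConditionData,
    z: np.ndarray,
    config: FitConfig,
) -> float:
    sim = _simulate_estimates(model_id, params, cond, z, config)
    return _kde_loglik(sim, cond.responses, config)


# ---------------------------------------------------------------------------
# Public likelihood / posterior operations


def response_loglik(
    model_id: str,
    params: ObserverParams,
    stimulus: TrialStimulus,
    responses: Sequence[float],
    config: FitConfig,
    rng: np.random.Generator,
) -> float:
    """Marginal log likelihood of responses for a single stimulus condition.

    ``responses`` are on the model's estimate scale (lateral deg/s). The
    measurement marginalization uses ``config.n_mc`` draws from ``rng``.
    """
    resp = np.asarray(responses, dtype=float)[None, :]
    cond = _ConditionData(
        s_self=np.atleast_1d(np.asarray(stimulus.s_self, dtype=float)),
        s_env=np.atleast_1d(np.asarray(stimulus.s_env, dtype=float)),
        s_env0=np.atleast_1d(np.asarray(stimulus.s_env0, dtype=float)),
        env_constant=np.atleast_1d(
            np.asarray(stimulus.s_env0 == stimulus.s_env)
        ),
        responses=resp,
        keys=pd.DataFrame(),
    )
    z = rng.standard_normal((3, 1, config.n_mc))
    return _dataset_loglik(model_id, params, cond, z, config)


def total_log_posterior(
    model_id: str,
    params: ObserverParams,
    dataset: pd.DataFrame,
    config: FitConfig,
    rng: np.random.Generator,
) -> float:
    """Sum of per-condition log likelihoods plus the log parameter prior."""
    cond = _condition_data(dataset, config)
    z = rng.standard_normal((3, len(cond.s_self), config.n_mc))
    return _dataset_loglik(model_id, params, cond, z, config) + log_prior(
        model_id, params
    )


# ---------------------------------------------------------------------------
# MAP fitting


def fit_model(model_id: str, dataset: pd.DataFrame, config: FitConfig) -> FitResult:
    """MAP fit of one observer model to one observer's dataset.

    Bounded Powell search over transformed coordinates (log scale for the
    positive parameters) with common random numbers across all objective
    evaluations of the fit, restarted from Latin-hypercube initial points.
    The final log likelihood averages ``config.n_final_evals`` fresh
    Monte-Carlo evaluations at the optimum.
    """
    fps = FREE_PARAMS[model_id]
    cond = _condition_data(dataset, config)
    if np.all(np.isnan(cond.responses)):
        raise ValueError("dataset has no responses")
    root = np.random.SeedSequence(config.seed)
    crn_ss, lhs_ss, final_ss = root.spawn(3)
    z = np.random.default_rng(crn_ss).standard_normal(
        (3, len(cond.s_self), config.n_mc)
    ).astype(np.float32)
    bounds = _theta_bounds(model_id, config)

    def neg_log_post(theta: np.ndarray) -> float:
        try:
            params = _theta_to_params(model_id, theta)
        except Exception:
            return 1e12
        lp = log_prior(model_id, params)
        if not np.isfinite(lp):
            return 1e12
        return -(_dataset_loglik(model_id, params, cond, z, config) + lp)

    sampler = qmc.LatinHypercube(d=len(fps), seed=np.random.default_rng(lhs_ss))
    unit = sampler.random(config.n_restarts)
    x0s = np.empty_like(unit)
    for j, fp in enumerate(fps):
        lo, hi = (np.log(fp.init_low), np.log(fp.init_high)) if fp.log_scale else (
            fp.init_low,
            fp.init_high,
        )
        blo, bhi = bounds[j]
        x0s[:, j] = np.clip(lo + unit[:, j] * (hi - lo), blo, bhi)

    best = None
    restarts = []
    any_converged = False
    for x0 in x0s:
        res = optimize.minimize(
            neg_log_post,
            x0,
            method="Powell",
            bounds=bounds,
            options={
                "xtol": config.xtol,
                "ftol": config.ftol,
                "maxfev": config.max_evals,
            },
        )
        restarts.append(
            {"x0": x0.tolist(), "x": res.x.tolist(), "fun": float(res.fun), "nfev": int(res.nfev), "success": bool(res.success)}
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    map_params = _theta_to_params(model_id, best.x)
    lp = log_prior(model_id, map_params)
    final_rng = np.random.default_rng(final_ss)
    lls = [
        _dataset_loglik(
            model_id,
            map_params,
            cond,
            final_rng.standard_normal((3, len(cond.s_self), config.n_mc)),
            config,
        )
        for _ in range(config.n_final_evals)
    ]
    log_lik = float(np.mean(lls))
    k = len(fps)
    return FitResult(
        model_id=model_id,
        map_params=map_params,
        log_posterior=log_lik + lp,
        log_likelihood=log_lik,
        aic=2.0 * k - 2.0 * log_lik,
        n_free=k,
        seed=config.seed,
        converged=any_converged,
        restarts=restarts,
        config_hash=config.hash(),
    )


# ---------------------------------------------------------------------------
# Model comparison and goodness of fit


def compare_models(
    fits: dict[str, Sequence[FitResult]],
    reference: str = "cci",
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-model AIC differences vs a reference model across observers.

    Returns one row per model with the mean delta AIC (positive = worse
    fit than the reference), a percentile bootstrap CI over observers, and
    the number of observers favoring the model over the reference.
    """
    if reference not in fits:
        raise ValueError(f"reference model {reference!r} not in fits")
    ref_aic = np.asarray([f.aic for f in fits[reference]], dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for model_id, frs in fits.items():
        aic = np.asarray([f.aic for f in frs], dtype=float)
        if aic.shape != ref_aic.shape:
            raise ValueError("all models must be fit to the same observers")
        delta = aic - ref_aic
        idx = rng.integers(0, len(delta), size=(n_boot, len(delta)))
        boot_means = delta[idx].mean(axis=1)
        rows.append(
            {
                "model_id": model_id,
                "mean_delta_aic": float(delta.mean()),
                "ci_low": float(np.percentile(boot_means, 2.5)),
                "ci_high": float(np.percentile(boot_means, 97.5)),
                "n_observers": len(delta),
                "n_favoring_model": int(np.sum(delta < 0)),
            }
        )
    return pd.DataFrame(rows)


def r_squared(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Coefficient of determination of predictions against observations."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    ss_res = np.sum((observed - predicted) ** 2)
    ss_tot = np.sum((observed - observed.mean()) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return float(1.0 - ss_res / ss_tot)


def model_r2(
    fit: FitResult,
    dataset: pd.DataFrame,
    n_sim: int = 10000,
    seed: int = 0,
    config: Optional[FitConfig] = None,
) -> float:
    """R^2 between condition-mean model predictions and condition-mean data.

    Simulates ``n_sim`` heading estimates per unique stimulus condition
    from the fitted parameters and compares the per-condition average
    reported heading (deg) with the observed per-condition average.
    """
    config = config or FitConfig(seed=seed)
    cond = _condition_data(dataset, config)
    z = np.random.default_rng(seed).standard_normal((3, len(cond.s_self), n_sim))
    sim = _simulate_estimates(fit.model_id, fit.map_params, cond, z, config)
    pred_deg = np.mean(
        np.asarray(lateral_to_heading(sim, config.reference_speed)), axis=1
    )
    obs_lat = cond.responses
    obs_deg = np.nanmean(
        np.asarray(lateral_to_heading(obs_lat, config.reference_speed)), axis=1
    )
    return r_squared(pred_deg, obs_deg)
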