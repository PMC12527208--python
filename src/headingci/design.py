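"""Factorial experiment design and simulated observer datasets.

The study design crosses 5 visual velocities (0, +/-5, +/-10 deg/s) x 10
heading directions (+/-5 ... +/-45 deg) x 3 visual-motion conditions
(Acceleration / Constant / Deceleration) = 150 distinct stimulus
conditions, each repeated 5 times (750 trials), with trial order randomly
interleaved. The condition fixes the pre-motion environmental velocity:

* Acceleration: ``s_env0 = 0``
* Constant:     ``s_env0 = s_env``
* Deceleration: ``s_env0 = 2 * s_env``

with ``s_env`` equal to the nominal visual velocity. Datasets are tidy
pandas DataFrames (one row per trial) so they serialize directly to CSV;
simulation mode retains the latent measurements and per-trial diagnostics.
"""

from __future__ import annotations

import itertools
from typing import Callable, Sequence

import numpy as np
import pandas as pd

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
    "CONDITIONS",
    "DEFAULT_VELOCITIES",
    "DEFAULT_HEADINGS",
    "build_design",
    "simulate_observer",
    "make_cohort",
    "sample_cci_params",
    "sample_fixed_params",
]

CONDITIONS = ("Acceleration", "Constant", "Deceleration")
DEFAULT_VELOCITIES = (-10.0, -5.0, 0.0, 5.0, 10.0)
DEFAULT_HEADINGS = (-45.0, -35.0, -25.0, -15.0, -5.0, 5.0, 15.0, 25.0, 35.0, 45.0)

#: Pre-motion environmental velocity as a multiple of the during-motion one.
_ENV0_FACTOR = {"Acceleration": 0.0, "Constant": 1.0, "Deceleration": 2.0}


def build_design(
    velocities: Sequence[float] = DEFAULT_VELOCITIES,
    headings: Sequence[float] = DEFAULT_HEADINGS,
    conditions: Sequence[str] = CONDITIONS,
    reps: int = 5,
    seed: int = 0,
    reference_speed: float = DEFAULT_REFERENCE_SPEED,
    angle_mapping: str = "sine",
) -> pd.DataFrame:
    """Full factorial design with randomized trial order.

    Returns one row per trial with the true latent state filled in per the
    condition schedule. Metadata (seed, factor sets, angle mapping) is
    stored in ``DataFrame.attrs``. ``angle_mapping="identity"`` switches
    the heading-angle commensuration to the angle-as-is sensitivity mode.
    """
    for name, levels in (
        ("velocities", velocities),
        ("headings", headings),
        ("conditions", conditions),
    ):
        if len(levels) == 0:
            raise ValueError(f"{name} must be non-empty")
        if len(set(levels)) != len(levels):
            raise ValueError(f"duplicate {name} levels: {levels}")
    unknown = set(conditions) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions: {sorted(unknown)}")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    rows = []
    for cond, vel, head, rep in itertools.product(
        conditions, velocities, headings, range(reps)
    ):
        s_env = float(vel)
        rows.append(
            {
                "condition": cond,
                "visual_velocity": float(vel),
                "heading_angle": float(head),
                "rep": rep,
                "s_self": float(heading_to_lateral(head, reference_speed, angle_mapping)),
                "s_env": s_env,
                "s_env0": _ENV0_FACTOR[cond] * s_env,
            }
        )
    df = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    df = df.sample(frac=1.0, random_state=rng).reset_index(drop=True)
    df.insert(0, "trial", np.arange(len(df)))
    df.attrs.update(
        seed=seed,
        reference_speed=reference_speed,
        angle_mapping=angle_mapping,
        velocities=tuple(velocities),
        headings=tuple(headings),
        conditions=tuple(conditions),
        reps=reps,
    )
    return df


def _design_stimulus(design: pd.DataFrame) -> TrialStimulus:
    return TrialStimulus(
        s_self=design["s_self"].to_numpy(),
        s_env=design["s_env"].to_numpy(),
        s_env0=design["s_env0"].to_numpy(),
    )


def simulate_observer(
    model_id: str,
    params: ObserverParams,
    design: pd.DataFrame,
    seed: int = 0,
    reference_speed: float | None = None,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    observer: str = "sim-0",
) -> pd.DataFrame:
    """Simulate one observer's responses over a design table.

    Per trial: draw the sensory measurements, run the model estimator, map
    the lateral estimate back to a reported heading angle (clamped to
    +/-90 deg by the arcsine mapping). Diagnostics (per-structure estimates
    and the structure posterior, where the model defines them) are kept.
    """
    if reference_speed is None:
        reference_speed = design.attrs.get("reference_speed", DEFAULT_REFERENCE_SPEED)
    angle_mapping = design.attrs.get("angle_mapping", "sine")
    rng = np.random.default_rng(seed)
    stim = _design_stimulus(design)
    sds = measurement_sds(params, stim, noise_floor)
    z = rng.standard_normal((3, len(design)))
    meas = SensoryMeasurement(
        x_vest=stim.s_self + sds[0] * z[0],
        x_vis=(stim.s_self - stim.s_env) + sds[1] * z[1],
        x_vis0=-stim.s_env0 + sds[2] * z[2],
    )
    kw = {}
    if model_id == "varweight":
        kw["env_constant"] = stim.s_env0 == stim.s_env
    est = observers.estimate(model_id, params, meas, sds, **kw)

    out = design.copy()
    out["observer"] = observer
    out["x_vest"] = meas.x_vest
    out["x_vis"] = meas.x_vis
    out["x_vis0"] = meas.x_vis0
    out["estimate_lateral"] = np.asarray(est.s_hat, dtype=float)
    out["reported_heading"] = lateral_to_heading(
        out["estimate_lateral"].to_numpy(), reference_speed, angle_mapping
    )
    if est.s_hat_c1 is not None:
        out["s_hat_c1"] = np.asarray(est.s_hat_c1, dtype=float)
    if est.s_hat_c2 is not None:
        out["s_hat_c2"] = np.asarray(est.s_hat_c2, dtype=float)
    if est.structure_posterior is not None:
        out["p_c1"] = np.broadcast_to(
            np.asarray(est.structure_posterior.p_c1, dtype=float), (len(out),)
        )
    out.attrs.update(design.attrs)
    out.attrs.update(model_id=model_id, sim_seed=seed, observer=observer)
    return out


def make_cohort(
    model_id: str,
    n_observers: int,
    param_sampler: Callable[[np.random.Generator], ObserverParams],
    design: pd.DataFrame,
    seed: int = 0,
) -> list[tuple[pd.DataFrame, ObserverParams]]:
    """Simulate a cohort with independently drawn true parameters.

    Returns ``[(dataset, true_params), ...]``; each dataset records its own
    simulation seed in ``attrs``.
    """
    root = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(root.spawn(n_observers)):
        rng = np.random.default_rng(child)
        params = param_sampler(rng)
        sim_seed = int(rng.integers(2**31 - 1))
        ds = simulate_observer(
            model_id, params, design, seed=sim_seed, observer=f"sim-{i}"
        )
        out.append((ds, params))
    return out


# ---------------------------------------------------------------------------
# Cohort parameter distributions (the study conditions for the synthetic
# parameter/model-recovery experiments)


def sample_cci_params(rng: np.random.Generator) -> ObserverParams:
    """Moderate contextual-causal-inference observer parameters.

    Medians sit near the fitting priors' medians scaled to the stimulus
    range (velocities up to 10 deg/s, lateral self-motion up to 8.5 deg/s):
    sigma_self ~ 5, sigma_env ~ 5, sigma_vest ~ 2 deg/s, w_vis ~ 0.15, with
    modest log-normal spread across observers; p_constant uniform on
    [0.2, 0.8].
    """
    return ObserverParams(
        model_id="cci",
        sigma_self=float(5.0 * np.exp(rng.normal(0.0, 0.25))),
        sigma_env=float(5.0 * np.exp(rng.normal(0.0, 0.25))),
        sigma_vest=float(2.0 * np.exp(rng.normal(0.0, 0.4))),
        w_vis=float(0.15 * np.exp(rng.normal(0.0, 0.3))),
        p_constant=float(rng.uniform(0.2, 0.8)),
    )


def sample_fixed_params(rng: np.random.Generator) -> ObserverParams:
    """Moderate fixed-weight observer parameters (linear-integration null)."""
    return ObserverParams(
        model_id="fixed",
        sigma_vest=float(2.0 * np.exp(rng.normal(0.0, 0.4))),
        w_vis=float(0.15 * np.exp(rng.normal(0.0, 0.3))),
        alpha_vest=float(rng.uniform(0.4, 0.8)),
        alpha_mom=float(rng.uniform(0.1, 0.35)),
        alpha_cont=float(rng.uniform(0.1, 0.35)),
    )
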