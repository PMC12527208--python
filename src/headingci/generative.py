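"""Latent-variable generative model of visual-vestibular heading trials.

A seated observer is translated in the frontal plane while a large-field
visual texture moves laterally. Three latent velocities (all lateral
components, in deg/s) determine what the senses measure:

* ``s_self`` -- the observer's own lateral velocity,
* ``s_env0`` -- environmental (world) motion *before* self-motion,
* ``s_env`` -- environmental motion *during* self-motion.

The senses return three noisy measurements::

    x_vest ~ N(s_self,           sigma_vest^2)
    x_vis  ~ N(s_self - s_env,   sigma_vis^2)     (retinal motion during)
    x_vis0 ~ N(-s_env0,          sigma_vis0^2)    (retinal motion before)

Visual noise follows Weber's law: sigma_vis = w_vis * |s_self - s_env| and
sigma_vis0 = w_vis * |s_env0|, floored at a small ``noise_floor`` so that
nulled retinal motion never yields a degenerate (zero-width) density.

Priors are zero-mean Gaussians ("slow-speed prior"): s_self ~ N(0,
sigma_self^2) and s_env0, s_env ~ N(0, sigma_env^2). A binary causal
structure C in {1, 2} states whether the environmental motion remained
constant (C=1: s_env = s_env0) or changed (C=2: independent draws).

Heading angle (deg from vertically upward, positive rightward) and lateral
velocity are commensurated through a reference speed, by default the 8.5
deg/s peak platform velocity: lateral = ref * sin(angle).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import IntEnum
from typing import Optional

import numpy as np

__all__ = [
    "MODEL_IDS",
    "DEFAULT_NOISE_FLOOR",
    "DEFAULT_REFERENCE_SPEED",
    "CausalStructure",
    "ObserverParams",
    "TrialStimulus",
    "SensoryMeasurement",
    "measurement_sds",
    "sample_measurements",
    "heading_to_lateral",
    "lateral_to_heading",
]

#: Observer models implemented by :mod:`headingci.observers`.
MODEL_IDS = (
    "cci",
    "integration",
    "segregation",
    "covariance",
    "fixed",
    "heuristic",
    "wta",
    "mci",
)

#: Floor (deg/s) applied to Weber-law SDs so zero-signal trials keep a
#: proper, if very narrow, measurement density.
DEFAULT_NOISE_FLOOR = 1e-3

#: Peak platform velocity (deg/s); default scale mapping heading angle to
#: a lateral velocity commensurate with the visual velocities.
DEFAULT_REFERENCE_SPEED = 8.5


class CausalStructure(IntEnum):
    """Causal structure of environmental motion across the two epochs."""

    CONSTANT = 1  # C=1: same environmental motion before and during
    CHANGED = 2  # C=2: independent environmental motion


class InvalidParameterError(ValueError):
    """Raised when observer parameters violate their domain constraints."""


@dataclass
class ObserverParams:
    """Parameters of one observer model.

    Fields irrelevant to ``model_id`` may be left ``None``; validation only
    inspects the fields the model uses.
    """

    model_id: str = "cci"
    sigma_self: Optional[float] = None  # prior SD of s_self (deg/s)
    sigma_env: Optional[float] = None  # prior SD of s_env, s_env0 (deg/s)
    sigma_vest: Optional[float] = None  # vestibular noise SD (deg/s)
    w_vis: Optional[float] = None  # visual Weber fraction
    p_constant: Optional[float] = None  # prior P(C=1), contextual models
    rho: Optional[float] = None  # env-motion correlation (covariance)
    alpha_vest: Optional[float] = None  # fixed-weight model weights
    alpha_mom: Optional[float] = None
    alpha_cont: Optional[float] = None
    p_common: Optional[float] = None  # prior P(common cause), MCI
    alpha_1: Optional[float] = None  # variable-weight diagnostic only
    alpha_2: Optional[float] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("sigma_self", "sigma_env", "sigma_vest"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise InvalidParameterError(f"{name} must be > 0, got {v}")
        if self.w_vis is not None and self.w_vis < 0:
            raise InvalidParameterError(f"w_vis must be >= 0, got {self.w_vis}")
        for name in ("p_constant", "p_common", "rho"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ObserverParams":
        return cls(**json.loads(text))


@dataclass
class TrialStimulus:
    """True latent state of one trial (fields may be numpy arrays)."""

    s_self: np.ndarray | float  # lateral self-motion (deg/s, signed)
    s_env: np.ndarray | float  # environmental motion during (deg/s)
    s_env0: np.ndarray | float  # environmental motion before (deg/s)
    heading_angle: np.ndarray | float | None = None  # deg in [-45, 45]
    condition: object = None  # Acceleration | Constant | Deceleration
    visual_velocity: np.ndarray | float | None = None  # nominal s_env
    rep: object = None


@dataclass
class SensoryMeasurement:
    """Noisy cues for one trial or a batch (fields broadcast together)."""

    x_vest: np.ndarray | float
    x_vis: np.ndarray | float
    x_vis0: np.ndarray | float


# ---------------------------------------------------------------------------
# Weber-law measurement widths


def measurement_sds(
    params: ObserverParams,
    stim: TrialStimulus,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Measurement SDs ``(sigma_vest, sigma_vis, sigma_vis0)`` for a trial.

    sigma_vis = w_vis * |s_self - s_env| and sigma_vis0 = w_vis * |s_env0|
    (Weber's law), both floored at ``noise_floor``; sigma_vest is
    signal-independent.
    """
    params.validate()
    if params.sigma_vest is None or params.w_vis is None:
        raise InvalidParameterError("sigma_vest and w_vis are required")
    s_self = np.asarray(stim.s_self, dtype=float)
    s_env = np.asarray(stim.s_env, dtype=float)
    s_env0 = np.asarray(stim.s_env0, dtype=float)
    sigma_vis = np.maximum(params.w_vis * np.abs(s_self - s_env), noise_floor)
    sigma_vis0 = np.maximum(params.w_vis * np.abs(s_env0), noise_floor)
    sigma_vest = np.broadcast_to(
        np.asarray(params.sigma_vest, dtype=float), sigma_vis.shape
    ).copy()
    return sigma_vest, sigma_vis, sigma_vis0


def sample_measurements(
    params: ObserverParams,
    stim: TrialStimulus,
    rng: np.random.Generator,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    size: Optional[int] = None,
) -> SensoryMeasurement:
    """Draw noisy sensory measurements for a trial (or trial batch).

    ``x_vest ~ N(s_self, sigma_vest^2)``, ``x_vis ~ N(s_self - s_env,
    sigma_vis^2)``, ``x_vis0 ~ N(-s_env0, sigma_vis0^2)``, independent.
    With ``size`` given, draws that many samples per trial (extra trailing
    axis).
    """
    sigma_vest, sigma_vis, sigma_vis0 = measurement_sds(params, stim, noise_floor)
    s_self = np.asarray(stim.s_self, dtype=float)
    s_env = np.asarray(stim.s_env, dtype=float)
    s_env0 = np.asarray(stim.s_env0, dtype=float)
    shape = np.broadcast(s_self, s_env, s_env0, sigma_vest).shape
    if size is not None:
        shape = shape + (size,)
        s_self = s_self[..., None]
        s_env = s_env[..., None]
        s_env0 = s_env0[..., None]
        sigma_vest = sigma_vest[..., None]
        sigma_vis = sigma_vis[..., None]
        sigma_vis0 = sigma_vis0[..., None]
    z = rng.standard_normal((3,) + shape)
    return SensoryMeasurement(
        x_vest=s_self + sigma_vest * z[0],
        x_vis=(s_self - s_env) + sigma_vis * z[1],
        x_vis0=-s_env0 + sigma_vis0 * z[2],
    )


# ---------------------------------------------------------------------------
# Heading angle <-> lateral velocity commensuration


def heading_to_lateral(
    angle: np.ndarray | float,
    reference_speed: float = DEFAULT_REFERENCE_SPEED,
    mode: str = "sine",
) -> np.ndarray | float:
    """Lateral velocity component (deg/s) of a heading angle (deg).

    ``mode="sine"`` (default): ``reference_speed * sin(angle)``, placing
    heading on the same velocity axis as the visual stimuli.
    ``mode="identity"``: treats the angle value itself as the latent
    signal — a sensitivity-analysis alternative, since the behavioral
    paradigm does not pin the commensuration down.
    """
    if not reference_speed > 0:
        raise ValueError("reference_speed must be > 0")
    if mode == "identity":
        return np.asarray(angle, dtype=float) if not np.isscalar(angle) else float(angle)
    if mode != "sine":
        raise ValueError(f"unknown mapping mode {mode!r}")
    return reference_speed * np.sin(np.deg2rad(angle))


def lateral_to_heading(
    lateral: np.ndarray | float,
    reference_speed: float = DEFAULT_REFERENCE_SPEED,
    mode: str = "sine",
) -> np.ndarray | float:
    """Heading angle (deg) whose lateral component is ``lateral``.

    In ``mode="sine"`` the argument of the arcsine is clamped to [-1, 1],
    so estimates whose magnitude exceeds the reference speed map to
    +/-90 deg; ``mode="identity"`` clamps the angle directly to [-90, 90].
    """
    if not reference_speed > 0:
        raise ValueError("reference_speed must be > 0")
    if mode == "identity":
        out = np.clip(np.asarray(lateral, dtype=float), -90.0, 90.0)
        return float(out) if np.isscalar(lateral) else out
    if mode != "sine":
        raise ValueError(f"unknown mapping mode {mode!r}")
    ratio = np.clip(np.asarray(lateral, dtype=float) / reference_speed, -1.0, 1.0)
    out = np.rad2deg(np.arcsin(ratio))
    return float(out) if np.isscalar(lateral) else out
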