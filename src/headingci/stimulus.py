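"""Visual-stimulus mathematics: velocity profiles and motion clouds.

Two pieces:

1. **Modified raised-cosine velocity profiles.** The platform (and the
   visual speed ramps) follow a raised-cosine rise, a plateau held at peak
   velocity, and a raised-cosine fall. Defaults match the inertial
   stimulus: 8.5 deg/s peak held for 0.4 s within a 2 s total at 60 Hz.
   ``condition_schedule`` builds the pre-/during-motion visual velocity
   pair for the three conditions.

2. **Motion clouds.** Non-rigid texture motion obtained by shaping the 3-D
   (fx, fy, ft) amplitude spectrum of white noise with (a) a Gaussian
   "speed plane" term concentrating energy on ``fx*Vx + fy*Vy + ft = 0``
   with width ``Bv * fr``, and (b) a log-scale radial spatial-frequency
   term ``(1/fr) * exp(-0.5 * (ln(fr/sf0) / ln((sf0+Bsf)/sf0))^2)``. The
   random phase comes from Fourier-transformed white noise, which keeps the
   spectrum Hermitian so the inverse transform is real.

With this construction the energy per *logarithmic* frequency interval
peaks at ``sf0``, matching the log-scale definition of the envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VelocityProfile",
    "MotionCloudSpec",
    "raised_cosine_profile",
    "constant_profile",
    "condition_schedule",
    "motion_cloud",
    "estimate_cloud_velocity",
    "radial_log_spectrum",
]


@dataclass
class VelocityProfile:
    """Sampled velocity time series at a fixed rate."""

    velocity: np.ndarray  # deg/s
    rate: float  # Hz

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.velocity)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.velocity) / self.rate

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.velocity)))


def raised_cosine_profile(
    peak: float = 8.5,
    rise_fall_total: float = 1.6,
    hold: float = 0.4,
    rate: float = 60.0,
) -> VelocityProfile:
    """Raised-cosine rise to ``peak``, plateau for ``hold``, mirror fall.

    ``rise_fall_total`` is the combined rise+fall time (split evenly);
    total duration is ``rise_fall_total + hold`` (defaults give the 2 s
    inertial profile). ``rise_fall_total=0`` degenerates to a constant
    plateau.
    """
    if rise_fall_total < 0 or hold < 0:
        raise ValueError("durations must be non-negative")
    if not rate > 0:
        raise ValueError("rate must be > 0")
    total = rise_fall_total + hold
    if total <= 0:
        raise ValueError("profile must have positive duration")
    n = int(round(total * rate)) + 1
    t = np.arange(n) / rate
    rise = rise_fall_total / 2.0
    v = np.full(n, float(peak))
    if rise > 0:
        up = t < rise
        v[up] = peak * 0.5 * (1.0 - np.cos(np.pi * t[up] / rise))
        down = t > rise + hold
        v[down] = peak * 0.5 * (1.0 - np.cos(np.pi * (total - t[down]) / rise))
    return VelocityProfile(v, rate)


def constant_profile(level: float, duration: float, rate: float = 60.0) -> VelocityProfile:
    """Constant velocity for ``duration`` seconds."""
    n = int(round(duration * rate)) + 1
    return VelocityProfile(np.full(n, float(level)), rate)


def _ramp(v0: float, v1: float, duration: float, rate: float) -> np.ndarray:
    """Raised-cosine transition from ``v0`` to ``v1`` over ``duration``."""
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * t / duration))


def condition_schedule(
    condition: str,
    desired_velocity: float,
    rate: float = 60.0,
    pre_duration: float = 2.0,
    ramp: float = 0.8,
    hold: float = 0.4,
    release: float = 0.8,
) -> tuple[VelocityProfile, VelocityProfile]:
    """Pre-motion and during-motion visual velocity profiles.

    * Constant: both epochs constant at ``desired_velocity``.
    * Acceleration: pre-motion at 0; at inertial onset the velocity ramps
      up to the desired value, holds for ``hold`` s, then returns to the
      initial velocity over ``release`` s.
    * Deceleration: pre-motion at twice the desired velocity, then ramps
      down to it at onset, holds, and returns.

    Transitions follow the raised-cosine shape.
    """
    if condition not in ("Acceleration", "Constant", "Deceleration"):
        raise ValueError(f"unknown condition {condition!r}")
    during_duration = ramp + hold + release
    if condition == "Constant":
        pre = constant_profile(desired_velocity, pre_duration, rate)
        during = constant_profile(desired_velocity, during_duration, rate)
        return pre, during
    v0 = 0.0 if condition == "Acceleration" else 2.0 * desired_velocity
    pre = constant_profile(v0, pre_duration, rate)
    n_hold = int(round(hold * rate))
    v = np.concatenate(
        [
            _ramp(v0, desired_velocity, ramp, rate),
            np.full(n_hold, float(desired_velocity)),
            _ramp(desired_velocity, v0, release, rate),
            [v0],
        ]
    )
    return pre, VelocityProfile(v, rate)


# ---------------------------------------------------------------------------
# Motion clouds


@dataclass
class MotionCloudSpec:
    """Spectral specification of a motion-cloud stimulus.

    Defaults emulate the study apparatus: a 25 deg-radius field rendered on
    a 128 px grid at 60 Hz, central spatial frequency and bandwidth of
    0.5 cpd, speed bandwidth 2.1 deg/s.
    """

    vx: float = 10.0  # central horizontal speed (deg/s)
    vy: float = 0.0  # central vertical speed (deg/s)
    bv: float = 2.1  # speed bandwidth (deg/s)
    sf0: float = 0.5  # central spatial frequency (cpd)
    bsf: float = 0.5  # spatial-frequency bandwidth (cpd)
    size: int = 128  # frame size (pixels, square)
    n_frames: int = 64
    frame_rate: float = 60.0  # Hz
    deg_per_pixel: float = 50.0 / 128.0

    def validate(self) -> None:
        if self.bv <= 0 or self.sf0 <= 0 or self.bsf <= 0:
            raise ValueError("bv, sf0 and bsf must be > 0")
        if self.size < 4 or self.n_frames < 4:
            raise ValueError("size and n_frames must be >= 4")


def _frequency_grids(spec: MotionCloudSpec):
    fx = np.fft.fftfreq(spec.size, d=spec.deg_per_pixel)  # cycles/deg
    fy = np.fft.fftfreq(spec.size, d=spec.deg_per_pixel)
    ft = np.fft.fftfreq(spec.n_frames, d=1.0 / spec.frame_rate)  # Hz
    return (
        ft[:, None, None],
        fy[None, :, None],
        fx[None, None, :],
    )


def _spectral_envelope(spec: MotionCloudSpec) -> np.ndarray:
    """Amplitude envelope over (ft, fy, fx); zero at the spatial DC.

    Nyquist planes (even-sized axes) are zeroed: their frequency sign is
    ambiguous, which would break the Hermitian symmetry of the envelope.
    """
    ft, fy, fx = _frequency_grids(spec)
    fr = np.hypot(fx, fy) + np.zeros_like(ft)
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.exp(
            -0.5 * ((fx * spec.vx + fy * spec.vy + ft) / (spec.bv * fr)) ** 2
        )
        log_bw = np.log((spec.sf0 + spec.bsf) / spec.sf0)
        radial = (1.0 / fr) * np.exp(-0.5 * (np.log(fr / spec.sf0) / log_bw) ** 2)
    env = np.where(fr > 0, speed * radial, 0.0)
    for axis, n, grid in ((0, spec.n_frames, ft), (1, spec.size, fy), (2, spec.size, fx)):
        if n % 2 == 0:
            env[(slice(None),) * axis + (n // 2,)] = 0.0
    return env


def motion_cloud(spec: MotionCloudSpec, seed: int = 0) -> np.ndarray:
    """Generate a motion-cloud image stack of shape (n_frames, size, size).

    Bandpass-filters white noise with the spectral envelope: the noise
    supplies a uniform random (Hermitian) phase spectrum, the envelope the
    amplitude. Output is real-valued, normalized to [0, 1]; the excluded
    DC component leaves the mean at mid-gray after normalization.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((spec.n_frames, spec.size, spec.size))
    spectrum = np.fft.fftn(noise)
    phase = spectrum / np.maximum(np.abs(spectrum), 1e-300)  # unit-modulus phases
    shaped = _spectral_envelope(spec) * phase
    frames = np.fft.ifftn(shaped)
    resid = np.abs(frames.imag).max()
    rms = np.sqrt(np.mean(frames.real**2))
    if rms > 0 and resid > 1e-10 * rms:
        raise AssertionError("non-Hermitian spectrum: imaginary residue too large")
    img = frames.real
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.full_like(img, 0.5)
    return img


def estimate_cloud_velocity(stack: np.ndarray, spec: MotionCloudSpec) -> tuple[float, float]:
    """Recover the dominant (Vx, Vy) from the energy-weighted plane fit.

    Least squares of ``fx*Vx + fy*Vy + ft ~ 0`` weighted by spectral
    energy, the translation-speed readout of the 3-D spectrum.
    """
    ft, fy, fx = _frequency_grids(spec)
    energy = np.abs(np.fft.fftn(stack - stack.mean())) ** 2
    fr = np.hypot(fx, fy) + np.zeros_like(ft)
    w = np.where(fr > 0, energy, 0.0).ravel()
    a = np.stack(
        [np.broadcast_to(fx, energy.shape).ravel(), np.broadcast_to(fy, energy.shape).ravel()],
        axis=1,
    )
    b = -np.broadcast_to(ft, energy.shape).ravel()
    aw = a * w[:, None]
    sol, *_ = np.linalg.lstsq(aw.T @ a, aw.T @ b, rcond=None)
    return float(sol[0]), float(sol[1])


def radial_log_spectrum(
    stack: np.ndarray, spec: MotionCloudSpec, n_bins: int = 48
) -> tuple[np.ndarray, np.ndarray]:
    """Spatial-frequency energy profile per logarithmic frequency bin.

    Cell energies are first summed over temporal frequency and divided by
    the radial frequency: the speed-plane envelope spreads each spatial
    frequency's energy over a temporal band of width ~ ``Bv * fr``, and
    dividing that factor out isolates the log-scale spatial envelope. On
    this scale the generated clouds peak at ``sf0``.

    Returns (bin centers in cpd, compensated energy per bin).
    """
    _, fy, fx = _frequency_grids(spec)
    energy = np.abs(np.fft.fftn(stack - stack.mean())) ** 2
    spatial = energy.sum(axis=0)  # integrate over temporal frequency
    fr = np.hypot(fx, fy)[0].ravel()
    e = spatial.ravel()
    mask = fr > 0
    log_fr = np.log(fr[mask])
    edges = np.linspace(log_fr.min(), np.log(fr.max()), n_bins + 1)
    hist, _ = np.histogram(log_fr, bins=edges, weights=e[mask] / fr[mask])
    centers = np.exp(0.5 * (edges[:-1] + edges[1:]))
    return centers, hist
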