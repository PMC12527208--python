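"""Behavioral analyses: heading bias, cue regression, adaptive weights.

* ``heading_bias`` computes the per-trial angular error (reported minus
  true heading), realigned so that positive bias points in the direction
  of the visual motion: the sign is flipped on leftward (negative visual
  velocity) trials, exploiting the left/right symmetry of the task; 0 deg/s
  trials enter unflipped. Errors are then aggregated by condition and
  unsigned visual speed.

* ``regression_decomposition`` fits, per observer, an OLS regression of
  the heading estimate on the predictions of the three information
  sources (all in lateral deg/s): vestibular (``s_self``), momentary
  vision (``s_self - s_env``) and contextual vision
  (``s_self - s_env + s_env0``), plus an intercept. Signed quantities are
  used directly (no mirroring). Group-level one-sample t statistics on the
  coefficients are returned when several observers are present.

* ``variable_weight_fit`` is the adaptive-weight diagnostic: the causal
  structure posterior of the contextual model is replaced by one of two
  free weights on the constant-structure estimate, selected by the *true*
  state of the environment (``alpha_1`` when ``s_env0 == s_env``; all
  0 deg/s trials satisfy the equality literally). A gap ``alpha_1 >
  alpha_2`` is the signature of causal inference; a linear integrator
  yields ``alpha_1 ~ alpha_2``. Fitting reuses the Monte-Carlo/KDE
  machinery of :mod:`headingci.fitting`.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .fitting import FitConfig, FitResult, fit_model
from .generative import ObserverParams, heading_to_lateral

__all__ = [
    "BiasTable",
    "WeightFit",
    "heading_bias",
    "regression_decomposition",
    "group_coefficient_tests",
    "simulated_bias_surface",
    "variable_weight_fit",
    "plot_bias",
    "plot_weights",
]


@dataclass
class WeightFit:
    """Adaptive-weight diagnostic fit."""

    alpha_1: float  # weight on the C=1 estimate when env was constant
    alpha_2: float  # ... when it was not
    params: ObserverParams  # accompanying generative parameters
    fit: FitResult


#: Alias: the bias table is a tidy DataFrame with columns
#: (observer, condition, visual_speed, bias, sem, n).
BiasTable = pd.DataFrame


def heading_bias(dataset: pd.DataFrame) -> BiasTable:
    """Realigned heading-bias table by condition and unsigned visual speed.

    Per-trial bias is ``reported_heading - heading_angle`` (deg) with the
    sign flipped on leftward-visual trials, so negative bias means
    "opposite to the visual motion". Empty cells are simply absent from
    the output (never reported as zero).
    """
    required = {"condition", "visual_velocity", "heading_angle", "reported_heading"}
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    df = dataset.copy()
    if "observer" not in df.columns:
        df["observer"] = "obs-0"
    err = df["reported_heading"] - df["heading_angle"]
    flip = np.where(df["visual_velocity"] < 0, -1.0, 1.0)
    df["bias"] = err * flip
    df["visual_speed"] = df["visual_velocity"].abs()
    out = (
        df.groupby(["observer", "condition", "visual_speed"])["bias"]
        .agg(bias="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
        .reset_index()
    )
    return out


def regression_decomposition(
    dataset: pd.DataFrame, response_col: str = "reported_heading"
) -> pd.DataFrame:
    """Per-observer OLS decomposition onto the three cue predictions.

    Regresses the lateral heading estimate on ``s_self``,
    ``s_self - s_env`` and ``s_self - s_env + s_env0`` plus an intercept.
    Returns one row per observer with coefficients ``beta0..beta3`` and
    their standard errors. Raises on a rank-deficient design (e.g., a
    single condition, where the predictors are collinear).
    """
    required = {"s_self", "s_env", "s_env0", response_col}
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    df = dataset.copy()
    if "observer" not in df.columns:
        df["observer"] = "obs-0"
    rows = []
    for obs, g in df.groupby("observer"):
        if response_col == "reported_heading":
            y = np.asarray(heading_to_lateral(g[response_col].to_numpy()))
        else:
            y = g[response_col].to_numpy(dtype=float)
        x1 = g["s_self"].to_numpy(dtype=float)
        x2 = x1 - g["s_env"].to_numpy(dtype=float)
        x3 = x2 + g["s_env0"].to_numpy(dtype=float)
        X = sm.add_constant(np.column_stack([x1, x2, x3]), has_constant="add")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient regression design for observer {obs!r}: "
                "the cue predictors are collinear (e.g., a single condition)"
            )
        res = sm.OLS(y, X).fit()
        row = {"observer": obs}
        for i in range(4):
            row[f"beta{i}"] = float(res.params[i])
            row[f"se{i}"] = float(res.bse[i])
        rows.append(row)
    return pd.DataFrame(rows)


def group_coefficient_tests(coefs: pd.DataFrame) -> pd.DataFrame:
    """One-sample t tests of each regression coefficient against zero."""
    rows = []
    for i, label in enumerate(["intercept", "vestibular", "momentary", "contextual"]):
        vals = coefs[f"beta{i}"].to_numpy(dtype=float)
        t, p = stats.ttest_1samp(vals, 0.0)
        rows.append(
            {
                "coefficient": label,
                "mean": float(vals.mean()),
                "t": float(t),
                "p": float(p),
                "df": len(vals) - 1,
            }
        )
    return pd.DataFrame(rows)


def simulated_bias_surface(
    model_id: str,
    params: ObserverParams,
    n_sim: int = 10000,
    seed: int = 0,
) -> BiasTable:
    """Model-predicted bias table from large-scale simulation.

    Simulates ``n_sim`` heading estimates for every unique stimulus
    condition of the default factorial design and aggregates the realigned
    angular error exactly as :func:`heading_bias` does. This is how the
    model curves of the bias-versus-speed figure are produced.
    """
    from . import fitting  # deferred: analysis <-> fitting share machinery
    from .design import build_design
    from .generative import lateral_to_heading

    design = build_design(reps=1, seed=0)
    config = FitConfig(seed=seed)
    cond = fitting._ConditionData(
        s_self=design["s_self"].to_numpy(),
        s_env=design["s_env"].to_numpy(),
        s_env0=design["s_env0"].to_numpy(),
        env_constant=(design["s_env0"] == design["s_env"]).to_numpy(),
        responses=np.zeros((len(design), 1)),
        keys=design[["condition", "visual_velocity", "heading_angle"]],
    )
    z = np.random.default_rng(seed).standard_normal((3, len(design), n_sim))
    sim = fitting._simulate_estimates(model_id, params, cond, z, config)
    reported = np.asarray(lateral_to_heading(sim, config.reference_speed))
    err = reported - design["heading_angle"].to_numpy()[:, None]
    flip = np.where(design["visual_velocity"].to_numpy() < 0, -1.0, 1.0)[:, None]
    df = design.copy()
    df["bias"] = (err * flip).mean(axis=1)
    df["sem"] = (err * flip).std(axis=1, ddof=1) / np.sqrt(n_sim)
    df["visual_speed"] = df["visual_velocity"].abs()
    out = (
        df.groupby(["condition", "visual_speed"])
        .agg(bias=("bias", "mean"), sem=("sem", "mean"), n=("bias", "size"))
        .reset_index()
    )
    out["n"] = out["n"] * n_sim
    return out


def variable_weight_fit(dataset: pd.DataFrame, config: FitConfig) -> WeightFit:
    """Fit the adaptive-weight diagnostic to one observer's dataset.

    Six free parameters: sigma_self, sigma_env, sigma_vest, w_vis and the
    two structure weights alpha_1 (environment actually constant) and
    alpha_2 (actually changed).
    """
    fr = fit_model("varweight", dataset, config)
    p = fr.map_params
    return WeightFit(alpha_1=p.alpha_1, alpha_2=p.alpha_2, params=p, fit=fr)


# ---------------------------------------------------------------------------
# Plots


def plot_bias(bias_table: BiasTable, ax=None):
    """Mean heading bias vs visual speed, one line per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pooled = (
        bias_table.groupby(["condition", "visual_speed"])["bias"].mean().reset_index()
    )
    for cond, g in pooled.groupby("condition"):
        g = g.sort_values("visual_speed")
        ax.plot(g["visual_speed"], g["bias"], marker="o", label=cond)
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("visual speed (deg/s)")
    ax.set_ylabel("heading bias (deg)")
    ax.legend()
    return ax


def plot_weights(weight_fits: list[WeightFit], ax=None):
    """Dumbbell plot of alpha_1 vs alpha_2 per observer."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for wf in weight_fits:
        ax.plot([0, 1], [wf.alpha_1, wf.alpha_2], color="gray", alpha=0.5, marker="o")
    a1 = np.mean([wf.alpha_1 for wf in weight_fits])
    a2 = np.mean([wf.alpha_2 for wf in weight_fits])
    ax.plot([0, 1], [a1, a2], color="black", marker="o", lw=2)
    ax.set_xticks([0, 1], ["env constant", "env changed"])
    ax.set_ylabel("weight on C=1 estimate")
    return ax
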