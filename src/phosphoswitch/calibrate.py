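"""Staged estimation of the unmeasured in-cell rates by differential evolution.

The staged workflow mirrors how the unmeasured rates are pinned down in
practice:

* ``jnk_stage`` — k_stim7 and dp1 from pp-JNK western-blot-like time
  courses, with a soft anchor forcing ~10% of JNK active at 40 min;
* ``p38_stage`` — k_stim6, dp2 and dp4 from two NanoBit-like p38:ATF2
  complex time courses (control and JNK-inhibited), which separate the
  p38 activation cycle from the S90-mediated suppression of binding;
* ``atf2_stage`` — dp3 from pp-ATF2 time courses, with a soft anchor
  forcing ~80% of ATF2 doubly phosphorylated at 40 min in the control.

All rates are searched in log10 space within [1e-6, 1e2] s⁻¹ by default.
Anchors enter the objective as weighted equality penalties, keeping it
smooth, rather than as hard re-parameterizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, least_squares

from .params import RATE_NAMES, ModelParameters
from .simulate import (
    Protocol,
    Trajectory,
    nanobit_signal,
    simulate_condition,
)
from .species import ConfigurationError, VARIANTS

#: observable names datasets may reference
FITTABLE_OBSERVABLES = (
    "pp_jnk_fraction",
    "pp_p38_fraction",
    "pp_atf2_fraction",
    "ps90_fraction",
    "p38_atf2_complex_total",
    "p38_atf2_complex_norm",  # NanoBit signal normalized to t = 0
)

STAGES: dict[str, tuple[str, ...]] = {
    "jnk_stage": ("k_stim7", "dp1"),
    "p38_stage": ("k_stim6", "dp2", "dp4"),
    "atf2_stage": ("dp3",),
}

STAGE_ANCHORS: dict[str, tuple[tuple[str, str, float, float], ...]] = {
    # (condition/variant, observable, time_s, target fraction)
    "jnk_stage": (("WT", "pp_jnk_fraction", 2400.0, 0.10),),
    "p38_stage": (),
    "atf2_stage": (("WT", "pp_atf2_fraction", 2400.0, 0.80),),
}

DEFAULT_BOUNDS = (1e-6, 1e2)
ANCHOR_WEIGHT = 100.0
PENALTY = 1e6

#: loosened solver tolerances for the many simulations inside a fit
FIT_RTOL = 1e-5
FIT_ATOL = 1e-9


@dataclass(frozen=True)
class FitDataset:
    """One measured (or synthetic) time series under a defined condition."""

    condition: str           # label, e.g. "CTR" or "JNK_IN_8"
    variant: str             # model variant simulated for this condition
    observable: str
    times: np.ndarray        # s
    values: np.ndarray
    weights: np.ndarray | None = None
    nanobit: bool = False    # simulate the merged exogenous-p38 system

    def __post_init__(self) -> None:
        if self.observable not in FITTABLE_OBSERVABLES:
            raise ConfigurationError(
                f"unknown observable {self.observable!r}; expected one of "
                f"{FITTABLE_OBSERVABLES}"
            )
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")


@dataclass
class ObjectiveSpec:
    """Datasets plus soft anchors defining one weighted least-squares objective."""

    datasets: list[FitDataset]
    base_params: ModelParameters = field(default_factory=ModelParameters)
    anchors: tuple[tuple[str, str, float, float], ...] = ()
    anchor_weight: float = ANCHOR_WEIGHT


def datasets_from_frame(df: pd.DataFrame, nanobit_observables=("p38_atf2_complex_norm",)) -> list[FitDataset]:
    """Group a tidy (condition, variant, observable, time_s, value, weight) table."""
    required = {"condition", "variant", "observable", "time_s", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"dataset table missing column(s) {sorted(missing)}")
    out = []
    for (cond, var, obs), g in df.groupby(
        ["condition", "variant", "observable"], sort=True
    ):
        g = g.sort_values("time_s")
        w = g["weight"].to_numpy(float) if "weight" in g else None
        out.append(
            FitDataset(
                cond,
                var,
                obs,
                g["time_s"].to_numpy(float),
                g["value"].to_numpy(float),
                w,
                nanobit=obs in nanobit_observables,
            )
        )
    return out


def _simulate_for(params: ModelParameters, ds: FitDataset,
                  cache: dict) -> Trajectory:
    key = (ds.variant, ds.nanobit, tuple(np.unique(ds.times)))
    if key not in cache:
        times = tuple(sorted(set(float(t) for t in ds.times)))
        protocol = Protocol(
            duration_s=max(2400.0, max(times)), sampling_times=times
        )
        cache[key] = simulate_condition(
            params,
            variant=ds.variant,
            protocol=protocol,
            nanobit=ds.nanobit,
            rtol=FIT_RTOL,
            atol=FIT_ATOL,
        )
    return cache[key]


def _observable_series(traj: Trajectory, observable: str) -> np.ndarray:
    if observable == "p38_atf2_complex_norm":
        return nanobit_signal(traj)
    return traj.observables[observable]


def objective_residuals(candidate: ModelParameters | dict[str, float],
                        spec: ObjectiveSpec) -> np.ndarray:
    """Stacked √weight-scaled residuals (datasets then anchors).

    The squared norm of this vector is :func:`objective_loss`.
    """
    if isinstance(candidate, dict):
        params = spec.base_params.updated(**candidate)
    else:
        params = candidate
    cache: dict = {}
    parts: list[np.ndarray] = []
    for ds in spec.datasets:
        traj = _simulate_for(params, ds, cache)
        series = _observable_series(traj, ds.observable)
        model = np.interp(ds.times, traj.times, series)
        w = np.ones_like(ds.values) if ds.weights is None else ds.weights
        parts.append(np.sqrt(w) * (model - ds.values))
    for variant, observable, t, target in spec.anchors:
        traj = _simulate_for(
            params,
            FitDataset(variant, variant, observable, np.array([t]),
                       np.array([target])),
            cache,
        )
        series = _observable_series(traj, observable)
        model = float(np.interp(t, traj.times, series))
        parts.append(np.array([np.sqrt(spec.anchor_weight) * (model - target)]))
    return np.concatenate(parts) if parts else np.zeros(0)


def objective_loss(candidate: ModelParameters | dict[str, float],
                   spec: ObjectiveSpec) -> float:
    """Weighted sum of squared residuals plus anchor penalties.

    Simulation failures return a large finite penalty so the optimizer
    can continue.
    """
    try:
        r = objective_residuals(candidate, spec)
    except Exception:
        return PENALTY
    return float(np.sum(r * r))


@dataclass
class FitResult:
    """Outcome of one seeded differential-evolution fit."""

    best_parameters: dict[str, float]
    loss: float
    seed: int
    stage: str
    bounds: dict[str, tuple[float, float]]
    trace: list[float]
    params: ModelParameters

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "seed": self.seed,
            "loss": self.loss,
            "best_parameters": self.best_parameters,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "trace": self.trace,
        }


def fit_differential_evolution(
    spec: ObjectiveSpec,
    stage: str,
    seed: int = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
    popsize: int = 15,
    maxiter: int = 500,
    tol: float = 0.01,
    mutation: tuple[float, float] = (0.5, 1.0),
    recombination: float = 0.7,
    polish: bool = True,
    polish_starts: int = 3,
) -> FitResult:
    """Seeded, reproducible DE fit of a stage's free parameters.

    Free parameters are searched in log10 space; ``bounds`` (linear
    scale) default to [1e-6, 1e2] per rate.  The stage determines the
    free set and attaches the stage's soft anchors to the objective.
    """
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; expected {sorted(STAGES)}")
    free = STAGES[stage]
    if not free:
        raise ConfigurationError("empty free-parameter set")
    for name in free:
        if name not in RATE_NAMES:
            raise ConfigurationError(f"free parameter {name} is not a model rate")
    bounds = bounds or {}
    box = [bounds.get(name, DEFAULT_BOUNDS) for name in free]
    log_box = [(np.log10(lo), np.log10(hi)) for lo, hi in box]
    spec = ObjectiveSpec(
        spec.datasets,
        spec.base_params,
        spec.anchors or STAGE_ANCHORS[stage],
        spec.anchor_weight,
    )

    def f(logtheta: np.ndarray) -> float:
        cand = {n: 10.0 ** v for n, v in zip(free, logtheta)}
        return objective_loss(cand, spec)

    trace: list[float] = []
    result = differential_evolution(
        f,
        log_box,
        seed=seed,
        popsize=popsize,
        maxiter=maxiter,
        tol=tol,
        mutation=mutation,
        recombination=recombination,
        polish=False,
        init="sobol",
        callback=lambda xk, convergence=0.0: trace.append(f(xk)),
    )
    x, fx = result.x, result.fun

    def residuals(logtheta: np.ndarray) -> np.ndarray:
        cand = {n: 10.0 ** v for n, v in zip(free, logtheta)}
        try:
            return objective_residuals(cand, spec)
        except Exception:
            return np.full(max(len(spec.datasets), 1), np.sqrt(PENALTY))

    if polish:
        # Normalized signals create compensation valleys whose shallow
        # local minima can trap the whole DE population.  The refinement
        # therefore runs Gauss-Newton from the DE winner AND from a few
        # seeded low-discrepancy points spread over the box, keeping the
        # best result.
        from scipy.stats import qmc

        lo = np.array([b[0] for b in log_box])
        hi = np.array([b[1] for b in log_box])
        starts = [np.clip(x, lo, hi)]
        if polish_starts > 1:
            sob = qmc.Sobol(len(free), seed=seed)
            n_extra = polish_starts - 1
            draw = sob.random(2 ** int(np.ceil(np.log2(n_extra))))[:n_extra]
            starts += list(draw * (hi - lo) + lo)
        for start in starts:
            local = least_squares(residuals, start, bounds=(lo, hi),
                                  xtol=1e-10, ftol=1e-12, gtol=1e-10,
                                  diff_step=1e-3, max_nfev=30)
            if 2 * local.cost < fx:
                x, fx = local.x, 2 * local.cost
    best = {n: float(10.0 ** v) for n, v in zip(free, x)}
    return FitResult(
        best_parameters=best,
        loss=float(fx),
        seed=seed,
        stage=stage,
        bounds={n: b for n, b in zip(free, box)},
        trace=trace,
        params=spec.base_params.updated(**best),
    )
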