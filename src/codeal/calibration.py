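"""Parameter fitting against observed pools and fluxes.

The objective blends percent bias and Nash–Sutcliffe efficiency per
observable; the optimizer is a bounded, seeded differential-evolution
search (a population evolving by recombination under a fixed evaluation
budget). Observed NO3 and NO2 are compared only as their sum, matching
how the combined pool is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .kinetics import Forcing, KineticParams
from .metrics import nse, percent_bias
from .simulator import SimulationConfig, run_simulation

__all__ = ["CalibrationSpec", "CalibrationResult", "objective", "calibrate"]


@dataclass
class CalibrationSpec:
    """Free parameters, their bounds and the search budget.

    ``free`` maps parameter names (``"Vmax[0]"``, ``"pEP"`` ...) to finite
    ``(low, high)`` bounds in the parameter's own units. ``budget`` is the
    total number of objective evaluations; ``popsize`` the population per
    generation. ``weights`` (optional) reweights observables in the
    objective; default equal weights.
    """

    free: dict[str, tuple[float, float]]
    budget: int = 200
    popsize: int = 10
    seed: int = 0
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("no free parameters")
        for name, (lo, hi) in self.free.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        if self.weights is not None:
            w = np.array(list(self.weights.values()), dtype=float)
            if np.any(w < 0) or w.sum() == 0:
                raise ValueError("weights must be nonnegative and not all zero")
        if self.budget < self.popsize:
            raise ValueError("budget must cover at least one population")


def _observed_means(obs: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Replicate-mean observation series per observable, sorted by time."""
    out = {}
    for name, sub in obs.groupby("observable"):
        mean = sub.groupby("time")["value"].mean().reset_index()
        out[str(name)] = mean.sort_values("time")
    return out


def objective(params: KineticParams, config: SimulationConfig, forcing: Forcing,
              obs: pd.DataFrame, weights: dict[str, float] | None = None) -> float:
    """Composite misfit over all observables present in ``obs``.

    Per observable k the score is
    ``0.5 * min(|PBIAS_k|/100, 1) + 0.5 * (1 - max(NSE_k, -1)) / 2``,
    zero for a perfect fit and one at the construction maximum
    (|PBIAS| >= 100% and NSE <= -1); the objective is the weighted sum.
    Simulated values are linearly interpolated to the observation times;
    observations are reduced to replicate means first.
    """
    traj = run_simulation(config, params, forcing)
    series = _observed_means(obs)
    if not series:
        raise ValueError("empty observation set")
    total = 0.0
    for name, sub in series.items():
        sim = np.interp(sub["time"].to_numpy(), traj.times, traj.observable(name))
        o = sub["value"].to_numpy()
        pb = abs(percent_bias(sim, o))
        ns = nse(sim, o) if o.size >= 2 and np.ptp(o) > 0 else (1.0 if np.allclose(sim, o) else -1.0)
        score = 0.5 * min(pb / 100.0, 1.0) + 0.5 * (1.0 - max(ns, -1.0)) / 2.0
        w = 1.0 if weights is None else weights.get(name, 0.0)
        total += w * score
    return float(total)


@dataclass
class CalibrationResult:
    params: KineticParams
    values: dict[str, float]
    objective: float
    trace: list[float]
    n_evaluations: int

    def to_dict(self) -> dict:
        return {
            "values": self.values,
            "objective": self.objective,
            "trace": self.trace,
            "n_evaluations": self.n_evaluations,
        }


def calibrate(spec: CalibrationSpec, base: KineticParams,
              config: SimulationConfig, forcing: Forcing,
              obs: pd.DataFrame) -> CalibrationResult:
    """Fit the free parameters by seeded differential evolution.

    The population (``spec.popsize`` members per free parameter generation)
    evolves by recombination within the bounds; the run is deterministic
    given ``spec.seed`` and capped at roughly ``spec.budget`` objective
    evaluations. Returns the best parameters, their objective and the
    best-so-far trace (one entry per generation, nonincreasing).

    Zero-width bounds pin a parameter at its single admissible value.
    """
    names = list(spec.free)
    fixed = {k: v[0] for k, v in spec.free.items() if v[0] == v[1]}
    search = {k: v for k, v in spec.free.items() if v[0] < v[1]}
    base = base.with_values(fixed) if fixed else base

    if not search:
        j = objective(base, config, forcing, obs, spec.weights)
        return CalibrationResult(params=base, values={k: base.get(k) for k in names},
                                 objective=j, trace=[j], n_evaluations=1)

    search_names = list(search)
    bounds = [search[k] for k in search_names]
    trace: list[float] = []
    n_eval = 0

    def fun(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        p = base.with_values(dict(zip(search_names, x)))
        return objective(p, config, forcing, obs, spec.weights)

    # budget = popsize * len(bounds) * (maxiter + 1) evaluations (no polish)
    maxiter = max(1, spec.budget // (spec.popsize * len(bounds)) - 1)

    def cb(xk, convergence=None):
        p = base.with_values(dict(zip(search_names, xk)))
        trace.append(objective(p, config, forcing, obs, spec.weights))

    result = differential_evolution(
        fun, bounds, seed=spec.seed, popsize=spec.popsize, maxiter=maxiter,
        polish=False, tol=0.0, init="latinhypercube", updating="immediate",
        callback=cb,
    )
    best = base.with_values(dict(zip(search_names, result.x)))
    trace = [min(trace[: i + 1]) for i in range(len(trace))] or [float(result.fun)]
    return CalibrationResult(
        params=best,
        values={k: best.get(k) for k in names},
        objective=float(result.fun),
        trace=trace,
        n_evaluations=n_eval,
    )
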