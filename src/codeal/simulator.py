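"""Time integration of the enzyme-allocation nitrogen-cycle ODE system."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .allocation import DEFAULT_FLOOR, ENZYMES, SUBSTRATES, _allocation_weights
from .kinetics import (
    FLUX_NAMES,
    STATE_SIZE,
    Forcing,
    KineticParams,
    ModelState,
    compute_fluxes,
    rhs,
)

__all__ = ["SimulationConfig", "Trajectory", "SolverError", "run_simulation"]


class SolverError(RuntimeError):
    """Raised when the integrator fails (step underflow, NaN state)."""


@dataclass
class SimulationConfig:
    """Integration settings for one simulation.

    ``t0``/``t1`` bound the horizon (days); ``dt_out`` is the output
    sampling step, decoupled from the internal solver steps. ``solver``
    is ``"adaptive"`` (LSODA, dense output) or ``"rk4"`` (fixed step
    ``fixed_step`` with per-step flux limiting so no pool is driven below
    zero). ``scheme`` selects the allocation scenario.
    """

    t0: float
    t1: float
    dt_out: float
    scheme: str
    initial: ModelState
    solver: Literal["adaptive", "rk4"] = "adaptive"
    rtol: float = 1e-8
    atol: float = 1e-10
    fixed_step: float = 0.05
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        if not self.t1 > self.t0:
            raise ValueError("t1 must exceed t0")
        if self.dt_out <= 0 or self.fixed_step <= 0:
            raise ValueError("output and fixed steps must be positive")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")

    def output_grid(self) -> np.ndarray:
        n = int(round((self.t1 - self.t0) / self.dt_out))
        grid = self.t0 + self.dt_out * np.arange(n + 1)
        if grid[-1] < self.t1 - 1e-9:
            grid = np.append(grid, self.t1)
        grid[-1] = min(grid[-1], self.t1)
        return grid


@dataclass
class Trajectory:
    """Sampled result of one simulation.

    ``states`` has one row per output time and 15 columns (six N pools,
    six enzyme pools, organic N, cumIn, cumOut); ``allocation`` and
    ``fluxes`` are evaluated at the same times. ``metadata`` records the
    scheme, a parameter digest and solver statistics.
    """

    times: np.ndarray
    states: np.ndarray
    allocation: np.ndarray
    fluxes: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.times.size
        if self.states.shape != (n, STATE_SIZE):
            raise ValueError("states shape inconsistent with times")
        if self.allocation.shape != (n, 6) or self.fluxes.shape != (n, len(FLUX_NAMES)):
            raise ValueError("allocation/flux matrices inconsistent with times")

    # -- column accessors ---------------------------------------------------

    @property
    def N(self) -> np.ndarray:
        return self.states[:, 0:6]

    @property
    def E(self) -> np.ndarray:
        return self.states[:, 6:12]

    @property
    def ON(self) -> np.ndarray:
        return self.states[:, 12]

    @property
    def cumIn(self) -> np.ndarray:
        return self.states[:, 13]

    @property
    def cumOut(self) -> np.ndarray:
        return self.states[:, 14]

    def total_N(self) -> np.ndarray:
        """Tracked N (six inorganic pools + organic N) at each output time."""
        return self.N.sum(axis=1) + self.ON

    def flux(self, name: str) -> np.ndarray:
        return self.fluxes[:, FLUX_NAMES.index(name)]

    def observable(self, name: str) -> np.ndarray:
        """Series of one named observable (pools and fluxes used for fitting)."""
        if name == "NH4":
            return self.N[:, 0]
        if name == "NO3_NO2":
            return self.N[:, 1] + self.N[:, 2]
        if name == "BNF":
            return self.flux("F_fix")
        if name == "net_N_min":
            return self.flux("F_min")
        if name == "nitrification":
            return self.flux("F_nit")
        if name == "plant_uptake":
            return self.flux("U_NH4") + self.flux("U_NO3")
        raise KeyError(f"unknown observable {name!r}")

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times}
        for i, s in enumerate(SUBSTRATES):
            cols[s] = self.N[:, i]
        cols["ON"] = self.ON
        for i, e in enumerate(ENZYMES):
            cols[f"E_{e}"] = self.E[:, i]
        for i, e in enumerate(ENZYMES):
            cols[f"f_{e}"] = self.allocation[:, i]
        for i, name in enumerate(FLUX_NAMES):
            cols[name] = self.fluxes[:, i]
        cols["cumIn"] = self.cumIn
        cols["cumOut"] = self.cumOut
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _fast_rhs_factory(params: KineticParams, forcing: Forcing, scheme: str,
                      floor: float):
    """Closure evaluating the same derivatives as :func:`codeal.kinetics.rhs`
    with attribute lookups and flux-object construction hoisted out."""
    Vmax = params.Vmax
    Ks = params.Ks
    pEP, rE, kmin = params.pEP, params.rE, params.kmin
    Vup1, Vup2 = params.Vup_NH4, params.Vup_NO3
    Kup1, Kup2 = params.Kup_NH4, params.Kup_NO3
    gNO, gN2O = params.gNO, params.gN2O
    boundary = params.n2_boundary != "dynamic"
    inhib = params.bnf_inhibition
    ft, fB, f1, f2, fL, fp = (forcing.time, forcing.B, forcing.I_NH4,
                              forcing.I_NO3, forcing.L, forcing.fplant)
    weights = _allocation_weights

    def f(t, y):
        N = np.maximum(y[0:6], 0.0)
        E = np.maximum(y[6:12], 0.0)
        ON = y[12] if y[12] > 0.0 else 0.0
        B = np.interp(t, ft, fB)
        I_NH4 = np.interp(t, ft, f1)
        I_NO3 = np.interp(t, ft, f2)
        L = np.interp(t, ft, fL)
        fpl = np.interp(t, ft, fp)
        sat = N / (N + Ks)
        F = Vmax * E * sat
        F_fix = F[5] * (1.0 - sat[0]) if inhib else F[5]
        F_min = kmin * ON
        U1 = Vup1 * fpl * N[0] / (Kup1 + N[0])
        U2 = Vup2 * fpl * N[1] / (Kup2 + N[1])
        G_NO = gNO * N[3]
        G_N2O = gN2O * N[4]
        falloc = weights(scheme, N, Ks, floor)
        dy = np.empty(STATE_SIZE)
        dy[0] = F_min + F_fix - F[0] - U1 + I_NH4
        dy[1] = F[0] - F[1] - U2 + I_NO3
        dy[2] = F[1] - F[2]
        dy[3] = F[2] - F[3] - G_NO
        dy[4] = F[3] - F[4] - G_N2O
        dy[5] = 0.0 if boundary else F[4] - F_fix
        dy[6:12] = falloc * (pEP * B) - rE * E
        dy[12] = L - F_min
        dy[13] = I_NH4 + I_NO3 + L + (F_fix if boundary else 0.0)
        dy[14] = U1 + U2 + G_NO + G_N2O + (F[4] if boundary else 0.0)
        return dy

    return f


def run_simulation(config: SimulationConfig, params: KineticParams,
                   forcing: Forcing) -> Trajectory:
    """Integrate the system over ``[t0, t1]`` and sample it on the output grid.

    The adaptive path uses LSODA with the configured tolerances and dense
    output; the fixed-step path uses classical RK4 with per-step flux
    limiting. Results are bit-reproducible for identical inputs. Raises
    :class:`SolverError` on integrator failure.
    """
    span = forcing.span
    if config.t0 < span[0] - 1e-9 or config.t1 > span[1] + 1e-9:
        raise ValueError(
            f"simulation horizon [{config.t0}, {config.t1}] not covered by "
            f"forcing span {span}")

    y0 = config.initial.as_array().copy()
    if params.n2_boundary != "dynamic":
        y0[5] = float(params.n2_boundary)

    grid = config.output_grid()
    stats: dict = {"solver": config.solver}

    if config.solver == "adaptive":
        fun = _fast_rhs_factory(params, forcing, config.scheme, config.floor)
        sol = solve_ivp(fun, (config.t0, config.t1), y0, method="LSODA",
                        t_eval=grid, rtol=config.rtol, atol=config.atol)
        if not sol.success:
            raise SolverError(f"LSODA failed at t={sol.t[-1] if sol.t.size else config.t0}: "
                              f"{sol.message}")
        times = sol.t
        states = sol.y.T.copy()
        stats.update(nfev=int(sol.nfev), n_steps=int(sol.t.size))
    elif config.solver == "rk4":
        times, states = _rk4(config, params, forcing, y0, grid)
        stats.update(fixed_step=config.fixed_step)
    else:
        raise ValueError(f"unknown solver {config.solver!r}")

    if not np.all(np.isfinite(states)):
        raise SolverError("non-finite values in integrated states")
    # tolerance-level negative excursions are zeroed for output
    pools = states[:, 0:13]
    if pools.min() < -1e3 * config.atol - 1e-12:
        raise SolverError(f"state went significantly negative (min {pools.min():.3e})")
    np.clip(pools, 0.0, None, out=pools)

    alloc = np.empty((times.size, 6))
    fluxmat = np.empty((times.size, len(FLUX_NAMES)))
    for k, t in enumerate(times):
        N, E, ON = states[k, 0:6], states[k, 6:12], states[k, 12]
        _, _, _, _, fpl = forcing.at(t)
        alloc[k] = _allocation_weights(config.scheme, N, params.Ks, config.floor)
        fluxmat[k] = compute_fluxes(N, E, ON, fpl, params).as_array()

    meta = {"scheme": config.scheme, "params_digest": params.digest(), **stats}
    return Trajectory(times=times, states=states, allocation=alloc,
                      fluxes=fluxmat, metadata=meta)


def _rk4(config: SimulationConfig, params: KineticParams, forcing: Forcing,
         y0: np.ndarray, grid: np.ndarray):
    """Classical RK4 with flux limiting, sampled exactly on the output grid."""
    h = config.fixed_step
    y = y0.copy()
    t = config.t0
    out = np.empty((grid.size, STATE_SIZE))
    out[0] = y
    gi = 1
    f = lambda tt, yy, hh: rhs(tt, yy, params, forcing, config.scheme,
                               config.floor, limit_step=hh)
    while gi < grid.size:
        t_next = grid[gi]
        while t < t_next - 1e-12:
            step = min(h, t_next - t)
            k1 = f(t, y, step)
            k2 = f(t + step / 2, y + step * k1 / 2, step)
            k3 = f(t + step / 2, y + step * k2 / 2, step)
            k4 = f(t + step, y + step * k3, step)
            y = y + (step / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += step
        out[gi] = y
        gi += 1
    return grid.copy(), out
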