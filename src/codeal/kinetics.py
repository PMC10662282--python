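"""Michaelis–Menten kinetics of the reduced inorganic-nitrogen enzyme network.

The model tracks six inorganic N pools ``[NH4, NO3, NO2, NO, N2O, N2]``
(mg N kg^-1 soil), six enzyme pools in carbon units (mg enzyme-C kg^-1,
aligned to the substrate each group consumes), one organic-N pool, and two
cumulative boundary-exchange accumulators. Time is in days.

Network topology (a deliberately reduced form of the host microbial-enzyme
decomposition model's N subsystem):

* nitrification is lumped as a single NH4 -> NO3 step catalyzed by ammonia
  oxidases; NO2 arises only inside the denitrification chain
  NO3 -> NO2 -> NO -> N2O -> N2;
* biological N fixation (N2 -> NH4, nitrogenase) is inhibited by the
  ammonium saturation level via the factor ``1 - NH4/(NH4 + Ks_NH4)``;
* mineralization ON -> NH4 is first order in organic N; plant uptake of
  NH4 and NO3 is Michaelis–Menten scaled by a plant-activity factor;
* NO and N2O may escape as gases at first-order rates;
* dinitrogen is either a fixed boundary pool (default — soil N2 is a
  practically unlimited reservoir) or a dynamic pool closing the cycle
  (used for conservation audits).

Enzyme pools carry carbon, not nitrogen, and do not enter the N balance.
Each group's synthesis is its allocation coefficient times a common
biomass-proportional production flux, so the *total* gross enzyme
production is identical across allocation scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Union

import hashlib
import json
import re

import numpy as np

from .allocation import (
    DEFAULT_FLOOR,
    ENZYMES,
    N_GROUPS,
    SUBSTRATES,
    _allocation_weights,
    as_half_saturation_vector,
    as_substrate_vector,
)

__all__ = [
    "KineticParams",
    "ModelState",
    "Forcing",
    "FluxVector",
    "FLUX_NAMES",
    "transformation_flux",
    "bnf_inhibition_factor",
    "enzyme_derivatives",
    "compute_fluxes",
    "rhs",
    "STATE_SIZE",
]

# State vector layout: 6 N pools, 6 enzyme pools, ON, cumIn, cumOut.
STATE_SIZE = 15
_I_N = slice(0, 6)
_I_E = slice(6, 12)
_I_ON = 12
_I_CUMIN = 13
_I_CUMOUT = 14

#: Flux vector column order used in trajectories and CSV output.
FLUX_NAMES: tuple[str, ...] = (
    "F_nit", "F_nar", "F_nir", "F_nor", "F_nos", "F_fix",
    "F_min", "U_NH4", "U_NO3", "G_NO", "G_N2O",
)


@dataclass(frozen=True)
class KineticParams:
    """Kinetic and physiological parameters of the N-enzyme network.

    Attributes
    ----------
    Vmax
        Specific maximal rates of the six enzymatic transformations
        (mg N (mg enzyme-C)^-1 d^-1), enzyme order ``[amo,nar,nir,nor,nos,fix]``.
    Ks
        Half-saturation constants of the six substrates (mg N kg^-1),
        substrate order.
    pEP
        Biomass-specific enzyme production rate (d^-1): gross enzyme
        synthesis is ``pEP * B(t)`` mg C kg^-1 d^-1, split among groups
        by the allocation coefficients.
    rE
        First-order enzyme turnover rate (d^-1).
    kmin
        First-order mineralization rate of organic N (d^-1).
    Vup_NH4, Vup_NO3
        Maximal plant-uptake rates (mg N kg^-1 d^-1).
    Kup_NH4, Kup_NO3
        Uptake half-saturation constants (mg N kg^-1).
    gNO, gN2O
        First-order gas-efflux rates for NO and N2O (d^-1).
    n2_boundary
        Either a fixed dinitrogen concentration (mg N kg^-1; the N2 pool is
        held there and fixation/denitrification exchange with the boundary)
        or the string ``"dynamic"`` for a closed, mass-conserving N2 pool.
    bnf_inhibition
        Whether ammonium saturation inhibits the fixation flux.
    """

    Vmax: np.ndarray
    Ks: np.ndarray
    pEP: float
    rE: float
    kmin: float
    Vup_NH4: float
    Vup_NO3: float
    Kup_NH4: float
    Kup_NO3: float
    gNO: float = 0.0
    gN2O: float = 0.0
    n2_boundary: Union[float, Literal["dynamic"]] = "dynamic"
    bnf_inhibition: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "Vmax", np.asarray(self.Vmax, dtype=float))
        object.__setattr__(self, "Ks", as_half_saturation_vector(self.Ks))
        if self.Vmax.shape != (N_GROUPS,) or np.any(self.Vmax <= 0):
            raise ValueError("Vmax must be six strictly positive rates")
        for name in ("pEP", "rE", "kmin", "Vup_NH4", "Vup_NO3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("Kup_NH4", "Kup_NO3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gNO < 0 or self.gN2O < 0:
            raise ValueError("gas-efflux rates must be nonnegative")
        if self.n2_boundary != "dynamic" and float(self.n2_boundary) < 0:
            raise ValueError("boundary N2 concentration must be nonnegative")

    # -- name-based access (used by ensembles and calibration) --------------

    _VEC_RE = re.compile(r"^(Vmax|Ks)\[(\d)\]$")

    def get(self, name: str) -> float:
        """Return one scalar parameter; vector entries as ``"Vmax[3]"``."""
        m = self._VEC_RE.match(name)
        if m:
            return float(getattr(self, m.group(1))[int(m.group(2))])
        return float(getattr(self, name))

    def with_values(self, updates: dict[str, float]) -> "KineticParams":
        """Return a copy with the named scalar entries replaced."""
        fields: dict[str, object] = {}
        vmax = self.Vmax.copy()
        ks = self.Ks.copy()
        for name, value in updates.items():
            m = self._VEC_RE.match(name)
            if m:
                target = vmax if m.group(1) == "Vmax" else ks
                target[int(m.group(2))] = value
            else:
                fields[name] = value
        return replace(self, Vmax=vmax, Ks=ks, **fields)

    def to_dict(self) -> dict:
        d = {
            "Vmax": self.Vmax.tolist(),
            "Ks": self.Ks.tolist(),
            "pEP": self.pEP, "rE": self.rE, "kmin": self.kmin,
            "Vup_NH4": self.Vup_NH4, "Vup_NO3": self.Vup_NO3,
            "Kup_NH4": self.Kup_NH4, "Kup_NO3": self.Kup_NO3,
            "gNO": self.gNO, "gN2O": self.gN2O,
            "n2_boundary": self.n2_boundary,
            "bnf_inhibition": self.bnf_inhibition,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(**d)

    def digest(self) -> str:
        """Stable short hash of the parameter set, for trajectory metadata."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ModelState:
    """Instantaneous model state.

    ``N`` — six inorganic N pools (mg N kg^-1), substrate order;
    ``E`` — six enzyme pools (mg enzyme-C kg^-1), enzyme order;
    ``ON`` — organic N (mg N kg^-1); ``cumIn``/``cumOut`` — cumulative
    boundary imports/exports of N (mg N kg^-1) since the simulation start.
    """

    N: np.ndarray
    E: np.ndarray
    ON: float
    cumIn: float = 0.0
    cumOut: float = 0.0

    def __post_init__(self) -> None:
        self.N = as_substrate_vector(self.N)
        self.E = np.asarray(self.E, dtype=float)
        if self.E.shape != (N_GROUPS,) or np.any(self.E < 0):
            raise ValueError("enzyme pools must be six nonnegative values")
        if self.ON < 0:
            raise ValueError("organic N pool must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.N, self.E, [self.ON, self.cumIn, self.cumOut]])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        return cls(N=y[_I_N].copy(), E=y[_I_E].copy(), ON=float(y[_I_ON]),
                   cumIn=float(y[_I_CUMIN]), cumOut=float(y[_I_CUMOUT]))

    def total_N(self) -> float:
        """Tracked nitrogen: the six inorganic pools plus organic N.

        Enzyme pools are carbon and excluded by construction.
        """
        return float(self.N.sum() + self.ON)


@dataclass
class Forcing:
    """Environmental drivers on a common time grid (days).

    ``B`` — microbial biomass C (mg C kg^-1); ``I_NH4``/``I_NO3`` — mineral N
    input rates (mg N kg^-1 d^-1); ``L`` — litter organic-N input
    (mg N kg^-1 d^-1); ``fplant`` — plant-activity factor in [0, 1] scaling
    uptake. Values between grid points are linearly interpolated.
    """

    time: np.ndarray
    B: np.ndarray
    I_NH4: np.ndarray
    I_NO3: np.ndarray
    L: np.ndarray
    fplant: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        if n < 2 or np.any(np.diff(self.time) <= 0):
            raise ValueError("forcing time grid must be strictly increasing with >= 2 points")
        for name in ("B", "I_NH4", "I_NO3", "L", "fplant"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"forcing series {name} must match the time grid length")
            setattr(self, name, arr)
        if np.any(self.B < 0):
            raise ValueError("biomass must be nonnegative")
        if np.any((self.fplant < 0) | (self.fplant > 1)):
            raise ValueError("fplant must lie in [0, 1]")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])

    def at(self, t: float) -> tuple[float, float, float, float, float]:
        """Interpolated ``(B, I_NH4, I_NO3, L, fplant)`` at time ``t``."""
        t0, t1 = self.span
        if t < t0 - 1e-9 or t > t1 + 1e-9:
            raise ValueError(f"time {t} outside forcing span [{t0}, {t1}]")
        return (
            float(np.interp(t, self.time, self.B)),
            float(np.interp(t, self.time, self.I_NH4)),
            float(np.interp(t, self.time, self.I_NO3)),
            float(np.interp(t, self.time, self.L)),
            float(np.interp(t, self.time, self.fplant)),
        )


@dataclass(frozen=True)
class FluxVector:
    """Instantaneous fluxes (mg N kg^-1 d^-1), all nonnegative.

    ``F_nit`` nitrification NH4->NO3; ``F_nar`` NO3->NO2; ``F_nir``
    NO2->NO; ``F_nor`` NO->N2O; ``F_nos`` N2O->N2; ``F_fix`` fixation
    N2->NH4 (after inhibition); ``F_min`` mineralization ON->NH4;
    ``U_NH4``/``U_NO3`` plant uptake; ``G_NO``/``G_N2O`` gas losses.
    """

    F_nit: float
    F_nar: float
    F_nir: float
    F_nor: float
    F_nos: float
    F_fix: float
    F_min: float
    U_NH4: float
    U_NO3: float
    G_NO: float
    G_N2O: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FLUX_NAMES])

    @property
    def enzymatic_total(self) -> float:
        """Sum of the six enzyme-catalyzed transformation fluxes."""
        return self.F_nit + self.F_nar + self.F_nir + self.F_nor + self.F_nos + self.F_fix


def transformation_flux(E_i, Vmax_i, N_i, Ks_i):
    """Michaelis–Menten flux ``Vmax * E * N / (Ks + N)`` of one enzyme group.

    Zero when either the enzyme pool or the substrate is zero, bounded by
    ``Vmax * E``. Scalar or array arguments are accepted.
    """
    E_i = np.asarray(E_i, dtype=float)
    N_i = np.asarray(N_i, dtype=float)
    if np.any(E_i < 0) or np.any(N_i < 0):
        raise ValueError("enzyme pool and substrate must be nonnegative")
    Vmax_i = np.asarray(Vmax_i, dtype=float)
    Ks_i = np.asarray(Ks_i, dtype=float)
    if np.any(Vmax_i <= 0) or np.any(Ks_i <= 0):
        raise ValueError("Vmax and Ks must be positive")
    out = Vmax_i * E_i * N_i / (Ks_i + N_i)
    return float(out) if out.ndim == 0 else out


def bnf_inhibition_factor(NH4: float, Ks_NH4: float) -> float:
    """Ammonium inhibition of fixation: ``1 - NH4/(NH4 + Ks_NH4)``.

    Equals 1 with no ammonium and decreases strictly toward 0 as ammonium
    accumulates; multiplies the fixation flux only.
    """
    if NH4 < 0:
        raise ValueError("NH4 must be nonnegative")
    if Ks_NH4 <= 0:
        raise ValueError("Ks_NH4 must be positive")
    return 1.0 - NH4 / (NH4 + Ks_NH4)


def enzyme_derivatives(E, f, B: float, pEP: float, rE: float) -> np.ndarray:
    """Enzyme-pool tendencies ``dE_i/dt = f_i * pEP * B - rE * E_i``.

    The allocation fractions ``f`` sum to one, so gross production summed
    over groups is ``pEP * B`` whatever the scenario: allocation moves
    synthesis between groups without changing its total carbon cost.
    """
    E = np.asarray(E, dtype=float)
    f = getattr(f, "values", f)
    f = np.asarray(f, dtype=float)
    if E.shape != (N_GROUPS,) or f.shape != (N_GROUPS,):
        raise ValueError("E and f must have shape (6,)")
    if B < 0 or pEP < 0 or rE < 0:
        raise ValueError("B, pEP, rE must be nonnegative")
    return f * pEP * B - rE * E


def compute_fluxes(N: np.ndarray, E: np.ndarray, ON: float, fplant: float,
                   params: KineticParams) -> FluxVector:
    """Assemble the full flux vector at one state.

    ``N`` and ``E`` follow the fixed substrate/enzyme ordering; negative
    entries are treated as zero (they can only arise transiently inside an
    adaptive integrator step).
    """
    N = np.maximum(np.asarray(N, dtype=float), 0.0)
    E = np.maximum(np.asarray(E, dtype=float), 0.0)
    ON = max(float(ON), 0.0)
    sat = N / (N + params.Ks)
    F = params.Vmax * E * sat  # enzyme i consumes substrate i
    F_fix = F[5]
    if params.bnf_inhibition:
        F_fix *= 1.0 - sat[0]
    U_NH4 = params.Vup_NH4 * fplant * N[0] / (params.Kup_NH4 + N[0])
    U_NO3 = params.Vup_NO3 * fplant * N[1] / (params.Kup_NO3 + N[1])
    return FluxVector(
        F_nit=float(F[0]), F_nar=float(F[1]), F_nir=float(F[2]),
        F_nor=float(F[3]), F_nos=float(F[4]), F_fix=float(F_fix),
        F_min=params.kmin * ON, U_NH4=float(U_NH4), U_NO3=float(U_NO3),
        G_NO=params.gNO * N[3], G_N2O=params.gN2O * N[4],
    )


def rhs(t: float, y: np.ndarray, params: KineticParams, forcing: Forcing,
        scheme: str, floor: float = DEFAULT_FLOOR,
        limit_step: float | None = None) -> np.ndarray:
    """Time derivative of the packed state vector.

    Pool balances::

        dNH4 = F_min + F_fix - F_nit - U_NH4 + I_NH4
        dNO3 = F_nit - F_nar - U_NO3 + I_NO3
        dNO2 = F_nar - F_nir
        dNO  = F_nir - F_nor - G_NO
        dN2O = F_nor - F_nos - G_N2O
        dN2  = 0 (boundary mode)   or   F_nos - F_fix (dynamic mode)
        dON  = L - F_min
        dE_i = f_i * pEP * B - rE * E_i

    The accumulators integrate boundary exchange: imports are the mineral
    and litter inputs (plus fixation drawn from the N2 boundary in boundary
    mode); exports are plant uptake and gas losses (plus N2 production sent
    to the boundary in boundary mode), so that
    ``total_N(t) - total_N(t0) == cumIn - cumOut`` for the exact solution.

    ``limit_step``, if given, is an explicit step length h: each pool's
    consuming fluxes are jointly scaled so the pool cannot be driven below
    zero within that step (used by the fixed-step integrator; scaling
    fluxes, unlike clipping states, preserves the conservation audit).
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (STATE_SIZE,):
        raise ValueError(f"state vector must have shape ({STATE_SIZE},)")
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite state at t={t}")
    N = np.maximum(y[_I_N], 0.0)
    E = np.maximum(y[_I_E], 0.0)
    ON = max(float(y[_I_ON]), 0.0)

    B, I_NH4, I_NO3, L, fp = forcing.at(t)
    f = _allocation_weights(scheme, N, params.Ks, floor)
    flux = compute_fluxes(N, E, ON, fp, params)

    boundary = params.n2_boundary != "dynamic"
    F_nit, F_nar, F_nir, F_nor, F_nos, F_fix = (
        flux.F_nit, flux.F_nar, flux.F_nir, flux.F_nor, flux.F_nos, flux.F_fix)
    F_min, U_NH4, U_NO3, G_NO, G_N2O = (
        flux.F_min, flux.U_NH4, flux.U_NO3, flux.G_NO, flux.G_N2O)

    if limit_step is not None and limit_step > 0:
        h = limit_step
        # production available to each pool within the step
        prod = np.array([F_min + F_fix + I_NH4, F_nit + I_NO3, F_nar, F_nir, F_nor,
                         0.0 if boundary else F_nos])
        cons = np.array([F_nit + U_NH4, F_nar + U_NO3, F_nir, F_nor + G_NO,
                         F_nos + G_N2O, 0.0 if boundary else F_fix])
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(cons * h > 0, np.minimum(1.0, (N + prod * h) / (cons * h)), 1.0)
        s = np.clip(s, 0.0, 1.0)
        F_nit *= s[0]; U_NH4 *= s[0]
        F_nar *= s[1]; U_NO3 *= s[1]
        F_nir *= s[2]
        F_nor *= s[3]; G_NO *= s[3]
        F_nos *= s[4]; G_N2O *= s[4]
        if not boundary:
            F_fix *= s[5]
        s_on = 1.0 if F_min * h <= ON + L * h or F_min == 0 else (ON + L * h) / (F_min * h)
        F_min *= min(1.0, s_on)

    dy = np.empty(STATE_SIZE)
    dy[0] = F_min + F_fix - F_nit - U_NH4 + I_NH4
    dy[1] = F_nit - F_nar - U_NO3 + I_NO3
    dy[2] = F_nar - F_nir
    dy[3] = F_nir - F_nor - G_NO
    dy[4] = F_nor - F_nos - G_N2O
    dy[5] = 0.0 if boundary else F_nos - F_fix
    dy[_I_E] = f * params.pEP * B - params.rE * E
    dy[_I_ON] = L - F_min
    dy[_I_CUMIN] = I_NH4 + I_NO3 + L + (F_fix if boundary else 0.0)
    dy[_I_CUMOUT] = U_NH4 + U_NO3 + G_NO + G_N2O + (F_nos if boundary else 0.0)
    return dy
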