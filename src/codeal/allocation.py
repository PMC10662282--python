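"""Competitive dynamic allocation of enzyme synthesis among N-cycle enzyme groups.

Six enzyme functional groups — ammonia oxidases, nitrate reductases, nitrite
reductases, nitric oxide reductases, nitrous oxide reductases, and
nitrogenases — compete for a shared synthesis budget. Each group is paired
one-to-one with the inorganic nitrogen substrate it consumes, and its share
of synthesis (the *allocation coefficient*) is recomputed at every instant
from the current substrate concentrations: allocation is therefore both
*dynamic* (time-variant) and *competitive* (the coefficients of all groups
are coupled through a common normalization).

Three allocation scenarios are provided:

``A0``
    weight each group by the raw concentration of its substrate, ``N_i``;
``A1``
    weight by the relative substrate availability ``N_i / Ks_i`` (the
    quantity that also sets the Michaelis–Menten saturation level
    ``N_i / (N_i + Ks_i)``);
``A2``
    weight by the inverse factor ``Ks_i / N_i``, which tends to equalize
    the realized fluxes across groups.

All arrays in this package share one fixed ordering, by substrate:
``[NH4, NO3, NO2, NO, N2O, N2]``, with the enzyme vector aligned to the
substrate each group consumes: ``[amo, nar, nir, nor, nos, fix]``
(nitrogenase last, paired with dinitrogen).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "SUBSTRATES",
    "ENZYMES",
    "ENZYME_LABELS",
    "N_GROUPS",
    "DEFAULT_FLOOR",
    "SCHEMES",
    "UnknownSchemeError",
    "AllocationCoefficients",
    "register_scheme",
    "saturation",
    "compute_allocation",
    "as_substrate_vector",
    "as_half_saturation_vector",
]

#: Fixed substrate ordering used by every array in the package.
SUBSTRATES: tuple[str, ...] = ("NH4", "NO3", "NO2", "NO", "N2O", "N2")

#: Enzyme groups aligned with the substrate each consumes.
ENZYMES: tuple[str, ...] = ("amo", "nar", "nir", "nor", "nos", "fix")

ENZYME_LABELS: dict[str, str] = {
    "amo": "ammonia oxidases",
    "nar": "nitrate reductases",
    "nir": "nitrite reductases",
    "nor": "nitric oxide reductases",
    "nos": "nitrous oxide reductases",
    "fix": "nitrogenases",
}

N_GROUPS = 6

#: Concentration floor (mg N kg^-1) applied before weighting, so the inverse
#: weighting of A2 stays finite at zero concentration.
DEFAULT_FLOOR = 1e-10


class UnknownSchemeError(KeyError):
    """Raised when an allocation scheme identifier is not registered."""


def as_substrate_vector(values) -> np.ndarray:
    """Validate and return a six-substrate concentration vector (mg N kg^-1)."""
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_GROUPS,):
        raise ValueError(f"substrate vector must have shape (6,), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("substrate vector contains non-finite entries")
    if np.any(arr < 0):
        raise ValueError("substrate concentrations must be nonnegative")
    return arr


def as_half_saturation_vector(values) -> np.ndarray:
    """Validate and return a six-entry half-saturation vector (mg N kg^-1)."""
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_GROUPS,):
        raise ValueError(f"half-saturation vector must have shape (6,), got {arr.shape}")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("half-saturation constants must be finite and strictly positive")
    return arr


def saturation(N_i, Ks_i):
    """Michaelis–Menten saturation level ``N / (N + Ks)``.

    Accepts scalars or arrays; the result lies in ``[0, 1)``, equals 0 at
    zero substrate and 0.5 at ``N == Ks``, and increases strictly with ``N``.
    """
    N_i = np.asarray(N_i, dtype=float)
    Ks_i = np.asarray(Ks_i, dtype=float)
    if np.any(N_i < 0):
        raise ValueError("substrate concentration must be nonnegative")
    if np.any(Ks_i <= 0):
        raise ValueError("half-saturation constant must be positive")
    out = N_i / (N_i + Ks_i)
    return float(out) if out.ndim == 0 else out


# --- scheme registry ---------------------------------------------------------

#: Maps scheme identifier -> weight function (N, Ks) -> unnormalized weights.
SCHEMES: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {}


def register_scheme(name: str, weight_fn: Callable[[np.ndarray, np.ndarray], np.ndarray]) -> None:
    """Register a new allocation scenario under ``name``.

    ``weight_fn(N, Ks)`` must return six nonnegative weights; they are
    normalized to coefficients by :func:`compute_allocation`.
    """
    SCHEMES[name] = weight_fn


register_scheme("A0", lambda N, Ks: N)
register_scheme("A1", lambda N, Ks: N / Ks)
register_scheme("A2", lambda N, Ks: Ks / N)


@dataclass(frozen=True)
class AllocationCoefficients:
    """Normalized allocation fractions for the six enzyme groups.

    ``values`` follows the substrate-aligned enzyme order
    ``[amo, nar, nir, nor, nos, fix]``; entries are in ``[0, 1]`` and sum
    to 1 within 1e-12.
    """

    values: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (N_GROUPS,):
            raise ValueError("allocation coefficients must have shape (6,)")
        if np.any(arr < -1e-15) or np.any(arr > 1 + 1e-15):
            raise ValueError("allocation coefficients must lie in [0, 1]")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError("allocation coefficients must sum to 1 within 1e-12")
        object.__setattr__(self, "values", arr)

    def __getitem__(self, i):
        return self.values[i]

    def as_dict(self) -> dict[str, float]:
        return {enz: float(v) for enz, v in zip(ENZYMES, self.values)}


def compute_allocation(
    scheme: str,
    N,
    Ks,
    floor: float = DEFAULT_FLOOR,
) -> AllocationCoefficients:
    """Compute the allocation coefficients of one scenario.

    Parameters
    ----------
    scheme
        Registered scenario identifier (``"A0"``, ``"A1"`` or ``"A2"``).
    N
        Six substrate concentrations, substrate order (mg N kg^-1).
    Ks
        Six half-saturation constants, same order (mg N kg^-1).
    floor
        Every concentration is raised to at least this value before
        weighting, so the A2 inverse weight is defined at zero
        concentration. Must be positive.

    Returns
    -------
    AllocationCoefficients
        Normalized fractions ``w_i / sum_j w_j`` where the weight ``w_i``
        is ``N_i`` (A0), ``N_i/Ks_i`` (A1) or ``Ks_i/N_i`` (A2).
    """
    if scheme not in SCHEMES:
        raise UnknownSchemeError(
            f"unknown allocation scheme {scheme!r}; registered: {sorted(SCHEMES)}"
        )
    if not floor > 0:
        raise ValueError("floor must be positive")
    N = as_substrate_vector(N)
    Ks = as_half_saturation_vector(Ks)
    w = np.asarray(SCHEMES[scheme](np.maximum(N, floor), Ks), dtype=float)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(f"scheme {scheme!r} produced a degenerate weight vector {w}")
    return AllocationCoefficients(values=w / total, scheme=scheme)


def _allocation_weights(scheme: str, N: np.ndarray, Ks: np.ndarray, floor: float) -> np.ndarray:
    """Fast path used by the ODE right-hand side: no validation, no wrapper."""
    w = SCHEMES[scheme](np.maximum(N, floor), Ks)
    return w / w.sum()
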