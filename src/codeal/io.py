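"""Configuration, forcing and observation file handling.

Configs are TOML with three tables: ``[simulation]`` (horizon, solver,
scheme), ``[initial]`` (initial pools) and ``[params]`` (kinetics).
Forcing is CSV with header ``time,B,I_NH4,I_NO3,L,fplant``; observations
are tidy CSV with header ``observable,time,value,replicate``.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .allocation import ENZYMES, SUBSTRATES
from .kinetics import Forcing, KineticParams, ModelState
from .simulator import SimulationConfig

__all__ = [
    "load_config",
    "load_forcing",
    "save_forcing",
    "load_observations",
    "save_observations",
    "load_ranges",
    "params_to_toml",
]

FORCING_COLUMNS = ("time", "B", "I_NH4", "I_NO3", "L", "fplant")
OBS_COLUMNS = ("observable", "time", "value", "replicate")


def load_config(path) -> tuple[SimulationConfig, KineticParams]:
    """Read a TOML config into a simulation config and parameter set."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    params = KineticParams.from_dict(doc["params"])
    init = doc.get("initial", {})
    state = ModelState(
        N=[float(init.get(s, 0.0)) for s in SUBSTRATES],
        E=[float(init.get(f"E_{e}", 0.0)) for e in ENZYMES],
        ON=float(init.get("ON", 0.0)),
    )
    sim = doc.get("simulation", {})
    config = SimulationConfig(
        t0=float(sim.get("t0", 0.0)),
        t1=float(sim["t1"]),
        dt_out=float(sim.get("dt_out", 1.0)),
        scheme=str(sim.get("scheme", "A1")),
        initial=state,
        solver=sim.get("solver", "adaptive"),
        rtol=float(sim.get("rtol", 1e-8)),
        atol=float(sim.get("atol", 1e-10)),
        fixed_step=float(sim.get("fixed_step", 0.05)),
    )
    return config, params


def load_forcing(path) -> Forcing:
    df = pd.read_csv(path)
    missing = set(FORCING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"forcing CSV missing columns: {sorted(missing)}")
    return Forcing(**{c: df[c].to_numpy(dtype=float) for c in FORCING_COLUMNS})


def save_forcing(forcing: Forcing, path) -> None:
    pd.DataFrame({c: getattr(forcing, c) for c in FORCING_COLUMNS}).to_csv(
        path, index=False)


def load_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV missing columns: {sorted(missing)}")
    return df


def save_observations(obs: pd.DataFrame, path) -> None:
    obs.loc[:, list(OBS_COLUMNS)].to_csv(path, index=False)


def load_ranges(path) -> dict[str, tuple[float, float]]:
    """Read per-parameter multiplicative bounds from a flat TOML table."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    table = doc.get("ranges", doc)
    return {str(k): (float(v[0]), float(v[1])) for k, v in table.items()}


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return repr(float(v)) if isinstance(v, float) else repr(v)


def params_to_toml(params: KineticParams, path, initial: ModelState | None = None,
                   simulation: dict | None = None) -> None:
    """Write a parameter set (optionally with initial state and simulation
    table) as a TOML config readable by :func:`load_config`."""
    lines = []
    if simulation:
        lines.append("[simulation]")
        lines += [f"{k} = {_toml_value(v)}" for k, v in simulation.items()]
        lines.append("")
    if initial is not None:
        lines.append("[initial]")
        lines += [f"{s} = {_toml_value(v)}" for s, v in zip(SUBSTRATES, initial.N)]
        lines += [f"E_{e} = {_toml_value(v)}" for e, v in zip(ENZYMES, initial.E)]
        lines.append(f"ON = {_toml_value(initial.ON)}")
        lines.append("")
    lines.append("[params]")
    lines += [f"{k} = {_toml_value(v)}" for k, v in params.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")
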