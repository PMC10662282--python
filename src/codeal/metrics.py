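"""Evaluation statistics: aggregated flux and enzyme metrics, fit measures,
the Wilcoxon signed-rank test and compact-letter grouping, and the
three-scenario comparison report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .allocation import ENZYMES
from .kinetics import Forcing, KineticParams
from .simulator import SimulationConfig, Trajectory, run_simulation

__all__ = [
    "flux_ninorg",
    "enz_ninorg",
    "percent_bias",
    "nse",
    "wilcoxon_signed_rank",
    "letter_groups",
    "ScenarioReport",
    "compare_schemes",
]


def flux_ninorg(traj: Trajectory) -> float:
    """Total inorganic N flux: the time integral (trapezoidal, on the output
    grid) of the six enzymatic transformation fluxes — fixation plus
    nitrification plus the four denitrification steps (mg N kg^-1 over the
    horizon)."""
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    total = (traj.flux("F_fix") + traj.flux("F_nit") + traj.flux("F_nar")
             + traj.flux("F_nir") + traj.flux("F_nor") + traj.flux("F_nos"))
    return float(np.trapezoid(total, traj.times))


def enz_ninorg(traj: Trajectory, params: KineticParams, forcing: Forcing,
               kind: str = "production") -> tuple[float, np.ndarray]:
    """Aggregate enzyme metric over the horizon, with per-group breakdown.

    ``kind="production"`` integrates gross enzyme synthesis
    ``f_i(t) * pEP * B(t)`` (mg enzyme-C kg^-1 produced); its grand total
    equals ``integral pEP*B dt`` for *every* allocation scheme, because the
    coefficients sum to one — allocation redirects synthesis between
    groups without changing its total cost. ``kind="standing"`` integrates
    the standing enzyme pools instead (mg enzyme-C kg^-1 · d).

    Returns ``(total, per_group)`` with ``per_group`` in enzyme order.
    """
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    if kind == "production":
        B = np.interp(traj.times, forcing.time, forcing.B)
        rates = traj.allocation * (params.pEP * B)[:, None]
    elif kind == "standing":
        rates = traj.E
    else:
        raise ValueError(f"unknown enzyme metric kind {kind!r}")
    per_group = np.trapezoid(rates, traj.times, axis=0)
    return float(per_group.sum()), per_group


def percent_bias(sim, obs) -> float:
    """Percent bias: ``100 * (mean(sim) - mean(obs)) / mean(obs)``.

    Positive when the simulation overestimates the observed mean. The two
    series need not be the same length (only means are compared).
    """
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    mo = obs.mean()
    if mo == 0:
        raise ValueError("observed mean is zero; percent bias undefined")
    return float(100.0 * (sim.mean() - mo) / mo)


def nse(sim, obs) -> float:
    """Nash–Sutcliffe efficiency ``1 - SS_err / SS_obs`` (<= 1; 1 is a
    perfect fit, 0 matches the observed-mean predictor)."""
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape or sim.size < 2:
        raise ValueError("sim and obs must be equal-length series of length >= 2")
    denom = np.sum((obs - obs.mean()) ** 2)
    if denom == 0:
        raise ValueError("constant observations; NSE undefined")
    return float(1.0 - np.sum((sim - obs) ** 2) / denom)


# --- Wilcoxon signed-rank test ----------------------------------------------

def _signed_rank_distribution(ranks: np.ndarray) -> np.ndarray:
    """Exact null distribution of W+ for the given (integer) ranks.

    Dynamic-programming convolution over sign assignments; equivalent to
    enumerating all 2^m patterns. ``counts[w]`` is the number of patterns
    with W+ == w.
    """
    max_w = int(ranks.sum())
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks.astype(int):
        counts[r:] += counts[:max_w + 1 - r].copy()
    return counts


def wilcoxon_signed_rank(x, y, alternative: str = "two-sided",
                         zero_method: str = "wilcox") -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test.

    Differences ``d = x - y`` are ranked by absolute value (average ranks
    for ties). Zero differences are dropped (``zero_method="wilcox"``,
    the classical convention) or kept in the ranking and then discarded
    from the rank sums (``"pratt"``). The p-value is exact — full
    enumeration of the 2^m sign assignments via convolution — when m <= 25
    with no ties and no zeros; otherwise a normal approximation with tie
    correction and continuity correction is used.

    Returns ``(W, p)`` with ``W = min(W+, W-)``. ``alternative="greater"``
    tests for ``x`` shifted above ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = x - y
    if np.all(d == 0):
        raise ValueError("all paired differences are zero; test undefined")
    n_zero = int(np.sum(d == 0))
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks_all = rankdata(np.abs(d))
        ranks_nz = ranks_all
        d_nz = d
    elif zero_method == "pratt":
        ranks_all = rankdata(np.abs(d))
        keep = d != 0
        ranks_nz = ranks_all[keep]
        d_nz = d[keep]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")

    m = d_nz.size
    w_plus = float(ranks_nz[d_nz > 0].sum())
    w_minus = float(ranks_nz[d_nz < 0].sum())
    W = min(w_plus, w_minus)

    has_ties = np.unique(np.abs(d_nz)).size < m
    exact_ok = m <= 25 and not has_ties and n_zero == 0

    if exact_ok:
        counts = _signed_rank_distribution(ranks_nz)
        total = counts.sum()  # == 2^m
        cum = counts.cumsum()
        w = int(round(w_plus))
        p_le = cum[w] / total
        p_ge = (total - (cum[w - 1] if w > 0 else 0.0)) / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return W, float(p)

    # normal approximation with tie and continuity corrections
    if zero_method == "pratt":
        n_all = d.size  # zeros included in ranking
        mu = (n_all * (n_all + 1) / 4.0) - n_zero * (n_zero + 1) / 4.0
        var = (n_all * (n_all + 1) * (2 * n_all + 1)
               - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24.0
        tie_groups = np.unique(np.abs(d_nz), return_counts=True)[1]
    else:
        mu = m * (m + 1) / 4.0
        var = m * (m + 1) * (2 * m + 1) / 24.0
        tie_groups = np.unique(np.abs(d_nz), return_counts=True)[1]
    var -= np.sum(tie_groups ** 3 - tie_groups) / 48.0
    if var <= 0:
        raise ValueError("degenerate variance in normal approximation")
    sd = np.sqrt(var)

    def z(stat: float, direction: str) -> float:
        # continuity correction of 0.5 toward the mean
        if direction == "ge":
            return (stat - mu - 0.5) / sd
        return (stat - mu + 0.5) / sd

    if alternative == "greater":
        p = norm.sf(z(w_plus, "ge"))
    elif alternative == "less":
        p = norm.cdf(z(w_plus, "le"))
    else:
        p = 2.0 * norm.sf((abs(w_plus - mu) - 0.5) / sd)
    return W, float(min(1.0, p))


def letter_groups(labels, pairwise_p: pd.DataFrame, alpha: float = 0.001) -> dict[str, str]:
    """Compact letter display: labels share at least one letter iff their
    pairwise p-value is >= ``alpha``.

    Insert-and-absorb construction: start from one letter covering all
    labels; for each significant pair, split every letter containing both;
    absorb letters that are subsets of others. ``pairwise_p`` must be a
    symmetric DataFrame indexed by the labels.
    """
    labels = list(labels)
    p = pairwise_p.loc[labels, labels]
    if not np.allclose(p.values, p.values.T, equal_nan=True):
        raise ValueError("pairwise p-value table must be symmetric")
    columns: list[set] = [set(labels)]
    for a, b in combinations(labels, 2):
        if p.loc[a, b] < alpha:
            new_cols = []
            for col in columns:
                if a in col and b in col:
                    new_cols.append(col - {a})
                    new_cols.append(col - {b})
                else:
                    new_cols.append(col)
            # absorb: drop any column that is a subset of another
            columns = [c for c in new_cols
                       if c and not any(c < other for other in new_cols)]
            # deduplicate
            seen, uniq = [], []
            for c in columns:
                if c not in seen:
                    seen.append(c)
                    uniq.append(c)
            columns = uniq
    columns.sort(key=lambda c: min(labels.index(l) for l in c))
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for i, col in enumerate(columns):
        for lab in labels:
            if lab in col:
                out[lab] += letters[i]
    return out


@dataclass
class ScenarioReport:
    """Results of running the allocation scenarios on one common testbed.

    Aggregates per-scheme Flux-Ninorg (time-integrated total enzymatic N
    flux), Enz-Ninorg in both readings (cumulative production and
    integrated standing pool), the flux-per-production efficiency ratio,
    per-observable percent bias against observations (when supplied),
    per-replicate paired metric values, the pairwise Wilcoxon p-value
    table and the compact letter groups.
    """

    schemes: tuple[str, ...]
    flux_ninorg: dict[str, float]
    enz_production: dict[str, float]
    enz_standing: dict[str, float]
    enz_production_by_group: dict[str, dict[str, float]]
    efficiency: dict[str, float]
    percent_bias: dict[str, dict[str, float]]
    replicate_flux: pd.DataFrame
    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    alpha: float

    def to_dict(self) -> dict:
        return {
            "schemes": list(self.schemes),
            "flux_ninorg": self.flux_ninorg,
            "enz_production": self.enz_production,
            "enz_standing": self.enz_standing,
            "enz_production_by_group": self.enz_production_by_group,
            "efficiency": self.efficiency,
            "percent_bias": self.percent_bias,
            "pairwise_p": {a: {b: float(self.pairwise_p.loc[a, b])
                               for b in self.schemes} for a in self.schemes},
            "letters": self.letters,
            "alpha": self.alpha,
        }


def compare_schemes(config: SimulationConfig, params: KineticParams,
                    forcing: Forcing, obs: pd.DataFrame | None = None,
                    schemes: tuple[str, ...] = ("A0", "A1", "A2"),
                    n_replicates: int = 24, seed: int = 0,
                    replicate_cv: float = 0.10,
                    alpha: float = 0.001) -> ScenarioReport:
    """Run every scheme on identical inputs and assemble the comparison.

    One reference run per scheme provides the aggregate metrics and the
    percent bias against ``obs`` (a tidy frame with columns
    ``observable,time,value,replicate``). ``n_replicates`` paired runs —
    each replicate perturbs the forcing identically across schemes — feed
    the pairwise Wilcoxon signed-rank tests on per-replicate Flux-Ninorg,
    from which the letter groups are derived.
    """
    from dataclasses import replace as _replace

    from .scenarios import OBSERVABLES, perturbed_forcings

    flux, enz_prod, enz_stand, eff = {}, {}, {}, {}
    by_group: dict[str, dict[str, float]] = {}
    pbias: dict[str, dict[str, float]] = {}
    for scheme in schemes:
        cfg = _replace(config, scheme=scheme)
        traj = run_simulation(cfg, params, forcing)
        flux[scheme] = flux_ninorg(traj)
        total_p, per_p = enz_ninorg(traj, params, forcing, kind="production")
        total_s, _ = enz_ninorg(traj, params, forcing, kind="standing")
        enz_prod[scheme] = total_p
        enz_stand[scheme] = total_s
        by_group[scheme] = {e: float(v) for e, v in zip(ENZYMES, per_p)}
        eff[scheme] = flux[scheme] / total_p if total_p > 0 else np.nan
        if obs is not None:
            pbias[scheme] = {}
            for name in OBSERVABLES:
                sub = obs[obs["observable"] == name]
                if sub.empty:
                    continue
                sim = np.interp(np.sort(sub["time"].unique()), traj.times,
                                traj.observable(name))
                pbias[scheme][name] = percent_bias(sim, sub["value"].to_numpy())

    reps = perturbed_forcings(forcing, n_replicates, seed, cv=replicate_cv)
    rep_rows = {}
    for scheme in schemes:
        cfg = _replace(config, scheme=scheme)
        rep_rows[scheme] = [flux_ninorg(run_simulation(cfg, params, f))
                            for f in reps]
    rep_df = pd.DataFrame(rep_rows)

    pmat = pd.DataFrame(np.ones((len(schemes), len(schemes))),
                        index=schemes, columns=schemes)
    for a, b in combinations(schemes, 2):
        _, pv = wilcoxon_signed_rank(rep_df[a], rep_df[b])
        pmat.loc[a, b] = pmat.loc[b, a] = pv
    letters = letter_groups(schemes, pmat, alpha=alpha)

    return ScenarioReport(
        schemes=tuple(schemes), flux_ninorg=flux, enz_production=enz_prod,
        enz_standing=enz_stand, enz_production_by_group=by_group,
        efficiency=eff, percent_bias=pbias, replicate_flux=rep_df,
        pairwise_p=pmat, letters=letters, alpha=alpha,
    )
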