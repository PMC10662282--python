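"""Evaluation statistics: aggregation oracles, fit measures, the signed-rank
test against full enumeration and scipy, and compact letter display."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

import codeal as cd
from codeal.metrics import letter_groups, nse, percent_bias, wilcoxon_signed_rank


def brute_force_wilcoxon(d, alternative):
    """Literal enumeration of all 2^m sign assignments (no ties, no zeros)."""
    d = np.asarray(d, dtype=float)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    m = len(d)
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=m)]
    ws = np.array(ws)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestAggregation:
    def test_zero_flux_integrates_to_zero(self, short_trajectory):
        traj = short_trajectory
        empty = cd.Trajectory(times=traj.times, states=traj.states,
                              allocation=traj.allocation,
                              fluxes=np.zeros_like(traj.fluxes))
        assert cd.flux_ninorg(empty) == 0.0

    def test_constant_flux_rectangle(self, short_trajectory):
        traj = short_trajectory
        times = np.linspace(0, 10, 11)
        n = times.size
        fluxes = np.zeros((n, len(cd.FLUX_NAMES)))
        fluxes[:, cd.FLUX_NAMES.index("F_nit")] = 2.0
        t2 = cd.Trajectory(times=times, states=np.zeros((n, 15)),
                           allocation=np.full((n, 6), 1 / 6), fluxes=fluxes)
        assert cd.flux_ninorg(t2) == pytest.approx(20.0, rel=1e-12)

    def test_piecewise_linear_matches_trapezoid_oracle(self, rng):
        times = np.sort(rng.uniform(0, 100, 17))
        series = rng.uniform(0, 3, (17, 6))
        n = times.size
        fluxes = np.zeros((n, len(cd.FLUX_NAMES)))
        for j, name in enumerate(("F_fix", "F_nit", "F_nar", "F_nir", "F_nor", "F_nos")):
            fluxes[:, cd.FLUX_NAMES.index(name)] = series[:, j]
        traj = cd.Trajectory(times=times, states=np.zeros((n, 15)),
                             allocation=np.full((n, 6), 1 / 6), fluxes=fluxes)
        total = series.sum(axis=1)
        oracle = sum((total[i] + total[i + 1]) / 2 * (times[i + 1] - times[i])
                     for i in range(n - 1))
        assert cd.flux_ninorg(traj) == pytest.approx(oracle, rel=1e-12)

    def test_enzyme_production_arithmetic(self):
        # pEP*B = 1 over 10 days, uniform allocation -> total 10, each 10/6
        times = np.linspace(0, 10, 21)
        n = times.size
        traj = cd.Trajectory(times=times, states=np.zeros((n, 15)),
                             allocation=np.full((n, 6), 1 / 6),
                             fluxes=np.zeros((n, len(cd.FLUX_NAMES))))
        params = cd.default_params().with_values({"pEP": 0.01})
        ones = np.ones(2)
        forcing = cd.Forcing(time=[0, 10], B=100 * ones, I_NH4=0 * ones,
                             I_NO3=0 * ones, L=0 * ones, fplant=0 * ones)
        total, per_group = cd.enz_ninorg(traj, params, forcing, "production")
        assert total == pytest.approx(10.0, rel=1e-12)
        np.testing.assert_allclose(per_group, np.full(6, 10 / 6), rtol=1e-12)

    def test_production_total_is_scheme_invariant(self, short_testbed):
        """Allocation redistributes enzyme synthesis; its grand total is fixed
        by pEP and B(t) alone."""
        from dataclasses import replace
        _, params, config, forcing = short_testbed
        totals = {}
        for scheme in ("A0", "A1", "A2"):
            traj = cd.run_simulation(replace(config, scheme=scheme), params, forcing)
            totals[scheme], per = cd.enz_ninorg(traj, params, forcing, "production")
            assert per.shape == (6,)
        ref = totals["A0"]
        for v in totals.values():
            assert v == pytest.approx(ref, rel=1e-9)


class TestFitMeasures:
    @pytest.mark.parametrize(
        "sim, obs, expected",
        [([1, 2, 3], [1, 2, 3], 0.0),
         ([110, 110], [100, 100], 10.0),
         ([40, 40, 40], [50, 50, 50], -20.0)],
    )
    def test_percent_bias(self, sim, obs, expected):
        assert percent_bias(sim, obs) == pytest.approx(expected, abs=1e-12)

    def test_percent_bias_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_bias([1, 2], [1, -1])

    def test_nse_perfect_and_mean_predictor(self):
        obs = np.array([1.0, 3.0, 5.0])
        assert nse(obs, obs) == pytest.approx(1.0)
        assert nse(np.full(3, obs.mean()), obs) == pytest.approx(0.0)

    def test_nse_worse_than_mean_is_negative(self):
        # hand computation: obs=[1,2,3], sim=[3,2,1]: SSE=8, SS_obs=2 -> 1-4=-3
        assert nse([3, 2, 1], [1, 2, 3]) == pytest.approx(-3.0)

    def test_nse_constant_obs_rejected(self):
        with pytest.raises(ValueError):
            nse([1, 2, 3], [2, 2, 2])


class TestWilcoxon:
    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    def test_five_positive_pairs_one_sided(self):
        x = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        W, p = wilcoxon_signed_rank(x, y, alternative="greater")
        assert W == 0.0  # W- = 0
        assert p == pytest.approx(1 / 32)

    def test_mixed_signs_rank_sum(self):
        d = np.array([1.0, -2.0, 3.0, -4.0, 5.0, 6.0])
        W, p = wilcoxon_signed_rank(d, np.zeros(6))
        # W+ = ranks of +1,+3,+5,+6 = 1+3+5+6 = 15; W- = 6
        assert W == 6.0
        assert p == pytest.approx(brute_force_wilcoxon(d, "two-sided"))

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_branch_equals_enumeration(self, rng, alternative):
        for n in range(3, 11):
            for _ in range(5):
                d = rng.standard_normal(n)
                d = np.where(np.abs(d) < 1e-6, 0.5, d)  # no zeros
                _, p = wilcoxon_signed_rank(d, np.zeros(n), alternative=alternative)
                assert p == pytest.approx(brute_force_wilcoxon(d, alternative),
                                          abs=1e-12)

    def test_exact_branch_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            W, p = wilcoxon_signed_rank(x, y)
            res = scipy_wilcoxon(x, y, mode="exact")
            assert W == pytest.approx(res.statistic)
            assert p == pytest.approx(res.pvalue, rel=1e-9)

    def test_normal_approximation_matches_scipy(self, rng):
        x = rng.standard_normal(60)
        y = x + rng.standard_normal(60) * 0.5 + 0.2
        W, p = wilcoxon_signed_rank(x, y)
        res = scipy_wilcoxon(x, y, mode="approx", correction=True)
        assert p == pytest.approx(res.pvalue, rel=1e-6)

    def test_pratt_zero_handling(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        W_w, _ = wilcoxon_signed_rank(x, y, zero_method="wilcox")
        W_p, _ = wilcoxon_signed_rank(x, y, zero_method="pratt")
        assert W_w == 0.0 and W_p == 0.0  # all nonzero d positive either way


class TestLetterGroups:
    @staticmethod
    def _pmat(labels, entries):
        df = pd.DataFrame(np.ones((len(labels), len(labels))),
                          index=labels, columns=labels)
        for (a, b), p in entries.items():
            df.loc[a, b] = df.loc[b, a] = p
        return df

    def test_all_significant_three_distinct_letters(self):
        labels = ["A0", "A1", "A2"]
        p = self._pmat(labels, {("A0", "A1"): 1e-5, ("A0", "A2"): 1e-5,
                                ("A1", "A2"): 1e-5})
        letters = letter_groups(labels, p, alpha=0.001)
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_none_significant_single_letter(self):
        labels = ["A0", "A1", "A2"]
        p = self._pmat(labels, {("A0", "A1"): 0.5, ("A0", "A2"): 0.9,
                                ("A1", "A2"): 0.2})
        letters = letter_groups(labels, p, alpha=0.001)
        assert set(letters.values()) == {"a"}

    def test_single_nonsignificant_pair_shares(self):
        labels = ["x", "y", "z"]
        for pair in itertools.combinations(labels, 2):
            entries = {p: 1e-6 for p in itertools.combinations(labels, 2)}
            entries[pair] = 0.5
            letters = letter_groups(labels, self._pmat(labels, entries), alpha=0.001)
            # sharing relation matches non-significance exactly (brute-force check)
            for a, b in itertools.combinations(labels, 2):
                shares = bool(set(letters[a]) & set(letters[b]))
                assert shares == ((a, b) == pair)

    def test_asymmetric_table_rejected(self):
        labels = ["a", "b"]
        df = pd.DataFrame([[1.0, 0.2], [0.4, 1.0]], index=labels, columns=labels)
        with pytest.raises(ValueError):
            letter_groups(labels, df)
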