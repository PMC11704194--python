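"""Survival machinery: hand log-rank oracle, Cox recovery, cutpoint scan,
exact Wilcoxon enumeration and BH control."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protegrate import survival_stats as ss
from protegrate.core import OmicsMatrix


def _surv(times, events, **extra):
    return pd.DataFrame({
        "sample": [f"s{i}" for i in range(len(times))],
        "os_time": times, "os_event": events, **extra,
    })


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [5.0, 8, 12, 20, 25]
        events = [1, 0, 1, 1, 0]
        surv = _surv(times * 2, events * 2, group=["a"] * 5 + ["b"] * 5)
        _, chi2, p = ss.km_logrank(surv)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_oracle(self):
        """Log-rank chi2 equals the observed-minus-expected computation done
        by hand over the event times."""
        surv = _surv([1.0, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1],
                     group=list("aaabbb"))
        _, chi2, _ = ss.km_logrank(surv)
        # hand computation: at each event time, E_a = d * n_a / n, V from the
        # hypergeometric variance; chi2 = (O_a - E_a)^2 / V
        n_a, n_b, O_a, E_a, V = 3, 3, 0.0, 0.0, 0.0
        for t, g in zip([1, 2, 3, 4, 5, 6], "aaabbb"):
            n = n_a + n_b
            E_a += n_a / n
            V += (n_a * n_b * (n - 1)) / (n ** 2 * (n - 1)) if n > 1 else 0.0
            if g == "a":
                O_a += 1
                n_a -= 1
            else:
                n_b -= 1
        expected_chi2 = (O_a - E_a) ** 2 / V
        assert chi2 == pytest.approx(expected_chi2, rel=1e-6)

    def test_planted_hazard_ratio_detected(self):
        ps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            grp = np.repeat(["lo", "hi"], n // 2)
            hz = np.where(grp == "hi", 0.06, 0.03)
            t = rng.exponential(1 / hz)
            c = rng.uniform(0, 60, n)
            surv = _surv(np.minimum(t, c), (t <= c).astype(int), group=grp)
            ps.append(ss.km_logrank(surv)[2])
        assert np.median(ps) < 0.05

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            ss.km_logrank(_surv([1.0, 2.0], [1, 1], group=["a", "a"]))


class TestCox:
    def test_planted_log_hazard_recovered(self):
        rng = np.random.default_rng(0)
        n = 500
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.7 * x)))
        c = rng.uniform(0, 80, n)
        surv = _surv(np.minimum(t, c), (t <= c).astype(int), marker=x)
        fit = ss.cox_univariate(surv, "marker")
        assert fit["coef"] == pytest.approx(0.7, abs=0.15)
        assert fit["hr"] == pytest.approx(np.exp(fit["coef"]))

    def test_null_covariate_ci_coverage(self):
        covered = 0
        trials = 60
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            n = 120
            x = rng.normal(size=n)
            t = rng.exponential(1 / 0.05, n)
            c = rng.uniform(0, 80, n)
            surv = _surv(np.minimum(t, c), (t <= c).astype(int), marker=x)
            fit = ss.cox_univariate(surv, "marker")
            covered += fit["ci_low"] <= 1.0 <= fit["ci_high"]
        # 95% nominal coverage, 3 binomial SEs of slack at 60 trials
        assert covered / trials >= 0.95 - 3 * np.sqrt(0.05 * 0.95 / trials)

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError):
            ss.cox_univariate(_surv([1.0, 2.0], [1, 1], marker=[1.0, 1.0]), "marker")


class TestOptimalCutpoint:
    def _brute_force_scan(self, surv, marker, minprop):
        """Oracle: standardized rank statistic at each admissible cutpoint,
        computed from the score definition with explicit loops."""
        a = ss.logrank_scores(surv["os_time"].to_numpy(), surv["os_event"].to_numpy())
        n = len(marker)
        lo = int(np.ceil(minprop * n))
        best = (None, -np.inf)
        for c in sorted(set(marker)):
            m = int(np.sum(marker <= c))
            if m < lo or n - m < lo:
                continue
            S = sum(ai for xi, ai in zip(marker, a) if xi <= c)
            mu = m * a.mean()
            var = m * (n - m) / (n * (n - 1)) * np.sum((a - a.mean()) ** 2)
            t = abs(S - mu) / np.sqrt(var)
            if t > best[1] + 1e-12:
                best = (c, t)
        return best

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        n = 20
        marker = rng.normal(size=n)
        t = rng.exponential(10, n)
        surv = _surv(t, rng.integers(0, 2, n))
        res = ss.optimal_cutpoint(surv, marker, minprop=0.1)
        cut, stat = self._brute_force_scan(surv, marker, 0.1)
        assert res.cutpoint == pytest.approx(cut)
        assert res.statistic == pytest.approx(stat, abs=1e-9)

    def test_indicator_marker_recovers_group_split(self):
        rng = np.random.default_rng(2)
        n = 100
        high_risk = np.repeat([0, 1], n // 2)
        marker = high_risk + rng.normal(0, 0.01, n)
        t = rng.exponential(1 / (0.03 * np.where(high_risk, 4.0, 1.0)))
        surv = _surv(np.minimum(t, 60), (t <= 60).astype(int))
        res = ss.optimal_cutpoint(surv, marker)
        agreement = ((marker <= res.cutpoint) == (high_risk == 0)).mean()
        assert agreement >= 0.95  # split sits at (or within a few subjects of)
        assert res.p < 0.01       # the planted group boundary

    def test_constant_marker_errors(self):
        surv = _surv([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10], [1] * 10)
        with pytest.raises(ValueError, match="admissible"):
            ss.optimal_cutpoint(surv, np.ones(10))

    def test_permutation_p_exceeds_naive_p(self):
        """The selection-adjusted permutation p is never smaller than the
        naive log-rank p at the chosen cutpoint on null data."""
        rng = np.random.default_rng(3)
        n = 60
        marker = rng.normal(size=n)
        t = rng.exponential(20, n)
        surv = _surv(np.minimum(t, 40), (t <= 40).astype(int))
        res = ss.optimal_cutpoint(surv, marker, n_permutations=200, seed=0)
        assert res.p_permutation >= res.p - 0.05


class TestDifferentialAbundance:
    def test_identical_groups_no_survivors(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 10, (20, 6))
        data = pd.DataFrame(np.hstack([base, base]),
                            index=[f"f{i}" for i in range(20)],
                            columns=[f"a{j}" for j in range(6)] + [f"b{j}" for j in range(6)])
        out = ss.differential_abundance(
            data, [[f"a{j}" for j in range(6)], [f"b{j}" for j in range(6)]])
        assert (out["direction"] == "ns").all()
        assert (out["fold_change"] == 1.0).all()

    def test_four_value_wilcoxon_matches_rank_permutation_enumeration(self):
        """Exact two-sided Wilcoxon p for 4v4 equals enumeration over all
        rank assignments."""
        a = np.array([1.0, 2.0, 3.0, 10.0])
        b = np.array([4.0, 5.0, 6.0, 7.0])
        data = pd.DataFrame([np.concatenate([a, b])], index=["f"],
                            columns=list("abcdwxyz"))
        out = ss.differential_abundance(data, [list("abcd"), list("wxyz")],
                                        min_per_group=3)
        u_obs = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        # enumeration oracle over all C(8,4) group assignments
        pooled = np.concatenate([a, b])
        stats_all = []
        for combo in itertools.combinations(range(8), 4):
            ga = pooled[list(combo)]
            gb = pooled[[i for i in range(8) if i not in combo]]
            stats_all.append(stats.mannwhitneyu(ga, gb).statistic)
        stats_all = np.array(stats_all)
        mid = 8  # U ranges 0..16, two-sided distance from mean
        expected = np.mean(np.abs(stats_all - mid) >= abs(u_obs - mid) - 1e-12)
        assert out.iloc[0]["p"] == pytest.approx(expected, rel=1e-9)

    def test_planted_twofold_shift_recovered(self):
        rng = np.random.default_rng(1)
        n_feat, n = 200, 30
        base = rng.lognormal(3, 0.3, (n_feat, 2 * n))
        data = pd.DataFrame(base, index=[f"f{i}" for i in range(n_feat)],
                            columns=[f"a{j}" for j in range(n)] + [f"b{j}" for j in range(n)])
        planted = [f"f{i}" for i in range(20)]
        data.loc[planted, [f"a{j}" for j in range(n)]] *= 2.0
        out = ss.differential_abundance(
            data, [[f"a{j}" for j in range(n)], [f"b{j}" for j in range(n)]],
            fc_threshold=1.5, use_adjusted=False)
        up = set(out.loc[out["direction"] == "up", "feature"])
        assert len(up & set(planted)) >= 18
        assert len(up - set(planted)) <= 3

    def test_kruskal_for_three_groups(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(5, 1, (10, 18)),
                            index=[f"f{i}" for i in range(10)],
                            columns=[f"s{j}" for j in range(18)])
        groups = [[f"s{j}" for j in range(0, 6)],
                  [f"s{j}" for j in range(6, 12)],
                  [f"s{j}" for j in range(12, 18)]]
        out = ss.differential_abundance(data, groups, test="kruskal")
        assert len(out) == 10 and out["fold_change"].isna().all()

    def test_imputed_cells_excluded(self):
        data = pd.DataFrame(np.ones((1, 8)), index=["f"],
                            columns=list("abcdwxyz"))
        mask = data.astype(bool)
        mask.iloc[0, :] = [True, True, False, False, False, False, False, False]
        m = OmicsMatrix(data, imputed=mask)
        out = ss.differential_abundance(m, [list("abcd"), list("wxyz")],
                                        min_per_group=3)
        assert out.empty  # group A has only 2 measured values
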