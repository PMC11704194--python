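"""Survival statistics and differential abundance.

Kaplan-Meier curves with log-rank tests, univariate Cox proportional
hazards (Efron ties), maximally selected rank statistics for optimal
dichotomizing cutpoints of continuous markers (with an optional
permutation-adjusted p, since the naive minimal p over cutpoints is
anti-conservative), and group-wise differential abundance tests with
fold-change and BH thresholds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from protegrate.core import OmicsMatrix, check_binary
from protegrate.stats_util import bh_adjust


def km_logrank(survival: pd.DataFrame, group_col: str = "group"):
    """Kaplan-Meier curves per group and the k-sample log-rank test.

    Returns ``(curves, chi2, p)`` where curves maps group label to its
    product-limit survival-function DataFrame.  Groups with zero events
    are computed with a warning.
    """
    time = survival["os_time"].to_numpy(dtype=float)
    event = check_binary(survival["os_event"].to_numpy(), "os_event")
    groups = survival[group_col]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups for a log-rank test")
    curves = {}
    for label, idx in groups.groupby(groups).groups.items():
        sub = survival.loc[idx]
        if sub["os_event"].sum() == 0:
            warnings.warn(f"group {label!r} has zero events")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_time"], sub["os_event"], label=str(label))
        curves[label] = kmf.survival_function_
    res = multivariate_logrank_test(time, groups.to_numpy(), event)
    return curves, float(res.test_statistic), float(res.p_value)


def cox_univariate(survival: pd.DataFrame, covariate: str) -> dict:
    """Univariate Cox PH fit: hazard ratio, 95% Wald CI, p and coefficient.

    The coefficient equals ln(HR).  Ties are handled with the Efron
    approximation.  Non-convergence raises with lifelines' diagnostics.
    """
    if survival[covariate].nunique() < 2:
        raise ValueError(f"covariate {covariate!r} does not vary")
    df = survival[["os_time", "os_event", covariate]].dropna()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="os_time", event_col="os_event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(f"Cox fit failed for {covariate!r}: {exc}") from exc
    s = cph.summary.loc[covariate]
    return {
        "coef": float(s["coef"]),
        "hr": float(s["exp(coef)"]),
        "ci_low": float(np.exp(s["coef lower 95%"])),
        "ci_high": float(np.exp(s["coef upper 95%"])),
        "p": float(s["p"]),
    }


# ---------------------------------------------------------------------------
# maximally selected rank statistics


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-subject log-rank scores a_i = event_i - Lambda_hat(t_i).

    Lambda_hat is the Nelson-Aalen cumulative hazard evaluated at the
    subject's observed time.  Scores sum to zero.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(time)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    # at-risk count just before each distinct time; events at each time
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    at_risk = n - first_idx
    d = np.array([event[time == u].sum() for u in uniq])
    increments = d / at_risk
    cumhaz_at = np.cumsum(increments)
    lam = np.interp(time, uniq, cumhaz_at)
    return event - lam


def _max_cutpoint_scan(marker: np.ndarray, scores: np.ndarray, minprop: float):
    """Standardized rank-score statistic at every admissible cutpoint.

    Returns (cutpoints, standardized statistics).  Cutpoint c defines the
    group {marker <= c}; admissible means both sides hold at least
    ceil(minprop * n) subjects.
    """
    n = len(marker)
    order = np.argsort(marker, kind="stable")
    x_sorted = marker[order]
    a_sorted = scores[order]
    csum = np.cumsum(a_sorted)
    a_var = np.sum((scores - scores.mean()) ** 2)
    lo = max(1, math.ceil(minprop * n))
    cuts, stat = [], []
    for m in range(lo, n - lo + 1):
        # cut between sorted positions m-1 and m; skip ties
        if x_sorted[m - 1] == x_sorted[m % n] and m < n:
            continue
        S = csum[m - 1]
        mu = m * scores.mean()
        var = m * (n - m) / (n * (n - 1)) * a_var
        if var <= 0:
            continue
        cuts.append(x_sorted[m - 1])
        stat.append(abs(S - mu) / math.sqrt(var))
    return np.array(cuts), np.array(stat)


@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float  # standardized log-rank statistic at the cutpoint
    groups: pd.Series  # 'low' (marker <= cutpoint) / 'high'
    p: float  # naive log-rank p at the selected cutpoint (anti-conservative)
    p_permutation: float | None = None  # adjusted for cutpoint selection


def optimal_cutpoint(
    survival: pd.DataFrame,
    marker: pd.Series | np.ndarray,
    minprop: float = 0.1,
    n_permutations: int = 0,
    seed: int = 0,
) -> CutpointResult:
    """Optimal dichotomizing threshold by maximally selected rank statistics.

    All admissible cutpoints (both sides >= minprop * n) are scanned and
    the one maximizing the standardized log-rank score statistic is
    returned (ties resolved toward the lower cutpoint).  The naive p is
    the ordinary log-rank p at the selected cutpoint and does not account
    for the selection; with ``n_permutations`` > 0 a permutation p for
    the maximal statistic is computed as well.
    """
    marker = np.asarray(marker, dtype=float)
    time = survival["os_time"].to_numpy(dtype=float)
    event = check_binary(survival["os_event"].to_numpy(), "os_event")
    scores = logrank_scores(time, event)
    cuts, stat = _max_cutpoint_scan(marker, scores, minprop)
    if len(cuts) == 0:
        raise ValueError("no admissible cutpoint (marker constant or minprop too large)")
    best = int(np.argmax(stat))  # argmax returns first max -> lower cutpoint
    cut = float(cuts[best])
    groups = pd.Series(
        np.where(marker <= cut, "low", "high"), index=survival.index, name="group"
    )
    res = multivariate_logrank_test(time, groups.to_numpy(), event)
    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        t_obs = stat[best]
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(scores)
            _, pstat = _max_cutpoint_scan(marker, perm, minprop)
            if len(pstat) and pstat.max() >= t_obs:
                hits += 1
        p_perm = (1 + hits) / (1 + n_permutations)
    return CutpointResult(
        cutpoint=cut,
        statistic=float(stat[best]),
        groups=groups,
        p=float(res.p_value),
        p_permutation=p_perm,
    )


# ---------------------------------------------------------------------------
# differential abundance


def differential_abundance(
    matrix: OmicsMatrix | pd.DataFrame,
    groups: list[list[str]],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    test: str = "wilcoxon",
    use_adjusted: bool = True,
    min_per_group: int = 3,
) -> pd.DataFrame:
    """Per-feature group comparison with fold change and BH control.

    Two groups: Wilcoxon rank-sum (``test="wilcoxon"``) or Student t
    (``"student_t"``); more than two: Kruskal-Wallis (``"kruskal"``) or
    one-way ANOVA (``"anova"``).  Fold change is the ratio of group means
    on the linear (unlogged) scale, first group over second; imputed
    cells are excluded, and features with fewer than ``min_per_group``
    measured values in any group are skipped.  Features are flagged up /
    down when |log FC| passes ``fc_threshold`` and the (adjusted, by
    default) p passes ``p_threshold``.
    """
    data = matrix.values_masked() if isinstance(matrix, OmicsMatrix) else matrix
    two_group = len(groups) == 2
    if two_group and test not in ("wilcoxon", "student_t"):
        raise ValueError("two-group tests: 'wilcoxon' or 'student_t'")
    if not two_group and test not in ("kruskal", "anova"):
        raise ValueError(">2-group tests: 'kruskal' or 'anova'")
    rows = []
    for feat in data.index:
        vals = [data.loc[feat, g].dropna().to_numpy(dtype=float) for g in groups]
        if any(len(v) < min_per_group for v in vals):
            continue
        if test == "wilcoxon":
            stat, p = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        elif test == "student_t":
            stat, p = stats.ttest_ind(vals[0], vals[1])
        elif test == "kruskal":
            stat, p = stats.kruskal(*vals)
        else:
            stat, p = stats.f_oneway(*vals)
        fc = float(vals[0].mean() / vals[1].mean()) if two_group and vals[1].mean() != 0 else np.nan
        rows.append(dict(feature=feat, statistic=float(stat), fold_change=fc, p=float(p)))
    out = pd.DataFrame(rows, columns=["feature", "statistic", "fold_change", "p"])
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    crit = out["q" if use_adjusted else "p"] < p_threshold
    direction = np.full(len(out), "ns", dtype=object)
    if two_group and len(out):
        direction[crit & (out["fold_change"] > fc_threshold)] = "up"
        direction[crit & (out["fold_change"] < 1.0 / fc_threshold)] = "down"
    elif len(out):
        direction[crit] = "significant"
    out["direction"] = direction
    return out
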