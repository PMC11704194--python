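"""Resampling-based consensus clustering (PAM on Spearman distance).

Repeatedly subsamples the cohort, clusters each subsample with PAM
(k-medoids, BUILD + SWAP) on 1 - Spearman correlation between sample
profiles, and records how often each sample pair lands in the same
cluster among the reps where both were drawn.  Model selection
diagnostics: consensus CDF curves, delta-area of the CDF per k, and
mean silhouette on the consensus-derived distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score


def pam(dist: np.ndarray, k: int) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Deterministic BUILD + SWAP: BUILD greedily seeds the k medoids,
    SWAP exhaustively tries every (medoid, non-medoid) exchange and
    applies the best strict improvement until convergence.  Ties break
    toward the lowest index.  Returns medoid-index labels remapped to
    0..k-1 in order of first appearance.
    """
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} samples")
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        cur = dist[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(cur - dist[:, j], 0).sum() if j not in medoids else -np.inf
            for j in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds):
        return dist[:, meds].min(axis=1).sum()

    best_cost = cost(medoids)
    improved = True
    while improved:
        improved = False
        best_swap = None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1:]
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
        if best_swap is not None:
            mi, h = best_swap
            medoids[mi] = h
            medoids = sorted(medoids)
            improved = True
    assign = np.asarray(medoids)[np.argmin(dist[:, medoids], axis=1)]
    _, labels = np.unique(assign, return_inverse=True)
    return labels


def spearman_distance(data: pd.DataFrame) -> np.ndarray:
    """1 - Spearman correlation between sample columns (profiles over features)."""
    ranks = data.rank(axis=0, method="average")
    corr = np.corrcoef(ranks.to_numpy(dtype=float).T)
    return 1.0 - corr


def top_variable_features(data: pd.DataFrame, fraction: float = 0.5, metric: str = "variance") -> pd.DataFrame:
    """Keep the top ``fraction`` most variable features (variance or MAD)."""
    if metric == "variance":
        spread = data.var(axis=1, ddof=1)
    elif metric == "mad":
        spread = (data.sub(data.median(axis=1), axis=0)).abs().median(axis=1)
    else:
        raise ValueError("metric must be 'variance' or 'mad'")
    n_keep = max(2, int(np.ceil(fraction * len(data))))
    return data.loc[spread.sort_values(ascending=False).index[:n_keep]]


@dataclass
class ConsensusResult:
    consensus: dict  # k -> samples x samples DataFrame in [0, 1]
    labels: dict  # k -> pd.Series of labels 1..k
    cdf: dict  # k -> (grid, CDF values)
    delta_area: dict  # k -> relative AUC increase of the consensus CDF
    silhouette: dict  # k -> mean silhouette on 1 - consensus
    chosen_k: int
    params: dict = field(default_factory=dict)


def consensus_cluster(
    matrix,
    k_range=range(2, 6),
    reps: int = 200,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    top_var_fraction: float = 0.5,
    var_metric: str = "variance",
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of sample profiles.

    Per repetition, ``ceil(p_item * n)`` samples are drawn without
    replacement (and, if ``p_feature < 1``, a feature subset as well),
    the subsample is clustered with PAM on Spearman distance, and
    co-clustering is tallied.  consensus(i, j) = co-cluster count /
    co-sampled count.  Final labels come from average-linkage
    hierarchical clustering of 1 - consensus cut at k.  The chosen k
    maximizes mean silhouette on the consensus distance, with delta-area
    as the tie-breaker.
    """
    data = getattr(matrix, "data", matrix)
    data = top_variable_features(data, top_var_fraction, var_metric)
    n = data.shape[1]
    k_range = list(k_range)
    if n < 3 * max(k_range):
        raise ValueError(f"need >= {3 * max(k_range)} samples for k up to {max(k_range)}")
    samples = data.columns
    rng = np.random.default_rng(seed)
    n_sub = int(np.ceil(p_item * n))
    full_dist = spearman_distance(data) if p_feature >= 1.0 else None

    # identical subsampling across k, as resampling-based consensus requires
    draws = [rng.permutation(n)[:n_sub] for _ in range(reps)]
    feat_draws = None
    if p_feature < 1.0:
        n_feat = int(np.ceil(p_feature * data.shape[0]))
        feat_draws = [rng.permutation(data.shape[0])[:n_feat] for _ in range(reps)]

    consensus, labels, cdf, areas, sil = {}, {}, {}, {}, {}
    for k in k_range:
        M = np.zeros((n, n))
        I = np.zeros((n, n))
        for r, idx in enumerate(draws):
            if full_dist is not None:
                d = full_dist[np.ix_(idx, idx)]
            else:
                sub = data.iloc[feat_draws[r], :].iloc[:, idx]
                d = spearman_distance(sub)
            lab = pam(d, k)
            I[np.ix_(idx, idx)] += 1
            same = lab[:, None] == lab[None, :]
            M[np.ix_(idx, idx)] += same
        if (I == 0).any():
            raise ValueError(
                "some sample pair was never co-sampled; increase reps or p_item"
            )
        C = M / I
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2
        consensus[k] = pd.DataFrame(C, index=samples, columns=samples)
        cons_dist = 1.0 - C
        np.fill_diagonal(cons_dist, 0.0)
        Z = linkage(squareform(cons_dist, checks=False), method="average")
        lab_k = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=samples)
        labels[k] = lab_k
        tri = C[np.triu_indices(n, 1)]
        grid = np.linspace(0, 1, 101)
        cdf_vals = np.searchsorted(np.sort(tri), grid, side="right") / len(tri)
        cdf[k] = (grid, cdf_vals)
        areas[k] = float(np.trapezoid(cdf_vals, grid))
        if lab_k.nunique() > 1:
            sil[k] = float(silhouette_score(cons_dist, lab_k, metric="precomputed"))
        else:
            sil[k] = np.nan
    delta = {}
    for i, k in enumerate(k_range):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[k_range[i - 1]]
            delta[k] = (areas[k] - prev) / prev if prev > 0 else np.nan
    # chosen k: max silhouette, delta-area breaking ties
    chosen = max(k_range, key=lambda k: (np.nan_to_num(sil[k], nan=-2.0), delta[k]))
    return ConsensusResult(
        consensus=consensus, labels=labels, cdf=cdf, delta_area=delta,
        silhouette=sil, chosen_k=int(chosen),
        params=dict(reps=reps, p_item=p_item, p_feature=p_feature,
                    top_var_fraction=top_var_fraction, var_metric=var_metric, seed=seed),
    )


def cluster_association(labels: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    """Association tests between cluster labels and clinical variables.

    Categorical variables: Fisher's exact test for 2x2 tables with any
    expected count <= 5, chi-square otherwise.  Continuous variables:
    Kruskal-Wallis across clusters.  Single-level variables are skipped.
    """
    rows = []
    common = labels.index.intersection(clinical.index)
    lab = labels.loc[common]
    for var in clinical.columns:
        v = clinical.loc[common, var].dropna()
        if v.nunique() < 2:
            continue
        l = lab.loc[v.index]
        if pd.api.types.is_numeric_dtype(v) and v.nunique() > 5:
            groups = [v[l == g].to_numpy() for g in l.unique()]
            stat, p = stats.kruskal(*groups)
            test = "kruskal"
        else:
            table = pd.crosstab(v, l)
            expected = stats.contingency.expected_freq(table.to_numpy())
            if table.shape == (2, 2) and (expected <= 5).any():
                _, p = stats.fisher_exact(table.to_numpy())
                test = "fisher"
            else:
                _, p, _, _ = stats.chi2_contingency(table.to_numpy())
                test = "chi2"
        rows.append(dict(variable=var, test=test, p=float(p)))
    return pd.DataFrame(rows, columns=["variable", "test", "p"])
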