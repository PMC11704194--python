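"""Single-sample enrichment scoring (ssGSEA) and derived activity scores.

One rank-based enrichment engine powers pathway scores, transcription
factor activity, immune/stromal scores and cell-type signature scores.
For a sample, features are ranked by abundance; the enrichment score of
a set is the integrated difference between the weighted in-set ECDF
(weights |rank|^alpha) and the uniform out-of-set ECDF, optionally
normalized by the max-min range of all scores in the cohort.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from protegrate.core import OmicsMatrix
from protegrate.stats_util import bh_adjust, zscore_rows


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, OmicsMatrix) else matrix


def ssgsea_sample(values: pd.Series, members: set, alpha: float = 0.25) -> float:
    """Unnormalized ssGSEA enrichment score for one sample and one set.

    Features are ordered by decreasing abundance; the rank statistic of a
    feature is its ascending average rank (largest abundance -> N).
    ES = sum over positions of (weighted in-set ECDF - out-set ECDF).
    """
    v = values.dropna()
    n = len(v)
    ranks = v.rank(method="average").to_numpy()
    in_set = np.array([f in members for f in v.index])
    n_in = int(in_set.sum())
    if n_in == 0 or n_in == n:
        raise ValueError("set must be a proper non-empty subset of measured features")
    order = np.lexsort((np.arange(n), -v.to_numpy()))
    in_ord = in_set[order]
    w = np.abs(ranks[order]) ** alpha
    w_in = np.where(in_ord, w, 0.0)
    ecdf_in = np.cumsum(w_in) / w_in.sum()
    ecdf_out = np.cumsum(~in_ord) / (n - n_in)
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea(
    matrix: OmicsMatrix | pd.DataFrame,
    sets: dict[str, list[str]],
    alpha: float = 0.25,
    min_size: int = 10,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA score matrix (sets x samples).

    Sets are first restricted to features present in the matrix; sets
    whose surviving size is below ``min_size`` are dropped with a
    warning.  With ``normalize=True`` all scores are divided by the
    max-min range of the raw enrichment scores across the whole cohort.
    """
    data = _as_frame(matrix)
    feats = set(data.index)
    surviving = {}
    for name, members in sets.items():
        present = [m for m in dict.fromkeys(members) if m in feats]
        if len(present) >= min_size:
            surviving[name] = set(present)
        else:
            warnings.warn(f"gene set {name!r}: {len(present)} members present < min_size={min_size}")
    if not surviving:
        raise ValueError("no gene set survives the min_size filter")
    out = pd.DataFrame(index=list(surviving), columns=data.columns, dtype=float)
    for sample in data.columns:
        col = data[sample]
        for name, members in surviving.items():
            out.loc[name, sample] = ssgsea_sample(col, members, alpha=alpha)
    if normalize:
        rng_ = out.to_numpy().max() - out.to_numpy().min()
        if rng_ > 0:
            out = out / rng_
    return out


def tf_activity(
    expr: OmicsMatrix | pd.DataFrame,
    tf_targets: dict[str, list[str]],
    alpha: float = 0.25,
    min_size: int = 10,
) -> pd.DataFrame:
    """Transcription-factor activity from target-gene enrichment.

    Each TF's regulon is scored by ssGSEA on the expression matrix.  TFs
    whose regulon collapses to a single measured target fall back to that
    target's z-scored abundance (with a warning); TFs with no measured
    target are skipped and logged.
    """
    data = _as_frame(expr)
    feats = set(data.index)
    multi, single = {}, {}
    for tf, targets in tf_targets.items():
        present = [t for t in dict.fromkeys(targets) if t in feats]
        if len(present) == 0:
            warnings.warn(f"TF {tf!r}: no measured targets; skipped")
        elif len(present) == 1:
            warnings.warn(f"TF {tf!r}: single measured target {present[0]}; using z-scored abundance")
            single[tf] = present[0]
        else:
            multi[tf] = present
    pieces = []
    if multi:
        pieces.append(ssgsea(data, multi, alpha=alpha, min_size=min(2, min_size)))
    if single:
        z = zscore_rows(data)
        zz = pd.DataFrame(
            {tf: z.loc[target] for tf, target in single.items()}
        ).T.set_axis(data.columns, axis=1)
        pieces.append(zz)
    if not pieces:
        raise ValueError("no TF has measured targets")
    return pd.concat(pieces)


def mgps(expr: OmicsMatrix | pd.DataFrame, cell_cycle_genes: list[str]) -> pd.Series:
    """Multi-gene proliferation score: mean standardized expression of
    cell-cycle-regulated genes per sample.  Genes absent from the matrix
    are ignored; zero-variance genes contribute 0."""
    data = _as_frame(expr)
    present = [g for g in dict.fromkeys(cell_cycle_genes) if g in data.index]
    if not present:
        raise ValueError("no cell-cycle gene present in the matrix")
    return zscore_rows(data.loc[present]).mean(axis=0)


def immune_stromal_scores(
    expr: OmicsMatrix | pd.DataFrame,
    immune_set: list[str],
    stromal_set: list[str],
    alpha: float = 0.25,
    min_size: int = 2,
) -> pd.DataFrame:
    """Immune and stromal signature scores plus their sum.

    Both signatures are scored by ssGSEA; the combined score is
    immune + stromal.  Tumor purity is not inferred.
    """
    scores = ssgsea(
        expr, {"immune": immune_set, "stromal": stromal_set},
        alpha=alpha, min_size=min_size,
    )
    if set(scores.index) != {"immune", "stromal"}:
        raise ValueError("immune or stromal signature has no overlap with the matrix")
    out = scores.copy()
    out.loc["combined"] = scores.loc["immune"] + scores.loc["stromal"]
    return out


def cell_type_scores(
    expr: OmicsMatrix | pd.DataFrame,
    signatures: dict[str, list[str]],
    alpha: float = 0.25,
    min_size: int = 2,
) -> pd.DataFrame:
    """Per-sample cell-type abundance scores from marker signatures.

    ssGSEA on user-provided cell-type marker sets; no spillover
    compensation is applied.
    """
    return ssgsea(expr, signatures, alpha=alpha, min_size=min_size)


def overrepresentation(
    hits: list[str], universe: list[str], sets: dict[str, list[str]]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    ``hits`` must be a subset of ``universe``; set members outside the
    universe are ignored.  Returns overlap sizes, upper-tail p and BH q.
    """
    uni = set(universe)
    hit_set = set(hits)
    stray = sorted(hit_set - uni)
    if stray:
        raise ValueError(f"hit gene(s) not in universe: {stray}")
    N, n = len(uni), len(hit_set)
    rows = []
    for name, members in sets.items():
        K = len(set(members) & uni)
        k = len(set(members) & hit_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(dict(set=name, set_size=K, overlap=k, p=p))
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    return out
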