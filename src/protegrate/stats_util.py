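"""Small shared statistical helpers (multiple testing, rank correlation)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are ignored (returned as NaN) and do not count toward the
    family size.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with two-sided t-approximation p.

    Matches :func:`scipy.stats.spearmanr`; kept as a named entry point so the
    ledger operations share one convention.
    """
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def rankdata_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise average ranks (1..n ascending), NaN preserved."""
    return df.rank(axis=0, method="average")


def zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score across samples; zero-variance rows map to 0."""
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    z = df.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)
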