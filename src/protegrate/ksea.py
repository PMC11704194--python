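"""Kinase-substrate enrichment analysis (KSEA).

A kinase's activity in a sample is summarized from the phosphosite
abundances of its known substrate sites.  The score follows the
standard KSEA form

    z = (s_bar - p_bar) * sqrt(m) / delta

where ``s_bar`` is the mean log2 abundance of the kinase's m mapped
substrate sites, ``p_bar`` the mean over all sites of that sample, and
``delta`` the standard deviation over all sites of that sample; a
two-sided normal p accompanies each z.  A mean-only variant (the raw
collective substrate mean, z-scored per kinase across samples) is
available as a toggle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from protegrate.core import OmicsMatrix
from protegrate.survival_stats import cox_univariate, optimal_cutpoint


def site_id(substrate: str, site: str) -> str:
    return f"{substrate}_{site}"


@dataclass
class KinaseActivity:
    """Kinase x sample activity z-scores with substrate counts."""

    z: pd.DataFrame  # kinases x samples
    p: pd.DataFrame  # two-sided normal p per cell
    n_substrates: pd.Series  # mapped, measured substrate sites per kinase


def ksea_scores(
    phospho: OmicsMatrix | pd.DataFrame,
    ks_map: pd.DataFrame,
    min_substrates: int = 3,
    log_transform: bool = True,
    statistic: str = "delta",
) -> KinaseActivity:
    """Per-sample kinase activity from substrate phosphosites.

    Parameters
    ----------
    phospho
        Phosphosite x sample abundances; row ids of the form
        ``PROTEIN_S123`` (anything matching ``site_id``).
    ks_map
        Kinase-substrate relations with columns ``kinase, substrate, site``.
    min_substrates
        Kinases mapping to fewer measured sites are dropped.
    log_transform
        Take log2 of positive abundances first (matrices straight from
        FOT normalization are on the linear scale).
    statistic
        ``"delta"`` for the (s_bar - p_bar) * sqrt(m) / delta z-score;
        ``"mean"`` for the raw substrate mean z-scored per kinase across
        samples (no per-cell p in that mode).
    """
    data = phospho.values_masked() if isinstance(phospho, OmicsMatrix) else phospho
    if log_transform:
        data = np.log2(data.where(data > 0))
    mapped = {}
    features = set(data.index)
    for kinase, grp in ks_map.groupby("kinase"):
        sites = sorted(
            {site_id(s, t) for s, t in zip(grp["substrate"], grp["site"])} & features
        )
        if len(sites) >= min_substrates:
            mapped[kinase] = sites
    if not mapped:
        raise ValueError("no kinase maps to any measured phosphosite")
    kinases = sorted(mapped)
    m = pd.Series({k: len(mapped[k]) for k in kinases})
    z = pd.DataFrame(index=kinases, columns=data.columns, dtype=float)
    if statistic == "mean":
        for k in kinases:
            z.loc[k] = data.loc[mapped[k]].mean(axis=0)
        mu, sd = z.mean(axis=1), z.std(axis=1, ddof=1)
        z = z.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
        p = pd.DataFrame(np.nan, index=z.index, columns=z.columns)
        return KinaseActivity(z=z, p=p, n_substrates=m)
    if statistic != "delta":
        raise ValueError("statistic must be 'delta' or 'mean'")
    for sample in data.columns:
        col = data[sample]
        p_bar = col.mean(skipna=True)
        delta = col.std(skipna=True, ddof=1)
        for k in kinases:
            s_bar = col.loc[mapped[k]].mean(skipna=True)
            z.loc[k, sample] = (s_bar - p_bar) * np.sqrt(m[k]) / delta
    p = pd.DataFrame(
        2 * stats.norm.sf(np.abs(z.to_numpy(dtype=float))),
        index=z.index, columns=z.columns,
    )
    return KinaseActivity(z=z, p=p, n_substrates=m)


def activity_survival_link(
    activity: KinaseActivity | pd.DataFrame,
    survival: pd.DataFrame,
    minprop: float = 0.1,
    min_shared: int = 20,
    n_permutations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Associate each kinase's activity with overall survival.

    For every kinase the activity is dichotomized at the maximally
    selected rank-statistic cutpoint; the log-rank p at that cutpoint
    and the Cox hazard ratio of the high- vs low-activity group are
    reported.  Kinases with constant activity carry a flag instead of an
    estimate.
    """
    act = activity.z if isinstance(activity, KinaseActivity) else activity
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    shared = act.columns.intersection(surv.index)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared samples; need >= {min_shared}")
    surv = surv.loc[shared].reset_index(names="sample")
    rows = []
    for kinase in act.index:
        marker = act.loc[kinase, shared].to_numpy(dtype=float)
        if np.nanstd(marker) == 0 or np.isnan(marker).any():
            rows.append(dict(kinase=kinase, cutpoint=np.nan, hr=np.nan,
                             logrank_p=np.nan, p_permutation=np.nan, flag="no_admissible_cutpoint"))
            continue
        try:
            cp = optimal_cutpoint(surv, marker, minprop=minprop,
                                  n_permutations=n_permutations, seed=seed)
        except ValueError:
            rows.append(dict(kinase=kinase, cutpoint=np.nan, hr=np.nan,
                             logrank_p=np.nan, p_permutation=np.nan, flag="no_admissible_cutpoint"))
            continue
        high = (cp.groups == "high").astype(int)
        cox = cox_univariate(surv.assign(high=high.to_numpy()), "high")
        rows.append(dict(kinase=kinase, cutpoint=cp.cutpoint, hr=cox["hr"],
                         logrank_p=cp.p, p_permutation=cp.p_permutation, flag=""))
    return pd.DataFrame(rows)
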