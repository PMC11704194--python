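"""CNV -> abundance correlation ledgers (cis / trans effects).

A *cis* effect is the association between a gene's own copy-number
value and that same gene's mRNA / protein / phosphoprotein abundance;
a *trans* effect links a copy-number locus to abundances of genes at
other loci.  Correlations are Spearman (average ranks for ties) with
two-sided p-values, BH-adjusted within each (layer, mode) family.
Imputed cells are excluded pairwise; pairs with fewer than
``min_pairs`` complete observations are skipped.
"""

from __future__ import annotations

import itertools
from collections.abc import Callable

import numpy as np
import pandas as pd
from scipy import stats

from protegrate.core import OmicsMatrix
from protegrate.stats_util import bh_adjust

LEDGER_COLUMNS = ["cnv_feature", "target_feature", "layer", "rho", "p", "q", "mode"]


def default_gene_of(feature: str) -> str:
    """Map a feature id to its gene symbol: 'GENE_S123' -> 'GENE'."""
    return str(feature).split("_")[0]


def collapse_phosphosites(
    matrix: OmicsMatrix, gene_of: Callable[[str], str] = default_gene_of
) -> OmicsMatrix:
    """Collapse phosphosite rows to one row per gene (max-abundance site).

    The representative site is the one with the highest mean measured
    abundance across samples, giving a phosphoprotein-level matrix for
    CNV-phosphoprotein correlation.
    """
    measured = matrix.values_masked()
    genes = measured.index.map(gene_of)
    order = measured.mean(axis=1, skipna=True)
    best = (
        pd.DataFrame({"gene": genes, "mean": order})
        .reset_index(names="feature")
        .sort_values(["gene", "mean"], ascending=[True, False])
        .drop_duplicates("gene")
    )
    data = matrix.data.loc[best["feature"]].set_axis(best["gene"], axis=0)
    imp = (
        None if matrix.imputed is None
        else matrix.imputed.loc[best["feature"]].set_axis(best["gene"], axis=0)
    )
    return OmicsMatrix(data=data, layer=matrix.layer, normalized=matrix.normalized,
                       imputed=imp, meta=dict(matrix.meta))


def correlate_layers(
    cnv: OmicsMatrix,
    target: OmicsMatrix,
    layer: str | None = None,
    mode: str = "cis_only",
    min_pairs: int = 10,
    gene_of: Callable[[str], str] = default_gene_of,
) -> pd.DataFrame:
    """Spearman correlation ledger between gene-level CNV and one omics layer.

    ``mode="cis_only"`` correlates each gene's copy number with its own
    abundance; ``mode="all"`` computes the full CNV x target cross
    product and labels same-gene rows cis, the rest trans.  BH
    adjustment is applied within each (layer, mode) family separately.
    """
    if mode not in ("cis_only", "all"):
        raise ValueError("mode must be 'cis_only' or 'all'")
    layer = layer or target.layer
    cvals = cnv.values_masked()
    tvals = target.values_masked()
    samples = cvals.columns.intersection(tvals.columns)
    cvals, tvals = cvals[samples], tvals[samples]
    tgene = pd.Series(tvals.index.map(gene_of), index=tvals.index)

    if mode == "cis_only":
        pairs = [
            (g, feat) for feat, g in tgene.items() if g in cvals.index
        ]
    else:
        pairs = list(itertools.product(cvals.index, tvals.index))

    rows = []
    for cnv_feat, t_feat in pairs:
        x = cvals.loc[cnv_feat].to_numpy(dtype=float)
        y = tvals.loc[t_feat].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_pairs:
            continue
        res = stats.spearmanr(x[ok], y[ok])
        rows.append(
            dict(
                cnv_feature=cnv_feat,
                target_feature=t_feat,
                layer=layer,
                rho=float(res.statistic),
                p=float(res.pvalue),
                mode="cis" if gene_of(t_feat) == cnv_feat else "trans",
                n=int(ok.sum()),
            )
        )
    ledger = pd.DataFrame(rows, columns=[*LEDGER_COLUMNS[:5], "mode", "n"])
    ledger["q"] = np.nan
    for m, idx in ledger.groupby("mode").groups.items():
        ledger.loc[idx, "q"] = bh_adjust(ledger.loc[idx, "p"])
    return ledger[[*LEDGER_COLUMNS, "n"]]


def cis_overlap(
    ledgers: dict[str, pd.DataFrame],
    p_threshold: float = 0.05,
    cag_list: list[str] | None = None,
    use_q: bool = False,
) -> dict:
    """Venn-style overlap of genes with significant cis effects per layer.

    Parameters
    ----------
    ledgers
        Mapping layer name -> correlation ledger (rows with mode 'cis'
        are used).
    p_threshold
        Significance threshold on raw p (or BH q with ``use_q=True``).
    cag_list
        Optional restriction to a cancer-associated-gene list.

    Returns a dict with per-layer significant gene sets, exclusive Venn
    region counts keyed by '&'-joined layer combinations, and the gene
    lists per region.
    """
    col = "q" if use_q else "p"
    sig: dict[str, set] = {}
    for layer, led in ledgers.items():
        if led.empty:
            sig[layer] = set()
            continue
        cis = led[(led["mode"] == "cis") & (led[col] < p_threshold)]
        genes = set(cis["cnv_feature"])
        if cag_list is not None:
            genes &= set(cag_list)
        sig[layer] = genes
    layers = list(ledgers)
    regions: dict[str, list[str]] = {}
    for r in range(1, len(layers) + 1):
        for combo in itertools.combinations(layers, r):
            inside = set.intersection(*(sig[l] for l in combo)) if combo else set()
            outside = set.union(set(), *(sig[l] for l in layers if l not in combo))
            regions["&".join(combo)] = sorted(inside - outside)
    return {
        "per_layer": {l: sorted(s) for l, s in sig.items()},
        "region_counts": {k: len(v) for k, v in regions.items()},
        "region_genes": regions,
    }
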