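"""Label-free quantification: iBAQ, FOT normalization, phosphosite QC.

iBAQ divides a protein's summed peptide intensity by its count of
theoretically observable tryptic peptides; FOT (fraction of total)
divides each protein's iBAQ by the sample's total iBAQ and scales by
1e6, after which missing values are imputed with 1e-5 (masked, so
rank statistics can exclude them).  Phosphosites are retained only at
localization probability strictly greater than 0.75.
"""

from __future__ import annotations

import decimal
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from protegrate.core import OmicsMatrix

FOT_SCALE = 1e6
IMPUTE_VALUE = 1e-5


def tryptic_peptides(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """Fully tryptic fragments: cleave C-terminal of K/R except before P.

    With ``missed_cleavages`` > 0, concatenations of up to that many
    adjacent fragments are included as well.
    """
    seq = sequence.strip().upper()
    if not seq:
        return []
    cut_after = [
        i for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0] + [i + 1 for i in cut_after] + [len(seq)]
    frags = [seq[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]
    peptides = list(frags)
    for mc in range(1, missed_cleavages + 1):
        for i in range(len(frags) - mc):
            peptides.append("".join(frags[i:i + mc + 1]))
    return peptides


def observable_peptides(
    sequence: str, min_len: int = 7, max_len: int = 30, missed_cleavages: int = 0
) -> int:
    """Count of theoretically observable tryptic peptides of a protein.

    A peptide is observable when its length falls in [min_len, max_len].
    An empty sequence yields 0 with a warning.
    """
    if not sequence.strip():
        warnings.warn("empty protein sequence: 0 observable peptides")
        return 0
    return sum(
        min_len <= len(p) <= max_len
        for p in tryptic_peptides(sequence, missed_cleavages)
    )


def observable_counts_from_fasta(
    sequences: dict[str, str], min_len: int = 7, max_len: int = 30,
    missed_cleavages: int = 0,
) -> pd.Series:
    """Observable-peptide counts for every protein in a FASTA mapping."""
    return pd.Series({
        acc: observable_peptides(seq, min_len, max_len, missed_cleavages)
        for acc, seq in sequences.items()
    }, name="observable")


def ibaq(peptides: pd.DataFrame, observable_counts: pd.Series | dict) -> OmicsMatrix:
    """iBAQ abundances: summed peptide intensity / observable peptide count.

    Parameters
    ----------
    peptides
        Long table with columns ``sample, protein, peptide, intensity``.
    observable_counts
        Per-protein observable-peptide counts; proteins missing from this
        table or with count < 1 are excluded with a warning.
    """
    counts = pd.Series(observable_counts, dtype=float)
    if (peptides["intensity"] < 0).any():
        raise ValueError("peptide intensities must be non-negative")
    totals = peptides.pivot_table(
        index="protein", columns="sample", values="intensity", aggfunc="sum"
    )
    known = totals.index.intersection(counts[counts >= 1].index)
    dropped = totals.index.difference(known)
    if len(dropped):
        warnings.warn(
            f"excluding {len(dropped)} protein(s) without observable-peptide count: "
            f"{sorted(dropped)[:5]}..."
        )
    mat = totals.loc[known].div(counts.loc[known], axis=0)
    return OmicsMatrix(data=mat, layer="protein")


def fot_normalize(
    matrix: OmicsMatrix,
    scale: float = FOT_SCALE,
    impute_value: float = IMPUTE_VALUE,
    impute: bool = True,
) -> OmicsMatrix:
    """Fraction-of-total normalization with post-hoc imputation.

    Each sample column is divided by its total abundance and multiplied
    by ``scale`` (default 1e6), so pre-imputation column sums equal the
    scale exactly.  Missing cells are then filled with ``impute_value``
    (default 1e-5) and recorded in the imputation mask.
    """
    data = matrix.data.astype(float)
    colsums = data.sum(axis=0, skipna=True)
    bad = colsums[(colsums <= 0) | ~np.isfinite(colsums)]
    if len(bad):
        raise ValueError(f"cannot FOT-normalize all-zero sample(s): {list(bad.index)}")
    fot = data.div(colsums, axis=1) * scale
    mask = fot.isna()
    if impute:
        fot = fot.where(~mask, impute_value)
    return OmicsMatrix(
        data=fot,
        layer=matrix.layer,
        normalized=True,
        imputed=mask if impute else None,
        meta={**matrix.meta, "fot_scale": scale, "impute_value": impute_value},
    )


def filter_phosphosites(records: pd.DataFrame, min_prob: float = 0.75) -> pd.DataFrame:
    """Keep phosphosites with localization probability strictly > min_prob.

    ``records`` needs columns ``protein, residue, position, probability``;
    abundance columns pass through untouched.  The filter is idempotent.
    """
    prob = records["probability"].astype(float)
    if ((prob < 0) | (prob > 1)).any():
        raise ValueError("localization probabilities must lie in [0, 1]")
    return records[prob > min_prob].copy()


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def residue_distribution(records_or_counts) -> pd.DataFrame:
    """Counts and percentages of phosphosites on S / T / Y residues.

    Accepts either a records table with a ``residue`` column or a mapping
    of residue -> count.  Percentages are 100*count/total rounded half-up
    to one decimal; with zero total, percentages are NaN-flagged.
    """
    if isinstance(records_or_counts, pd.DataFrame):
        bad = set(records_or_counts["residue"]) - set("STY")
        if bad:
            raise ValueError(f"unknown phosphoresidues: {sorted(bad)}")
        counts = records_or_counts["residue"].value_counts()
    else:
        counts = pd.Series(dict(records_or_counts), dtype=float)
    counts = counts.reindex(list("STY"), fill_value=0).astype(int)
    total = int(counts.sum())
    if total == 0:
        pct = pd.Series([np.nan] * 3, index=counts.index)
    else:
        pct = counts.map(lambda c: _round_half_up(100.0 * c / total, 1))
    return pd.DataFrame({"count": counts, "percent": pct})


def qc_correlation(a: OmicsMatrix | pd.Series, b: OmicsMatrix | pd.Series) -> float:
    """Spearman correlation between two runs on shared, non-imputed features.

    Used for QC of repeated standards; requires at least 3 shared features.
    """
    sa = _as_series(a)
    sb = _as_series(b)
    shared = sa.dropna().index.intersection(sb.dropna().index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared measured features; need >= 3")
    rho = stats.spearmanr(sa.loc[shared], sb.loc[shared]).statistic
    return float(rho)


def _as_series(x) -> pd.Series:
    if isinstance(x, OmicsMatrix):
        df = x.values_masked()
        if df.shape[1] != 1:
            raise ValueError("QC correlation expects single-sample matrices or Series")
        return df.iloc[:, 0]
    return pd.Series(x)
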