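"""Shared in-memory containers.

Tabular inputs (segments, mutations, peptides, survival, relations) are
plain :class:`pandas.DataFrame` objects with documented column names;
the one container that carries state beyond a table is
:class:`OmicsMatrix`, which couples an abundance matrix with its layer
tag, normalization state and imputation mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column names for a segment table (SEG semantics, 1-based inclusive)
SEG_COLUMNS = ["sample", "chrom", "start", "end", "nmark", "log2"]

#: canonical column names for a MAF-like mutation table; ``context`` is the
#: reference-strand trinucleotide around the variant position (e.g. "ACA")
MAF_COLUMNS = ["sample", "gene", "chrom", "pos", "ref", "alt", "variant_class", "context"]

#: canonical survival-table columns; extra columns are covariates/labels
SURVIVAL_COLUMNS = ["sample", "os_time", "os_event"]


@dataclass
class OmicsMatrix:
    """Features x samples abundance matrix for one omics layer.

    Parameters
    ----------
    data
        Abundances, rows = features (genes / proteins / phosphosites),
        columns = samples.
    layer
        One of ``"mrna"``, ``"protein"``, ``"phospho"``, ``"cnv"`` or a
        free-form tag.
    normalized
        True once FOT (fraction-of-total) normalization has been applied.
    imputed
        Optional boolean mask, same shape as ``data``; True marks cells
        that were filled with the imputation constant rather than measured.
        Rank-based statistics exclude masked cells by default.
    """

    data: pd.DataFrame
    layer: str = "protein"
    normalized: bool = False
    imputed: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.imputed is not None:
            if self.imputed.shape != self.data.shape:
                raise ValueError("imputation mask shape does not match data")
            self.imputed = self.imputed.astype(bool)

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def values_masked(self) -> pd.DataFrame:
        """Data with imputed cells replaced by NaN (measured values only)."""
        if self.imputed is None:
            return self.data
        return self.data.mask(self.imputed)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            data=self.data.copy(),
            layer=self.layer,
            normalized=self.normalized,
            imputed=None if self.imputed is None else self.imputed.copy(),
            meta=dict(self.meta),
        )


def check_binary(values: np.ndarray, name: str) -> np.ndarray:
    """Validate a 0/1 array (e.g. event indicators), returning it as int."""
    arr = np.asarray(values)
    uniq = np.unique(arr[~pd.isna(arr)])
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError(f"{name} must be binary 0/1, got values {uniq}")
    return arr.astype(int)
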