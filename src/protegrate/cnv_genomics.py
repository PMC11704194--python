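"""Copy-number and mutation genomics.

Gene-level copy numbers and weighted arm scores from segment tables,
amplification/deletion calls at a log2-ratio cutoff, tumor mutational
burden, 96-trinucleotide-context matrices, NMF mutational-signature
extraction with reference matching, and pairwise co-occurrence /
mutual-exclusivity tests.

Coordinates are 1-based inclusive end-to-end (SEG convention); overlap
lengths are computed as ``min(end) - max(start) + 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from protegrate.core import OmicsMatrix
from protegrate.stats_util import bh_adjust

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
#: the six pyrimidine-reference substitutions, conventional order
SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
#: the 96 contexts in the conventional 6x16 order: substitution, then 5' base, then 3' base
CONTEXTS_96 = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
]


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _overlap_join(intervals: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Cartesian join per chromosome with positive-overlap rows only."""
    seg_chroms = set(segments["chrom"].astype(str))
    known = set(intervals["chrom"].astype(str))
    unknown = sorted(seg_chroms - known)
    if unknown:
        raise ValueError(f"segment table contains unknown chromosome name(s): {unknown}")
    merged = intervals.merge(segments, on="chrom", suffixes=("_iv", "_seg"))
    ov = (
        np.minimum(merged["end_iv"], merged["end_seg"])
        - np.maximum(merged["start_iv"], merged["start_seg"])
        + 1
    )
    merged = merged.assign(overlap=ov)
    return merged[merged["overlap"] > 0]


def _weighted_mean_matrix(joined: pd.DataFrame, key: str) -> pd.DataFrame:
    joined = joined.assign(wx=joined["overlap"] * joined["log2"])
    grp = joined.groupby([key, "sample"], sort=True)[["wx", "overlap"]].sum()
    score = grp["wx"] / grp["overlap"]
    return score.unstack("sample")


def gene_copy_number(segments: pd.DataFrame, genes: pd.DataFrame) -> OmicsMatrix:
    """Length-weighted mean segment log2 ratio over each gene body.

    Parameters
    ----------
    segments
        Columns ``sample, chrom, start, end, log2`` (1-based inclusive).
    genes
        Gene model with columns ``gene, chrom, start, end`` (and usually
        ``arm``); symbols must be unique.

    Returns
    -------
    OmicsMatrix (layer="cnv") of genes x samples; genes with no
    overlapping segment in a sample are NaN.
    """
    if genes["gene"].duplicated().any():
        dup = genes.loc[genes["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene symbols in gene model: {dup}")
    iv = genes.rename(columns={"start": "start_iv", "end": "end_iv"})[
        ["gene", "chrom", "start_iv", "end_iv"]
    ]
    seg = segments.rename(columns={"start": "start_seg", "end": "end_seg"})
    joined = _overlap_join(iv, seg)
    mat = _weighted_mean_matrix(joined, "gene")
    mat = mat.reindex(index=genes["gene"], columns=sorted(segments["sample"].unique()))
    return OmicsMatrix(data=mat, layer="cnv")


def arm_score(
    segments: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    arm_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Length-weighted arm-level copy score.

    score(arm, sample) = sum(len_i * r_i) / sum(len_i) over the segments
    overlapping the arm, where len_i is the overlap length and r_i the
    segment log2 ratio.  The weighted sum is normalized by the total
    overlapped length so arm scores stay on the log2-ratio scale and the
    +/-1 amplification/deletion cutoff remains meaningful.

    Arm boundaries come from ``arm_table`` (columns arm, chrom, start, end)
    or, failing that, from the extent of the genes annotated to each arm.
    """
    if arm_table is None:
        if genes is None or "arm" not in genes.columns:
            raise ValueError("provide arm_table or a gene model with an 'arm' column")
        arm_table = (
            genes.groupby("arm")
            .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
            .reset_index()
        )
    if segments.empty:
        warnings.warn("empty segment table: arm score matrix is all-missing")
        return pd.DataFrame(index=arm_table["arm"], columns=[], dtype=float)
    iv = arm_table.rename(columns={"start": "start_iv", "end": "end_iv"})[
        ["arm", "chrom", "start_iv", "end_iv"]
    ]
    seg = segments.rename(columns={"start": "start_seg", "end": "end_seg"})
    joined = _overlap_join(iv, seg)
    mat = _weighted_mean_matrix(joined, "arm")
    return mat.reindex(index=arm_table["arm"], columns=sorted(segments["sample"].unique()))


def call_amp_del(values: pd.DataFrame, cutoff: float = 1.0) -> pd.DataFrame:
    """Categorical SCNA calls: amplified if value >= cutoff, deleted if
    value <= -cutoff, else neutral.  Boundary values are called (inclusive)."""
    if not np.isfinite(cutoff) or cutoff <= 0:
        raise ValueError("cutoff must be a finite positive number")
    arr = values.to_numpy(dtype=float)
    out = np.full(arr.shape, "neutral", dtype=object)
    out[arr >= cutoff] = "amplified"
    out[arr <= -cutoff] = "deleted"
    out[~np.isfinite(arr)] = "missing"
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def tmb(mutations: pd.DataFrame, coding_mb: float, samples=None) -> pd.Series:
    """Tumor mutational burden: coding mutations per megabase.

    All somatic variants in the table (SNVs and indels, synonymous
    included) are counted and divided by the captured coding-region size
    in Mb.  ``samples`` optionally fixes the output index so that
    zero-mutation samples report 0 rather than being absent.
    """
    if coding_mb <= 0:
        raise ValueError("coding_mb must be positive")
    counts = mutations.groupby("sample").size()
    if samples is not None:
        counts = counts.reindex(samples, fill_value=0)
    return counts / coding_mb


def context_matrix(mutations: pd.DataFrame, samples=None) -> pd.DataFrame:
    """96 x samples matrix of single-nucleotide-variant context counts.

    Each SNV carries its reference-strand trinucleotide ``context``
    (5' base, ref, 3' base).  Purine-reference variants are collapsed to
    the pyrimidine convention by reverse complement, giving the six
    substitution classes C>A, C>G, C>T, T>A, T>C, T>G with 16 flanking
    combinations each.  Non-SNV rows (multi-base ref/alt) are ignored.
    Column sums equal per-sample SNV counts.
    """
    if samples is None:
        samples = sorted(mutations["sample"].unique())
    mat = pd.DataFrame(0, index=pd.Index(CONTEXTS_96, name="context"), columns=samples)
    if mutations.empty:
        return mat
    snv = mutations[
        mutations["ref"].astype(str).str.len().eq(1)
        & mutations["alt"].astype(str).str.len().eq(1)
        & mutations["ref"].ne("-")
        & mutations["alt"].ne("-")
    ]
    for idx, row in snv.iterrows():
        ref, alt, ctx = str(row["ref"]), str(row["alt"]), str(row["context"])
        if len(ctx) != 3 or ctx[1] != ref:
            raise ValueError(f"row {idx}: context {ctx!r} inconsistent with ref {ref!r}")
        if any(b not in _BASES for b in ctx + alt):
            raise ValueError(f"row {idx}: unknown base symbol in {ctx!r}>{alt!r}")
        if ref in "AG":  # collapse to pyrimidine reference strand
            ctx = _revcomp(ctx)
            ref = ctx[1]
            alt = alt.translate(_COMPLEMENT)
        label = f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"
        mat.loc[label, row["sample"]] += 1
    return mat


# ---------------------------------------------------------------------------
# mutational signatures


@dataclass
class SignatureFit:
    """NMF decomposition of a 96-context matrix with reference matching."""

    profiles: pd.DataFrame  # 96 x k, columns sum to 1
    exposures: pd.DataFrame  # k x samples, non-negative
    cosine: pd.DataFrame  # k x R cosine similarity to reference profiles
    matched: dict  # signature name -> best-matching reference name
    objective_trace: list = field(default_factory=list)  # Frobenius errors, best restart


def _nmf_mu(V: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float):
    """Multiplicative-update NMF, Frobenius objective.

    Returns (W, H, trace); the trace of reconstruction errors is
    non-increasing by construction of the Lee-Seung updates.
    """
    n, m = V.shape
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, m)) * scale
    eps = 1e-12
    trace = [float(np.linalg.norm(V - W @ H))]
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ H @ H.T + eps)
        err = float(np.linalg.norm(V - W @ H))
        trace.append(err)
        prev = trace[-2]
        if prev > 0 and (prev - err) / prev < tol:
            break
    return W, H, trace


def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise cosine similarities: result[i, j] = cos(A[:, i], B[:, j])."""
    An = A / np.maximum(np.linalg.norm(A, axis=0, keepdims=True), 1e-300)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0, keepdims=True), 1e-300)
    return An.T @ Bn


def extract_signatures(
    contexts: pd.DataFrame,
    k: int,
    reference: pd.DataFrame,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> SignatureFit:
    """Extract ``k`` mutational signatures by NMF and match them to references.

    The 96 x samples count matrix is factorized with multiplicative
    updates (Frobenius objective), best of ``n_restarts`` random
    initializations.  Profiles are column-normalized to probability
    vectors (exposures rescaled accordingly) and each is assigned the
    reference signature with maximal cosine similarity.

    Samples with zero mutations are dropped with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    col_ok = contexts.sum(axis=0) > 0
    if not col_ok.all():
        warnings.warn(f"dropping {int((~col_ok).sum())} zero-count sample(s)")
    V_df = contexts.loc[:, col_ok]
    if k > min(contexts.shape[0], V_df.shape[1]):
        raise ValueError(f"k={k} exceeds min(96, n_samples={V_df.shape[1]})")
    V = V_df.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        W, H, trace = _nmf_mu(V, k, rng, max_iter, tol)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    W, H, trace = best
    colsum = W.sum(axis=0)
    colsum[colsum == 0] = 1.0
    profiles = W / colsum
    exposures = H * colsum[:, None]
    names = [f"Sig{i + 1}" for i in range(k)]
    ref = reference.reindex(index=contexts.index)
    cos = cosine_similarity_matrix(profiles, ref.to_numpy(dtype=float))
    cos_df = pd.DataFrame(cos, index=names, columns=ref.columns)
    matched = {name: cos_df.loc[name].idxmax() for name in names}
    return SignatureFit(
        profiles=pd.DataFrame(profiles, index=contexts.index, columns=names),
        exposures=pd.DataFrame(exposures, index=names, columns=V_df.columns),
        cosine=cos_df,
        matched=matched,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# co-occurrence / mutual exclusivity


def cooccurrence(events: pd.DataFrame, pairs=None) -> pd.DataFrame:
    """Pairwise Fisher's exact tests of binary event co-occurrence.

    Parameters
    ----------
    events
        Binary features x samples matrix (1 = event present).
    pairs
        Iterable of (feature_a, feature_b); all unordered pairs if None.

    Returns a table with odds ratio, two-sided Fisher p, BH q and a
    direction label (co-occurring if OR > 1, mutually exclusive
    otherwise).  Degenerate margins (a feature present in all or no
    samples) yield p = 1 and are flagged.
    """
    E = events.astype(bool)
    feats = list(E.index)
    if pairs is None:
        pairs = [(feats[i], feats[j]) for i in range(len(feats)) for j in range(i + 1, len(feats))]
    rows = []
    for a, b in pairs:
        va, vb = E.loc[a].to_numpy(), E.loc[b].to_numpy()
        n11 = int(np.sum(va & vb))
        n10 = int(np.sum(va & ~vb))
        n01 = int(np.sum(~va & vb))
        n00 = int(np.sum(~va & ~vb))
        degenerate = va.all() or (~va).all() or vb.all() or (~vb).all()
        if degenerate:
            orat, p = np.nan, 1.0
        else:
            orat, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
        direction = "co-occurring" if (np.isnan(orat) or orat > 1) else "exclusive"
        rows.append(
            dict(
                feature_a=a, feature_b=b, n11=n11, n10=n10, n01=n01, n00=n00,
                odds_ratio=orat, p=p, direction=direction, degenerate=degenerate,
            )
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    return out
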