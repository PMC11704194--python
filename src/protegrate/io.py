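"""Readers and writers for the plain-text formats the pipeline consumes.

SEG (segment tables), MAF-like mutation TSVs, GCT 1.2 and plain TSV
abundance matrices, GMT gene sets, kinase-substrate relation TSVs and
survival tables.  All formats are tab-separated text; genomic
coordinates are 1-based inclusive (SEG convention).
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from protegrate.core import MAF_COLUMNS, OmicsMatrix

# SEG files use the DNAcopy column names
_SEG_FILE_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
_SEG_RENAME = dict(zip(_SEG_FILE_COLUMNS, ["sample", "chrom", "start", "end", "nmark", "log2"]))


def read_seg(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in _SEG_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file {path} missing columns: {missing}")
    df = df.rename(columns=_SEG_RENAME)
    return df[["sample", "chrom", "start", "end", "nmark", "log2"]]


def write_seg(path: str | os.PathLike, segments: pd.DataFrame, header: str | None = None) -> None:
    out = segments.rename(columns={v: k for k, v in _SEG_RENAME.items()})
    _write_with_header(path, out[_SEG_FILE_COLUMNS], header)


def read_maf(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "context": str})
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table {path} missing columns: {missing}")
    return df[MAF_COLUMNS]


def write_maf(path: str | os.PathLike, mutations: pd.DataFrame, header: str | None = None) -> None:
    _write_with_header(path, mutations[MAF_COLUMNS], header)


def read_gct(path: str | os.PathLike) -> pd.DataFrame:
    """Read a GCT 1.2 matrix into a features x samples DataFrame."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "1.2"):
            raise ValueError(f"{path}: expected GCT 1.2, got header {version!r}")
        fh.readline()  # dimensions line; pandas infers them
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df.drop(columns=["Description"], errors="ignore")


def write_gct(path: str | os.PathLike, matrix: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        out = matrix.copy()
        out.insert(0, "Description", "na")
        out.index.name = "Name"
        out.to_csv(fh, sep="\t")


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_matrix_tsv(path: str | os.PathLike, matrix: pd.DataFrame, header: str | None = None) -> None:
    _write_with_header(path, matrix, header, index=True)


def read_omics_matrix(path: str | os.PathLike, layer: str = "protein") -> OmicsMatrix:
    path = Path(path)
    data = read_gct(path) if path.suffix.lower() == ".gct" else read_matrix_tsv(path)
    return OmicsMatrix(data=data, layer=layer)


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, name TAB description TAB members..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(path: str | os.PathLike, sets: dict[str, list[str]], description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_survival(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample", "os_time", "os_event"):
        if col not in df.columns:
            raise ValueError(f"survival table {path} missing column {col!r}")
    return df


def write_survival(path: str | os.PathLike, survival: pd.DataFrame, header: str | None = None) -> None:
    _write_with_header(path, survival, header)


def read_kinase_substrates(path: str | os.PathLike, min_networkin_score: float = 1.0) -> pd.DataFrame:
    """Read a kinase-substrate relation TSV (kinase, substrate, site, source[, score]).

    NetworKIN-style predicted relations carry a score and are kept only when
    the score exceeds ``min_networkin_score``; curated rows (no score) pass.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("kinase", "substrate", "site"):
        if col not in df.columns:
            raise ValueError(f"kinase-substrate table {path} missing column {col!r}")
    if "score" in df.columns:
        keep = df["score"].isna() | (df["score"] > min_networkin_score)
        df = df[keep]
    df = df.drop_duplicates(subset=["kinase", "substrate", "site"])
    return df.reset_index(drop=True)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Protein sequences keyed by record id (first token of the header)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One symbol per line (e.g. a cancer-associated-gene list)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def _write_with_header(path, df: pd.DataFrame, header: str | None, index: bool = False) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)
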