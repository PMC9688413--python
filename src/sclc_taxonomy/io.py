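"""Readers and writers for the on-disk formats.

Formats: GMT gene sets, expression TSV (genes as rows, first column gene id),
MatrixMarket sparse UMI matrices with features/barcodes sidecars, and the
clinical CSV with survival and immunohistochemistry columns. All round-trips
preserve row/column order and content.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .matrix import ExpressionMatrix, GeneSetCollection, ValidationError

CLINICAL_REQUIRED = [
    "sample_id",
    "os_time",
    "os_event",
    "vimentin_proportion",
    "vimentin_intensity",
    "cd8_f1",
    "cd8_f2",
    "cd8_f3",
    "cd8_f4",
    "cd8_f5",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- GMT


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = sorted(collection[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------- expression TSV


def read_expression_tsv(path, unit: str) -> ExpressionMatrix:
    """Genes-as-rows TSV; first column holds gene ids, header holds sample ids."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: expected a gene-id column plus >=1 sample column")
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set = set()
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {len(header)})"
                )
            gid = parts[0]
            if gid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            gene_ids.append(gid)
    return ExpressionMatrix(np.asarray(rows, dtype=float), gene_ids, sample_ids, unit)


def write_expression_tsv(expr: ExpressionMatrix, path, gene_col: str = "gene_id") -> None:
    df = expr.to_frame()
    df.index.name = gene_col
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_gene_lengths_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (gene_id, length)")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
    if s.index.has_duplicates:
        raise ParseError(f"{path}: duplicate gene ids in length table")
    return s


def write_gene_lengths_tsv(lengths: pd.Series, path) -> None:
    df = pd.DataFrame({"gene_id": lengths.index, "length": lengths.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- MTX (single cell)


def read_mtx_dir(directory) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read a 10x-style triplet: matrix.mtx (genes × cells), features.tsv, barcodes.tsv.

    Cells whose column holds no explicit entries are retained as zero vectors
    (the MTX header fixes the full dimensions).
    """
    mat = spio.mmread(os.path.join(directory, "matrix.mtx")).tocsr()
    with open(os.path.join(directory, "features.tsv")) as fh:
        features = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with open(os.path.join(directory, "barcodes.tsv")) as fh:
        barcodes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if mat.shape != (len(features), len(barcodes)):
        raise ParseError(
            f"{directory}: matrix shape {mat.shape} inconsistent with "
            f"{len(features)} features / {len(barcodes)} barcodes"
        )
    return mat, features, barcodes


def write_mtx_dir(matrix, features, barcodes, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    spio.mmwrite(os.path.join(directory, "matrix.mtx"), sp.coo_matrix(matrix))
    with open(os.path.join(directory, "features.tsv"), "w") as fh:
        fh.writelines(f"{f}\n" for f in features)
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        fh.writelines(f"{b}\n" for b in barcodes)


# ---------------------------------------------------------------- clinical CSV


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    for col in CLINICAL_REQUIRED[1:]:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ParseError(f"{path}: column {col!r} is not numeric")
    if (df["os_time"] <= 0).any():
        raise ValidationError(f"{path}: os_time must be positive")
    if not df["os_event"].isin([0, 1]).all():
        raise ValidationError(f"{path}: os_event must be 0/1")
    return df


def write_clinical_csv(df: pd.DataFrame, path) -> None:
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns {missing}")
    df.to_csv(path, index=False)
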