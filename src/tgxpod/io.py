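"""Readers and writers for the pipeline's standard file formats.

All tabular formats are UTF-8 tab-separated with a header row and '.'
decimals; dose columns are always linear mg/kg/day.  Expression matrices
travel either as dense TSV (genes x samples) or MatrixMarket coordinate
files plus row/column annotation TSVs.  Gene sets use the standard GMT
layout (set name, description, member gene ids, tab-separated).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .genebmd import GeneDoseMatrix
from .pod import GeneSetCollection

__all__ = [
    "read_apical", "write_apical",
    "read_deg_table", "write_deg_table",
    "read_expression", "write_expression",
    "read_expression_mtx", "write_expression_mtx",
    "read_gmt", "write_gmt",
]

_APICAL_INDIVIDUAL = {"series", "dose", "value"}
_APICAL_SUMMARY = {"series", "dose", "n", "mean", "sd"}
_DEG_REQUIRED = {"gene", "dose", "fdr"}


def _require(df: pd.DataFrame, required: set[str], path, kind: str):
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{path}: {kind} table is missing columns {missing}")


def read_apical(path) -> pd.DataFrame:
    """Apical endpoint TSV; layout auto-detected from its columns."""
    df = pd.read_csv(path, sep="\t")
    if _APICAL_INDIVIDUAL <= set(df.columns):
        return df
    if _APICAL_SUMMARY <= set(df.columns):
        return df
    raise ValueError(
        f"{path}: apical table needs columns {sorted(_APICAL_INDIVIDUAL)} "
        f"(individual) or {sorted(_APICAL_SUMMARY)} (summary)")


def write_apical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, _DEG_REQUIRED, path, "DE")
    if "fc" not in df.columns and "log2fc" not in df.columns:
        raise ValueError(f"{path}: DE table needs an 'fc' or 'log2fc' column")
    return df


def write_deg_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _read_meta(meta_path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t")
    _require(meta, {"sample", "dose"}, meta_path, "sample metadata")
    return meta


def read_expression(matrix_path, meta_path, raw_path=None) -> GeneDoseMatrix:
    """Dense TSV expression matrix (first column gene id) + metadata TSV."""
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = _read_meta(meta_path)
    missing = sorted(set(meta["sample"]) - set(mat.columns))
    if missing:
        raise ValueError(f"{matrix_path}: samples {missing} in metadata "
                         "but not in the matrix")
    mat = mat[meta["sample"].tolist()]
    raw = None
    if raw_path is not None:
        rawdf = pd.read_csv(raw_path, sep="\t", index_col=0)
        raw = rawdf.loc[mat.index, meta["sample"].tolist()].to_numpy(float)
    return GeneDoseMatrix(genes=list(mat.index),
                          doses=meta["dose"].to_numpy(float),
                          log2=mat.to_numpy(float), raw=raw, meta=meta)


def write_expression(matrix: GeneDoseMatrix, matrix_path, meta_path,
                     raw_path=None) -> None:
    cols = (matrix.meta["sample"].tolist() if matrix.meta is not None
            else [f"s{j + 1:02d}" for j in range(matrix.doses.size)])
    pd.DataFrame(matrix.log2, index=pd.Index(matrix.genes, name="gene"),
                 columns=cols).to_csv(matrix_path, sep="\t")
    meta = matrix.meta if matrix.meta is not None else pd.DataFrame(
        {"sample": cols, "dose": matrix.doses})
    meta.to_csv(meta_path, sep="\t", index=False)
    if raw_path is not None and matrix.raw is not None:
        pd.DataFrame(matrix.raw, index=pd.Index(matrix.genes, name="gene"),
                     columns=cols).to_csv(raw_path, sep="\t")


def read_expression_mtx(mtx_path, genes_path, meta_path) -> GeneDoseMatrix:
    """MatrixMarket coordinate matrix; explicit zeros are preserved."""
    mat = sio.mmread(mtx_path)
    if sp.issparse(mat):
        mat = mat.toarray()
    genes = pd.read_csv(genes_path, sep="\t")["gene"].tolist()
    meta = _read_meta(meta_path)
    return GeneDoseMatrix(genes=genes, doses=meta["dose"].to_numpy(float),
                          log2=np.asarray(mat, float), meta=meta)


def write_expression_mtx(matrix: GeneDoseMatrix, mtx_path, genes_path,
                         meta_path) -> None:
    sio.mmwrite(str(mtx_path), sp.coo_matrix(matrix.log2))
    pd.DataFrame({"gene": matrix.genes}).to_csv(genes_path, sep="\t", index=False)
    meta = matrix.meta if matrix.meta is not None else pd.DataFrame(
        {"sample": [f"s{j + 1:02d}" for j in range(matrix.doses.size)],
         "dose": matrix.doses})
    meta.to_csv(meta_path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Standard GMT: one set per line — name, description, member ids."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs a name, description "
                    "and at least one member gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {f for f in fields[2:] if f.strip()}
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na",
                                *sorted(members)]) + "\n")
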