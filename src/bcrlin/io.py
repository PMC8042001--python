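"""Readers and writers for the package's plain-text interchange formats.

Rearrangements travel as AIRR-style TSV (booleans encoded T/F), per-cell
metadata as TSV, expression as Matrix-Market (genes x cells, Cell Ranger
orientation) with ``genes.tsv`` / ``barcodes.tsv`` sidecars, and gene sets
as newline-delimited lists.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "read_rearrangements",
    "write_rearrangements",
    "read_cell_meta",
    "write_cell_meta",
    "read_expression_mtx",
    "write_expression_mtx",
    "read_gene_list",
]

_BOOL_COLUMNS = ("productive",)


def write_rearrangements(records: pd.DataFrame, path: str | Path) -> None:
    out = records.copy()
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map({True: "T", False: "F"})
    out.to_csv(path, sep="\t", index=False)


def read_rearrangements(path: str | Path) -> pd.DataFrame:
    records = pd.read_csv(path, sep="\t", dtype={"junction": str, "junction_aa": str,
                                                 "sequence": str, "c_call": str,
                                                 "d_call": str})
    for col in _BOOL_COLUMNS:
        if col in records.columns:
            records[col] = records[col].map({"T": True, "F": False,
                                             True: True, False: False})
    for col in ("junction", "junction_aa", "sequence", "c_call", "d_call"):
        if col in records.columns:
            records[col] = records[col].fillna("")
    return records


def write_cell_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_mtx(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write a cells x genes AnnData as genes x cells MTX with sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    mat = sp.coo_matrix(x.T if sp.issparse(x) else sp.csr_matrix(x).T)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)


def read_expression_mtx(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    mat = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")).T)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    return ad.AnnData(X=mat,
                      obs=pd.DataFrame(index=pd.Index(barcodes, name=None)),
                      var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
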