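"""Cell- and chain-level quality control for paired scRNA-seq + VDJ data.

Implements four filters applied before any repertoire statistic:

* a doublet *budget*: how many barcodes to discard per library as a linear
  function of the detected cell number (the per-cell doublet score itself is
  supplied by the caller, e.g. a DoubletFinder pANN column);
* gene-count and mitochondrial-fraction cell filters;
* selection of a single productive IGH contig per cell, keeping the most
  abundant contig only when its UMI support is more than 10-fold that of the
  runner-up (cells failing this are treated as B-cell doublets);
* removal of BCR/TCR double-positive barcodes (TCR positivity requires both
  a TRA and a TRB contig).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DoubletBudget",
    "DataError",
    "doublet_exclusion_count",
    "doublet_exclusion_raw",
    "exclude_top_scored",
    "qc_filter_cells",
    "select_single_productive_igh",
    "select_single_productive_igh_table",
    "flag_bcr_tcr_doublets",
]


class DataError(ValueError):
    """Raised when an input table violates a documented contract."""


@dataclass(frozen=True)
class DoubletBudget:
    """Number of barcodes to exclude (``n_exclude``) out of ``n_detected``."""

    n_detected: int
    n_exclude: int


def doublet_exclusion_raw(n_detected: int | float) -> float:
    """Expected doublet count before flooring: (0.000879·N + 0.702)·0.01·N.

    The linear term reflects the rise of the droplet collision rate with
    loading density on the 10x platform.
    """
    if n_detected < 0:
        raise ValueError(f"detected cell count must be >= 0, got {n_detected}")
    n = float(n_detected)
    return (0.000879 * n + 0.702) * 0.01 * n


def doublet_exclusion_count(n_detected: int) -> DoubletBudget:
    """Doublet budget for a library of ``n_detected`` barcodes.

    The raw value is floored: a fractional cell cannot be excluded, and
    flooring is the conservative choice. Monotone non-decreasing in N.
    """
    if not float(n_detected).is_integer() or n_detected < 0:
        raise ValueError(f"detected cell count must be a non-negative integer, got {n_detected}")
    return DoubletBudget(int(n_detected), int(math.floor(doublet_exclusion_raw(n_detected))))


def exclude_top_scored(
    meta: pd.DataFrame,
    scores: Mapping[str, float] | pd.Series,
    n_exclude: int,
    cell_col: str = "cell_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop the ``n_exclude`` cells with the highest doublet score.

    Ties at the cut are broken by ascending barcode, so the retained set is
    stable across runs. Returns ``(retained, removed)``.
    """
    scores = pd.Series(scores)
    missing = meta[cell_col][~meta[cell_col].isin(scores.index)]
    if len(missing):
        raise DataError(f"no doublet score for cells: {sorted(missing)[:10]}")
    if n_exclude < 0 or n_exclude > len(meta):
        raise ValueError(f"n_exclude must be in [0, {len(meta)}], got {n_exclude}")
    if n_exclude == 0:
        return meta.copy(), meta.iloc[0:0].copy()
    order = meta.assign(_score=meta[cell_col].map(scores)).sort_values(
        ["_score", cell_col], ascending=[False, True], kind="mergesort"
    )
    removed = order.iloc[:n_exclude].drop(columns="_score")
    retained = meta.loc[meta.index.difference(removed.index)].sort_index()
    return retained, removed.sort_index()


_QC_REASONS = ("low_genes", "high_genes", "high_mito")


def qc_filter_cells(
    meta: pd.DataFrame,
    min_genes: int = 200,
    max_genes: int = 5000,
    max_mito: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression-level cell filter.

    A cell is retained iff ``min_genes <= n_genes <= max_genes`` and
    ``mito_fraction <= max_mito``; the bounds themselves are retained (the
    exclusion criteria are strict: fewer than 200 or more than 5000 genes,
    more than 50% mitochondrial UMIs). Returns ``(retained, rejection_log)``
    where the log has columns ``cell_id`` and ``reason`` (first failing
    check among low_genes, high_genes, high_mito).
    """
    n_genes = meta["n_genes"]
    mito = meta["mito_fraction"]
    reason = np.select(
        [n_genes < min_genes, n_genes > max_genes, mito > max_mito],
        _QC_REASONS,
        default="",
    )
    retained = meta[reason == ""].copy()
    log = pd.DataFrame({
        "cell_id": meta.loc[reason != "", "cell_id"],
        "reason": reason[reason != ""],
    }).reset_index(drop=True)
    return retained, log


def select_single_productive_igh(
    contigs: pd.DataFrame,
    fold: float = 10.0,
) -> tuple[pd.Series | None, str | None]:
    """Select one productive IGH contig for a single cell.

    * exactly one productive IGH: returned regardless of UMI count;
    * two or more: the most abundant is kept only when its UMI count is more
      than ``fold`` times (strictly) that of the second most abundant,
      otherwise the cell is rejected as ``multi_productive`` (a putative
      B-cell doublet);
    * none productive: rejected as ``none_productive``.

    Non-productive contigs never enter the ratio test. With three or more
    productive contigs only the top two are compared. Equal UMI counts are
    ordered by sequence for a deterministic dominant contig.

    Returns ``(record, None)`` on success or ``(None, reason)``.
    """
    if len(contigs) == 0:
        raise ValueError("no contigs supplied for cell")
    if (contigs["locus"] != "IGH").any():
        raise DataError("select_single_productive_igh expects only IGH contigs")
    if contigs["cell_id"].nunique() > 1:
        raise DataError("contigs from more than one cell supplied")
    prod = contigs[contigs["productive"].astype(bool)]
    if len(prod) == 0:
        return None, "none_productive"
    prod = prod.sort_values(["duplicate_count", "sequence"],
                            ascending=[False, True], kind="mergesort")
    if len(prod) == 1:
        return prod.iloc[0], None
    top, second = prod.iloc[0], prod.iloc[1]
    if top["duplicate_count"] > fold * second["duplicate_count"]:
        return top, None
    return None, "multi_productive"


def select_single_productive_igh_table(
    records: pd.DataFrame,
    fold: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply :func:`select_single_productive_igh` across a rearrangement table.

    Considers only IGH-locus rows; other loci are ignored here (see
    :func:`flag_bcr_tcr_doublets` for TCR handling). Returns
    ``(selected, rejections)``: one selected row per retained cell, and a
    log with columns ``cell_id`` and ``reason``.
    """
    igh = records[records["locus"] == "IGH"]
    selected: list[pd.Series] = []
    rejected: list[tuple[str, str]] = []
    for cell_id, contigs in igh.groupby("cell_id", sort=True):
        record, reason = select_single_productive_igh(contigs, fold=fold)
        if record is not None:
            selected.append(record)
        else:
            rejected.append((cell_id, reason))
    selected_df = (pd.DataFrame(selected).reset_index(drop=True)
                   if selected else igh.iloc[0:0].copy())
    rejections = pd.DataFrame(rejected, columns=["cell_id", "reason"])
    return selected_df, rejections


def flag_bcr_tcr_doublets(records: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    """Partition barcodes into the B-cell set and BCR/TCR double positives.

    BCR-positive: at least one IGH contig. TCR-positive: both a TRA and a
    TRB contig assembled (a TRA alone does not make a cell TCR-positive).
    The B-cell set is BCR-positive AND NOT TCR-positive; double positives
    are flagged for removal before B-cell subgrouping. Returns
    ``(b_cell_ids, flagged_ids)``, both sorted.
    """
    loci = records.groupby("cell_id")["locus"].agg(set)
    bcr = loci.map(lambda s: "IGH" in s)
    tcr = loci.map(lambda s: "TRA" in s and "TRB" in s)
    b_cells = loci.index[bcr & ~tcr]
    flagged = loci.index[bcr & tcr]
    return pd.Index(sorted(b_cells)), pd.Index(sorted(flagged))
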