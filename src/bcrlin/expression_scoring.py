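"""Signature scoring, cell-cycle scoring and tertile survival stratification.

Gene-set signature scores follow the relative-expression heatmap recipe:
library-size normalize each cell to a fixed total, log-transform, average
the member genes per cell, z-score that value across all cells, then report
the mean z-score per cluster.

Two cell-cycle quantities are computed. The *cycle score* is simply the
fraction of a cell's UMIs falling in cell-cycle genes. The S and G2/M
*module scores* are mean normalized expression of the respective gene list
minus a size-matched random background (a simple, seeded stand-in for
binned background schemes); the phase call applies fixed threshold rules:
S when s > 0.1 and s > g2m, G2/M when g2m > 0.1 and g2m > s, otherwise
"other" (ties and sub-threshold scores satisfy neither strict comparison).

Survival stratification selects the top and bottom floor(n x fraction)
patients by signature score (92 of 279 at the default 33%), leaving the
middle out; downstream Kaplan-Meier / Cox fitting is delegated to any
standard survival package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc

from .repertoire_qc import DataError

__all__ = [
    "SignatureScore",
    "StratificationResult",
    "normalize_log",
    "normalize_and_zscore",
    "cell_cycle_score",
    "module_score",
    "assign_phase",
    "assign_phases",
    "cell_cycle_phases",
    "stratify_patients",
]


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Library-size normalize each cell to ``target_sum`` and log(1+x)."""
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    return out


def _present_genes(adata: ad.AnnData, genes, label: str) -> list[str]:
    genes = list(genes)
    present = [g for g in genes if g in adata.var_names]
    missing = sorted(set(genes) - set(present))
    if not present:
        raise DataError(f"none of the {label} genes are present in the matrix")
    if missing:
        warnings.warn(f"{len(missing)} {label} gene(s) absent from the matrix: "
                      f"{missing[:10]}")
    return present


def _dense_mean(adata: ad.AnnData, genes: list[str]) -> np.ndarray:
    x = adata[:, genes].X
    x = x.toarray() if hasattr(x, "toarray") else np.asarray(x)
    return np.asarray(x, dtype=np.float64).mean(axis=1).ravel()


@dataclass
class SignatureScore:
    """Per-cell z-scored signature values and their per-cluster means."""

    name: str
    genes_used: list[str]
    per_cell: pd.Series  # z-scores, mean 0 / SD 1 across all cells
    cluster_means: pd.Series


def normalize_and_zscore(
    adata: ad.AnnData,
    gene_set,
    name: str = "signature",
    cluster_key: str = "cluster_high",
    target_sum: float = 1e4,
) -> SignatureScore:
    """Score a gene set per cell and summarize per cluster.

    Per-cell value: mean over the present set genes of library-size
    normalized, log-transformed expression; z-scored across all cells
    (a zero-variance score is defined as all zeros, not NaN). Genes absent
    from the matrix are dropped with a warning; an entirely absent set is
    an error.
    """
    genes = _present_genes(adata, gene_set, name)
    norm = normalize_log(adata, target_sum=target_sum)
    raw = _dense_mean(norm, genes)
    sd = raw.std()
    # zero-variance scores (constant input up to float noise) are defined as 0
    if sd <= 1e-12 * max(1.0, float(np.abs(raw).max(initial=0.0))):
        z = np.zeros_like(raw)
    else:
        z = (raw - raw.mean()) / sd
    per_cell = pd.Series(z, index=adata.obs_names, name=name)
    if cluster_key not in adata.obs:
        raise DataError(f"obs lacks cluster column {cluster_key!r}")
    cluster_means = per_cell.groupby(adata.obs[cluster_key], observed=True).mean()
    cluster_means.name = name
    return SignatureScore(name=name, genes_used=genes,
                          per_cell=per_cell, cluster_means=cluster_means.sort_index())


def cell_cycle_score(adata: ad.AnnData, cc_genes) -> pd.Series:
    """Fraction of each cell's total UMIs in cell-cycle genes (raw counts)."""
    genes = _present_genes(adata, cc_genes, "cell-cycle")
    x = adata.X
    totals = np.asarray(x.sum(axis=1)).ravel()
    zero = adata.obs_names[totals == 0]
    if len(zero):
        raise DataError(f"cells with zero total UMIs: {list(zero[:10])}")
    cc = adata[:, genes].X
    cc_totals = np.asarray(cc.sum(axis=1)).ravel()
    return pd.Series(cc_totals / totals, index=adata.obs_names, name="cycle_score")


def module_score(
    adata_norm: ad.AnnData,
    genes,
    seed: int = 0,
    label: str = "module",
) -> pd.Series:
    """Mean normalized expression of a gene list minus a random background.

    The background is a size-matched, seeded random draw from the genes not
    in the list, so the score is centred near zero for an unremarkable cell.
    ``adata_norm`` must already be normalized/log-transformed
    (:func:`normalize_log`).
    """
    genes = _present_genes(adata_norm, genes, label)
    others = [g for g in adata_norm.var_names if g not in set(genes)]
    if not others:
        raise DataError("no background genes available for module scoring")
    rng = np.random.default_rng(seed)
    background = list(rng.choice(others, size=min(len(genes), len(others)), replace=False))
    score = _dense_mean(adata_norm, genes) - _dense_mean(adata_norm, background)
    return pd.Series(score, index=adata_norm.obs_names, name=f"{label}_score")


def assign_phase(s_score: float, g2m_score: float, threshold: float = 0.1) -> str:
    """Phase call from S and G2/M module scores.

    S when ``s > threshold`` and ``s > g2m``; G2M when ``g2m > threshold``
    and ``g2m > s``; otherwise ``other`` — an exact tie or two sub-threshold
    scores satisfies neither strict comparison.
    """
    if not (np.isfinite(s_score) and np.isfinite(g2m_score)):
        raise ValueError("phase scores must be finite")
    if s_score > threshold and s_score > g2m_score:
        return "S"
    if g2m_score > threshold and g2m_score > s_score:
        return "G2M"
    return "other"


def assign_phases(s_scores, g2m_scores, threshold: float = 0.1) -> np.ndarray:
    """Vectorized :func:`assign_phase`."""
    s = np.asarray(s_scores, dtype=float)
    g = np.asarray(g2m_scores, dtype=float)
    if not (np.isfinite(s).all() and np.isfinite(g).all()):
        raise ValueError("phase scores must be finite")
    return np.select([(s > threshold) & (s > g), (g > threshold) & (g > s)],
                     ["S", "G2M"], default="other")


def cell_cycle_phases(
    adata: ad.AnnData,
    s_genes,
    g2m_genes,
    seed: int = 0,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """S/G2M module scores and phase calls for every cell."""
    norm = normalize_log(adata)
    s = module_score(norm, s_genes, seed=seed, label="s")
    g2m = module_score(norm, g2m_genes, seed=seed + 1, label="g2m")
    return pd.DataFrame({
        "s_score": s,
        "g2m_score": g2m,
        "phase": assign_phases(s.to_numpy(), g2m.to_numpy(), threshold=threshold),
    }, index=adata.obs_names)


@dataclass
class StratificationResult:
    """Top / bottom score tertiles of a scored patient cohort."""

    top: pd.DataFrame
    bottom: pd.DataFrame
    middle: pd.DataFrame
    group_size: int


def stratify_patients(
    records: pd.DataFrame,
    fraction: float = 0.33,
    score_col: str = "score",
    id_col: str = "patient_id",
) -> StratificationResult:
    """Split a scored cohort into top/bottom ``fraction`` groups.

    ``k = floor(n * fraction)`` patients enter each group (92 per group for
    n = 279 at 33%); the middle is excluded. Ties are broken by ascending
    patient id, so groups are deterministic, disjoint and of size k even
    when all scores are equal.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    n = len(records)
    if n < 3:
        raise ValueError(f"need at least 3 patients, got {n}")
    scores = pd.to_numeric(records[score_col], errors="raise")
    if not np.isfinite(scores).all():
        raise DataError("non-finite signature scores")
    k = int(np.floor(n * fraction))
    order = records.sort_values([score_col, id_col], kind="mergesort")
    bottom = order.iloc[:k]
    top = order.iloc[n - k:]
    middle = order.iloc[k : n - k]
    return StratificationResult(top=top.reset_index(drop=True),
                                bottom=bottom.reset_index(drop=True),
                                middle=middle.reset_index(drop=True),
                                group_size=k)
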