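"""Clone calling, SHM and class-switch statistics, public-clone matching.

Clonally related B cells are defined by a shared inferred germline
rearrangement: the same V, D and J gene usage (allele suffixes stripped)
and the same junction length in nucleotides. Junction *sequence* identity
is deliberately not required — members of a clone diverge by somatic
hypermutation (SHM).

SHM counts and frequencies are computed over the V and J segments only
(the D segment and the junction are excluded), so a "germline" cell is one
with zero V+J mutations. Class-switched cells are those whose constant
region is neither IGHM nor IGHD.

Public clones are clonotypes — (V gene, J gene, CDRH3 amino-acid sequence)
triples — observed in two independent cohorts; their frequency is the
number of shared unique clonotypes over the number of unique clonotypes in
the study cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire_qc import DataError

__all__ = [
    "BcrStatus",
    "PublicCloneResult",
    "RepertoireSummary",
    "strip_allele",
    "assign_clones",
    "shm_stats",
    "add_shm_stats",
    "classify_bcr_status",
    "add_bcr_status",
    "repertoire_summary",
    "unique_clonotypes",
    "public_clone_fraction",
    "public_clone_chi2",
]

_ISOTYPE_PREFIXES = (
    ("IGHG", "IGG"), ("IGHA", "IGA"), ("IGHM", "IGM"), ("IGHD", "IGD"), ("IGHE", "IGE"),
)
ISOTYPE_CLASSES = ("IGM", "IGD", "IGG", "IGA", "IGE", "unknown")
_UNSWITCHED = {"IGM", "IGD"}


def strip_allele(call: object) -> str:
    """``IGHV3-23*01`` → ``IGHV3-23``; missing calls → empty string."""
    if call is None or (isinstance(call, float) and np.isnan(call)):
        return ""
    return str(call).split("*")[0]


# ---------------------------------------------------------------------------
# clone calling
# ---------------------------------------------------------------------------


def _clone_keys(records: pd.DataFrame, use_allele: bool) -> pd.DataFrame:
    norm = (lambda s: s.fillna("").astype(str)) if use_allele else \
        (lambda s: s.map(strip_allele))
    return pd.DataFrame({
        "v_gene": norm(records["v_call"]),
        "d_gene": norm(records["d_call"]),
        "j_gene": norm(records["j_call"]),
        "junction_length": records["junction"].fillna("").str.len().astype(int),
    }, index=records.index)


def assign_clones(
    records: pd.DataFrame,
    use_allele: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition cells into clones by germline identity.

    ``records`` must hold one IGH row per cell (post-QC). Two cells are in
    the same clone iff their (V gene, D gene, J gene, junction length) keys
    are equal; an absent D call compares equal only to other absent-D
    records. Clone ids are assigned in lexicographic key order, so they are
    deterministic for a given table.

    Returns ``(records_with_clone_id, clones)`` where ``clones`` has one
    row per clone: key columns, ``size``, per-compartment sizes, and the
    mean over members of the per-cell SHM frequency.
    """
    if records["cell_id"].duplicated().any():
        dupes = records.loc[records["cell_id"].duplicated(), "cell_id"].tolist()[:10]
        raise DataError(f"duplicate cell_id in clone input: {dupes}")
    keys = _clone_keys(records, use_allele)
    out = records.copy()
    key_tuples = list(keys.itertuples(index=False, name=None))
    ordered = sorted(set(key_tuples))
    width = max(5, len(str(len(ordered))))
    clone_id_of = {k: f"CL{i + 1:0{width}d}" for i, k in enumerate(ordered)}
    out["clone_id"] = [clone_id_of[k] for k in key_tuples]

    with_freq = add_shm_stats(out)
    grouped = with_freq.groupby("clone_id", sort=True)
    clones = pd.DataFrame({
        "size": grouped.size(),
        "mean_mut_frequency": grouped["mut_frequency"].mean(),
    })
    key_df = pd.DataFrame(
        [clone_id_of[k] for k in key_tuples], columns=["clone_id"], index=keys.index
    ).join(keys).drop_duplicates("clone_id").set_index("clone_id")
    clones = key_df.join(clones)
    if "compartment" in records.columns:
        comp = with_freq.groupby(["clone_id", "compartment"]).size().unstack(fill_value=0)
        for compartment in ("tumor", "blood"):
            clones[f"n_{compartment}"] = comp.get(compartment, 0)
    clones = clones.sort_index().reset_index()
    return out, clones


# ---------------------------------------------------------------------------
# SHM
# ---------------------------------------------------------------------------


def shm_stats(v_mut_count: int, j_mut_count: int, vj_aligned_length: int) -> tuple[int, float]:
    """SHM count and frequency over the V and J segments only.

    ``mut_count = v_mut + j_mut``; ``mut_frequency = mut_count / L`` where
    ``L`` is the aligned V+J length in nucleotides.
    """
    if vj_aligned_length <= 0:
        raise DataError("vj_aligned_length must be positive")
    count = int(v_mut_count) + int(j_mut_count)
    if count < 0 or count > vj_aligned_length:
        raise DataError("mutation counts must be in [0, vj_aligned_length]")
    return count, count / vj_aligned_length


def add_shm_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`shm_stats`: adds ``mut_count`` and ``mut_frequency``."""
    length = records["vj_aligned_length"]
    if (length <= 0).any():
        bad = records.loc[length <= 0, "cell_id"].tolist()[:10]
        raise DataError(f"non-positive vj_aligned_length for cells: {bad}")
    out = records.copy()
    out["mut_count"] = records["v_mut_count"].astype(int) + records["j_mut_count"].astype(int)
    if (out["mut_count"] > length).any() or (out["mut_count"] < 0).any():
        raise DataError("mutation counts exceed aligned length")
    out["mut_frequency"] = out["mut_count"] / length
    return out


# ---------------------------------------------------------------------------
# isotype / CSR / germline status
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BcrStatus:
    isotype_class: str  # IGM, IGD, IGG, IGA, IGE or unknown
    switched: bool
    germline: bool
    isotype_known: bool


def _isotype_class(c_call: object) -> str:
    call = "" if c_call is None or (isinstance(c_call, float) and np.isnan(c_call)) \
        else str(c_call).upper()
    for prefix, cls in _ISOTYPE_PREFIXES:
        if call.startswith(prefix):
            return cls
    return "unknown"


def classify_bcr_status(c_call: object, mut_count: int) -> BcrStatus:
    """Isotype class, switch status and germline status for one record.

    Switched means the isotype is outside {IGM, IGD}; an unknown isotype is
    reported unswitched with ``isotype_known=False``. Germline means zero
    V+J mutations (an antigen-inexperienced signature).
    """
    cls = _isotype_class(c_call)
    known = cls != "unknown"
    return BcrStatus(
        isotype_class=cls,
        switched=known and cls not in _UNSWITCHED,
        germline=int(mut_count) == 0,
        isotype_known=known,
    )


def add_bcr_status(records: pd.DataFrame) -> pd.DataFrame:
    """Adds ``isotype_class``, ``switched``, ``isotype_known``, ``germline``."""
    out = records if "mut_count" in records.columns else add_shm_stats(records)
    out = out.copy()
    cls = out["c_call"].map(_isotype_class)
    out["isotype_class"] = cls
    out["isotype_known"] = cls != "unknown"
    out["switched"] = out["isotype_known"] & ~cls.isin(_UNSWITCHED)
    out["germline"] = out["mut_count"] == 0
    return out


# ---------------------------------------------------------------------------
# repertoire summaries
# ---------------------------------------------------------------------------


@dataclass
class RepertoireSummary:
    """Per-group repertoire statistics.

    ``groups``: one row per group (n_cells, clonal_fraction,
    germline_fraction, switched_fraction, mean_mut_frequency and one
    ``frac_<isotype>`` column per isotype class).
    ``clone_sizes``: within-group clone-size histogram (clones with >= 2
    members in the group).
    ``clone_mut``: per clone and group, the mean member SHM frequency.
    """

    groups: pd.DataFrame
    clone_sizes: pd.DataFrame
    clone_mut: pd.DataFrame


def repertoire_summary(
    records: pd.DataFrame,
    group_by: str = "compartment",
) -> RepertoireSummary:
    """Summarize isotype usage, germline fraction, clonality and SHM per group.

    ``records`` must carry ``clone_id`` (see :func:`assign_clones`); SHM and
    status columns are derived if absent. The clonal fraction is the number
    of cells belonging to clones of *total* size >= 2 divided by the number
    of cells in the group (clonal B cells among all B cells).
    """
    if "clone_id" not in records.columns:
        raise DataError("records need a clone_id column; run assign_clones first")
    df = add_bcr_status(records)
    global_sizes = df["clone_id"].value_counts()
    df["_clonal"] = df["clone_id"].map(global_sizes) >= 2

    rows, size_rows, mut_rows = [], [], []
    for group, sub in df.groupby(group_by, sort=True):
        if len(sub) == 0:
            warnings.warn(f"empty group {group!r} in repertoire summary")
        row = {
            group_by: group,
            "n_cells": len(sub),
            "clonal_fraction": float(sub["_clonal"].mean()),
            "germline_fraction": float(sub["germline"].mean()),
            "switched_fraction": float(sub["switched"].mean()),
            "mean_mut_frequency": float(sub["mut_frequency"].mean()),
        }
        iso = sub["isotype_class"].value_counts(normalize=True)
        for cls in ISOTYPE_CLASSES:
            row[f"frac_{cls}"] = float(iso.get(cls, 0.0))
        rows.append(row)

        within = sub.groupby("clone_id")
        sizes = within.size()
        for size, count in sizes[sizes >= 2].value_counts().sort_index().items():
            size_rows.append({group_by: group, "size": int(size), "n_clones": int(count)})
        for clone_id, mean_freq in within["mut_frequency"].mean().items():
            mut_rows.append({group_by: group, "clone_id": clone_id,
                             "size": int(sizes[clone_id]),
                             "mean_mut_frequency": float(mean_freq)})

    return RepertoireSummary(
        groups=pd.DataFrame(rows),
        clone_sizes=pd.DataFrame(size_rows, columns=[group_by, "size", "n_clones"]),
        clone_mut=pd.DataFrame(mut_rows, columns=[group_by, "clone_id", "size",
                                                  "mean_mut_frequency"]),
    )


# ---------------------------------------------------------------------------
# public clones
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PublicCloneResult:
    shared_count: int
    n_study: int
    percentage: float  # 100 * shared / unique study clonotypes


def unique_clonotypes(records: pd.DataFrame | Iterable[tuple]) -> set[tuple[str, str, str]]:
    """Deduplicated (V gene, J gene, CDRH3 aa) clonotypes of a table.

    Accepts a rearrangement table (columns ``v_call``/``j_call``/
    ``junction_aa``, alleles stripped) or any iterable of triples.
    Records without a CDRH3 amino-acid sequence are dropped.
    """
    if isinstance(records, pd.DataFrame):
        v = records["v_call"].map(strip_allele)
        j = records["j_call"].map(strip_allele)
        aa = records["junction_aa"].fillna("")
        return {(vi, ji, ai) for vi, ji, ai in zip(v, j, aa) if ai}
    return {tuple(t) for t in records if t[2]}


def public_clone_fraction(
    study: pd.DataFrame | Iterable[tuple],
    reference: pd.DataFrame | Iterable[tuple],
) -> PublicCloneResult:
    """Fraction of the study's unique clonotypes found in a reference cohort.

    Matching is exact equality of (V gene, J gene, CDRH3 amino acids) after
    deduplication on both sides; the percentage is shared / study uniques.
    """
    study_set = unique_clonotypes(study)
    if not study_set:
        raise DataError("study cohort contains no clonotypes")
    shared = study_set & unique_clonotypes(reference)
    return PublicCloneResult(
        shared_count=len(shared),
        n_study=len(study_set),
        percentage=100.0 * len(shared) / len(study_set),
    )


def public_clone_chi2(
    public_a: int, total_a: int, public_b: int, total_b: int,
    correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 (public, non-public) x cohort table.

    Continuity correction is off by default. Returns (statistic, p-value).
    """
    table = np.array([[public_a, total_a - public_a],
                      [public_b, total_b - public_b]])
    if (table < 0).any():
        raise ValueError("public counts cannot exceed totals")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)
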