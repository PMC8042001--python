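"""Clonal-sharing matrices between expression clusters.

For every unordered pair of B cells that are clonally related
(*same-germline* mode) or carry an identical observed IGH nucleotide
sequence (*same-sequence* mode), one event is recorded on the (cluster A,
cluster B) cell of a symmetric matrix; pairs within one cluster accumulate
on the diagonal. Events are partitioned by the compartments of the two
cells: both tumor (TNBC), both blood (PBMC), or one of each (mixed).

Raw counts scale with cluster size, so they are normalized to

    N_normalized = (N / N_A) * (N / N_B) * 10,000

where N is the event count of a cluster pair and N_A, N_B are the cell
numbers of the two clusters. For the TNBC and PBMC groups, cluster sizes
are counted within the matching compartment; the mixed group uses
combined-compartment sizes so that the unordered-pair matrix stays
symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .repertoire_qc import DataError

__all__ = [
    "SharingEvents",
    "GROUPS",
    "count_sharing_events",
    "normalize_value",
    "normalize_sharing",
    "sharing_long_table",
]

GROUPS = ("TNBC", "PBMC", "mixed")
NORMALIZATION_SCALE = 10_000.0


@dataclass
class SharingEvents:
    """Raw (and optionally normalized) sharing-event matrices.

    ``counts``/``normalized`` map each compartment group to a symmetric
    clusters x clusters DataFrame; ``cluster_sizes`` maps each group to the
    per-cluster cell counts used for normalization.
    """

    mode: str  # same_germline | same_sequence
    resolution: str  # low | high
    clusters: list[str]
    counts: dict[str, pd.DataFrame]
    cluster_sizes: dict[str, pd.Series]
    normalized: dict[str, pd.DataFrame] | None = None

    def total_events(self) -> int:
        return int(sum(self._pair_total(m) for m in self.counts.values()))

    @staticmethod
    def _pair_total(mat: pd.DataFrame) -> int:
        a = mat.to_numpy()
        return int((a.sum() + np.trace(a)) // 2)  # off-diagonal stored twice


def _pair_group(comp_a: str, comp_b: str) -> str:
    if comp_a == "tumor" and comp_b == "tumor":
        return "TNBC"
    if comp_a == "blood" and comp_b == "blood":
        return "PBMC"
    return "mixed"


def count_sharing_events(
    records: pd.DataFrame,
    meta: pd.DataFrame,
    mode: str = "same_germline",
    resolution: str = "high",
) -> SharingEvents:
    """Count qualifying unordered cell pairs per cluster pair and group.

    ``records`` holds one IGH row per cell with ``cell_id``, ``compartment``
    and — depending on mode — ``clone_id`` (same_germline) or ``sequence``
    (same_sequence). ``meta`` supplies the cluster label at the requested
    resolution (column ``cluster_low`` or ``cluster_high``). Every cell of
    ``records`` must be labeled; unlabeled barcodes raise :class:`DataError`.

    Each qualifying pair contributes exactly one event (unordered, no
    self-pairs). Cells that share a clone *and* an identical sequence count
    in both modes, which are reported separately.
    """
    if mode not in ("same_germline", "same_sequence"):
        raise ValueError(f"unknown mode {mode!r}")
    if resolution not in ("low", "high"):
        raise ValueError(f"unknown resolution {resolution!r}")
    cluster_col = f"cluster_{resolution}"
    key_col = "clone_id" if mode == "same_germline" else "sequence"
    if key_col not in records.columns:
        raise DataError(f"records lack the {key_col!r} column required for mode {mode!r}")

    labels = meta.set_index("cell_id")[cluster_col]
    unlabeled = sorted(set(records["cell_id"]) - set(labels.dropna().index))
    if unlabeled:
        raise DataError(f"cells without a {cluster_col} label: {unlabeled[:10]}")

    cells = records[["cell_id", "compartment", key_col]].copy()
    cells["cluster"] = cells["cell_id"].map(labels)
    clusters = sorted(cells["cluster"].unique())
    index = {c: i for i, c in enumerate(clusters)}
    k = len(clusters)

    mats = {g: np.zeros((k, k), dtype=np.int64) for g in GROUPS}
    for _, group_df in cells.groupby(key_col, sort=False):
        if len(group_df) < 2:
            continue
        members = list(zip(group_df["cluster"], group_df["compartment"]))
        for (cl_a, co_a), (cl_b, co_b) in combinations(members, 2):
            g = _pair_group(co_a, co_b)
            i, j = index[cl_a], index[cl_b]
            mats[g][i, j] += 1
            if i != j:
                mats[g][j, i] += 1

    per_cluster = cells.groupby(["cluster", "compartment"]).size().unstack(fill_value=0)
    sizes = {
        "TNBC": per_cluster.get("tumor", pd.Series(0, index=per_cluster.index)),
        "PBMC": per_cluster.get("blood", pd.Series(0, index=per_cluster.index)),
        "mixed": per_cluster.sum(axis=1),
    }
    sizes = {g: s.reindex(clusters, fill_value=0).astype(int) for g, s in sizes.items()}

    counts = {g: pd.DataFrame(m, index=clusters, columns=clusters) for g, m in mats.items()}
    return SharingEvents(mode=mode, resolution=resolution, clusters=clusters,
                         counts=counts, cluster_sizes=sizes)


def normalize_value(n: float, n_a: float, n_b: float) -> float:
    """(N / N_A) * (N / N_B) * 10,000 for a single cluster pair."""
    if n == 0:
        return 0.0
    if n_a <= 0 or n_b <= 0:
        raise DataError("nonzero event count with an empty cluster")
    return (n / n_a) * (n / n_b) * NORMALIZATION_SCALE


def normalize_sharing(events: SharingEvents) -> SharingEvents:
    """Normalize raw event counts by the cluster sizes of their group.

    Cells with N = 0 map to 0 regardless of sizes; a cluster of size 0 with
    a nonzero count is a data inconsistency (error); cells involving an
    empty cluster are masked as NaN rather than propagating a division by
    zero. The diagonal uses N_A = N_B = the cluster's own size.
    """
    normalized: dict[str, pd.DataFrame] = {}
    for group, mat in events.counts.items():
        n = mat.to_numpy(dtype=float)
        s = events.cluster_sizes[group].to_numpy(dtype=float)
        ok = np.outer(s > 0, s > 0)
        if ((n > 0) & ~ok).any():
            raise DataError(
                f"group {group!r}: nonzero sharing count for a cluster with zero cells"
            )
        out = np.zeros_like(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            formula = (n / s[:, None]) * (n / s[None, :]) * NORMALIZATION_SCALE
        out[ok] = formula[ok]
        out[~ok & (n == 0)] = np.nan
        normalized[group] = pd.DataFrame(out, index=mat.index, columns=mat.columns)
    return replace(events, normalized=normalized)


def sharing_long_table(events: SharingEvents) -> pd.DataFrame:
    """Long-format export: one row per group and unordered cluster pair."""
    if events.normalized is None:
        events = normalize_sharing(events)
    rows = []
    for group in GROUPS:
        mat = events.counts[group]
        norm = events.normalized[group]
        sizes = events.cluster_sizes[group]
        for i, a in enumerate(events.clusters):
            for b in events.clusters[i:]:
                rows.append({
                    "cluster_a": a, "cluster_b": b, "group": group,
                    "mode": events.mode, "resolution": events.resolution,
                    "N": int(mat.loc[a, b]),
                    "N_A": int(sizes[a]), "N_B": int(sizes[b]),
                    "N_normalized": float(norm.loc[a, b]),
                })
    return pd.DataFrame(rows)
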