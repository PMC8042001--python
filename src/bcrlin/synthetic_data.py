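"""Synthetic paired BCR-repertoire + expression data with known ground truth.

The generator emulates the input tables of a paired 5' single-cell
VDJ + gene-expression experiment on tumor and peripheral-blood samples:

* an AIRR-style rearrangement table (one row per assembled contig) with
  planted B-cell clones (shared V/D/J genes and junction length), per-cell
  somatic-hypermutation (SHM) counts at compartment-specific rates, isotype
  switching, UMI support, spurious secondary productive IGH contigs,
  TRA/TRB contamination, and barcode-collision doublets;
* a small sparse gene x cell UMI count matrix with planted per-cluster
  signature shifts and elevated cell-cycle gene expression in cycling cells.

Every quantity a downstream stage estimates (clone membership, mutation
counts, phase labels, doublet barcodes) is recorded in :class:`GroundTruth`,
so recovery can be tested without any external download.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from Bio.Seq import Seq

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulationConfigError",
    "simulate_repertoire",
    "simulate_expression",
    "V_GENES",
    "D_GENES",
    "J_GENES",
    "JUNCTION_LENGTHS",
]


class SimulationConfigError(ValueError):
    """Raised when a :class:`SimConfig` field is non-finite or out of range."""


# ---------------------------------------------------------------------------
# fixed synthetic V/D/J dictionary
#
# A small fixed dictionary (not real IMGT alleles): clone keys need realistic
# collision structure, not sequence-level realism.  Allele suffixes (*01/*02)
# are attached at emission time so that gene-level key stripping is exercised.
# ---------------------------------------------------------------------------

V_GENES: tuple[str, ...] = tuple(
    f"IGHV{family}-{num}"
    for family, num in [
        (1, 2), (1, 18), (1, 46), (1, 69),
        (2, 5), (2, 26), (2, 70),
        (3, 7), (3, 11), (3, 21), (3, 23), (3, 30), (3, 48),
        (4, 4), (4, 34), (4, 39), (4, 59),
        (5, 51), (6, 1), (7, 81),
    ]
)
D_GENES: tuple[str, ...] = (
    "IGHD1-1", "IGHD2-2", "IGHD3-10", "IGHD3-22", "IGHD4-17", "IGHD6-19",
)
J_GENES: tuple[str, ...] = tuple(f"IGHJ{i}" for i in range(1, 7))
#: junction lengths in nt, multiples of 3 so CDRH3 translation is in frame
JUNCTION_LENGTHS: tuple[int, ...] = tuple(range(30, 76, 3))

_N_KEYS = len(V_GENES) * len(D_GENES) * len(J_GENES) * len(JUNCTION_LENGTHS)

_NT = np.array(list("ACGT"))

#: high-resolution cluster labels and their low-resolution parents
CLUSTERS_HIGH: tuple[str, ...] = tuple(f"C{i}" for i in range(1, 14))
_HIGH_TO_LOW: dict[str, str] = {
    "C1": "naive", "C2": "naive",
    "C3": "memory", "C4": "memory", "C5": "memory", "C6": "memory",
    "C7": "memory", "C8": "memory", "C9": "memory", "C10": "memory",
    "C11": "plasma",
    "C12": "memory",
    "C13": "atypical",
}
CLUSTERS_LOW: tuple[str, ...] = ("naive", "memory", "plasma", "atypical")

# switched / unswitched isotype menus (constant regions as called by annotation)
_SWITCHED_ISOTYPES = ("IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1", "IGHA2", "IGHE")
_SWITCHED_WEIGHTS = (0.40, 0.20, 0.14, 0.05, 0.14, 0.05, 0.02)
_UNSWITCHED_ISOTYPES = ("IGHM", "IGHD")
_UNSWITCHED_WEIGHTS = (0.72, 0.28)


def _key_from_index(idx: int) -> tuple[str, str, str, int]:
    v = V_GENES[idx % len(V_GENES)]
    idx //= len(V_GENES)
    d = D_GENES[idx % len(D_GENES)]
    idx //= len(D_GENES)
    j = J_GENES[idx % len(J_GENES)]
    idx //= len(J_GENES)
    length = JUNCTION_LENGTHS[idx]
    return v, d, j, length


def _check_prob(name: str, p: float) -> None:
    if not (isinstance(p, (int, float)) and math.isfinite(p) and 0.0 <= p <= 1.0):
        raise SimulationConfigError(f"{name} must be a probability in [0, 1], got {p!r}")


def _check_count(name: str, n: int, minimum: int = 1) -> None:
    if not (isinstance(n, (int, np.integer)) and n >= minimum):
        raise SimulationConfigError(f"{name} must be an integer >= {minimum}, got {n!r}")


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults reproduce the qualitative tumor/blood contrasts of a TNBC
    cohort: tumor repertoires are more clonal (19% vs 7% of cells in clones
    of size >= 2), more mutated (2% vs 1% per V+J nucleotide) and more
    class-switched than the paired blood repertoires.
    """

    n_cells_per_sample: int = 200
    n_samples_tumor: int = 5
    n_samples_blood: int = 5
    #: fraction of cells placed in clones of size >= 2, per compartment
    clonal_fraction_tumor: float = 0.19
    clonal_fraction_blood: float = 0.07
    #: categorical distribution over clone sizes >= 2 (weights, renormalized)
    clone_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.55, 3: 0.20, 4: 0.12, 5: 0.06, 6: 0.04, 8: 0.02, 10: 0.01}
    )
    #: expected SHM per V+J nucleotide
    shm_rate_tumor: float = 0.02
    shm_rate_blood: float = 0.01
    #: probability a cell carries a non-IGM/IGD isotype
    p_switch_tumor: float = 0.60
    p_switch_blood: float = 0.35
    #: probability a tumor clone places one member in the paired blood sample
    p_cross_compartment: float = 0.05
    #: probability a barcode receives two cells' contigs (and summed counts)
    p_doublet: float = 0.01
    #: probability of a spurious second productive IGH with minor UMI count
    p_multi_productive: float = 0.14
    #: probability of an extra non-productive IGH contig
    p_nonproductive: float = 0.05
    #: probability a B-cell barcode also carries assembled TRA and TRB contigs
    p_tcr_doublet: float = 0.045
    umi_dominant_range: tuple[int, int] = (20, 80)
    umi_minor_range: tuple[int, int] = (1, 5)
    #: aligned V+J nucleotides (range the per-clone length is drawn from)
    vj_length_range: tuple[int, int] = (320, 380)
    # ----- expression ------------------------------------------------------
    n_genes: int = 200
    n_signature_genes: int = 10
    n_cell_cycle_genes: int = 10
    #: multiplicative shift of signature genes in the planted cluster (1 = null)
    signature_strength: float = 3.0
    #: high-resolution cluster carrying the planted signature shift
    signature_cluster: str = "C1"
    #: multiplicative shift of cell-cycle genes in S/G2M cells (1 = null)
    cell_cycle_strength: float = 4.0
    p_s_phase: float = 0.05
    p_g2m_phase: float = 0.05
    #: guaranteed minimum total UMI per cell in the count matrix
    min_total_umi: int = 100
    n_clusters_high: int = 13
    n_clusters_low: int = 4
    #: draw background rearrangement keys without replacement (exact planting)
    unique_background: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "clonal_fraction_tumor", "clonal_fraction_blood", "p_switch_tumor",
            "p_switch_blood", "p_cross_compartment", "p_doublet",
            "p_multi_productive", "p_nonproductive", "p_tcr_doublet",
            "p_s_phase", "p_g2m_phase",
        ):
            _check_prob(name, getattr(self, name))
        if self.p_s_phase + self.p_g2m_phase > 1.0:
            raise SimulationConfigError("p_s_phase + p_g2m_phase must be <= 1")
        for name in ("n_cells_per_sample", "n_genes", "min_total_umi"):
            _check_count(name, getattr(self, name))
        for name in ("n_samples_tumor", "n_samples_blood"):
            _check_count(name, getattr(self, name), minimum=0)
        if self.n_samples_tumor + self.n_samples_blood < 1:
            raise SimulationConfigError("at least one sample is required")
        _check_count("n_signature_genes", self.n_signature_genes)
        _check_count("n_cell_cycle_genes", self.n_cell_cycle_genes)
        if self.n_signature_genes + self.n_cell_cycle_genes > self.n_genes:
            raise SimulationConfigError("designated gene sets exceed n_genes")
        for name in ("shm_rate_tumor", "shm_rate_blood"):
            rate = getattr(self, name)
            if not (math.isfinite(rate) and 0.0 <= rate <= 1.0):
                raise SimulationConfigError(f"{name} must be a per-nt rate in [0, 1]")
        for name in ("signature_strength", "cell_cycle_strength"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise SimulationConfigError(f"{name} must be finite and >= 0")
        for name in ("umi_dominant_range", "umi_minor_range", "vj_length_range"):
            lo, hi = getattr(self, name)
            if not (int(lo) == lo and int(hi) == hi and 1 <= lo <= hi):
                raise SimulationConfigError(f"{name} must be a positive integer range")
        if not self.clone_size_distribution:
            raise SimulationConfigError("clone_size_distribution must be non-empty")
        for size, w in self.clone_size_distribution.items():
            if size < 2:
                raise SimulationConfigError("clone sizes must be >= 2")
            if not (math.isfinite(w) and w >= 0):
                raise SimulationConfigError("clone size weights must be finite and >= 0")
        if sum(self.clone_size_distribution.values()) <= 0:
            raise SimulationConfigError("clone size weights must sum to > 0")
        if self.n_clusters_high != len(CLUSTERS_HIGH) or self.n_clusters_low != len(CLUSTERS_LOW):
            raise SimulationConfigError(
                "this generator ships a fixed 13-cluster / 4-group label scheme"
            )
        if self.signature_cluster not in CLUSTERS_HIGH:
            raise SimulationConfigError(f"unknown signature_cluster {self.signature_cluster!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise SimulationConfigError("seed must be an integer")

    # gene naming -----------------------------------------------------------
    @property
    def gene_names(self) -> list[str]:
        sig = [f"SIG{i:02d}" for i in range(1, self.n_signature_genes + 1)]
        cc = [f"CC{i:02d}" for i in range(1, self.n_cell_cycle_genes + 1)]
        rest = [f"G{i:04d}" for i in range(1, self.n_genes - len(sig) - len(cc) + 1)]
        return sig + cc + rest

    @property
    def signature_genes(self) -> list[str]:
        return self.gene_names[: self.n_signature_genes]

    @property
    def cell_cycle_genes(self) -> list[str]:
        n = self.n_signature_genes
        return self.gene_names[n : n + self.n_cell_cycle_genes]


@dataclass
class GroundTruth:
    """Planted truth for one simulated experiment.

    ``cells`` is indexed by each simulated cell's original barcode and holds
    sample_id, compartment, clone_id, phase, v_mut_count, j_mut_count,
    is_multi_productive, and ``emitted_as`` (the barcode the cell's contigs
    appear under: differs from the index only for doublet donors).
    ``doublet_barcodes`` lists emitted host barcodes that received two cells.
    """

    cells: pd.DataFrame
    doublet_barcodes: list[str]

    @property
    def clone_of(self) -> pd.Series:
        return self.cells["clone_id"]

    @property
    def phase_of(self) -> pd.Series:
        return self.cells["phase"]

    def clonal_fraction(self, compartment: str | None = None) -> float:
        """Fraction of simulated cells in clones of size >= 2."""
        cells = self.cells
        if compartment is not None:
            cells = cells[cells["compartment"] == compartment]
        sizes = self.cells["clone_id"].value_counts()
        return float((cells["clone_id"].map(sizes) >= 2).mean())


# ---------------------------------------------------------------------------
# cell scaffold (shared between repertoire and expression)
# ---------------------------------------------------------------------------


def _plant_clones(config: SimConfig, rng: np.random.Generator,
                  sample_cells: dict[str, list[str]],
                  samples: list[tuple[str, str, int]]) -> tuple[pd.Series, list[dict]]:
    """Assign each barcode a true clone id; clones of size >= 2 are planted.

    Returns (clone_id per barcode, clone records). Per-sample clonal budgets
    are met exactly: round(f * n) cells per sample end up in clones of
    size >= 2. A fraction of tumor clones place one extra member in the
    paired blood sample, consuming that sample's budget.
    """
    sizes = np.array(sorted(config.clone_size_distribution))
    weights = np.array([config.clone_size_distribution[s] for s in sizes], dtype=float)
    weights /= weights.sum()

    clone_serial = itertools.count(1)
    clones: list[dict] = []
    clone_of: dict[str, str] = {}
    # cross-compartment member reservations: blood sample -> list of clone dicts
    cross: dict[str, list[dict]] = {}
    blood_by_patient = {pat: sid for sid, comp, pat in samples if comp == "blood"}

    def plant_sample(sample_id: str, compartment: str, patient: int) -> None:
        frac = (config.clonal_fraction_tumor if compartment == "tumor"
                else config.clonal_fraction_blood)
        pool = list(rng.permutation(sample_cells[sample_id]))
        budget = int(round(frac * len(pool)))
        pos = 0
        # blood samples first honor cross-compartment reservations
        if compartment == "blood":
            for clone in cross.get(sample_id, []):
                if budget - pos < 1:
                    break
                clone["members"].append(pool[pos])
                clone_of[pool[pos]] = clone["clone_id"]
                pos += 1
        while budget - pos >= 2:
            size = int(rng.choice(sizes, p=weights))
            size = min(size, budget - pos)
            if budget - pos - size == 1:
                size += 1  # never strand a single leftover clonal slot
            members = pool[pos : pos + size]
            pos += size
            cid = f"T{next(clone_serial):05d}"
            clone = {"clone_id": cid, "members": list(members),
                     "sample_id": sample_id, "compartment": compartment}
            clones.append(clone)
            for bc in members:
                clone_of[bc] = cid
            if (compartment == "tumor" and patient in blood_by_patient
                    and rng.random() < config.p_cross_compartment):
                cross.setdefault(blood_by_patient[patient], []).append(clone)
        for bc in pool[pos:]:
            clone_of[bc] = f"S_{bc}"  # singleton: its own clone of size 1

    # tumor samples first so cross reservations exist before blood planting
    for sample_id, compartment, patient in samples:
        if compartment == "tumor":
            plant_sample(sample_id, compartment, patient)
    for sample_id, compartment, patient in samples:
        if compartment == "blood":
            plant_sample(sample_id, compartment, patient)

    return pd.Series(clone_of, name="clone_id"), clones


def _build_scaffold(config: SimConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Per-cell scaffold shared by repertoire and expression simulation."""
    rng = np.random.default_rng([config.seed, 11])

    samples = (
        [(f"TNBC{i+1}", "tumor", i) for i in range(config.n_samples_tumor)]
        + [(f"PBMC{i+1}", "blood", i) for i in range(config.n_samples_blood)]
    )
    n = config.n_cells_per_sample
    rows = []
    sample_cells: dict[str, list[str]] = {}
    for sample_id, compartment, patient in samples:
        barcodes = [f"{sample_id}:{i:05d}" for i in range(n)]
        sample_cells[sample_id] = barcodes
        for bc in barcodes:
            rows.append((bc, sample_id, compartment, patient))
    cells = pd.DataFrame(rows, columns=["barcode", "sample_id", "compartment", "patient"])
    cells = cells.set_index("barcode")

    clone_of, clones = _plant_clones(config, rng, sample_cells, samples)
    cells["clone_id"] = clone_of

    # rearrangement keys: clones first, then background (singleton) cells
    n_singletons = int((cells["clone_id"].str.startswith("S_")).sum())
    n_need = len(clones) + n_singletons
    if config.unique_background:
        if n_need > _N_KEYS:
            raise SimulationConfigError(
                f"{n_need} unique rearrangements requested but the V/D/J x length "
                f"key space holds only {_N_KEYS}; reduce cell numbers or set "
                f"unique_background=False"
            )
        key_idx = rng.choice(_N_KEYS, size=n_need, replace=False)
    else:
        clone_keys = rng.choice(_N_KEYS, size=len(clones), replace=False)
        bg_keys = rng.integers(0, _N_KEYS, size=n_singletons)
        key_idx = np.concatenate([clone_keys, bg_keys])
    key_of: dict[str, int] = {}
    for clone, idx in zip(clones, key_idx[: len(clones)]):
        clone["key_idx"] = int(idx)
        for bc in clone["members"]:
            key_of[bc] = int(idx)
    singles = cells.index[cells["clone_id"].str.startswith("S_")]
    for bc, idx in zip(singles, key_idx[len(clones):]):
        key_of[bc] = int(idx)
    cells["key_idx"] = pd.Series(key_of)

    n_cells = len(cells)
    # cluster labels: fixed non-uniform composition over the 13 subgroups
    w = 1.0 / (np.arange(len(CLUSTERS_HIGH)) + 2.0)
    w /= w.sum()
    cells["cluster_high"] = rng.choice(CLUSTERS_HIGH, size=n_cells, p=w)
    cells["cluster_low"] = cells["cluster_high"].map(_HIGH_TO_LOW)

    cells["phase"] = rng.choice(
        ["S", "G2M", "other"], size=n_cells,
        p=[config.p_s_phase, config.p_g2m_phase,
           1.0 - config.p_s_phase - config.p_g2m_phase],
    )

    # per-cell QC metadata (simulated summaries, cf. a full-size matrix)
    cells["n_genes"] = np.clip(rng.normal(1550, 450, n_cells), 50, 6500).astype(int)
    cells["mito_fraction"] = rng.beta(2.0, 18.0, n_cells)
    cells["total_umi"] = np.clip(rng.normal(4800, 1200, n_cells), 500, None).astype(int)

    cells["is_multi_productive"] = rng.random(n_cells) < config.p_multi_productive
    cells["has_nonproductive"] = rng.random(n_cells) < config.p_nonproductive
    cells["has_tcr"] = rng.random(n_cells) < config.p_tcr_doublet
    cells["is_switched"] = np.where(
        cells["compartment"].to_numpy() == "tumor",
        rng.random(n_cells) < config.p_switch_tumor,
        rng.random(n_cells) < config.p_switch_blood,
    )

    # doublets as barcode collisions within a sample: donor's contigs and
    # counts are emitted under the host barcode; donor barcode disappears
    emitted_as = pd.Series(cells.index, index=cells.index, name="emitted_as")
    for sample_id, _, _ in samples:
        barcodes = np.array(sample_cells[sample_id])
        n_pairs = int(math.floor(config.p_doublet * len(barcodes)))
        if n_pairs == 0:
            continue
        chosen = rng.choice(barcodes, size=2 * n_pairs, replace=False)
        for host, donor in zip(chosen[:n_pairs], chosen[n_pairs:]):
            emitted_as[donor] = host
    cells["emitted_as"] = emitted_as
    return cells, clones


# ---------------------------------------------------------------------------
# repertoire
# ---------------------------------------------------------------------------


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    chars = list(seq)
    for pos in positions:
        old = chars[pos]
        choices = [b for b in "ACGT" if b != old]
        chars[pos] = choices[rng.integers(0, 3)]
    return "".join(chars)


def _draw_isotype(rng: np.random.Generator, switched: bool) -> str:
    if switched:
        return str(rng.choice(_SWITCHED_ISOTYPES, p=_SWITCHED_WEIGHTS))
    return str(rng.choice(_UNSWITCHED_ISOTYPES, p=_UNSWITCHED_WEIGHTS))


def simulate_repertoire(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate an annotated AIRR-style rearrangement table.

    Returns ``(records, meta, truth)``: one row per assembled contig
    (IGH, plus TRA/TRB for planted BCR/TCR doublets), per-cell metadata, and
    the planted ground truth. With a fixed config the output is bit-for-bit
    reproducible, and barcodes agree with :func:`simulate_expression`.
    """
    config.validate()
    cells, clones = _build_scaffold(config)
    rng = np.random.default_rng([config.seed, 22])

    lo_len, hi_len = config.vj_length_range

    # per-rearrangement germline context, generated in deterministic order:
    # clones first (creation order), then singleton cells (scaffold order)
    germline: dict[str, dict] = {}  # clone_id -> dict

    def make_germline(clone_id: str, key_idx: int) -> dict:
        v, d, j, junction_len = _key_from_index(key_idx)
        vj_len = int(rng.integers(lo_len, hi_len + 1))
        v_len = int(round(0.85 * vj_len))
        g = {
            "v_call": f"{v}*0{rng.integers(1, 3)}",
            "d_call": d,
            "j_call": j,
            "junction": _random_nt(rng, junction_len),
            "vj_seq": _random_nt(rng, vj_len),
            "vj_len": vj_len,
            "v_len": v_len,
        }
        germline[clone_id] = g
        return g

    for clone in clones:
        make_germline(clone["clone_id"], clone["key_idx"])
    for bc, row in cells[cells["clone_id"].str.startswith("S_")].iterrows():
        make_germline(row["clone_id"], int(row["key_idx"]))

    records: list[dict] = []
    true_v_mut = pd.Series(0, index=cells.index, dtype=int)
    true_j_mut = pd.Series(0, index=cells.index, dtype=int)

    for bc, row in cells.iterrows():
        g = germline[row["clone_id"]]
        rate = (config.shm_rate_tumor if row["compartment"] == "tumor"
                else config.shm_rate_blood)
        vj_len = g["vj_len"]
        n_mut = min(int(rng.poisson(rate * vj_len)), vj_len)
        positions = rng.choice(vj_len, size=n_mut, replace=False) if n_mut else np.array([], int)
        v_mut = int((positions < g["v_len"]).sum())
        j_mut = n_mut - v_mut
        true_v_mut[bc], true_j_mut[bc] = v_mut, j_mut
        vj_seq = _mutate(rng, g["vj_seq"], positions) if n_mut else g["vj_seq"]
        junction = g["junction"]
        sequence = vj_seq[: g["v_len"]] + junction + vj_seq[g["v_len"]:]
        emit_bc = row["emitted_as"]
        records.append({
            "cell_id": emit_bc,
            "sample_id": row["sample_id"],
            "compartment": row["compartment"],
            "locus": "IGH",
            "productive": True,
            "v_call": g["v_call"],
            "d_call": g["d_call"],
            "j_call": g["j_call"],
            "junction": junction,
            "junction_aa": str(Seq(junction).translate()),
            "c_call": _draw_isotype(rng, bool(row["is_switched"])),
            "duplicate_count": int(rng.integers(config.umi_dominant_range[0],
                                                config.umi_dominant_range[1] + 1)),
            "v_mut_count": v_mut,
            "j_mut_count": j_mut,
            "vj_aligned_length": vj_len,
            "sequence": sequence,
        })

        if row["is_multi_productive"]:
            # spurious second productive IGH: unrelated rearrangement, minor UMI
            idx = int(rng.integers(0, _N_KEYS))
            v, d, j, junction_len = _key_from_index(idx)
            vj2 = int(rng.integers(lo_len, hi_len + 1))
            v2_len = int(round(0.85 * vj2))
            junction2 = _random_nt(rng, junction_len)
            seq2 = _random_nt(rng, vj2)
            records.append({
                "cell_id": emit_bc,
                "sample_id": row["sample_id"],
                "compartment": row["compartment"],
                "locus": "IGH",
                "productive": True,
                "v_call": f"{v}*01",
                "d_call": d,
                "j_call": j,
                "junction": junction2,
                "junction_aa": str(Seq(junction2).translate()),
                "c_call": "IGHM",
                "duplicate_count": int(rng.integers(config.umi_minor_range[0],
                                                    config.umi_minor_range[1] + 1)),
                "v_mut_count": 0,
                "j_mut_count": 0,
                "vj_aligned_length": vj2,
                "sequence": seq2[:v2_len] + junction2 + seq2[v2_len:],
            })

        if row["has_nonproductive"]:
            junction3 = _random_nt(rng, 31)  # out-of-frame
            records.append({
                "cell_id": emit_bc,
                "sample_id": row["sample_id"],
                "compartment": row["compartment"],
                "locus": "IGH",
                "productive": False,
                "v_call": f"{V_GENES[int(rng.integers(len(V_GENES)))]}*01",
                "d_call": "",
                "j_call": J_GENES[int(rng.integers(len(J_GENES)))],
                "junction": junction3,
                "junction_aa": "",
                "c_call": "",
                "duplicate_count": int(rng.integers(config.umi_minor_range[0],
                                                    config.umi_minor_range[1] + 1)),
                "v_mut_count": 0,
                "j_mut_count": 0,
                "vj_aligned_length": int(rng.integers(lo_len, hi_len + 1)),
                "sequence": _random_nt(rng, 420),
            })

        if row["has_tcr"]:
            for locus, vg, jg in (("TRA", "TRAV1-2", "TRAJ33"), ("TRB", "TRBV20-1", "TRBJ2-1")):
                tr_junction = _random_nt(rng, 36)
                records.append({
                    "cell_id": emit_bc,
                    "sample_id": row["sample_id"],
                    "compartment": row["compartment"],
                    "locus": locus,
                    "productive": True,
                    "v_call": vg,
                    "d_call": "",
                    "j_call": jg,
                    "junction": tr_junction,
                    "junction_aa": str(Seq(tr_junction).translate()),
                    "c_call": "",
                    "duplicate_count": int(rng.integers(1, 20)),
                    "v_mut_count": 0,
                    "j_mut_count": 0,
                    "vj_aligned_length": 300,
                    "sequence": _random_nt(rng, 400),
                })

    records_df = pd.DataFrame.from_records(records)
    records_df = records_df.sort_values(
        ["cell_id", "locus", "duplicate_count", "sequence"],
        ascending=[True, True, False, True], kind="mergesort",
    ).reset_index(drop=True)

    emitted = cells[cells.index == cells["emitted_as"]]
    meta = emitted.reset_index()[[
        "barcode", "sample_id", "compartment", "cluster_low", "cluster_high",
        "total_umi", "n_genes", "mito_fraction",
    ]].rename(columns={"barcode": "cell_id"})

    truth_cells = cells[[
        "sample_id", "compartment", "clone_id", "phase", "emitted_as",
        "is_multi_productive",
    ]].copy()
    truth_cells["v_mut_count"] = true_v_mut
    truth_cells["j_mut_count"] = true_j_mut
    doublet_hosts = sorted(set(cells.loc[cells.index != cells["emitted_as"], "emitted_as"]))
    truth = GroundTruth(cells=truth_cells, doublet_barcodes=doublet_hosts)
    return records_df, meta, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(config: SimConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate a sparse UMI count matrix paired with the repertoire.

    Returns ``(adata, meta)``. ``adata`` is cells x genes (AnnData
    convention) with integer counts; ``adata.var`` flags the designated
    signature and cell-cycle gene sets. Cells of the planted signature
    cluster have the signature set shifted by ``signature_strength``; S/G2M
    cells have the cell-cycle set shifted by ``cell_cycle_strength``. Every
    cell's total is at least ``min_total_umi`` by construction. Barcodes and
    metadata match :func:`simulate_repertoire` for the same config.
    """
    config.validate()
    cells, _ = _build_scaffold(config)
    rng = np.random.default_rng([config.seed, 33])

    genes = config.gene_names
    n_genes = len(genes)
    base = rng.gamma(shape=0.5, scale=4.0, size=n_genes)
    base = np.maximum(base, 0.02)

    sig_idx = np.arange(config.n_signature_genes)
    cc_idx = np.arange(config.n_signature_genes,
                       config.n_signature_genes + config.n_cell_cycle_genes)

    lam = np.tile(base, (len(cells), 1))
    in_sig_cluster = (cells["cluster_high"] == config.signature_cluster).to_numpy()
    lam[np.ix_(in_sig_cluster, sig_idx)] *= config.signature_strength
    cycling = cells["phase"].isin(["S", "G2M"]).to_numpy()
    lam[np.ix_(cycling, cc_idx)] *= config.cell_cycle_strength

    counts = rng.poisson(lam).astype(np.int64)

    # collapse doublet donors onto their host barcode (summed expression)
    emitted_mask = cells.index.to_numpy() == cells["emitted_as"].to_numpy()
    emitted_barcodes = cells.index[emitted_mask]
    pos = {bc: i for i, bc in enumerate(emitted_barcodes)}
    merged = counts[emitted_mask].copy()
    for donor_row, host in zip(np.flatnonzero(~emitted_mask),
                               cells.loc[~emitted_mask, "emitted_as"]):
        merged[pos[host]] += counts[donor_row]

    # enforce the configured per-cell floor via a filler housekeeping gene
    totals = merged.sum(axis=1)
    deficit = np.maximum(config.min_total_umi - totals, 0)
    merged[:, -1] += deficit

    emitted = cells[emitted_mask]
    obs = emitted.reset_index()[[
        "barcode", "sample_id", "compartment", "cluster_low", "cluster_high",
        "total_umi", "n_genes", "mito_fraction",
    ]].rename(columns={"barcode": "cell_id"})
    obs = obs.set_index("cell_id", drop=False)
    obs.index.name = None

    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["is_signature"] = False
    var.iloc[sig_idx, var.columns.get_loc("is_signature")] = True
    var["is_cell_cycle"] = False
    var.iloc[cc_idx, var.columns.get_loc("is_cell_cycle")] = True

    adata = ad.AnnData(X=sp.csr_matrix(merged), obs=obs, var=var)
    meta = obs.reset_index(drop=True)
    return adata, meta
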