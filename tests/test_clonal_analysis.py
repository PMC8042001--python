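"""Clone calling, SHM arithmetic, status classification, public clones."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bcrlin import (
    DataError,
    SimConfig,
    assign_clones,
    add_bcr_status,
    classify_bcr_status,
    public_clone_chi2,
    public_clone_fraction,
    repertoire_summary,
    shm_stats,
    simulate_repertoire,
    strip_allele,
    unique_clonotypes,
)
from bcrlin.clonal_analysis import _clone_keys
from conftest import contig_table


def brute_force_partition(records: pd.DataFrame) -> dict[str, int]:
    """All-pairs transitive-closure oracle over germline-key equality."""
    keys = list(_clone_keys(records, use_allele=False).itertuples(index=False, name=None))
    n = len(keys)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if keys[i] == keys[j]:
                parent[find(i)] = find(j)
    return {records.iloc[i]["cell_id"]: find(i) for i in range(n)}


def partitions_equal(a: dict, b: dict) -> bool:
    from collections import defaultdict
    groups_a, groups_b = defaultdict(set), defaultdict(set)
    for cell, g in a.items():
        groups_a[g].add(cell)
    for cell, g in b.items():
        groups_b[g].add(cell)
    return set(map(frozenset, groups_a.values())) == set(map(frozenset, groups_b.values()))


class TestAssignClones:
    def test_same_key_different_junction_sequence_same_clone(self):
        # the definition keys on junction LENGTH, not sequence identity
        records = contig_table([
            {"cell_id": "a", "junction": "TGTGCGAGAGAT"},
            {"cell_id": "b", "junction": "TGTAAAAAAGAT"},
        ])
        with_clones, clones = assign_clones(records)
        assert with_clones["clone_id"].nunique() == 1
        assert clones.iloc[0]["size"] == 2

    def test_differing_j_gene_splits_clones(self):
        records = contig_table([
            {"cell_id": "a", "j_call": "IGHJ4"},
            {"cell_id": "b", "j_call": "IGHJ5"},
        ])
        with_clones, _ = assign_clones(records)
        assert with_clones["clone_id"].nunique() == 2

    def test_allele_suffix_stripped_by_default(self):
        records = contig_table([
            {"cell_id": "a", "v_call": "IGHV1-2*01"},
            {"cell_id": "b", "v_call": "IGHV1-2*02"},
        ])
        with_clones, _ = assign_clones(records)
        assert with_clones["clone_id"].nunique() == 1
        with_alleles, _ = assign_clones(records, use_allele=True)
        assert with_alleles["clone_id"].nunique() == 2

    def test_absent_d_call_matches_only_absent_d(self):
        records = contig_table([
            {"cell_id": "a", "d_call": np.nan},
            {"cell_id": "b", "d_call": np.nan},
            {"cell_id": "c", "d_call": "IGHD1-1"},
        ])
        with_clones, _ = assign_clones(records)
        cid = with_clones.set_index("cell_id")["clone_id"]
        assert cid["a"] == cid["b"] != cid["c"]

    def test_duplicate_cell_id_is_error(self):
        records = contig_table([{"cell_id": "a"}, {"cell_id": "a"}])
        with pytest.raises(DataError):
            assign_clones(records)

    def test_matches_brute_force_oracle_on_synthetic_repertoire(self):
        cfg = SimConfig(n_cells_per_sample=100, n_samples_tumor=1, n_samples_blood=1,
                        unique_background=False, seed=42)
        records, _, _ = simulate_repertoire(cfg)
        igh = records[(records["locus"] == "IGH") & records["productive"]]
        one_per_cell = igh.sort_values("duplicate_count", ascending=False) \
            .drop_duplicates("cell_id").reset_index(drop=True)
        with_clones, clones = assign_clones(one_per_cell)
        ours = dict(zip(with_clones["cell_id"], with_clones["clone_id"]))
        assert partitions_equal(ours, brute_force_partition(one_per_cell))
        assert clones["size"].sum() == len(one_per_cell)

    def test_clone_ids_deterministic(self):
        records = contig_table([
            {"cell_id": "a", "j_call": "IGHJ5"},
            {"cell_id": "b", "j_call": "IGHJ1"},
        ])
        _, clones1 = assign_clones(records)
        _, clones2 = assign_clones(records.iloc[::-1].reset_index(drop=True))
        assert list(clones1["j_gene"]) == list(clones2["j_gene"])


class TestShmStats:
    def test_zero_mutations_is_germline(self):
        assert shm_stats(0, 0, 300) == (0, 0.0)

    def test_arithmetic(self):
        assert shm_stats(5, 1, 300) == (6, pytest.approx(0.02))

    def test_monotone_in_mutations(self):
        freqs = [shm_stats(v, 0, 300)[1] for v in range(10)]
        assert freqs == sorted(freqs)

    def test_zero_length_is_error(self):
        with pytest.raises(DataError):
            shm_stats(0, 0, 0)


class TestBcrStatus:
    @pytest.mark.parametrize("c_call, muts, cls, switched, germline", [
        ("IGHG2", 3, "IGG", True, False),
        ("IGHM", 0, "IGM", False, True),
        ("IGHD", 4, "IGD", False, False),  # non-germline, non-switched
        ("IGHA1", 0, "IGA", True, True),
        ("IGHE", 1, "IGE", True, False),
    ])
    def test_classification(self, c_call, muts, cls, switched, germline):
        status = classify_bcr_status(c_call, muts)
        assert (status.isotype_class, status.switched, status.germline) == \
            (cls, switched, germline)

    def test_unknown_isotype_flagged_unswitched(self):
        status = classify_bcr_status("", 2)
        assert status.isotype_class == "unknown"
        assert status.switched is False and status.isotype_known is False


class TestRepertoireSummary:
    def test_all_singletons_zero_clonal_fraction(self):
        records = contig_table([{"cell_id": f"c{i}", "j_call": f"IGHJ{i + 1}"}
                                for i in range(4)])
        with_clones, _ = assign_clones(records)
        summary = repertoire_summary(with_clones)
        assert (summary.groups["clonal_fraction"] == 0).all()

    def test_one_19_cell_clone_among_100_cells(self):
        rows = [{"cell_id": f"m{i}"} for i in range(19)]
        rows += [{"cell_id": f"s{i}", "junction": "TGT" * (11 + i % 15),
                  "j_call": f"IGHJ{i % 6 + 1}", "v_call": f"IGHV1-{i}*01"}
                 for i in range(81)]
        with_clones, _ = assign_clones(contig_table(rows))
        sizes = with_clones["clone_id"].value_counts()
        assert sizes.max() == 19 and (sizes == 1).sum() == 81
        summary = repertoire_summary(with_clones)
        assert summary.groups.iloc[0]["clonal_fraction"] == pytest.approx(0.19)

    def test_clone_mean_mut_frequency(self):
        records = contig_table([
            {"cell_id": "a", "v_mut_count": 3, "vj_aligned_length": 300},   # 0.01
            {"cell_id": "b", "v_mut_count": 9, "vj_aligned_length": 300},   # 0.03
        ])
        _, clones = assign_clones(records)
        assert clones.iloc[0]["mean_mut_frequency"] == pytest.approx(0.02)

    def test_germline_plus_nongermline_is_one(self, medium_sim):
        records, _, _ = medium_sim
        igh = records[(records["locus"] == "IGH") & records["productive"]]
        one = igh.sort_values("duplicate_count", ascending=False) \
            .drop_duplicates("cell_id")
        with_clones, _ = assign_clones(one)
        status = add_bcr_status(with_clones)
        for _, sub in status.groupby("compartment"):
            assert sub["germline"].mean() + (~sub["germline"]).mean() == pytest.approx(1.0)

    def test_isotype_fractions_sum_to_one(self, medium_sim):
        records, _, _ = medium_sim
        igh = records[(records["locus"] == "IGH") & records["productive"]]
        one = igh.drop_duplicates("cell_id")
        with_clones, _ = assign_clones(one)
        summary = repertoire_summary(with_clones)
        frac_cols = [c for c in summary.groups.columns if c.startswith("frac_")]
        assert np.allclose(summary.groups[frac_cols].sum(axis=1), 1.0)


class TestPublicClones:
    def clonotypes(self, n, prefix="CARA"):
        return [("IGHV1-2", "IGHJ4", f"{prefix}{i}W") for i in range(n)]

    def test_disjoint_sets(self):
        result = public_clone_fraction(self.clonotypes(10), self.clonotypes(10, "CSSS"))
        assert (result.shared_count, result.percentage) == (0, 0.0)

    def test_identical_sets(self):
        result = public_clone_fraction(self.clonotypes(40), self.clonotypes(40))
        assert (result.shared_count, result.percentage) == (40, 100.0)

    def test_partial_overlap(self):
        study = self.clonotypes(40)
        reference = study[:4] + self.clonotypes(100, "CTTT")
        result = public_clone_fraction(study, reference)
        assert result.shared_count == 4
        assert result.percentage == pytest.approx(10.0)

    def test_deduplication_before_matching(self):
        study = self.clonotypes(5) * 3  # duplicated clonotypes collapse
        result = public_clone_fraction(study, self.clonotypes(5))
        assert result.n_study == 5 and result.percentage == 100.0

    def test_empty_study_is_error(self):
        with pytest.raises(DataError):
            public_clone_fraction([], self.clonotypes(3))

    def test_clonotypes_from_rearrangement_table(self):
        records = contig_table([
            {"cell_id": "a", "v_call": "IGHV1-2*01", "junction_aa": "CARDYW"},
            {"cell_id": "b", "v_call": "IGHV1-2*02", "junction_aa": "CARDYW"},
            {"cell_id": "c", "junction_aa": ""},  # no CDRH3: dropped
        ])
        assert unique_clonotypes(records) == {("IGHV1-2", "IGHJ4", "CARDYW")}

    def test_chi2_matches_hand_pearson(self):
        # 2x2 of (public, nonpublic) x cohort, no continuity correction
        table = np.array([[72, 3158], [193, 7527]])
        chi2, p = public_clone_chi2(72, 3230, 193, 7720)
        expected = 0.0
        total = table.sum()
        for i in range(2):
            for j in range(2):
                e = table[i].sum() * table[:, j].sum() / total
                expected += (table[i, j] - e) ** 2 / e
        assert chi2 == pytest.approx(expected)
        assert p == pytest.approx(stats.chi2.sf(expected, 1))


def test_strip_allele():
    assert strip_allele("IGHV3-23*01") == "IGHV3-23"
    assert strip_allele(np.nan) == ""
    assert strip_allele(None) == ""
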