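# bcrlin

Paired single-cell BCR-repertoire + transcriptome analysis for tumor and
blood B cells.

Droplet-based 5′ single-cell experiments deliver, for the same cell, a
whole-transcriptome UMI count profile and the assembled sequence of its
rearranged immunoglobulin heavy chain (*IGH*). That pairing makes it
possible to ask where a B-cell lineage lives: whether tumor-infiltrating
B cells are clonally expanded, class-switched and somatically mutated
relative to circulating B cells, and which transcriptional subgroups share
clonal ancestry. `bcrlin` implements that analysis chain as a tested,
reusable library:

- **Chain- and cell-level QC** — gene-count and mitochondrial filters; a
  doublet budget `X = (0.000879·N + 0.702)·0.01·N` (floored) for a library
  of `N` detected cells, with exclusion of the top-`X` cells by any
  supplied doublet score; selection of a single productive *IGH* per cell,
  keeping the dominant contig only when its UMI count is *more than*
  10-fold that of the runner-up; removal of BCR/TCR double-positive
  barcodes (TCR⁺ requires both TRA and TRB).
- **Clone calling** — cells sharing V, D, J gene usage (alleles stripped)
  and junction length are one clone; clones of size ≥ 2 define the clonal
  fraction. SHM counts/frequencies use the V and J segments only, so
  "germline" means zero V+J mutations; "switched" means an isotype outside
  {IGM, IGD}. Public clones are (V, J, CDRH3-aa) clonotypes shared with a
  reference cohort, with a Pearson χ² contrast on public/non-public counts.
- **Cluster sharing** — for every unordered pair of cells in one clone
  (*same-germline*) or with an identical observed *IGH* sequence
  (*same-sequence*), one event on the (cluster A, cluster B) cell of a
  symmetric matrix, partitioned into tumor/blood/mixed pair groups and
  normalized as `N_norm = (N/N_A)·(N/N_B)·10,000` with `N_A`, `N_B` the
  cluster cell counts.
- **Expression scoring** — per-cell gene-set means of library-size
  normalized, log-transformed expression, z-scored across cells and
  averaged per cluster; a cell-cycle score as the UMI fraction in
  cell-cycle genes; S/G2M module scores with threshold phase calls
  (S iff s > 0.1 and s > g2m, symmetrically for G2M, otherwise "other");
  and tertile survival stratification (top/bottom ⌊n·fraction⌋ patients
  by score — 92 per group for a 279-patient cohort at 33%).
- **A synthetic-data generator** — ground-truthed paired repertoires and
  count matrices (planted clones, compartment-specific SHM and switching
  rates, spurious secondary contigs, barcode-collision doublets, planted
  cluster signatures), so every stage is testable without any download.

## Worked example

```python
import bcrlin as b

cfg = b.SimConfig(n_cells_per_sample=500, n_samples_tumor=2,
                  n_samples_blood=2, seed=42)
records, meta, truth = b.simulate_repertoire(cfg)

selected, rejections = b.select_single_productive_igh_table(records)
b_cells, flagged = b.flag_bcr_tcr_doublets(records)
selected = selected[selected["cell_id"].isin(set(b_cells))]

with_clones, clones = b.assign_clones(selected)
summary = b.repertoire_summary(with_clones)
print(summary.groups[["compartment", "n_cells", "clonal_fraction",
                      "germline_fraction", "switched_fraction",
                      "mean_mut_frequency"]].round(4).to_string(index=False))
```

prints

```
compartment  n_cells  clonal_fraction  germline_fraction  switched_fraction  mean_mut_frequency
      blood      915           0.0721             0.0317             0.3617              0.0100
      tumor      912           0.1908             0.0011             0.6250              0.0199
```

Of 1,980 simulated cells, 66 were rejected as multi-productive B-cell
doublets by the 10-fold UMI rule and 90 as BCR/TCR double positives. The
recovered per-compartment statistics sit on the planted study conditions:
tumor B cells are ~19% clonal with a 2%-per-nt SHM frequency and mostly
switched isotypes, blood B cells ~7% clonal at 1% SHM — the repertoire
contrast the pipeline is designed to quantify. Continuing,

```python
events = b.normalize_sharing(
    b.count_sharing_events(with_clones, meta,
                           mode="same_germline", resolution="low"))
print(events.total_events())          # 352 clonally-related cell pairs
print(events.normalized["TNBC"])     # symmetric cluster-sharing heatmap table
```

gives the normalized intra-/inter-cluster sharing matrix for tumor-tumor
cell pairs; `events.normalized["PBMC"]` and `["mixed"]` hold the blood-blood
and tumor-blood panels. For survival work,
`b.stratify_patients(cohort, fraction=0.33)` returns disjoint top/bottom
score groups ready for any Kaplan–Meier/Cox routine (e.g. lifelines'
`KaplanMeierFitter` on `result.top` vs `result.bottom`).

A thin CLI mirrors the library:
`bcrlin simulate|qc|clones|public|sharing|score|stratify --help`.

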