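# Methods

## Scope and data model

`bcrlin` analyses paired single-cell data from tumor ("TNBC") and blood
("PBMC") compartments: an AIRR-style rearrangement table (one row per
assembled contig, with V/D/J calls, junction nucleotides, CDRH3 amino
acids, isotype call, UMI support, and per-segment mutation counts) and a
gene × cell UMI count matrix with per-cell metadata carrying sample,
compartment and cluster labels at two resolutions (4 coarse groups, 13
subgroups). Upstream read mapping, contig assembly, V(D)J annotation and
transcriptome clustering are inputs, not part of this package.

## Quality control

**Doublet budget.** For a library with `N` detected cells the number of
barcodes to exclude is `X = ⌊(0.000879·N + 0.702)·0.01·N⌋` — a linear
model of the droplet collision rate in cell loading. The per-cell doublet
score is caller-supplied; `exclude_top_scored` removes the top-`X` cells
with deterministic tie-breaking by barcode. `X` is floored because a
fractional cell cannot be excluded; flooring is the conservative choice.

**Cell filters.** Cells with fewer than 200 or more than 5,000 detected
genes, or more than 50% mitochondrial UMIs, are removed. The exclusions
are strict inequalities, so cells exactly at a bound are retained.

**Single productive IGH.** Only the heavy chain is analysed (light chains
add pairing ambiguity and would drop cells). Among a cell's productive
IGH contigs, the most abundant is kept only when its UMI count is
strictly more than 10-fold that of the second most abundant; otherwise
the cell is rejected as a putative B-cell doublet (`multi_productive`).
"More than 10-fold" is read strictly (top > 10×second): 55 vs 5 passes,
50 vs 5 does not. With three or more productive contigs only the top two
are compared; non-productive contigs never enter the test. Equal UMI
counts are ordered by sequence so the dominant contig is deterministic.

**BCR/TCR double positives.** A barcode is TCR-positive only when both a
TRA and a TRB contig are assembled; an IGH plus a lone TRA remains a
B cell. BCR⁺TCR⁺ barcodes are removed before subgrouping.

## Clone calling and repertoire statistics

Two cells belong to one clone iff they share V, D and J gene usage and
junction length (nucleotides of the IMGT junction). Gene-level equality is
used by default — allele suffixes (`*01`) are stripped — because V(D)J
annotation rarely resolves alleles consistently across cells; allele-level
matching is available via `use_allele=True`. A missing D call compares
equal only to other missing-D records, so unknowable D segments never
merge distinct clones silently. Junction *sequence* identity is not
required: clone members diverge by SHM. Clone ids are assigned in
lexicographic key order and are therefore deterministic.

SHM counts and frequencies use only the V and J segments
(`mut_count = v_mut + j_mut`, `mut_frequency = mut_count / L` with `L`
the aligned V+J length); the D segment and junction are excluded because
junctional diversity is not somatic mutation. A cell is "germline" iff
`mut_count = 0`, and "switched" iff its isotype class (prefix of the
constant-region call: IGHG1–4 → IGG, etc.) is outside {IGM, IGD}; an
unrecognized isotype is reported as `unknown`, unswitched, with
`isotype_known=False`.

The clonal fraction of a group is the number of cells in clones of total
size ≥ 2 over the number of cells in the group (clonal B cells among all
B cells). The per-group clone-size histogram uses within-group member
counts, since a clone may span compartments.

Public clones are exact (V gene, J gene, CDRH3 amino-acid) triples shared
with a reference cohort after deduplication on both sides; the percentage
is shared / study uniques. The 2×2 contrast of public vs non-public
counts between two cohorts uses the Pearson χ² statistic
(scipy `chi2_contingency`), without continuity correction by default.

## Cluster sharing matrices

For each unordered pair of distinct cells that are clonally related
(*same-germline*) or carry an identical observed IGH nucleotide sequence
(*same-sequence*), one event is added to the symmetric cluster × cluster
matrix of the pair's compartment group: both tumor, both blood, or mixed.
A clone of `s` cells contributes `s·(s−1)/2` events; pairs within one
cluster accumulate on the diagonal. Cells related in both modes count in
both matrices — the modes are reported separately. Ordered-pair counting
and self-pairs are deliberately excluded; the brute-force oracle tests pin
this convention.

Raw counts are normalized as `N_norm = (N/N_A)·(N/N_B)·10,000`, `N_A` and
`N_B` being the cell numbers of the two clusters. Tumor-tumor and
blood-blood matrices use cluster sizes counted within the matching
compartment. The mixed group uses combined-compartment sizes: a per-side
compartment rule is not well defined for an unordered cluster pair (either
compartment can sit on either cluster), and the combined choice keeps the
matrix symmetric. Zero counts normalize to zero regardless of sizes; a
cluster with zero cells yields a masked (NaN) cell, and a nonzero count
with an empty cluster is a data-inconsistency error.

## Expression scoring

Counts are library-size normalized to 10,000 per cell and log(1+x)
transformed (scanpy; scale factor configurable). A signature score is the
per-cell mean over the gene set of this normalized expression, z-scored
across all cells — so scores have mean 0 and SD 1 by construction, and a
zero-variance score (constant input, up to float noise below 1e−12
relative) is defined as 0 rather than NaN — then averaged per cluster for
heatmap tables. Genes absent from the matrix are dropped with a warning; a
fully absent set is an error.

The cell-cycle *score* is the fraction of a cell's raw UMIs in cell-cycle
genes (conserved: the UMI-weighted mean of per-cell scores equals the
pooled fraction). S and G2/M *module scores* are the mean normalized
expression of the respective list minus a size-matched, seeded random
background drawn from the remaining genes — a deliberately simple,
documented background scheme; expression-binned backgrounds would change
scores slightly but the phase rules are applied exactly as stated: S iff
s > 0.1 and s > g2m; G2M iff g2m > 0.1 and g2m > s; everything else —
including exact ties and sub-threshold pairs — is "other". Gene lists ship
as editable text inputs; no biology is hard-coded.

## Survival stratification

Patients are sorted by signature score; the top and bottom
`k = ⌊n·fraction⌋` form the comparison groups and the middle is excluded.
`k = ⌊279·0.33⌋ = 92` reproduces the 92-per-group split of a 279-patient
cohort, which is why flooring (not rounding) is used. Ties are broken by
patient id, so groups are deterministic, disjoint and of size `k` even
with constant scores. The fraction must lie in (0, 0.5] so the groups
cannot overlap. Model fitting (Kaplan–Meier, log-rank, Cox with clinical
covariates) is delegated to standard survival packages.

## Synthetic data generator

The generator's defaults define the study conditions the tests run under:
5 tumor + 5 blood samples; clonal fractions 0.19 (tumor) and 0.07
(blood); SHM rates 0.02 and 0.01 expected mutations per V+J nucleotide;
switched-isotype probabilities 0.60 and 0.35; 14% spurious secondary
productive contigs; 1% barcode-collision doublets; 4.5% BCR/TCR doublet
barcodes. These encode the qualitative tumor/blood contrasts the pipeline
must recover (more and larger clones, more SHM, more switching in tumor).

Mechanics and deliberate simplifications:

- **V/D/J dictionary**: 20 synthetic V, 6 D and 6 J gene names with
  junction lengths in {30, …, 75} nt (multiples of 3, so CDRH3 translates
  in frame) — 11,520 possible germline keys. Real IMGT alleles are not
  used; clone keys need collision *structure*, not sequence realism.
- **Clone planting**: per-sample clonal budgets `round(f·n)` are filled
  with clone sizes drawn from a configurable distribution (default mass
  on 2–10, median 2), so the planted clonal fraction is exact by
  construction. A small fraction (5%) of tumor clones place one member in
  the paired blood sample, producing mixed-compartment lineages.
- **Background uniqueness**: by default, non-clonal cells draw their keys
  without replacement (`unique_background=True`). With ~10,000 cells in an
  11,520-key space, sampling with replacement would create on the order of
  a thousand chance key collisions and inflate the apparent clonal
  fraction several-fold — real repertoires avoid this only because their
  key space is astronomically larger. `unique_background=False` restores
  chance collisions for stress-testing clone calling itself.
- **SHM**: per cell, mutations ~ Poisson(rate × L) over an aligned V+J
  length L ∈ [320, 380], split V/J by position (85% V), applied as
  substitutions to the clone's germline sequence. Members with zero
  mutations therefore share the observed sequence exactly, which is what
  the same-sequence event mode detects. Indels and SHM hot-spot targeting
  are not modeled.
- **Artifacts**: secondary productive contigs carry minor UMIs (1–5)
  against dominant 20–80, so a subset falls inside the 10-fold window and
  is rejected — the planted 14% is the *spurious-contig* rate, not the
  post-rule rejection rate. Doublets are barcode collisions: the union of
  two cells' contigs and the sum of their counts under one barcode; since
  two dominant contigs can never differ 10-fold given the UMI ranges,
  doublets are reliably rejected by the single-IGH rule.
- **Expression**: 200 genes with gamma-distributed base rates and Poisson
  counts; a designated signature set is shifted ×3 in one cluster and a
  cell-cycle set ×4 in cells with planted S/G2M phase (5% each); a filler
  gene tops every cell up to the configured 100-UMI floor. The matrix is a
  scaled-down stand-in for a feature-barcode matrix — per-cell QC metadata
  (total UMIs, detected genes, mitochondrial fraction) is simulated at the
  scaffold level rather than recomputed from these 200 genes, and the two
  agree across `simulate_repertoire`/`simulate_expression` because both
  derive from one seeded scaffold stream. Barcodes likewise match across
  the two outputs for a fixed config.

With a fixed seed all outputs are bit-for-bit reproducible.

**What passing tests show — and don't.** Parameter recovery on this
generator demonstrates that the estimators are unbiased under the model's
own assumptions (Poisson SHM, exact key-based clones, independent cells).
It does not certify behavior on real data, where annotation errors,
allele ambiguity, junction-length miscalls, non-Poisson mutation
clustering and shared convergent rearrangements blur clone boundaries.

## Problem sizes

The default test and reproduction runs use 10,000-cell cohorts (5+5
samples × 1,000 cells) for parameter recovery and sharing statistics,
100 repertoires of ≤ 500 cells for the brute-force clone-calling oracle,
and a 279-record cohort for stratification — sizes at which binomial 99%
confidence intervals on the planted fractions are a few tenths of a
percentage point wide, tight enough to detect estimator bias while
keeping a full run in well under a minute.

## Known limitations

- Light chains (IGK/IGL) are ignored by design; cells are identified by a
  single productive IGH.
- Clone calling is exact-key; no junction-sequence clustering, so
  convergent rearrangements with equal keys would merge (negligible in
  the synthetic setting by construction, not in very large real cohorts).
- The S/G2M background scheme is simpler than expression-binned scoring;
  scores are comparable within a dataset, not across methods.
- Doublet *scores* are out of scope: only the exclusion budget and the
  generic top-X exclusion are provided.
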