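# Methods

This note documents the models, conventions and numerical choices behind
`pairedtag`, and what the synthetic experiments do and do not establish
about real data.

## The synthetic experiment

The generator emulates the structure of a joint single-nucleus histone +
transcriptome (Paired-Tag) study: two histone-mark captures (H3K4me1,
H3K27me3) crossed with four sample groups (female/male × control/exposed),
each nucleus carrying a matched histone-fragment profile and an RNA UMI
profile. Defaults (all configurable on `SimConfig`):

* **Genome / genes.** 8 chromosomes × 1 Mb of uniform random sequence;
  400 genes of 2 kb placed on a regular grid so neighbouring promoters
  (TSS ± 1 kb) never overlap; strands drawn per gene. All coordinates are
  0-based half-open; TSS = start on '+', end − 1 on '−'.
* **Population.** 500 cells per group; four cell types at fractions
  0.70 / 0.17 / 0.08 / 0.05 (excitatory, inhibitory, astrocyte, OPC —
  the broad composition of neonatal cortex, dominated by neurons).
* **RNA.** Negative-binomial counts, dispersion 0.3 (overdispersed
  snRNA-seq-like), ~800 counts per cell over 400 genes; ten marker genes
  per type up-weighted 8×; condition effects as per-gene log2 fold changes
  (default: 50 genes at |log2FC| = 1, alternating sign so per-cell totals
  stay balanced between conditions).
* **Histone fragments.** 1,200 fragments per cell: 60% uniform genomic
  background, 40% placed uniformly within TSS ± 1 kb of the genes *marked*
  for that cell — the planted per-condition bivalency states plus
  cell-type-specific marked genes. H3K27me3 carries 40 type-specific genes
  per type versus 3 for H3K4me1: the repressive mark is deliberately the
  information-dense chromatin modality, so histone-only clustering
  resolves types with H3K27me3 but not with H3K4me1. Planted states:
  20 stable bivalent, 20 bivalent → K4-only under exposure, 10 stable
  K4-only, 10 stable K27-only.
* **Noise processes.** Per-barcode substitution probability 0.01 (at most
  one substituted base per barcode per read); PCR duplicates as
  k ~ Geometric extras per molecule, P(k) = (1 − d)·d^k with d = 0.1
  (expected total N/(1 − d), analytically checkable); 5% adapter
  contamination and 90% poly-dT read-through on RNA, drawn from short
  inserts so trimming is exercised; 2% low-quality tails; 3% low-MAPQ
  fragments; one planted high-pileup artifact position per chromosome.
  `zero_noise()` switches all of these off.
* **Read layout.** 150-bp reads; Read 2 =
  `[pad 9+j][BC3][linker2 29bp][BC2][linker1 21bp][UMI 8bp][BC1][pad]` with
  jitter j ∈ 0–3, putting BC1/BC2/BC3 first bases at 1-based positions
  84–87 / 47–50 / 10–13. Barcode and UMI lengths (8 bp) and the linker
  sequences are package conventions — assays vary here, so all are
  configurable. The PCR index travels in the FASTQ header comment.
* **Whitelists.** 12 / 96 / 96 barcodes per round (round 1 identifies the
  sample of origin), generated greedily with pairwise Hamming distance ≥ 3
  under a fixed reagent seed. With ≥ 3 separation and a one-substitution
  error model, an erroneous barcode is either uniquely corrected to its
  source or discarded — mis-assignment is impossible, which the recovery
  tests assert.

**What the simulation does not model:** realistic sequence composition,
splicing/intronic reads, ambient RNA, doublet nuclei, indel sequencing
errors, mappability structure, or chromatin domains broader than promoter
windows. Passing tests therefore demonstrate that the *computations* are
correct and calibrated under their stated assumptions, not that any
biological conclusion transfers to real tissue.

## Demultiplexing

Linkers are anchored per jitter offset, exact first, then allowing one
substitution per linker (consistent with the one-mismatch barcode
tolerance); barcodes whose first base would fall outside the stated window
are rejected as `out_of_window` even when linkers match. Barcode
resolution is substitution-only (no indels), forward-strand only: exact
hit wins; otherwise a Hamming-1 neighbour index must name exactly one
whitelist entry; `N` mismatches everything. Read 1 QC: 3' adapter removal
(≥ 10 bp overlap, ≤ 10% mismatches), then for RNA a terminal run of ≥ 6
T/A bases, then 3' bases below Q = 30 — the "minimal base calling quality"
is read as 3'-quality trimming rather than a mean-quality filter — and
reads shorter than 30 bp are dropped. The demux report is a strict ledger:
every input read lands in exactly one category.

## Quantification

"Position" for deduplication and pileup filtering is (chromosome, 5' start,
strand). Among duplicate copies the highest-MAPQ record is kept, which
makes deduplication commute with the MAPQ filter. The pileup cutoff is
read as strict-greater (pooled depth > 10 removed, 10 kept); fragments are
assigned to 5-kb bins by their 5' start. Gene counting is union
(featureCounts-style): a record increments every overlapping gene; a
`drop`-ambiguous alternative is available. The two coverage filters
(< 200 RNA / < 500 DNA) are applied sequentially, first on total counts,
then on nonzero-feature counts, keeping only nuclei with matched profiles.
Top-bin removal takes ceil(0.02 · n_bins) bins by total coverage with ties
broken by genomic coordinate (earlier kept) for determinism.

## Embedding and clustering

The TF-IDF variant is `log(1 + 10⁴ · tf · idf)` with tf row-normalized and
idf = n_cells / document frequency (one of several variants in common use;
pluggable). LSI components are sorted by singular value and component 1 —
empirically depth-correlated — is dropped (components 2–30 retained); PCA
centers and unit-scales variable genes and keeps components 1–30. Both use
a fixed seed and the sign convention "largest-magnitude loading positive".
Variable genes rank by the variance/mean dispersion of the log-normalized
matrix with coordinate tie-breaks. The kNN graph (k = 20, self included)
is weighted by Jaccard overlap of neighbourhoods restricted to
kNN-adjacent pairs, pruned below 1/15. The joint graph is a fixed global
blend `w·G_RNA + (1−w)·G_DNA` (default w = 0.5) — a deliberate
simplification of per-cell weighted-nearest-neighbor integration, whose
limit cases (w = 0, 1) are exact. Louvain runs under a seeded RNG; a
bisection helper finds the resolution giving a target cluster count,
mirroring the fixed-cluster-count practice; clusters under 50 cells are
flagged excluded. Cluster labels take the argmax mean marker z-score with
an optional margin; clusters exceeding the score threshold for ≥ 2 major
types are flagged as doublets.

## Differential testing

The rank-sum test uses mid-ranks, a tie-corrected variance and a 0.5
continuity correction; for total n ≤ 12 the default mode switches to exact
enumeration over all C(n, nx) rank assignments (two-sided p = 2·min tail,
capped at 1; all-identical samples give p = 1 by convention). The normal
approximation's worst-case deviation from exact at n ≤ 12 is ~0.13, which
is precisely why the exact path exists and is the default at those sizes.
Group means and fold changes are reported on the back-transformed (expm1)
normalized scale: fold changes computed on log1p values compress a true 2×
effect to ~1.46×, colliding with the |FC| > 1.25 preset. "|fold change| >
1.25" is interpreted on the linear scale (|log2FC| > log2 1.25). Features
must be detected in ≥ 10% of either group to be tested; groups under 50
cells are refused. BH-FDR is the step-up estimator with enforced
monotonicity.

## Annotation

Precedence Promoter > 5'UTR > 3'UTR > Exon > Intron > Downstream > distal
intergenic, membership by any-overlap. The annotation promoter window is
inclusive of the bases at TSS ± 1 kb (width 2,001 bases, symmetric around
the TSS base), which makes classification exactly invariant under
coordinate reflection plus strand flip. Without exon models a gene's whole
span counts as exonic. Downstream extends ≤ 3 kb past the 3' end,
strand-aware. Reported distance is peak-center to nearest TSS, signed
positive downstream, ties broken by gene id.

## Promoter signal and bivalency

Signal counting uses the strand-aware offset of each fragment 5' end from
the TSS, with window membership offset ∈ [−1000, 1000); the metagene grid
bins the same interval (default 50-bp steps, minus-strand genes flipped),
so per-gene profile row sums equal the promoter counts exactly. RPM =
count / group mapped fragments × 10⁶; FPKM divides additionally by the
window length in kb (2 kb for promoters, 5 kb for bins; the unit is stored
with the value). The mark-presence threshold is the 95th percentile of RPM
over randomly placed promoter-sized background windows (excluding
promoters), multiplied by a fold-enrichment factor of 2: the raw
percentile is the upper envelope of background sampling noise, and by
construction ~5% of background-like promoters would exceed it, so presence
additionally demands genuine enrichment above that envelope. Thresholds
are recorded in every call table. Bivalency truth in the simulation is
cell-type-resolved, and recovery is evaluated on one cell type's pooled
fragments, where every gene is fully marked or fully unmarked for that
population.

## Problem sizes

The test suite and the acceptance script run the generator at the scales
the analyses need rather than at sequencing scale: the clustering recovery
uses the full default design (2,000 cells per mark, ~4.8 M unique DNA
fragments), demultiplexing checks use ~100–230 k reads, differential
calibration uses 200 cells per condition over 2,200 genes (null) and 600
genes (power), and bivalency recovery uses 150 cells per group over 400
genes. These sizes were chosen so each planted effect is comfortably
detectable under the stated noise; all are `SimConfig` parameters.

## Known limitations

Per-cell WNN modality weights, the MAST hurdle model, UMAP visualization,
peak calling and alignment itself are out of scope; the pipeline consumes
aligned, tagged fragments (a trivial exact-substring locator supports toy
end-to-end tests only). The bivalency caller thresholds pooled
(pseudobulk) signal — it does not model per-cell mark co-occurrence. The
annotation category fractions of any real dataset depend on its genome and
peak set; only the computation, not any published percentage, is
reproduced here.
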