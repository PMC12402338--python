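"""Synthetic Paired-Tag data with planted ground truth.

The generator emulates a joint single-nucleus histone-mark + transcriptome
experiment of the Paired-Tag design: two histone-mark captures (H3K4me1 and
H3K27me3) crossed with four sample groups (female/male x control/exposed),
each nucleus carrying a matched DNA (histone fragment) profile and an RNA
(UMI count) profile. Known answers are planted at every level so each
downstream stage can be verified exactly:

* cell identities — each nucleus belongs to a cell type with marker genes
  up-weighted in its RNA profile (negative-binomial counts);
* chromatin structure — DNA fragments fall uniformly over a toy genome as
  background, plus concentrated promoter (TSS +/- 1 kb) placement at genes
  whose planted mark state includes the simulated mark, with additional
  cell-type-specific marked genes (denser for H3K27me3 than H3K4me1, which
  mirrors the repressive mark's better cell-type resolution);
* promoter bivalency — per-gene mark states (bivalent / K4-only / K27-only /
  unmarked) planted per condition, including bivalent -> K4-only transitions
  under exposure;
* expression effects — per-gene log2 fold changes between conditions.

Reads are emitted as paired gzip FASTQ with the combinatorial three-round
barcode layout on Read 2 (barcode first bases jittered within the 84th-87th,
47th-50th and 10th-13th base windows), or alignment can be bypassed entirely
by emitting tagged BED-like fragment files.
"""

from __future__ import annotations

import dataclasses
import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .utils import BASES, hamming, random_dna_array, stream

MARK_K4 = "H3K4me1"
MARK_K27 = "H3K27me3"
MARKS = (MARK_K4, MARK_K27)
CONDITIONS = ("control", "exposed")
STATES = ("bivalent", "K4-only", "K27-only", "unmarked")

#: Which marks each promoter state carries.
STATE_MARKS = {
    "bivalent": frozenset(MARKS),
    "K4-only": frozenset({MARK_K4}),
    "K27-only": frozenset({MARK_K27}),
    "unmarked": frozenset(),
}

# Fixed linker sequences between barcode rounds. Lengths (29 and 21 bp) are
# chosen so that with 8-bp barcodes, an 8-bp UMI and a 9-bp prefix pad the
# jitter-0 layout puts the first bases of BC1/BC2/BC3 at positions 84/47/10
# (1-based) of Read 2.
LINKER1 = "GTGGCCGATGTTTCGCATCGGCGTACGAC"[:21]
LINKER2 = "ATCCACGTGCTTGAGAGGCCAGAGCATTC"

NEXTERA_ADAPTER = "CTGTCTCTTATACACATCT"


@dataclass(frozen=True)
class CellTypeSpec:
    """A simulated cell type: name, marker gene ids, population fraction."""

    name: str
    markers: tuple[str, ...]
    fraction: float


@dataclass(frozen=True)
class GroupSpec:
    """One capture group: exposure condition x sex x profiled histone mark."""

    condition: str
    sex: str
    mark: str

    @property
    def name(self) -> str:
        cond = "Ctr" if self.condition == "control" else "Ecig"
        return f"{self.sex}_{cond}_{self.mark}"


def _default_groups() -> tuple[GroupSpec, ...]:
    return tuple(
        GroupSpec(condition, sex, mark)
        for mark in MARKS
        for sex in ("F", "M")
        for condition in CONDITIONS
    )


@dataclass
class SimConfig:
    """Full parameterization of one synthetic Paired-Tag experiment.

    The same seed always yields byte-identical outputs. See
    :func:`default_config` for the planted default design.
    """

    seed: int = 0
    # genome / gene models
    n_chromosomes: int = 8
    chromosome_length: int = 1_000_000
    n_genes: int = 400
    gene_length: int = 2_000
    # population
    n_cells_per_group: int = 500
    groups: tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    cell_types: tuple[CellTypeSpec, ...] = ()
    # RNA model
    rna_counts_per_cell: int = 800
    nb_dispersion: float = 0.3
    marker_upweight: float = 8.0
    expression_effect: dict[str, float] = field(default_factory=dict)
    base_expression: dict[str, float] = field(default_factory=dict)
    # DNA model
    fragments_per_cell_dna: int = 1_200
    promoter_fraction_dna: float = 0.4
    fragment_length: int = 300
    planted_bivalency: dict[str, tuple[str, str]] = field(default_factory=dict)
    type_marked_genes: dict[str, dict[str, tuple[str, ...]]] = field(default_factory=dict)
    mark_intensity: dict[str, dict[str, float]] = field(default_factory=dict)
    low_mapq_rate: float = 0.03
    pileup_artifacts_per_chrom: int = 1
    pileup_artifact_depth: int = 30
    # read emission
    read_length: int = 150
    bc_length: int = 8
    umi_length: int = 8
    whitelist_sizes: tuple[int, int, int] = (12, 96, 96)
    barcode_error_rate: float = 0.01
    duplicate_rate: float = 0.1
    adapter_contamination_rate: float = 0.05
    polydt_rate: float = 0.9
    low_quality_tail_rate: float = 0.02
    jitter_max: int = 3
    n_pcr_indices: int = 4

    # ------------------------------------------------------------------
    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_chromosomes <= 0 or self.chromosome_length <= 0:
            raise ConfigurationError("genome dimensions must be positive")
        if self.n_genes <= 0 or self.gene_length <= 0:
            raise ConfigurationError("gene dimensions must be positive")
        if self.n_cells_per_group <= 0:
            raise ConfigurationError("n_cells_per_group must be positive")
        if not self.cell_types:
            raise ConfigurationError("at least one cell type is required")
        total = sum(ct.fraction for ct in self.cell_types)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"cell-type fractions sum to {total}, expected 1")
        genes = set(self.gene_names())
        for ct in self.cell_types:
            missing = set(ct.markers) - genes
            if missing:
                raise ConfigurationError(f"markers not among genes: {sorted(missing)}")
        for g in self.groups:
            if g.mark not in MARKS:
                raise ConfigurationError(f"unknown mark {g.mark!r}")
            if g.condition not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {g.condition!r}")
        for gene, states in self.planted_bivalency.items():
            if gene not in genes:
                raise ConfigurationError(f"planted gene {gene!r} not among genes")
            for s in states:
                if s not in STATES:
                    raise ConfigurationError(f"unknown bivalency state {s!r}")
        for mark, per_type in self.type_marked_genes.items():
            if mark not in MARKS:
                raise ConfigurationError(f"unknown mark {mark!r} in type_marked_genes")
            for genes_t in per_type.values():
                missing = set(genes_t) - genes
                if missing:
                    raise ConfigurationError(f"type-marked genes unknown: {sorted(missing)}")
        if not 0 <= self.duplicate_rate < 1:
            raise ConfigurationError("duplicate_rate must be in [0, 1)")
        if not 0 <= self.barcode_error_rate <= 1:
            raise ConfigurationError("barcode_error_rate must be in [0, 1]")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def default_cell_types(gene_names: list[str]) -> tuple[CellTypeSpec, ...]:
    """Four cortical cell types with ten marker genes each.

    Fractions follow the broad composition of neonatal cortex: excitatory
    neurons dominate, inhibitory neurons are the second-largest class, and
    glia (astrocytes, OPCs) are minorities.
    """
    return (
        CellTypeSpec("excitatory", tuple(gene_names[0:10]), 0.70),
        CellTypeSpec("inhibitory", tuple(gene_names[10:20]), 0.17),
        CellTypeSpec("astrocyte", tuple(gene_names[20:30]), 0.08),
        CellTypeSpec("opc", tuple(gene_names[30:40]), 0.05),
    )


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default planted experiment.

    Design (gene indices refer to the 400 default genes):

    * genes 1-40: ten RNA marker genes per cell type (8x up-weighted);
    * genes 41-200: forty H3K27me3 cell-type-specific marked genes per type —
      the repressive mark carries dense type-specific chromatin signal;
    * genes 201-212: three H3K4me1 cell-type-specific genes per type — the
      enhancer mark is deliberately sparse in type information;
    * genes 213-272: planted promoter bivalency states per condition:
      20 stable bivalent, 20 bivalent -> K4-only transitions under exposure,
      10 stable K4-only, 10 stable K27-only;
    * genes 281-330: expression effects of |log2FC| = 1 between conditions
      (alternating sign).
    """
    cfg = SimConfig(seed=seed).replace(**overrides)
    names = cfg.gene_names()
    planted_defaults: dict = {}
    if "cell_types" not in overrides:
        planted_defaults["cell_types"] = default_cell_types(names)
    if "type_marked_genes" not in overrides and len(names) >= 272:
        type_names = [ct.name for ct in
                      planted_defaults.get("cell_types", cfg.cell_types)]
        k27 = {t: tuple(names[40 + 40 * i: 40 + 40 * (i + 1)])
               for i, t in enumerate(type_names)}
        k4 = {t: tuple(names[200 + 3 * i: 200 + 3 * (i + 1)])
              for i, t in enumerate(type_names)}
        planted_defaults["type_marked_genes"] = {MARK_K27: k27, MARK_K4: k4}
    if "planted_bivalency" not in overrides and len(names) >= 272:
        planted: dict[str, tuple[str, str]] = {}
        for g in names[212:232]:
            planted[g] = ("bivalent", "bivalent")
        for g in names[232:252]:
            planted[g] = ("bivalent", "K4-only")
        for g in names[252:262]:
            planted[g] = ("K4-only", "K4-only")
        for g in names[262:272]:
            planted[g] = ("K27-only", "K27-only")
        planted_defaults["planted_bivalency"] = planted
    if "expression_effect" not in overrides and len(names) >= 330:
        planted_defaults["expression_effect"] = {
            g: (1.0 if i % 2 == 0 else -1.0)
            for i, g in enumerate(names[280:330])}
    cfg = cfg.replace(**planted_defaults)
    cfg.validate()
    return cfg


def coupled_expression_config(seed: int = 0, n_coupled: int = 120,
                              coupling: float = 1.0, spread: float = 0.8,
                              **overrides) -> tuple[SimConfig, list[str]]:
    """Default config plus genes whose expression is coupled to promoter K27.

    The last ``n_coupled`` genes are planted bivalent with per-gene promoter
    placement intensities drawn lognormally and independently for the two
    marks; baseline expression is proportional to (K27 intensity)^-coupling.
    This realizes the repressive-mark hypothesis — promoter H3K27me3
    anticorrelates with expression — while H3K4me1 placement stays
    independent of expression. Returns (config, coupled gene ids).
    """
    cfg = default_config(seed=seed, **overrides)
    names = cfg.gene_names()
    if n_coupled > len(names):
        raise ConfigurationError("n_coupled exceeds the number of genes")
    coupled = names[len(names) - n_coupled:]
    rng = stream(seed, 8)
    k27_int = np.exp(rng.normal(0.0, spread, n_coupled))
    k4_int = np.exp(rng.normal(0.0, spread, n_coupled))
    planted = dict(cfg.planted_bivalency)
    mark_int = {MARK_K4: dict(cfg.mark_intensity.get(MARK_K4, {})),
                MARK_K27: dict(cfg.mark_intensity.get(MARK_K27, {}))}
    base = dict(cfg.base_expression)
    for g, i27, i4 in zip(coupled, k27_int, k4_int):
        planted[g] = ("bivalent", "bivalent")
        mark_int[MARK_K27][g] = float(i27)
        mark_int[MARK_K4][g] = float(i4)
        base[g] = float(i27 ** -coupling)
    cfg = cfg.replace(planted_bivalency=planted, mark_intensity=mark_int,
                      base_expression=base)
    cfg.validate()
    return cfg, coupled


def zero_noise(config: SimConfig) -> SimConfig:
    """A copy of ``config`` with every noise process switched off."""
    return config.replace(
        barcode_error_rate=0.0,
        duplicate_rate=0.0,
        adapter_contamination_rate=0.0,
        low_quality_tail_rate=0.0,
        low_mapq_rate=0.0,
        pileup_artifacts_per_chrom=0,
    )


# ----------------------------------------------------------------------
# whitelists and barcode layout
# ----------------------------------------------------------------------

def generate_whitelists(
    sizes: tuple[int, int, int] = (12, 96, 96),
    length: int = 8,
    min_distance: int = 3,
    seed: int = 20250901,
) -> list[list[str]]:
    """Three per-round barcode whitelists with a pairwise Hamming floor.

    Barcodes within a round keep pairwise distance >= ``min_distance`` (a
    standard barcode-design constraint); with distance >= 3 a single
    substitution is always uniquely correctable to the true barcode.
    The default seed is fixed independently of the experiment seed: the
    whitelists play the role of lab reagents, stable across runs.
    """
    rng = np.random.default_rng(seed)
    lists: list[list[str]] = []
    for size in sizes:
        chosen: list[str] = []
        attempts = 0
        while len(chosen) < size:
            attempts += 1
            if attempts > 200_000:
                raise ConfigurationError(
                    f"cannot find {size} barcodes of length {length} at distance {min_distance}"
                )
            cand = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
            if all(hamming(cand, c) >= min_distance for c in chosen):
                chosen.append(cand)
        lists.append(chosen)
    return lists


# ----------------------------------------------------------------------
# genome and gene models
# ----------------------------------------------------------------------

def generate_toy_genome(config: SimConfig) -> dict[str, str]:
    """Random toy genome: ``n_chromosomes`` uniform-base sequences."""
    if config.n_chromosomes <= 0 or config.chromosome_length <= 0:
        raise ConfigurationError("genome dimensions must be positive")
    rng = stream(config.seed, 0)
    genome: dict[str, str] = {}
    for i in range(config.n_chromosomes):
        seq = random_dna_array(rng, 1, config.chromosome_length)[0]
        genome[f"chr{i + 1}"] = str(seq)
    return genome


def generate_gene_models(genome: dict[str, str], config: SimConfig) -> pd.DataFrame:
    """Evenly spaced, promoter-disjoint gene models over the toy genome.

    Genes are distributed round-robin across chromosomes on a regular grid;
    strand is drawn per gene from the seeded stream. Coordinates are 0-based
    half-open; TSS = start on '+', end - 1 on '-'.
    """
    rng = stream(config.seed, 1)
    chroms = list(genome)
    n_chrom = len(chroms)
    per_chrom = [config.n_genes // n_chrom + (1 if i < config.n_genes % n_chrom else 0)
                 for i in range(n_chrom)]
    names = config.gene_names()
    rows = []
    gi = 0
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        length = len(genome[chrom])
        step = length // (k + 1)
        # promoters (TSS +/- 1 kb) must not overlap between neighbours
        if step < config.gene_length + 2_000:
            raise ConfigurationError(
                f"cannot place {k} genes of {config.gene_length} bp plus 2 kb promoter "
                f"spacing on a {length} bp chromosome"
            )
        for j in range(k):
            center = (j + 1) * step
            start = center - config.gene_length // 2
            end = start + config.gene_length
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            tss = start if strand == "+" else end - 1
            rows.append((names[gi], chrom, start, end, strand, tss))
            gi += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"])
    return genes


# ----------------------------------------------------------------------
# truth container
# ----------------------------------------------------------------------

@dataclass
class SimTruth:
    """Planted ground truth plus the unique (pre-duplication) molecules."""

    config: SimConfig
    genome_lengths: dict[str, int]
    genes: pd.DataFrame
    cells: pd.DataFrame  # cell_id, group, condition, sex, mark, cell_type, bc1..bc3, barcode
    rna_counts: np.ndarray  # cells x genes, aligned with .cells rows / gene_names()
    rna_fragments: pd.DataFrame
    dna_fragments: pd.DataFrame
    rna_dup_counts: np.ndarray  # extra copies per unique molecule
    dna_dup_counts: np.ndarray
    whitelists: list[list[str]]

    # -- planted-state queries ----------------------------------------
    def marked_genes(self, mark: str, cell_type: str, condition: str) -> list[str]:
        """Genes whose promoter carries ``mark`` in cells of this type/condition."""
        ci = CONDITIONS.index(condition)
        out = [g for g, states in self.config.planted_bivalency.items()
               if mark in STATE_MARKS[states[ci]]]
        out += list(self.config.type_marked_genes.get(mark, {}).get(cell_type, ()))
        return sorted(set(out))

    def aggregate_states(self, condition: str) -> pd.Series:
        """Per-gene promoter state of the pooled cell population.

        A mark is present for the pooled population when the gene is planted
        with that mark in ``condition`` or is cell-type-specifically marked in
        any simulated type (those cells are part of the pool).
        """
        ci = CONDITIONS.index(condition)
        type_marked = {m: set().union(*(set(v) for v in self.config.type_marked_genes.get(m, {}).values()))
                       if self.config.type_marked_genes.get(m) else set()
                       for m in MARKS}
        states = {}
        for g in self.config.gene_names():
            marks = set()
            if g in self.config.planted_bivalency:
                marks |= STATE_MARKS[self.config.planted_bivalency[g][ci]]
            for m in MARKS:
                if g in type_marked[m]:
                    marks.add(m)
            if marks == set(MARKS):
                states[g] = "bivalent"
            elif marks == {MARK_K4}:
                states[g] = "K4-only"
            elif marks == {MARK_K27}:
                states[g] = "K27-only"
            else:
                states[g] = "unmarked"
        return pd.Series(states, name=f"state_{condition}")

    def cell_type_states(self, cell_type: str, condition: str) -> pd.Series:
        """Per-gene promoter state within one cell type's population.

        Within a single type every gene is either fully marked (planted for
        the condition, or type-specific for this type) or fully unmarked, so
        pooled fragments of that type carry clean state signal.
        """
        marked = {m: set(self.marked_genes(m, cell_type, condition)) for m in MARKS}
        states = {}
        for g in self.config.gene_names():
            k4 = g in marked[MARK_K4]
            k27 = g in marked[MARK_K27]
            states[g] = ("bivalent" if k4 and k27 else
                         "K4-only" if k4 else "K27-only" if k27 else "unmarked")
        return pd.Series(states, name=f"state_{cell_type}_{condition}")

    def expected_rna_mean(self, gene: str, cell_type: str, condition: str) -> float:
        """Closed-form negative-binomial mean for one gene in one cell class."""
        cfg = self.config
        mu = cfg.rna_counts_per_cell / cfg.n_genes
        mu *= cfg.base_expression.get(gene, 1.0)
        ct = next(c for c in cfg.cell_types if c.name == cell_type)
        if gene in ct.markers:
            mu *= cfg.marker_upweight
        if condition == "exposed" and gene in cfg.expression_effect:
            mu *= 2.0 ** cfg.expression_effect[gene]
        return mu

    # -- serialization -------------------------------------------------
    def truth_table(self) -> pd.DataFrame:
        """Cell-level truth: barcode triple, type and group per cell."""
        return self.cells.copy()

    def gene_table(self) -> pd.DataFrame:
        """Gene-level truth: planted state per condition and expression effect."""
        ctl = self.aggregate_states("control")
        exp = self.aggregate_states("exposed")
        df = pd.DataFrame({"state_control": ctl, "state_exposed": exp})
        df["log2fc"] = [self.config.expression_effect.get(g, 0.0) for g in df.index]
        df.index.name = "gene_id"
        return df.reset_index()

    def write_tables(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.truth_table().to_csv(os.path.join(outdir, "truth_cells.tsv"), sep="\t", index=False)
        self.gene_table().to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t", index=False)

    def fragments_with_duplicates(self, modality: str) -> pd.DataFrame:
        """Unique molecules expanded by their planted PCR duplicate counts."""
        if modality == "RNA":
            frags, dups = self.rna_fragments, self.rna_dup_counts
        elif modality == "DNA":
            frags, dups = self.dna_fragments, self.dna_dup_counts
        else:
            raise ConfigurationError(f"unknown modality {modality!r}")
        reps = np.asarray(dups) + 1
        return frags.loc[frags.index.repeat(reps)].reset_index(drop=True)


# ----------------------------------------------------------------------
# cells, RNA counts, DNA fragments
# ----------------------------------------------------------------------

def _type_counts(fractions: list[float], n: int) -> list[int]:
    """Deterministic per-type cell counts: floor + largest-remainder."""
    raw = [f * n for f in fractions]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def _nb_draws(rng: np.random.Generator, mu: np.ndarray, dispersion: float, size) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion (var = mu + d*mu^2)."""
    if dispersion <= 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size)


def simulate_cells(config: SimConfig, genes: pd.DataFrame | None = None,
                   genome: dict[str, str] | None = None) -> SimTruth:
    """Draw the full population: cells, RNA counts and unique DNA/RNA molecules."""
    config.validate()
    if genome is None:
        genome_lengths = {f"chr{i + 1}": config.chromosome_length
                          for i in range(config.n_chromosomes)}
    else:
        genome_lengths = {c: len(s) for c, s in genome.items()}
    if genes is None:
        # gene placement only needs chromosome lengths
        genes = generate_gene_models(
            {c: "N" * genome_lengths[c] for c in genome_lengths}, config
        )

    rng_cells = stream(config.seed, 2)
    rng_rna = stream(config.seed, 3)
    rng_dna = stream(config.seed, 4)
    rng_dup = stream(config.seed, 5)

    whitelists = generate_whitelists(config.whitelist_sizes, config.bc_length)
    if len(config.groups) > len(whitelists[0]):
        raise ConfigurationError("more groups than round-1 barcodes (sample-of-origin)")

    gene_names = config.gene_names()
    gene_index = {g: i for i, g in enumerate(gene_names)}
    n_groups = len(config.groups)
    n_cells = config.n_cells_per_group

    # ---- cell table ----
    rows = []
    w2, w3 = whitelists[1], whitelists[2]
    n_pairs = len(w2) * len(w3)
    if n_cells > n_pairs:
        raise ConfigurationError("more cells per group than round-2 x round-3 combinations")
    for gi, grp in enumerate(config.groups):
        pair_ids = rng_cells.choice(n_pairs, size=n_cells, replace=False)
        counts = _type_counts([ct.fraction for ct in config.cell_types], n_cells)
        types = np.repeat([ct.name for ct in config.cell_types], counts)
        rng_cells.shuffle(types)
        for ci in range(n_cells):
            b2, b3 = divmod(int(pair_ids[ci]), len(w3))
            rows.append((
                f"{grp.name}:{ci:05d}", grp.name, grp.condition, grp.sex, grp.mark,
                types[ci], whitelists[0][gi], w2[b2], w3[b3],
            ))
    cells = pd.DataFrame(rows, columns=[
        "cell_id", "group", "condition", "sex", "mark", "cell_type", "bc1", "bc2", "bc3",
    ])
    cells["barcode"] = cells.bc3 + cells.bc2 + cells.bc1

    # ---- RNA counts ----
    base_mu = config.rna_counts_per_cell / config.n_genes
    mu_gene = np.full(config.n_genes, base_mu)
    for g, v in config.base_expression.items():
        mu_gene[gene_index[g]] = base_mu * v
    rna_counts = np.zeros((len(cells), config.n_genes), dtype=np.int32)
    for (ctype, cond), block in cells.groupby(["cell_type", "condition"], sort=True):
        mu = mu_gene.copy()
        ct = next(c for c in config.cell_types if c.name == ctype)
        for g in ct.markers:
            mu[gene_index[g]] *= config.marker_upweight
        if cond == "exposed":
            for g, lfc in config.expression_effect.items():
                mu[gene_index[g]] *= 2.0 ** lfc
        idx = block.index.to_numpy()
        rna_counts[idx] = _nb_draws(rng_rna, mu, config.nb_dispersion, (len(idx), config.n_genes))

    # ---- RNA unique molecules: one per UMI count, uniform within the gene span ----
    cell_idx_r, gene_idx_r = np.nonzero(rna_counts)
    reps = rna_counts[cell_idx_r, gene_idx_r]
    cell_of = np.repeat(cell_idx_r, reps)
    gene_of = np.repeat(gene_idx_r, reps)
    g_start = genes["start"].to_numpy()[gene_of]
    g_end = genes["end"].to_numpy()[gene_of]
    span = np.maximum(g_end - g_start - config.fragment_length, 1)
    starts = g_start + (rng_rna.random(len(gene_of)) * span).astype(np.int64)
    rna_fragments = pd.DataFrame({
        "chrom": pd.Categorical(genes["chrom"].to_numpy()[gene_of]),
        "start": starts,
        "end": np.minimum(starts + config.fragment_length,
                          np.array([genome_lengths[c] for c in genes["chrom"].to_numpy()[gene_of]])),
        "strand": pd.Categorical(genes["strand"].to_numpy()[gene_of]),
        "cell": pd.Categorical(cells["barcode"].to_numpy()[cell_of]),
        "cell_id": pd.Categorical(cells["cell_id"].to_numpy()[cell_of]),
        "umi": random_dna_array(rng_rna, len(gene_of), config.umi_length),
        "pcr_index": pd.Categorical(
            np.char.add("PI", (rng_rna.integers(1, config.n_pcr_indices + 1,
                                                len(gene_of))).astype(str))),
        "mapq": np.full(len(gene_of), 60, dtype=np.int16),
        "gene": pd.Categorical(np.array(gene_names, dtype=object)[gene_of]),
    })

    # ---- DNA unique molecules ----
    chrom_names = list(genome_lengths)
    chrom_len = np.array([genome_lengths[c] for c in chrom_names], dtype=np.int64)
    chrom_p = chrom_len / chrom_len.sum()
    tss = genes.set_index("gene_id")["tss"]
    gene_chrom = genes.set_index("gene_id")["chrom"]

    dna_parts = []
    for (grp_name, ctype), block in cells.groupby(["group", "cell_type"], sort=True):
        grp = next(g for g in config.groups if g.name == grp_name)
        marked = _sorted_marked(config, grp.mark, ctype, grp.condition)
        n_block = len(block)
        n_frag = config.fragments_per_cell_dna
        if marked:
            n_prom = rng_dna.binomial(n_frag, config.promoter_fraction_dna, size=n_block)
        else:
            n_prom = np.zeros(n_block, dtype=np.int64)
        n_bg = n_frag - n_prom

        # promoter placements
        tot_prom = int(n_prom.sum())
        if tot_prom:
            weights = np.array([config.mark_intensity.get(grp.mark, {}).get(g, 1.0)
                                for g in marked], dtype=float)
            weights = weights / weights.sum()
            pick = rng_dna.choice(len(marked), size=tot_prom, p=weights)
            marked_arr = np.array(marked, dtype=object)
            gsel = marked_arr[pick]
            center = tss.loc[gsel].to_numpy()
            offs = rng_dna.integers(-1_000, 1_000, size=tot_prom)
            pstart = center + offs
            pchrom = gene_chrom.loc[gsel].to_numpy()
            cell_rep = np.repeat(block["barcode"].to_numpy(), n_prom)
            cell_id_rep = np.repeat(block["cell_id"].to_numpy(), n_prom)
            dna_parts.append(pd.DataFrame({
                "chrom": pchrom, "start": pstart, "cell": cell_rep, "cell_id": cell_id_rep,
            }))
        tot_bg = int(n_bg.sum())
        if tot_bg:
            ci = rng_dna.choice(len(chrom_names), size=tot_bg, p=chrom_p)
            pos = (rng_dna.random(tot_bg) * (chrom_len[ci] - config.fragment_length)).astype(np.int64)
            dna_parts.append(pd.DataFrame({
                "chrom": np.array(chrom_names, dtype=object)[ci],
                "start": pos,
                "cell": np.repeat(block["barcode"].to_numpy(), n_bg),
                "cell_id": np.repeat(block["cell_id"].to_numpy(), n_bg),
            }))

    dna = pd.concat(dna_parts, ignore_index=True) if dna_parts else pd.DataFrame(
        columns=["chrom", "start", "cell", "cell_id"])
    # clip, pileup artifacts, tags
    lens = np.array([genome_lengths[c] for c in dna["chrom"]], dtype=np.int64)
    dna["start"] = np.clip(dna["start"].to_numpy(), 0, lens - config.fragment_length)
    dna["end"] = np.minimum(dna["start"] + config.fragment_length, lens)

    if config.pileup_artifacts_per_chrom > 0 and len(dna):
        # plant high-pileup artifact positions: many cells stacking on one spot
        art_rows = []
        all_cells = cells["barcode"].to_numpy()
        all_ids = cells["cell_id"].to_numpy()
        for ci, chrom in enumerate(chrom_names):
            for _ in range(config.pileup_artifacts_per_chrom):
                pos = int(rng_dna.integers(0, genome_lengths[chrom] - config.fragment_length))
                sel = rng_dna.choice(len(all_cells), size=config.pileup_artifact_depth)
                art_rows.append(pd.DataFrame({
                    "chrom": chrom, "start": pos, "cell": all_cells[sel],
                    "cell_id": all_ids[sel], "end": pos + config.fragment_length,
                }))
        dna = pd.concat([dna] + art_rows, ignore_index=True)

    n_dna = len(dna)
    dna["strand"] = pd.Categorical(np.full(n_dna, "+"))
    dna["cell"] = pd.Categorical(dna["cell"])
    dna["cell_id"] = pd.Categorical(dna["cell_id"])
    dna["chrom"] = pd.Categorical(dna["chrom"])
    dna["umi"] = random_dna_array(rng_dna, n_dna, config.umi_length)
    dna["pcr_index"] = pd.Categorical(
        np.char.add("PI", rng_dna.integers(1, config.n_pcr_indices + 1, n_dna).astype(str)))
    mapq = np.full(n_dna, 60, dtype=np.int16)
    if config.low_mapq_rate > 0 and n_dna:
        low = rng_dna.random(n_dna) < config.low_mapq_rate
        mapq[low] = rng_dna.integers(0, 11, size=int(low.sum()))
    dna["mapq"] = mapq
    dna = dna[["chrom", "start", "end", "strand", "cell", "cell_id",
               "umi", "pcr_index", "mapq"]]

    # ---- duplicate counts (geometric extras; mean d/(1-d)) ----
    d = config.duplicate_rate
    if d > 0:
        rna_dups = rng_dup.geometric(1.0 - d, size=len(rna_fragments)) - 1
        dna_dups = rng_dup.geometric(1.0 - d, size=len(dna)) - 1
    else:
        rna_dups = np.zeros(len(rna_fragments), dtype=np.int64)
        dna_dups = np.zeros(len(dna), dtype=np.int64)

    return SimTruth(
        config=config, genome_lengths=genome_lengths, genes=genes, cells=cells,
        rna_counts=rna_counts, rna_fragments=rna_fragments, dna_fragments=dna,
        rna_dup_counts=rna_dups, dna_dup_counts=dna_dups, whitelists=whitelists,
    )


def _sorted_marked(config: SimConfig, mark: str, cell_type: str, condition: str) -> list[str]:
    ci = CONDITIONS.index(condition)
    out = {g for g, states in config.planted_bivalency.items()
           if mark in STATE_MARKS[states[ci]]}
    out |= set(config.type_marked_genes.get(mark, {}).get(cell_type, ()))
    return sorted(out)


# ----------------------------------------------------------------------
# emission: fragments files and FASTQ
# ----------------------------------------------------------------------

FRAGMENT_COLUMNS = ["chrom", "start", "end", "cell", "umi", "pcr_index", "strand", "mapq"]


def emit_fragments(truth: SimTruth, outdir: str, modalities: tuple[str, ...] = ("DNA", "RNA"),
                   groups: list[str] | None = None) -> dict[tuple[str, str], str]:
    """Write coordinate-sorted BED-like fragment files per (group, modality).

    Records carry chrom/start/end plus cell barcode, UMI, PCR index, strand
    and MAPQ; PCR duplicates are included (the same realization that
    :func:`emit_reads` uses), so deduplication is exercised downstream.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[tuple[str, str], str] = {}
    barcode_to_group = dict(zip(truth.cells["barcode"], truth.cells["group"]))
    for modality in modalities:
        frags = truth.fragments_with_duplicates(modality)
        grp_col = frags["cell"].astype(str).map(barcode_to_group)
        for grp_name, block in frags.groupby(grp_col, sort=True):
            if groups is not None and grp_name not in groups:
                continue
            block = block.sort_values(["chrom", "start", "end"], kind="mergesort")
            path = os.path.join(outdir, f"{grp_name}.{modality}.fragments.tsv")
            block[FRAGMENT_COLUMNS].to_csv(path, sep="\t", index=False)
            paths[(grp_name, modality)] = path
        if groups is not None:
            for grp_name in groups:
                if (grp_name, modality) not in paths:
                    # empty but valid file with header
                    path = os.path.join(outdir, f"{grp_name}.{modality}.fragments.tsv")
                    pd.DataFrame(columns=FRAGMENT_COLUMNS).to_csv(path, sep="\t", index=False)
                    paths[(grp_name, modality)] = path
    return paths


def _mutate_one_base(rng: np.random.Generator, s: str) -> str:
    pos = int(rng.integers(0, len(s)))
    alt = BASES[int(rng.integers(0, 3))]
    if alt == s[pos]:
        alt = BASES[(BASES.index(alt) + 1) % 4]
    return s[:pos] + alt + s[pos + 1:]


def emit_reads(truth: SimTruth, genome: dict[str, str], outdir: str,
               modalities: tuple[str, ...] = ("DNA", "RNA"),
               groups: list[str] | None = None) -> dict:
    """Emit paired gzip FASTQ per (group, modality) plus a read-level truth table.

    Read 2 layout (jitter j in 0..jitter_max shifts everything right):

    ``[pad 9+j][BC3][linker2 29bp][BC2][linker1 21bp][UMI][BC1][suffix pad]``

    so the first bases of BC1/BC2/BC3 fall at 1-based positions 84+j / 47+j /
    10+j. Barcode substitution errors (at most one base per barcode per read),
    3' adapter contamination, RNA poly-dT tails and low-quality tails are
    injected at the configured rates; the PCR index travels in the read
    header comment.
    """
    cfg = truth.config
    rng = stream(cfg.seed, 6)
    os.makedirs(outdir, exist_ok=True)
    cells = truth.cells.set_index("cell_id")
    barcode_of = {cid: (row.bc1, row.bc2, row.bc3)
                  for cid, row in cells.iterrows()}
    group_of = cells["group"].to_dict()

    paths: dict[tuple[str, str], tuple[str, str]] = {}
    truth_rows = []
    counter = 0
    qual_hi = "I" * cfg.read_length

    for modality in modalities:
        frags = truth.fragments_with_duplicates(modality)
        grp_col = frags["cell_id"].astype(str).map(group_of)
        for grp_name, block in frags.groupby(grp_col, sort=True):
            if groups is not None and grp_name not in groups:
                continue
            n = len(block)
            jit = rng.integers(0, cfg.jitter_max + 1, size=n)
            err_draw = rng.random((n, 3)) < cfg.barcode_error_rate
            adapter_draw = rng.random(n) < cfg.adapter_contamination_rate
            polydt_draw = rng.random(n) < cfg.polydt_rate
            lowq_draw = rng.random(n) < cfg.low_quality_tail_rate
            pads = random_dna_array(rng, n, 9 + cfg.jitter_max)
            suffixes = random_dna_array(rng, n, cfg.read_length)
            fills = random_dna_array(rng, n, cfg.read_length)
            # contaminated reads come from short inserts, so the adapter or
            # poly-dT tail is visible within the read and trimming is exercised
            short_lens = rng.integers(40, max(cfg.read_length - 20, 41), size=n)

            r1_path = os.path.join(outdir, f"{grp_name}.{modality}.R1.fastq.gz")
            r2_path = os.path.join(outdir, f"{grp_name}.{modality}.R2.fastq.gz")
            with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
                starts = block["start"].to_numpy()
                ends = block["end"].to_numpy()
                chroms = block["chrom"].astype(str).to_numpy()
                cids = block["cell_id"].astype(str).to_numpy()
                umis = block["umi"].to_numpy()
                pis = block["pcr_index"].astype(str).to_numpy()
                for i in range(n):
                    cid = cids[i]
                    bc1, bc2, bc3 = barcode_of[cid]
                    if err_draw[i, 0]:
                        bc1 = _mutate_one_base(rng, bc1)
                    if err_draw[i, 1]:
                        bc2 = _mutate_one_base(rng, bc2)
                    if err_draw[i, 2]:
                        bc3 = _mutate_one_base(rng, bc3)
                    j = int(jit[i])
                    r2 = (pads[i][:9 + j] + bc3 + LINKER2 + bc2 + LINKER1
                          + umis[i] + bc1 + suffixes[i])
                    r2 = r2[:cfg.read_length]
                    # read 1: genomic/cDNA insert
                    chrom, s, e = chroms[i], int(starts[i]), int(ends[i])
                    insert = genome[chrom][s:s + cfg.read_length]
                    flen = min(e - s, cfg.read_length)
                    if adapter_draw[i]:
                        flen = min(flen, int(short_lens[i]))
                        r1 = (insert[:flen] + NEXTERA_ADAPTER + fills[i])[:cfg.read_length]
                    elif modality == "RNA" and polydt_draw[i]:
                        flen = min(flen, int(short_lens[i]))
                        r1 = (insert[:flen] + "T" * cfg.read_length)[:cfg.read_length]
                    else:
                        r1 = insert
                    if len(r1) < cfg.read_length:
                        r1 = (r1 + fills[i])[:cfg.read_length]
                    q1 = qual_hi[:len(r1)]
                    if lowq_draw[i]:
                        q1 = q1[:-15] + "#" * 15
                    rid = f"r{counter:08d}"
                    counter += 1
                    f1.write(f"@{rid} PI:{pis[i]}\n{r1}\n+\n{q1}\n")
                    f2.write(f"@{rid} PI:{pis[i]}\n{r2}\n+\n{qual_hi[:len(r2)]}\n")
                    truth_rows.append((rid, cid, grp_name, modality))
            paths[(grp_name, modality)] = (r1_path, r2_path)

    truth_reads = pd.DataFrame(truth_rows, columns=["read_id", "cell_id", "group", "modality"])
    truth_path = os.path.join(outdir, "truth_reads.tsv")
    truth_reads.to_csv(truth_path, sep="\t", index=False)
    return {"paths": paths, "truth_reads": truth_reads, "truth_reads_path": truth_path}
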