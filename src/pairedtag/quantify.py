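"""From tagged fragments to QC-filtered cell x feature count matrices.

The stage consumes aligned, tagged records (BED-like fragments carrying cell
barcode, UMI, PCR index, MAPQ) and produces a cell x gene matrix for RNA and
a cell x 5-kb-bin matrix for the histone (DNA) modality, applying the
standard Paired-Tag quality filters:

* DNA reads kept only when MAPQ > 10 (strict);
* PCR duplicates collapsed on (position, cell barcode, PCR index, UMI),
  where position = (chromosome, 5' start, strand);
* positions with pooled depth above a cutoff (default 10) removed entirely,
  regardless of barcode/index/UMI;
* low-coverage nuclei removed (< 200 RNA / < 500 DNA, applied to totals and
  to nonzero-feature counts), keeping only nuclei with matched profiles;
* the top 2% highest-covered bins removed; the DNA matrix binarized.

Matrices are AnnData objects (cells as obs, features as var) with sparse
integer counts.
"""

from __future__ import annotations

import math

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, InputError

FRAGMENT_KEYS = ["chrom", "start", "cell", "umi", "pcr_index"]


def _require_columns(fragments: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in fragments.columns]
    if missing:
        raise InputError(f"fragments missing required columns: {missing}")


def five_prime(fragments: pd.DataFrame) -> pd.Series:
    """Strand-aware 5' position: start on '+', end - 1 on '-'."""
    if "strand" not in fragments.columns:
        return fragments["start"]
    minus = fragments["strand"].astype(str).to_numpy() == "-"
    pos = fragments["start"].to_numpy().copy()
    pos[minus] = fragments["end"].to_numpy()[minus] - 1
    return pd.Series(pos, index=fragments.index)


def filter_mapq(fragments: pd.DataFrame, threshold: int = 10) -> pd.DataFrame:
    """Keep fragments with MAPQ strictly greater than ``threshold``."""
    _require_columns(fragments, ["mapq"])
    return fragments[fragments["mapq"] > threshold]


def deduplicate(fragments: pd.DataFrame) -> pd.DataFrame:
    """One representative per (position, cell barcode, PCR index, UMI).

    Position is (chromosome, 5' start, strand). Among copies of one tuple
    the highest-MAPQ record is kept (so deduplication commutes with the
    MAPQ filter); the output is independent of input order and the
    operation is idempotent.
    """
    _require_columns(fragments, FRAGMENT_KEYS)
    if fragments.empty:
        return fragments.copy()
    key_cols = ["chrom", "_pos5", "cell", "pcr_index", "umi"]
    if "strand" in fragments.columns:
        key_cols.insert(2, "strand")
    work = fragments.assign(_pos5=five_prime(fragments).to_numpy())
    sort_cols, ascending = list(key_cols), [True] * len(key_cols)
    if "mapq" in work.columns:
        sort_cols.append("mapq")
        ascending.append(False)
    work = work.sort_values(sort_cols, ascending=ascending, kind="mergesort")
    out = work.drop_duplicates(subset=key_cols, keep="first").drop(columns="_pos5")
    return out.reset_index(drop=True)


def remove_high_pileup(fragments: pd.DataFrame, cutoff: int = 10) -> pd.DataFrame:
    """Drop every fragment at positions with pooled depth above ``cutoff``.

    Depth is pooled over all cells, UMIs and PCR indices at (chromosome,
    5' start, strand); positions with depth > cutoff (strict) are removed
    entirely. Applied after deduplication, before matrix construction.
    """
    if fragments.empty or math.isinf(cutoff):
        return fragments.copy()
    key = pd.DataFrame({"chrom": fragments["chrom"].astype(str),
                        "pos": five_prime(fragments).to_numpy()})
    if "strand" in fragments.columns:
        key["strand"] = fragments["strand"].astype(str)
    depth = key.groupby(list(key.columns), observed=True)["pos"].transform("size")
    return fragments[depth.to_numpy() <= cutoff]


def _matrix_from_pairs(cells: pd.Series, feat_idx: np.ndarray, n_features: int,
                       feature_names: list[str], feature_kind: str) -> ad.AnnData:
    cell_cat = pd.Categorical(cells.astype(str))
    mat = sp.coo_matrix(
        (np.ones(len(feat_idx), dtype=np.int64), (cell_cat.codes, feat_idx)),
        shape=(len(cell_cat.categories), n_features),
    ).tocsr()
    adata = ad.AnnData(
        X=mat,
        obs=pd.DataFrame(index=pd.Index(cell_cat.categories, name="cell")),
        var=pd.DataFrame(index=pd.Index(feature_names, name="feature")),
    )
    adata.uns["feature_kind"] = feature_kind
    return adata


def make_bins(genome_sizes: dict[str, int], bin_size: int = 5_000) -> pd.DataFrame:
    """Tile every chromosome with fixed-size bins (no gaps, no overlaps)."""
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be positive")
    rows = []
    for chrom, length in genome_sizes.items():
        n = (length + bin_size - 1) // bin_size
        for i in range(n):
            rows.append((chrom, i, i * bin_size, min((i + 1) * bin_size, length)))
    return pd.DataFrame(rows, columns=["chrom", "index", "start", "end"])


def build_bin_matrix(fragments: pd.DataFrame, genome_sizes: dict[str, int],
                     bin_size: int = 5_000) -> ad.AnnData:
    """Cell x 5-kb-bin counts; each fragment increments the bin of its 5' start."""
    _require_columns(fragments, ["chrom", "start", "cell"])
    bins = make_bins(genome_sizes, bin_size)
    bin_names = [f"{c}:{s}-{e}" for c, s, e in zip(bins.chrom, bins.start, bins.end)]
    offset = {}
    running = 0
    for chrom, length in genome_sizes.items():
        offset[chrom] = running
        running += (length + bin_size - 1) // bin_size
    chroms = fragments["chrom"].astype(str)
    unknown = set(chroms.unique()) - set(genome_sizes)
    if unknown:
        raise InputError(f"fragments on unknown chromosomes: {sorted(unknown)}")
    pos = five_prime(fragments).to_numpy()
    lengths = chroms.map(genome_sizes).to_numpy()
    if (pos < 0).any() or (pos >= lengths).any():
        raise InputError("fragment position beyond chromosome end")
    feat_idx = chroms.map(offset).to_numpy() + pos // bin_size
    adata = _matrix_from_pairs(fragments["cell"], feat_idx, len(bin_names), bin_names, "bin")
    adata.var["chrom"] = bins["chrom"].to_numpy()
    adata.var["start"] = bins["start"].to_numpy()
    adata.var["end"] = bins["end"].to_numpy()
    return adata


def overlapping_genes(fragments: pd.DataFrame, genes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pairs (fragment row position, gene row position) for every interval overlap.

    A record overlaps a gene when [start, end) intersects the gene span.
    Implemented as a per-chromosome sweep over the (small) gene tables.
    """
    f_idx_parts, g_idx_parts = [], []
    genes = genes.reset_index(drop=True)
    frag_pos = np.arange(len(fragments))
    fr_chrom = fragments["chrom"].astype(str).to_numpy()
    fr_start = fragments["start"].to_numpy()
    fr_end = fragments["end"].to_numpy()
    for chrom, gblock in genes.groupby("chrom", sort=False):
        sel = fr_chrom == str(chrom)
        if not sel.any():
            continue
        fs, fe, fp = fr_start[sel], fr_end[sel], frag_pos[sel]
        for g_pos, g in gblock.iterrows():
            hit = (fs < g.end) & (fe > g.start)
            if hit.any():
                f_idx_parts.append(fp[hit])
                g_idx_parts.append(np.full(int(hit.sum()), g_pos))
    if not f_idx_parts:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(f_idx_parts), np.concatenate(g_idx_parts)


def build_gene_matrix(fragments: pd.DataFrame, genes: pd.DataFrame,
                      ambiguous: str = "count_all") -> tuple[ad.AnnData, int]:
    """Cell x gene UMI counts from deduplicated RNA records.

    A record increments every gene whose span it overlaps (``count_all``,
    featureCount-style union counting); with ``ambiguous="drop"`` records
    overlapping more than one gene are discarded. Returns the matrix and the
    number of records assigned to no gene (reported, not counted).
    """
    _require_columns(fragments, ["chrom", "start", "end", "cell"])
    if ambiguous not in ("count_all", "drop"):
        raise ConfigurationError(f"unknown ambiguous policy {ambiguous!r}")
    genes = genes.reset_index(drop=True)
    f_idx, g_idx = overlapping_genes(fragments, genes)
    if ambiguous == "drop" and len(f_idx):
        n_hits = np.bincount(f_idx, minlength=len(fragments))
        keep = n_hits[f_idx] == 1
        f_idx, g_idx = f_idx[keep], g_idx[keep]
    assigned = np.zeros(len(fragments), dtype=bool)
    assigned[f_idx] = True
    n_unassigned = int((~assigned).sum())
    gene_names = genes["gene_id"].tolist()
    cells = fragments["cell"].iloc[f_idx] if len(f_idx) else fragments["cell"].iloc[:0]
    adata = _matrix_from_pairs(cells, g_idx, len(gene_names), gene_names, "gene")
    return adata, n_unassigned


def feature_counts(adata: ad.AnnData) -> np.ndarray:
    """Per-cell number of nonzero features."""
    return np.asarray((adata.X > 0).sum(axis=1)).ravel()


def total_counts(adata: ad.AnnData) -> np.ndarray:
    return np.asarray(adata.X.sum(axis=1)).ravel()


def filter_low_coverage_cells(rna: ad.AnnData, dna: ad.AnnData,
                              min_rna: int = 200, min_dna: int = 500,
                              by: str = "features") -> tuple[ad.AnnData, ad.AnnData, list[str]]:
    """Keep nuclei with matched RNA+DNA profiles above both coverage floors.

    ``by="features"`` compares nonzero-feature counts, ``by="totals"`` total
    counts; the pipeline applies the total-count filter first and the feature
    filter second, both at <200 RNA / <500 DNA. Cells present in only one
    modality are an input error. Returns the two restricted matrices plus the
    removed cell identifiers.
    """
    shared = rna.obs_names.intersection(dna.obs_names)
    if len(shared) == 0:
        raise InputError("RNA and DNA matrices share no cells")
    rna = rna[shared].copy()
    dna = dna[shared].copy()
    stat = feature_counts if by == "features" else total_counts
    if by not in ("features", "totals"):
        raise ConfigurationError(f"unknown filter statistic {by!r}")
    keep = (stat(rna) >= min_rna) & (stat(dna) >= min_dna)
    removed = list(np.asarray(shared)[~keep])
    if not keep.any():
        raise InputError(
            f"no cells pass the coverage filters (RNA >= {min_rna}, DNA >= {min_dna})")
    return rna[keep].copy(), dna[keep].copy(), removed


def filter_top_bins(dna: ad.AnnData, fraction: float = 0.02) -> ad.AnnData:
    """Remove the ceil(fraction * n_bins) bins with the highest total coverage.

    Ties at the boundary are broken by genomic coordinate: earlier bins are
    kept, later ones removed, so the result is deterministic.
    """
    if not 0 <= fraction < 1:
        raise ConfigurationError("fraction must be in [0, 1)")
    if dna.n_vars == 0:
        raise InputError("empty bin matrix")
    if fraction == 0:
        return dna.copy()
    n_remove = math.ceil(fraction * dna.n_vars)
    totals = np.asarray(dna.X.sum(axis=0)).ravel()
    # removal order: coverage descending, ties by coordinate descending, so
    # among boundary ties the later-coordinate bins are removed first
    order = np.lexsort((-np.arange(dna.n_vars), -totals))
    drop = set(order[:n_remove].tolist())
    keep = np.array([i not in drop for i in range(dna.n_vars)])
    return dna[:, keep].copy()


def binarize(dna: ad.AnnData) -> ad.AnnData:
    """Entries become 1 where positive; idempotent."""
    out = dna.copy()
    x = out.X.tocsr() if sp.issparse(out.X) else sp.csr_matrix(out.X)
    x.data = (x.data > 0).astype(np.int64)
    x.eliminate_zeros()
    out.X = x
    return out


def exact_match_locate(reads: list[tuple[str, str]], genome: dict[str, str]) -> pd.DataFrame:
    """Trivial exact-substring locator for toy genomes.

    Maps each (read_id, sequence) to the first exact occurrence across
    chromosomes; unmapped reads get chrom ``None``/MAPQ 0, unique hits MAPQ
    60. Only intended for end-to-end tests on small synthetic genomes —
    real alignment is delegated to external aligners and is out of scope.
    """
    rows = []
    for read_id, seq in reads:
        hit = None
        for chrom, ref in genome.items():
            pos = ref.find(seq)
            if pos >= 0:
                hit = (chrom, pos)
                break
        if hit is None:
            rows.append((read_id, None, -1, -1, 0))
        else:
            rows.append((read_id, hit[0], hit[1], hit[1] + len(seq), 60))
    return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end", "mapq"])
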