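"""Promoter histone signal, metagene profiles, bivalency calls and transitions.

For each gene the promoter signal is the number of fragment 5' ends falling
in the strand-aware window TSS +/- 1 kb, normalized either to reads per
million mapped fragments (RPM = count / group total x 1e6) or to fragments
per kilobase per million (FPKM = count / (window kb x group total in
millions)). Metagene profiles bin the same window on a fixed grid (default
50 bp), flipping minus-strand genes so positive positions run downstream of
the TSS.

A mark is called "present" at a promoter when its RPM reaches a threshold,
by default the 95th percentile of the RPM observed in randomly placed
promoter-sized background windows; the joint state of the two marks gives
the bivalency call (bivalent / K4-only / K27-only / unmarked) per condition,
and state pairs across conditions give named transitions (e.g. bivalent ->
K4-only is the loss of the repressive mark, "K27 resolved").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError
from .quantify import five_prime
from .simulate import MARK_K4, MARK_K27

TRANSITION_LABELS = {
    ("bivalent", "K4-only"): "K27 resolved",
    ("bivalent", "K27-only"): "K4 lost",
    ("bivalent", "unmarked"): "bivalency lost",
    ("K4-only", "bivalent"): "K27 gained",
    ("K27-only", "bivalent"): "K4 gained",
    ("unmarked", "bivalent"): "bivalency gained",
}


def _strand_aware_offsets(pos5: np.ndarray, tss: int, strand: str) -> np.ndarray:
    """Offset of each 5' position relative to the TSS, positive downstream."""
    return pos5 - tss if strand == "+" else tss - pos5


def _window_bounds(tss: int, strand: str, window: int) -> tuple[int, int]:
    """Genomic half-open [lo, hi) whose strand-aware offsets span [-window, window)."""
    if strand == "+":
        return tss - window, tss + window
    return tss - window + 1, tss + window + 1


def _positions_by_chrom(fragments: pd.DataFrame) -> dict[str, np.ndarray]:
    pos5 = five_prime(fragments).to_numpy()
    chroms = fragments["chrom"].astype(str).to_numpy()
    order = np.argsort(chroms, kind="mergesort")
    out: dict[str, np.ndarray] = {}
    sorted_chroms = chroms[order]
    sorted_pos = pos5[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_chroms[1:] != sorted_chroms[:-1], True])
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        out[sorted_chroms[s]] = np.sort(sorted_pos[s:e])
    return out


def promoter_signal(fragments: pd.DataFrame, genes: pd.DataFrame,
                    window: int = 1_000,
                    total_fragments: int | None = None) -> pd.DataFrame:
    """Per-gene promoter fragment count with RPM and FPKM normalizations.

    A fragment is counted for a gene when its strand-aware offset from the
    TSS lies in [-window, window). ``total_fragments`` defaults to the size
    of ``fragments`` (the group's mapped total); a zero total is an error.
    """
    total = len(fragments) if total_fragments is None else int(total_fragments)
    if total == 0:
        raise InputError("group has zero total fragments")
    sorted_pos = _positions_by_chrom(fragments)
    counts = np.zeros(len(genes), dtype=np.int64)
    for i, g in enumerate(genes.itertuples()):
        arr = sorted_pos.get(g.chrom)
        if arr is None:
            continue
        lo, hi = _window_bounds(g.tss, g.strand, window)
        counts[i] = int(np.searchsorted(arr, hi) - np.searchsorted(arr, lo))
    rpm = counts / total * 1e6
    fpkm = counts / ((2 * window / 1_000) * (total / 1e6))
    return pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        "count": counts, "rpm": rpm, "fpkm": fpkm,
    })


@dataclass
class TssProfile:
    """Binned metagene signal around the TSS.

    ``positions`` holds the left edge (bp relative to TSS, downstream
    positive) of each grid bin; ``matrix`` is genes x bins; ``mean`` the
    unweighted per-position mean over genes.
    """

    positions: np.ndarray
    matrix: np.ndarray
    gene_ids: list[str]

    @property
    def mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def tss_profile(fragments: pd.DataFrame, genes: pd.DataFrame,
                window: int = 1_000, step: int = 50) -> TssProfile:
    """Strand-flipped per-gene binned counts over TSS +/- window.

    The grid covers [-window, window) in ``step``-bp bins; the per-gene row
    sums equal the :func:`promoter_signal` counts (same window convention).
    """
    if (2 * window) % step != 0:
        raise ConfigurationError(f"step {step} does not divide the {2 * window} bp window")
    n_bins = (2 * window) // step
    sorted_pos = _positions_by_chrom(fragments)
    mat = np.zeros((len(genes), n_bins), dtype=np.int64)
    for i, g in enumerate(genes.itertuples()):
        arr = sorted_pos.get(g.chrom)
        if arr is None:
            continue
        lo, hi = _window_bounds(g.tss, g.strand, window)
        hit = arr[np.searchsorted(arr, lo):np.searchsorted(arr, hi)]
        offs = _strand_aware_offsets(hit, g.tss, g.strand)
        bins = (offs + window) // step
        np.add.at(mat[i], bins.astype(int), 1)
    positions = np.arange(-window, window, step)
    return TssProfile(positions, mat, genes["gene_id"].tolist())


def background_threshold(fragments: pd.DataFrame, genome_sizes: dict[str, int],
                         genes: pd.DataFrame | None = None, window: int = 1_000,
                         n_windows: int = 500, percentile: float = 95.0,
                         enrichment: float = 2.0, seed: int = 0,
                         total_fragments: int | None = None) -> float:
    """RPM threshold: a percentile over random background windows, times a
    fold-enrichment factor.

    Windows of promoter size (2 x ``window``) are placed uniformly over the
    genome, avoiding promoter regions when gene models are supplied. The
    raw percentile describes the upper envelope of background sampling
    noise; by construction ~(100 - percentile)% of background-like windows
    still exceed it, so the default threshold demands ``enrichment``-fold
    (2x) that envelope — a promoter must be genuinely enriched, not merely
    in the background upper tail, to count as marked.
    """
    rng = np.random.default_rng(seed)
    total = len(fragments) if total_fragments is None else int(total_fragments)
    if total == 0:
        raise InputError("group has zero total fragments")
    chrom_names = list(genome_sizes)
    lengths = np.array([genome_sizes[c] for c in chrom_names], dtype=np.int64)
    probs = lengths / lengths.sum()
    promoters = None
    if genes is not None:
        promoters = {(g.chrom): [] for g in genes.itertuples()}
        for g in genes.itertuples():
            promoters[g.chrom].append((g.tss - 2 * window, g.tss + 2 * window))
    pos5 = five_prime(fragments).to_numpy()
    chroms = fragments["chrom"].astype(str).to_numpy()
    by_chrom = {c: np.sort(pos5[chroms == c]) for c in chrom_names}
    counts = []
    attempts = 0
    while len(counts) < n_windows and attempts < 50 * n_windows:
        attempts += 1
        ci = int(rng.choice(len(chrom_names), p=probs))
        chrom = chrom_names[ci]
        start = int(rng.integers(0, max(lengths[ci] - 2 * window, 1)))
        if promoters is not None:
            bad = any(start < e and start + 2 * window > s
                      for s, e in promoters.get(chrom, []))
            if bad:
                continue
        arr = by_chrom[chrom]
        counts.append(int(np.searchsorted(arr, start + 2 * window) - np.searchsorted(arr, start)))
    if not counts:
        raise InputError("could not place any background window")
    return enrichment * float(np.percentile(np.asarray(counts) / total * 1e6, percentile))


def call_bivalency(k4_signal: pd.DataFrame, k27_signal: pd.DataFrame,
                   k4_threshold: float, k27_threshold: float,
                   condition: str | None = None) -> pd.DataFrame:
    """Joint mark-state call per gene from the two promoter RPM tables.

    A mark is present when its RPM >= its threshold; both -> bivalent, one
    -> K4-only / K27-only, neither -> unmarked. Thresholds used are recorded
    in the output.
    """
    for name, df in (("K4", k4_signal), ("K27", k27_signal)):
        if "rpm" not in df.columns:
            raise InputError(f"{name} signal table lacks an 'rpm' column")
    merged = k4_signal[["gene_id", "rpm"]].merge(
        k27_signal[["gene_id", "rpm"]], on="gene_id", suffixes=("_k4", "_k27"),
        how="inner", validate="one_to_one",
    )
    if len(merged) != len(k4_signal) or len(merged) != len(k27_signal):
        raise InputError("K4 and K27 signal tables cover different gene sets")
    k4_on = merged["rpm_k4"] >= k4_threshold
    k27_on = merged["rpm_k27"] >= k27_threshold
    state = np.where(k4_on & k27_on, "bivalent",
                     np.where(k4_on, "K4-only",
                              np.where(k27_on, "K27-only", "unmarked")))
    out = pd.DataFrame({
        "gene_id": merged["gene_id"], "state": state,
        "rpm_k4": merged["rpm_k4"], "rpm_k27": merged["rpm_k27"],
        "k4_threshold": k4_threshold, "k27_threshold": k27_threshold,
    })
    if condition is not None:
        out["condition"] = condition
    return out


def call_transitions(control_calls: pd.DataFrame,
                     exposed_calls: pd.DataFrame) -> pd.DataFrame:
    """Label the state pair of each gene across conditions.

    Unchanged states are ``stable``; named transitions cover the bivalency
    gains/losses (e.g. bivalent -> K4-only is "K27 resolved"); any other
    pair is labelled ``"<from>-><to>"``.
    """
    a = control_calls.set_index("gene_id")["state"]
    b = exposed_calls.set_index("gene_id")["state"]
    if set(a.index) != set(b.index):
        raise InputError("control and exposed calls cover different gene sets")
    b = b.reindex(a.index)
    labels = []
    for s1, s2 in zip(a, b):
        if s1 == s2:
            labels.append("stable")
        else:
            labels.append(TRANSITION_LABELS.get((s1, s2), f"{s1}->{s2}"))
    return pd.DataFrame({
        "gene_id": a.index, "state_control": a.to_numpy(),
        "state_exposed": b.to_numpy(), "transition": labels,
    }).reset_index(drop=True)


def correlate_signal_expression(signal, expression) -> tuple[float, float]:
    """Pearson r and two-sided t-based p between promoter signal and expression."""
    x = np.asarray(signal, dtype=float)
    y = np.asarray(expression, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def compare_group_signal(signals_a, signals_b, test: str = "wilcoxon") -> tuple[float, float]:
    """Two-sided two-sample comparison of promoter signal between DEG sets.

    ``wilcoxon`` uses the package's rank-sum test; ``ttest`` Welch's t.
    Symmetric under group swap.
    """
    a = np.asarray(signals_a, dtype=float)
    b = np.asarray(signals_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("both groups need >= 2 observations")
    if test == "wilcoxon":
        from .differential import wilcoxon_rank_sum

        return wilcoxon_rank_sum(a, b, mode="normal")
    if test == "ttest":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise ConfigurationError(f"unknown test {test!r}")
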