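"""Combinatorial barcode demultiplexing of Paired-Tag Read 2.

Read 2 carries three rounds of cellular barcodes separated by fixed linker
sequences; the first bases of BC1, BC2 and BC3 must fall within the 84th-87th,
47th-50th and 10th-13th bases of the read (1-based). Barcodes are located by
anchoring the linkers (exact match first, then a single-mismatch fallback),
then resolved against per-round whitelists with at most one substitution and
a uniqueness requirement: a raw barcode within Hamming distance 1 of exactly
one whitelist entry is corrected to it; anything else is discarded as
``no_match`` or ``ambiguous``. Matching is substitution-only (no indels) and
forward-strand only. Round-1 barcodes identify the sample of origin.

Read 1 is adapter-trimmed (and poly-dT-trimmed for RNA), 3'-quality-trimmed
and length-filtered (defaults L=30, Q=30) before leaving the stage.
"""

from __future__ import annotations

import collections
import gzip
import itertools
import os
from dataclasses import dataclass, field

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigurationError, InputError
from .simulate import LINKER1, LINKER2, NEXTERA_ADAPTER
from .utils import BASES, mismatches_capped

OK = "ok"
LINKER_NOT_FOUND = "linker_not_found"
OUT_OF_WINDOW = "out_of_window"
NO_MATCH = "no_match"
AMBIGUOUS = "ambiguous"

STATUSES = (OK, LINKER_NOT_FOUND, OUT_OF_WINDOW, NO_MATCH, AMBIGUOUS)


@dataclass(frozen=True)
class BarcodeLayout:
    """Geometry of Read 2: barcode/UMI lengths, linkers and position windows.

    ``windows`` are 1-based inclusive ranges for the first base of each
    barcode round; the defaults encode BC1: 84-87, BC2: 47-50, BC3: 10-13
    with window width 4 (start-position jitter 0-3).
    """

    bc_lengths: tuple[int, int, int] = (8, 8, 8)
    umi_length: int = 8
    linker1: str = LINKER1
    linker2: str = LINKER2
    windows: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = (
        (84, 87), (47, 50), (10, 13),
    )

    def __post_init__(self) -> None:
        (w1, w2, w3) = self.windows
        if not (w3[0] < w2[0] < w1[0]):
            raise ConfigurationError("windows must be ordered BC3 < BC2 < BC1 along Read 2")
        widths = {hi - lo for lo, hi in self.windows}
        if widths != {3}:
            raise ConfigurationError("window width must be 4 (jitter 0-3)")
        # layout must be internally consistent: at jitter j the three barcode
        # start positions move together
        b3, b2, b1 = w3[0], w2[0], w1[0]
        if b2 != b3 + self.bc_lengths[2] + len(self.linker2):
            raise ConfigurationError("BC2 window incompatible with BC3 length + linker2")
        if b1 != b2 + self.bc_lengths[1] + len(self.linker1) + self.umi_length:
            raise ConfigurationError("BC1 window incompatible with BC2 length + linker1 + UMI")

    @property
    def jitter_range(self) -> range:
        lo, hi = self.windows[2]
        return range(0, hi - lo + 1)

    @property
    def footprint(self) -> int:
        """Minimum Read 2 length able to contain the full layout at max jitter."""
        return self.windows[0][1] - 1 + self.bc_lengths[0]


@dataclass
class QCParams:
    """Read 1 trimming/filtering parameters (defaults L=30, Q=30, MAPQ 10)."""

    min_length: int = 30
    min_quality: int = 30
    mapq_threshold: int = 10
    adapter: str = NEXTERA_ADAPTER

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ConfigurationError("min_length must be >= 1")
        if not 0 <= self.min_quality <= 41:
            raise ConfigurationError("min_quality must be in [0, 41]")


class BarcodeReference:
    """Per-round whitelists with exact and Hamming-1 lookup indices.

    The combined reference enumerates every barcode combination (|W1| x |W2|
    x |W3|); with the default 96 x 96 x 12 round sizes that is 110,592 cells.
    """

    def __init__(self, whitelists: list[list[str]]):
        if len(whitelists) != 3:
            raise ConfigurationError("exactly three whitelists are required")
        self.whitelists = [list(w) for w in whitelists]
        self.exact: list[dict[str, int]] = []
        self.neighbors: list[dict[str, set[int]]] = []
        for rnd, wl in enumerate(self.whitelists):
            if not wl:
                raise ConfigurationError(f"round {rnd + 1} whitelist is empty")
            lengths = {len(b) for b in wl}
            if len(lengths) != 1:
                raise ConfigurationError(f"round {rnd + 1} has mixed barcode lengths")
            if len(set(wl)) != len(wl):
                raise ConfigurationError(f"round {rnd + 1} whitelist has duplicate entries")
            exact = {b: i for i, b in enumerate(wl)}
            neigh: dict[str, set[int]] = collections.defaultdict(set)
            for i, b in enumerate(wl):
                for pos in range(len(b)):
                    for alt in BASES + "N":
                        if alt != b[pos]:
                            neigh[b[:pos] + alt + b[pos + 1:]].add(i)
            self.exact.append(exact)
            self.neighbors.append(dict(neigh))

    @property
    def n_combinations(self) -> int:
        n = 1
        for wl in self.whitelists:
            n *= len(wl)
        return n

    def resolve_round(self, raw: str, rnd: int) -> int | str:
        """Resolve one raw barcode: whitelist index, ``no_match`` or ``ambiguous``.

        An exact hit wins outright (it is the unique minimum-distance entry
        because whitelist entries are pairwise distinct). Otherwise the
        Hamming-1 neighbour index is consulted; exactly one candidate means a
        corrected assignment, more than one is ambiguous. ``N`` counts as a
        mismatch against every base.
        """
        exact = self.exact[rnd]
        if len(raw) != len(next(iter(exact))):
            raise InputError(f"round {rnd + 1}: barcode length {len(raw)} != whitelist length")
        hit = exact.get(raw)
        if hit is not None:
            return hit
        cands = self.neighbors[rnd].get(raw)
        if cands is None:
            return NO_MATCH
        if len(cands) == 1:
            return next(iter(cands))
        return AMBIGUOUS


def build_barcode_reference(whitelists: list[list[str]]) -> BarcodeReference:
    return BarcodeReference(whitelists)


@dataclass
class LocatedBarcodes:
    status: str
    bc1: str = ""
    bc2: str = ""
    bc3: str = ""
    umi: str = ""
    jitter: int = -1


def locate_barcodes(read2: str, layout: BarcodeLayout,
                    max_linker_mismatch: int = 1) -> LocatedBarcodes:
    """Anchor the linkers within the allowed jitter and extract raw barcodes.

    Tries each jitter offset with exact linker matches first, then retries
    allowing up to ``max_linker_mismatch`` substitutions per linker. When no
    offset works, a free exact search for linker2 distinguishes reads whose
    layout sits outside the allowed windows (``out_of_window``) from reads
    with corrupted linkers (``linker_not_found``).
    """
    b3_lo = layout.windows[2][0] - 1  # 0-based first-base position at jitter 0
    l3, l2len, l1len = layout.bc_lengths[2], len(layout.linker2), len(layout.linker1)
    if len(read2) < layout.footprint:
        return LocatedBarcodes(LINKER_NOT_FOUND)
    for cap in (0, max_linker_mismatch):
        for j in layout.jitter_range:
            p3 = b3_lo + j
            p_l2 = p3 + l3
            p2 = p_l2 + l2len
            p_l1 = p2 + layout.bc_lengths[1]
            p_umi = p_l1 + l1len
            p1 = p_umi + layout.umi_length
            if mismatches_capped(read2[p_l2:p_l2 + l2len], layout.linker2, cap) > cap:
                continue
            if mismatches_capped(read2[p_l1:p_l1 + l1len], layout.linker1, cap) > cap:
                continue
            return LocatedBarcodes(
                OK,
                bc1=read2[p1:p1 + layout.bc_lengths[0]],
                bc2=read2[p2:p2 + layout.bc_lengths[1]],
                bc3=read2[p3:p3 + l3],
                umi=read2[p_umi:p_umi + layout.umi_length],
                jitter=j,
            )
    # diagnose: is the layout present but shifted outside the windows?
    pos = read2.find(layout.linker2)
    if pos >= 0:
        implied_b3 = pos - l3
        if implied_b3 < b3_lo or implied_b3 > b3_lo + layout.jitter_range[-1]:
            return LocatedBarcodes(OUT_OF_WINDOW)
    return LocatedBarcodes(LINKER_NOT_FOUND)


@dataclass
class CellBarcode:
    """A fully resolved cell: whitelist entries per round plus derived labels."""

    bc1: str
    bc2: str
    bc3: str

    @property
    def cell_id(self) -> str:
        return self.bc3 + self.bc2 + self.bc1

    @property
    def sample_of_origin(self) -> str:
        """Round-1 barcode labels the sample (the 12 first-round wells)."""
        return self.bc1


def assign_cell(raw: tuple[str, str, str], reference: BarcodeReference):
    """Resolve a raw barcode triple to a cell, or a discard reason.

    Mirrors one-mismatch unique alignment against the combinatorial
    reference: each round must resolve within Hamming distance <= 1 to
    exactly one whitelist entry; reads failing any round are discarded with
    reason ``no_match`` (distance > 1 everywhere) or ``ambiguous`` (two or
    more entries at the minimal distance <= 1).
    """
    resolved = []
    for rnd, raw_bc in enumerate(raw):
        res = reference.resolve_round(raw_bc, rnd)
        if res == NO_MATCH:
            return NO_MATCH
        if res == AMBIGUOUS:
            return AMBIGUOUS
        resolved.append(reference.whitelists[rnd][res])
    return CellBarcode(*resolved)


# ----------------------------------------------------------------------
# Read 1 trimming
# ----------------------------------------------------------------------

def _find_adapter(seq: str, adapter: str, min_overlap: int = 10,
                  max_mismatch_frac: float = 0.10) -> int:
    """Leftmost 3' adapter start, or -1.

    A hit needs >= ``min_overlap`` aligned bases and a mismatch fraction of
    at most ``max_mismatch_frac`` over the aligned portion.
    """
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        overlap = min(len(adapter), n - i)
        allowed = int(max_mismatch_frac * overlap)
        if mismatches_capped(seq[i:i + overlap], adapter[:overlap], allowed) <= allowed:
            return i
    return -1


def trim_and_filter(seq: str, qual: str, modality: str, qc: QCParams):
    """Adapter-, poly-dT- and quality-trim Read 1; drop if shorter than L.

    Returns ``(seq, qual, reason)`` where reason is ``None`` when kept.
    Poly-dT removal (RNA only) strips a terminal run of >= 6 T's or A's left
    after adapter trimming; quality trimming removes 3' bases below Q.
    """
    pos = _find_adapter(seq, qc.adapter)
    if pos >= 0:
        seq, qual = seq[:pos], qual[:pos]
    if modality == "RNA" and seq:
        tail = seq[-1]
        if tail in "AT":
            run = len(seq) - len(seq.rstrip(tail))
            if run >= 6:
                seq, qual = seq[:-run], qual[:-run]
    cut = len(qual)
    while cut > 0 and (ord(qual[cut - 1]) - 33) < qc.min_quality:
        cut -= 1
    seq, qual = seq[:cut], qual[:cut]
    if len(seq) < qc.min_length:
        return seq, qual, "length"
    return seq, qual, None


# ----------------------------------------------------------------------
# file-level demultiplexing
# ----------------------------------------------------------------------

@dataclass
class DemuxResult:
    output_path: str
    report: pd.DataFrame          # counts by status (+ trim drops)
    per_sample: pd.DataFrame      # assigned reads per sample-of-origin
    assignments: pd.DataFrame     # read_id -> cell_id for kept reads


def demux_fastq(r1_path: str, r2_path: str, reference: BarcodeReference,
                modality: str, out_path: str,
                layout: BarcodeLayout | None = None,
                qc: QCParams | None = None) -> DemuxResult:
    """Demultiplex one paired FASTQ library.

    Kept reads are written as gzip FASTQ with the cell barcode, UMI and PCR
    index encoded in the read name as ``@orig|CB:xxx|UMI:yyy|PI:zzz``. The
    report counts every input read exactly once:
    ``reads_in = assigned + no_match + ambiguous + linker_not_found +
    out_of_window``, with assigned further split into kept vs trim-dropped.
    """
    layout = layout or BarcodeLayout()
    qc = qc or QCParams()
    counts = collections.Counter()
    per_sample = collections.Counter()
    assignments = []
    os.makedirs(os.path.dirname(os.path.abspath(out_path)), exist_ok=True)
    with gzip.open(r1_path, "rt") as f1, gzip.open(r2_path, "rt") as f2, \
            gzip.open(out_path, "wt") as out:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (t1, s1, q1), (t2, s2, _q2) in itertools.zip_longest(it1, it2, fillvalue=(None,) * 3):
            if t1 is None or t2 is None:
                raise InputError("R1/R2 read counts differ")
            counts["reads_in"] += 1
            loc = locate_barcodes(s2, layout)
            if loc.status != OK:
                counts[loc.status] += 1
                continue
            cell = assign_cell((loc.bc1, loc.bc2, loc.bc3), reference)
            if isinstance(cell, str):
                counts[cell] += 1
                continue
            counts["assigned"] += 1
            per_sample[cell.sample_of_origin] += 1
            name = t1.split()[0]
            pi = ""
            for tok in t1.split()[1:]:
                if tok.startswith("PI:"):
                    pi = tok[3:]
            seq, qual, reason = trim_and_filter(s1, q1, modality, qc)
            if reason is not None:
                counts[f"dropped_{reason}"] += 1
                continue
            counts["kept"] += 1
            out.write(f"@{name}|CB:{cell.cell_id}|UMI:{loc.umi}|PI:{pi}\n{seq}\n+\n{qual}\n")
            assignments.append((name, cell.cell_id, loc.umi, pi))

    report = pd.DataFrame(
        [(k, counts.get(k, 0)) for k in
         ("reads_in", "assigned", "kept", "dropped_length",
          NO_MATCH, AMBIGUOUS, LINKER_NOT_FOUND, OUT_OF_WINDOW)],
        columns=["status", "count"],
    )
    sample_df = pd.DataFrame(sorted(per_sample.items()), columns=["sample", "assigned"])
    assign_df = pd.DataFrame(assignments, columns=["read_id", "cell", "umi", "pcr_index"])
    return DemuxResult(out_path, report, sample_df, assign_df)
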