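"""Gene models and genic annotation of peaks/bins.

Gene models use 0-based half-open coordinates internally (GTF's 1-based
closed convention is converted at the boundary); the TSS is the start of a
'+' gene and end - 1 of a '-' gene. A peak is assigned exactly one category
by overlap with gene-derived regions under the precedence

    Promoter > 5'UTR > 3'UTR > Exon > Intron > Downstream > DistalIntergenic

where Promoter = TSS +/- 1 kb (symmetric), Downstream extends up to 3 kb
past the gene 3' end (strand-aware), and membership is decided by any
overlap of the peak interval with the region. The signed distance reported
is peak-center-to-nearest-TSS, positive downstream of the TSS in the gene's
reading direction; nearest-gene ties break by gene id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

CATEGORIES = (
    "Promoter", "5'UTR", "3'UTR", "Exon", "Intron", "Downstream", "DistalIntergenic",
)

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]


def compute_tss(start: int, end: int, strand: str) -> int:
    """TSS of a 0-based half-open gene span: start on '+', end - 1 on '-'."""
    if strand == "+":
        return start
    if strand == "-":
        return end - 1
    raise InputError(f"invalid strand {strand!r}")


def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.strip().rstrip(";").split(";"):
        field = field.strip()
        if not field:
            continue
        key, _, value = field.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def parse_gene_models(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a GTF into (genes, exons) tables with 0-based half-open spans.

    Only ``gene`` and ``exon`` features are consumed; malformed lines raise
    with their line number.
    """
    genes, exons = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise InputError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if strand not in "+-":
                raise InputError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            try:
                start0 = int(start) - 1
                end0 = int(end)
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-numeric coordinates") from None
            gene_id = _parse_attributes(attrs).get("gene_id", "")
            if feature == "gene":
                genes.append((gene_id, chrom, start0, end0, strand,
                              compute_tss(start0, end0, strand)))
            elif feature == "exon":
                exons.append((gene_id, chrom, start0, end0, strand))
    gene_df = pd.DataFrame(genes, columns=GENE_COLUMNS)
    exon_df = pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end", "strand"])
    return gene_df, exon_df


def write_gene_models(genes: pd.DataFrame, path: str,
                      exons: pd.DataFrame | None = None) -> None:
    """Write gene (and optional exon) models as GTF (1-based closed)."""
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.chrom}\tpairedtag\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            if exons is not None:
                for _, e in exons[exons.gene_id == g.gene_id].iterrows():
                    fh.write(f"{e.chrom}\tpairedtag\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n")


def promoter_windows(genes: pd.DataFrame, upstream: int = 1_000, downstream: int = 1_000,
                     chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """TSS +/- 1 kb promoter intervals, clipped at chromosome bounds."""
    tss = genes["tss"].to_numpy()
    start = tss - upstream
    end = tss + downstream
    start = np.maximum(start, 0)
    if chrom_sizes is not None:
        limits = genes["chrom"].map(chrom_sizes).to_numpy()
        end = np.minimum(end, limits)
    return pd.DataFrame({
        "gene_id": genes["gene_id"], "chrom": genes["chrom"],
        "start": start, "end": end,
    })


def _overlaps(p_start: int, p_end: int, r_start: int, r_end: int) -> bool:
    return p_start < r_end and p_end > r_start


def annotate_peak(peak: tuple[str, int, int], genes: pd.DataFrame,
                  exons: pd.DataFrame | None = None,
                  promoter_up: int = 1_000, promoter_down: int = 1_000,
                  downstream_limit: int = 3_000,
                  known_chroms: set[str] | None = None) -> tuple[str, str, int]:
    """Classify one peak: (category, nearest gene, signed center-to-TSS distance).

    Membership in each category is any-overlap of the peak with the
    corresponding gene region; the highest-precedence category wins. The
    distance is measured from the peak center to the nearest TSS, signed
    positive downstream in the gene's orientation; ties on |distance| break
    by gene id.
    """
    chrom, p_start, p_end = peak
    known = known_chroms if known_chroms is not None else set(genes.chrom)
    if chrom not in known:
        raise InputError(f"unknown chromosome {chrom!r}")
    chrom_genes = genes[genes.chrom == chrom]

    hits = {c: False for c in CATEGORIES}
    for g in chrom_genes.itertuples():
        # inclusive of the bases at both ends so the window is symmetric
        # around the TSS base (strand-mirror invariant)
        prom_start, prom_end = g.tss - promoter_up, g.tss + promoter_down + 1
        if _overlaps(p_start, p_end, prom_start, prom_end):
            hits["Promoter"] = True
        if _overlaps(p_start, p_end, g.start, g.end):
            in_exon = False
            if exons is not None and len(exons):
                gexons = exons[exons.gene_id == g.gene_id]
                in_exon = any(_overlaps(p_start, p_end, e.start, e.end)
                              for e in gexons.itertuples())
                hits["Exon" if in_exon else "Intron"] = True
            else:
                # without exon models the whole span counts as exonic
                hits["Exon"] = True
        if g.strand == "+":
            ds = (g.end, g.end + downstream_limit)
        else:
            ds = (g.start - downstream_limit, g.start)
        if _overlaps(p_start, p_end, *ds):
            hits["Downstream"] = True

    category = "DistalIntergenic"
    for c in CATEGORIES[:-1]:
        if hits[c]:
            category = c
            break

    center = (p_start + p_end) // 2
    if chrom_genes.empty:
        return category, "", 0
    dists = []
    for g in chrom_genes.itertuples():
        raw = center - g.tss
        signed = raw if g.strand == "+" else -raw
        dists.append((abs(signed), g.gene_id, signed))
    dists.sort()
    _, nearest, signed = dists[0]
    return category, nearest, int(signed)


def annotate_peaks(peaks: pd.DataFrame, genes: pd.DataFrame,
                   exons: pd.DataFrame | None = None,
                   known_chroms: set[str] | None = None, **kwargs) -> pd.DataFrame:
    """Vector wrapper over :func:`annotate_peak` for a BED-like peak table."""
    known = known_chroms if known_chroms is not None else set(peaks.chrom) | set(genes.chrom)
    rows = []
    for p in peaks.itertuples():
        cat, nearest, dist = annotate_peak(
            (p.chrom, int(p.start), int(p.end)), genes, exons,
            known_chroms=known, **kwargs)
        rows.append((p.chrom, p.start, p.end, cat, nearest, dist))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "category",
                                       "nearest_gene", "distance_to_tss"])


def summarize_annotation(categories) -> pd.Series:
    """Fraction of peaks per category; fractions sum to 1."""
    cats = pd.Series(list(categories))
    if cats.empty:
        raise InputError("no annotated peaks to summarize")
    frac = cats.value_counts(normalize=True)
    return frac.reindex([c for c in CATEGORIES if c in frac.index])
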