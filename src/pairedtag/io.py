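"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are converted at the boundary: GTF is 1-based closed
on disk and 0-based half-open in memory (see :mod:`pairedtag.genomics`);
BED-like fragments files are native 0-based half-open. Matrices travel as
MatrixMarket (MTX) plus features/barcodes TSV sidecars. gzip is detected by
magic bytes, so plain and compressed inputs both work.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

FRAGMENT_DTYPES = {"start": np.int64, "end": np.int64, "mapq": np.int32}


def open_text(path: str, mode: str = "rt"):
    """Open a path as text, transparently decompressing gzip (by magic bytes)."""
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode.replace("t", ""))
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode.replace("t", ""))


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    with open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def chrom_sizes(genome: dict[str, str]) -> dict[str, int]:
    return {c: len(s) for c, s in genome.items()}


def write_chrom_sizes(sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    out = {}
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 2:
                raise InputError(f"{path}:{lineno}: expected two columns")
            out[fields[0]] = int(fields[1])
    return out


# ---------------------------------------------------------------- fragments

def write_fragments(fragments: pd.DataFrame, path: str) -> None:
    fragments.to_csv(path, sep="\t", index=False)


def read_fragments(path: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"cell": str, "umi": str, "pcr_index": str})
    except Exception as exc:  # pragma: no cover - error path
        raise InputError(f"cannot parse fragments file {path}: {exc}") from exc
    for col, dtype in FRAGMENT_DTYPES.items():
        if col in df.columns:
            df[col] = df[col].astype(dtype)
    return df


# ---------------------------------------------------------------- matrices

def write_matrix(adata: ad.AnnData, prefix: str) -> None:
    """Write an AnnData as <prefix>.mtx + <prefix>.barcodes.tsv / .features.tsv."""
    x = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(f"{prefix}.mtx", x)
    pd.Series(adata.obs_names).to_csv(f"{prefix}.barcodes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.var_names).to_csv(f"{prefix}.features.tsv", sep="\t",
                                      index=False, header=False)


def read_matrix(prefix: str, feature_kind: str = "") -> ad.AnnData:
    x = sp.csr_matrix(scipy.io.mmread(f"{prefix}.mtx"))
    barcodes = pd.read_csv(f"{prefix}.barcodes.tsv", sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(f"{prefix}.features.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(
        X=x,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell")),
        var=pd.DataFrame(index=pd.Index(features, name="feature")),
    )
    if feature_kind:
        adata.uns["feature_kind"] = feature_kind
    return adata


# ---------------------------------------------------------------- tracks

def write_bedgraph(coverage: pd.DataFrame, path: str) -> None:
    """Write (chrom, start, end, value) rows as bedGraph for browser inspection."""
    with open(path, "w") as fh:
        for row in coverage.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value}\n")


def fragment_coverage_bedgraph(fragments: pd.DataFrame, bin_size: int = 50) -> pd.DataFrame:
    """Binned 5'-end coverage suitable for :func:`write_bedgraph`."""
    from .quantify import five_prime

    pos = five_prime(fragments).to_numpy() // bin_size
    df = pd.DataFrame({"chrom": fragments["chrom"].astype(str), "bin": pos})
    counts = df.value_counts(["chrom", "bin"]).reset_index(name="value")
    counts["start"] = counts["bin"] * bin_size
    counts["end"] = counts["start"] + bin_size
    return counts[["chrom", "start", "end", "value"]].sort_values(
        ["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------- config / manifest

def read_config(path: str) -> dict:
    with open_text(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError(f"config {path} is not a YAML mapping")
    return cfg


def write_config(config: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str, seed: int, params: dict, outputs: list[str]) -> str:
    """Record the effective configuration and output checksums of a run."""
    manifest = {
        "seed": seed,
        "parameters": params,
        "outputs": {os.path.relpath(p, outdir): file_checksum(p) for p in sorted(outputs)},
    }
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
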