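"""End-to-end orchestration over a (possibly simulated) Paired-Tag run.

``run_pipeline`` chains the stages simulate -> [demux] -> quantify ->
cluster -> differential -> annotate -> bivalency on one histone-mark
dataset, writing per-stage reports, a count ledger and a manifest (seed,
effective parameters, output checksums). All stage defaults are the
published processing values: MAPQ > 10; duplicates collapsed on (position,
cell barcode, PCR index, UMI); pileup cutoff 10; 5-kb bins; < 200 RNA /
< 500 DNA cell filters; top-2% bin removal; 30 components (PCA 1-30, LSI
2-30); minimum cluster size 50; promoter TSS +/- 1 kb; significance preset
FDR < 0.01 with |fold change| > 1.25.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bivalency as bv
from . import cluster as cl
from . import demux as dx
from . import differential as de
from . import genomics as gn
from . import io as pio
from . import quantify as qt
from . import simulate as sim
from .errors import InputError


@dataclass
class PipelineParams:
    """Effective stage parameters; defaults are the published values."""

    mapq_threshold: int = 10
    pileup_cutoff: int = 10
    bin_size: int = 5_000
    min_rna: int = 200
    min_dna: int = 500
    top_bin_fraction: float = 0.02
    n_components: int = 30
    n_neighbors: int = 20
    weight_rna: float = 0.5
    resolution: float = 1.0
    min_cluster_size: int = 50
    promoter_window: int = 1_000
    preset: str = "fdr0.01_fc1.25"
    n_variable_genes: int = 2_000

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    outdir: str
    truth: sim.SimTruth
    ledger: pd.DataFrame
    rna: object
    dna: object
    assignment: cl.ClusterAssignment | None
    manifest_path: str
    tables: dict = field(default_factory=dict)


def _dedup_and_filter_dna(frags: pd.DataFrame, params: PipelineParams) -> tuple[pd.DataFrame, dict]:
    n_in = len(frags)
    frags = qt.filter_mapq(frags, params.mapq_threshold)
    n_mapq = n_in - len(frags)
    frags = qt.deduplicate(frags)
    n_dup = n_in - n_mapq - len(frags)
    frags2 = qt.remove_high_pileup(frags, params.pileup_cutoff)
    n_pileup = len(frags) - len(frags2)
    return frags2, {"input": n_in, "mapq_removed": n_mapq,
                    "duplicates_removed": n_dup, "pileup_removed": n_pileup,
                    "retained": len(frags2)}


def run_mark_dataset(truth: sim.SimTruth, mark: str, params: PipelineParams,
                     seed: int = 0):
    """Quantify + cluster one histone-mark dataset (both its conditions).

    Returns (rna AnnData, dna AnnData, joint ClusterAssignment, ledger dict).
    The matrices are restricted to nuclei with matched profiles passing the
    coverage filters; obs carries group/condition/cell-type truth labels for
    downstream comparisons.
    """
    cfg = truth.config
    group_names = [g.name for g in cfg.groups if g.mark == mark]
    cells = truth.cells[truth.cells["mark"] == mark]
    barcode_meta = cells.set_index("barcode")

    dna_all = truth.fragments_with_duplicates("DNA")
    rna_all = truth.fragments_with_duplicates("RNA")
    in_mark = dna_all["cell"].astype(str).isin(set(barcode_meta.index))
    dna_frags = dna_all[in_mark]
    rna_frags = rna_all[rna_all["cell"].astype(str).isin(set(barcode_meta.index))]

    dna_frags, dna_ledger = _dedup_and_filter_dna(dna_frags, params)
    n_rna_in = len(rna_frags)
    rna_frags = qt.deduplicate(rna_frags)
    rna_ledger = {"input": n_rna_in, "duplicates_removed": n_rna_in - len(rna_frags)}

    sizes = dict(truth.genome_lengths)
    dna_mat = qt.build_bin_matrix(dna_frags, sizes, params.bin_size)
    rna_mat, n_unassigned = qt.build_gene_matrix(rna_frags, truth.genes)
    rna_ledger["unassigned_to_gene"] = n_unassigned

    # coverage filters in published order: totals first, then feature counts
    rna_mat, dna_mat, removed_totals = qt.filter_low_coverage_cells(
        rna_mat, dna_mat, params.min_rna, params.min_dna, by="totals")
    rna_mat, dna_mat, removed_features = qt.filter_low_coverage_cells(
        rna_mat, dna_mat, params.min_rna, params.min_dna, by="features")
    dna_mat = qt.filter_top_bins(dna_mat, params.top_bin_fraction)

    meta = barcode_meta.loc[rna_mat.obs_names]
    for col in ("cell_id", "group", "condition", "sex", "cell_type"):
        rna_mat.obs[col] = meta[col].to_numpy()
        dna_mat.obs[col] = meta[col].to_numpy()

    # embeddings and joint clustering
    norm = cl.normalize_rna(rna_mat.X)
    hvg = cl.select_variable_genes(norm, min(params.n_variable_genes, rna_mat.n_vars))
    emb_rna = cl.reduce(norm[:, hvg], "pca", params.n_components, seed=seed)
    binary = qt.binarize(dna_mat)
    emb_dna = cl.reduce(cl.tfidf(binary.X), "lsi", params.n_components, seed=seed)
    g_rna = cl.knn_graph(emb_rna, params.n_neighbors)
    g_dna = cl.knn_graph(emb_dna, params.n_neighbors)
    joint = cl.joint_graph(g_rna, g_dna, params.weight_rna)
    n_types = len(cfg.cell_types)
    assignment = cl.search_resolution(joint, n_types, seed=seed,
                                      min_size=params.min_cluster_size)
    markers = {ct.name: list(ct.markers) for ct in cfg.cell_types}
    assignment = cl.label_clusters(assignment, norm, list(rna_mat.var_names), markers)
    scores = cl.marker_scores(norm, list(rna_mat.var_names), assignment, markers)
    assignment = cl.flag_doublet_clusters(assignment, scores)

    ledger = {
        "mark": mark, "groups": group_names,
        "dna": dna_ledger, "rna": rna_ledger,
        "cells_removed_total_filter": len(removed_totals),
        "cells_removed_feature_filter": len(removed_features),
        "cells_retained": rna_mat.n_obs,
    }
    return rna_mat, dna_mat, assignment, ledger, norm


def run_pipeline(config: sim.SimConfig, outdir: str, params: PipelineParams | None = None,
                 seed: int | None = None, emit_fastq: bool = False) -> PipelineResult:
    """Simulate a full experiment and run every stage, writing reports.

    With ``emit_fastq`` the simulated reads round-trip through demultiplexing
    (slower); otherwise the tagged-fragment shortcut is taken and demux is
    exercised by its own tests. Re-running with an identical config
    reproduces identical outputs (the manifest records checksums).
    """
    params = params or PipelineParams()
    seed = config.seed if seed is None else seed
    os.makedirs(outdir, exist_ok=True)
    outputs: list[str] = []

    genome = sim.generate_toy_genome(config)
    genes = sim.generate_gene_models(genome, config)
    truth = sim.simulate_cells(config, genes=genes, genome=genome)

    fasta = os.path.join(outdir, "genome.fa")
    pio.write_fasta(genome, fasta)
    gtf = os.path.join(outdir, "genes.gtf")
    gn.write_gene_models(genes, gtf)
    truth.write_tables(outdir)
    outputs += [fasta, gtf, os.path.join(outdir, "truth_cells.tsv"),
                os.path.join(outdir, "truth_genes.tsv")]

    if emit_fastq:
        reads = sim.emit_reads(truth, genome, os.path.join(outdir, "reads"))
        ref = dx.build_barcode_reference(truth.whitelists)
        for (grp, modality), (r1, r2) in reads["paths"].items():
            res = dx.demux_fastq(r1, r2, ref, modality,
                                 os.path.join(outdir, "demux", f"{grp}.{modality}.fastq.gz"))
            report_path = os.path.join(outdir, "demux", f"{grp}.{modality}.report.tsv")
            res.report.to_csv(report_path, sep="\t", index=False)
            outputs.append(report_path)

    marks_present = sorted({g.mark for g in config.groups})
    per_mark = {}
    ledgers = []
    for mark in marks_present:
        rna_mat, dna_mat, assignment, ledger, norm = run_mark_dataset(
            truth, mark, params, seed=seed)
        per_mark[mark] = (rna_mat, dna_mat, assignment, norm)
        ledgers.append(ledger)
        prefix = os.path.join(outdir, f"{mark}.rna")
        pio.write_matrix(rna_mat, prefix)
        pio.write_matrix(dna_mat, os.path.join(outdir, f"{mark}.dna"))
        outputs += [f"{prefix}.mtx", f"{prefix}.barcodes.tsv", f"{prefix}.features.tsv"]
        assign_path = os.path.join(outdir, f"{mark}.clusters.tsv")
        pd.DataFrame({
            "cell": rna_mat.obs_names, "cluster": assignment.labels,
            "cell_type_label": [assignment.type_labels.get(int(c), "")
                                for c in assignment.labels],
        }).to_csv(assign_path, sep="\t", index=False)
        outputs.append(assign_path)

    # differential expression: exposed vs control within the largest cell type
    tables: dict = {}
    mark0 = marks_present[0]
    rna_mat, dna_mat, assignment, norm = per_mark[mark0]
    biggest = rna_mat.obs["cell_type"].value_counts().idxmax()
    sel = (rna_mat.obs["cell_type"] == biggest).to_numpy()
    try:
        deg = de.find_markers(
            norm.toarray()[sel], list(rna_mat.var_names),
            rna_mat.obs["condition"].to_numpy()[sel], target="exposed",
            reference="control", preset=params.preset)
        deg_path = os.path.join(outdir, f"{mark0}.{biggest}.deg.tsv")
        deg.to_csv(deg_path, sep="\t", index=False)
        outputs.append(deg_path)
        tables["deg"] = deg
    except InputError:
        tables["deg"] = None

    # differential bins + annotation
    try:
        norm_dna = cl.normalize_rna(dna_mat.X)
        debins = de.find_markers(
            norm_dna.toarray()[sel], list(dna_mat.var_names),
            dna_mat.obs["condition"].to_numpy()[sel], target="exposed",
            reference="control", preset=params.preset)
        sig = debins[debins["significant"]]
        if len(sig):
            peaks = pd.DataFrame([
                (n.split(":")[0],) + tuple(map(int, n.split(":")[1].split("-")))
                for n in sig["feature"]], columns=["chrom", "start", "end"])
            annot = gn.annotate_peaks(peaks, genes,
                                      known_chroms=set(truth.genome_lengths))
            annot_path = os.path.join(outdir, f"{mark0}.depeaks.annotated.tsv")
            annot.to_csv(annot_path, sep="\t", index=False)
            outputs.append(annot_path)
            tables["depeak_annotation"] = annot
        tables["debins"] = debins
    except InputError:
        tables["debins"] = None

    # bivalency: aggregate promoter states per condition from truth fragments
    calls = {}
    for condition in sim.CONDITIONS:
        per_mark_signal = {}
        thresholds = {}
        for mark in (sim.MARK_K4, sim.MARK_K27):
            if mark not in per_mark:
                continue
            group_names = {g.name for g in config.groups
                           if g.mark == mark and g.condition == condition}
            frags = truth.dna_fragments
            keep = frags["cell_id"].astype(str).map(
                truth.cells.set_index("cell_id")["group"]).isin(group_names)
            frags = frags[keep]
            per_mark_signal[mark] = bv.promoter_signal(frags, genes, params.promoter_window)
            thresholds[mark] = bv.background_threshold(
                frags, truth.genome_lengths, genes, params.promoter_window, seed=seed)
        if len(per_mark_signal) == 2:
            calls[condition] = bv.call_bivalency(
                per_mark_signal[sim.MARK_K4], per_mark_signal[sim.MARK_K27],
                thresholds[sim.MARK_K4], thresholds[sim.MARK_K27], condition)
    if len(calls) == 2:
        transitions = bv.call_transitions(calls["control"], calls["exposed"])
        tpath = os.path.join(outdir, "bivalency_transitions.tsv")
        transitions.to_csv(tpath, sep="\t", index=False)
        outputs.append(tpath)
        tables["transitions"] = transitions
        tables["bivalency_calls"] = calls

    ledger_df = pd.json_normalize(ledgers)
    ledger_path = os.path.join(outdir, "ledger.tsv")
    ledger_df.to_csv(ledger_path, sep="\t", index=False)
    outputs.append(ledger_path)

    manifest = pio.write_manifest(outdir, seed, params.as_dict(), outputs)
    rna0, dna0, assign0, _ = per_mark[mark0]
    return PipelineResult(outdir=outdir, truth=truth, ledger=ledger_df,
                          rna=rna0, dna=dna0, assignment=assign0,
                          manifest_path=manifest, tables=tables)
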