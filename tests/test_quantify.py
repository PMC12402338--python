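"""Fragment filtering, deduplication and matrix construction contracts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairedtag import quantify as qt
from pairedtag.errors import ConfigurationError, InputError


def make_frags(rows):
    """rows: (chrom, start, cell, umi, pcr_index[, strand[, mapq]])."""
    out = []
    for r in rows:
        chrom, start, cell, umi, pi = r[:5]
        strand = r[5] if len(r) > 5 else "+"
        mapq = r[6] if len(r) > 6 else 60
        out.append((chrom, start, start + 100, strand, cell, umi, pi, mapq))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "strand",
                                      "cell", "umi", "pcr_index", "mapq"])


class TestMapqFilter:
    def test_strict_greater_boundary(self):
        frags = make_frags([("chr1", 0, "c", "u", "p", "+", 10),
                            ("chr1", 0, "c", "u", "p", "+", 11)])
        kept = qt.filter_mapq(frags, 10)
        assert kept["mapq"].tolist() == [11]

    def test_threshold_zero_keeps_positive(self):
        frags = make_frags([("chr1", i, "c", f"u{i}", "p", "+", 1) for i in range(5)])
        assert len(qt.filter_mapq(frags, 0)) == 5

    def test_empty_input(self):
        assert qt.filter_mapq(make_frags([]), 10).empty


class TestDeduplicate:
    def test_copies_collapse_to_one(self):
        frags = make_frags([("chr1", 100, "c", "u", "p")] * 5)
        assert len(qt.deduplicate(frags)) == 1

    def test_distinct_umi_both_kept(self):
        frags = make_frags([("chr1", 100, "c", "u1", "p"),
                            ("chr1", 100, "c", "u2", "p")])
        assert len(qt.deduplicate(frags)) == 2

    def test_order_invariance_and_idempotence(self, rng):
        rows = [("chr1", int(rng.integers(0, 50)) * 10, f"c{rng.integers(3)}",
                 f"u{rng.integers(4)}", f"p{rng.integers(2)}") for _ in range(200)]
        frags = make_frags(rows)
        shuffled = frags.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = qt.deduplicate(frags)
        b = qt.deduplicate(shuffled)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(qt.deduplicate(a), a)

    def test_commutes_with_mapq_filter(self, rng):
        rows = [("chr1", int(rng.integers(0, 20)) * 10, f"c{rng.integers(2)}",
                 f"u{rng.integers(3)}", "p", "+", int(rng.integers(0, 30)))
                for _ in range(300)]
        frags = make_frags(rows)
        a = qt.filter_mapq(qt.deduplicate(frags), 10).reset_index(drop=True)
        b = qt.deduplicate(qt.filter_mapq(frags, 10)).reset_index(drop=True)
        key = ["chrom", "start", "cell", "umi", "pcr_index", "mapq"]
        assert set(map(tuple, a[key].to_numpy())) == set(map(tuple, b[key].to_numpy()))

    def test_missing_key_is_input_error(self):
        with pytest.raises(InputError):
            qt.deduplicate(pd.DataFrame({"chrom": ["chr1"], "start": [0]}))

    def test_strand_distinguishes_positions(self):
        frags = make_frags([("chr1", 100, "c", "u", "p", "+"),
                            ("chr1", 1, "c", "u", "p", "-")])
        frags.loc[1, "end"] = 101  # 5' end = 100 on the minus strand
        assert len(qt.deduplicate(frags)) == 2


class TestPileup:
    def test_boundary_eleven_removed_ten_kept(self):
        eleven = [("chr1", 500, f"c{i}", f"u{i}", "p") for i in range(11)]
        ten = [("chr2", 500, f"c{i}", f"u{i}", "p") for i in range(10)]
        frags = make_frags(eleven + ten)
        out = qt.remove_high_pileup(frags, 10)
        assert (out["chrom"] == "chr2").all() and len(out) == 10

    def test_infinite_cutoff_identity(self):
        frags = make_frags([("chr1", i, "c", f"u{i}", "p") for i in range(20)])
        pd.testing.assert_frame_equal(qt.remove_high_pileup(frags, np.inf), frags)

    def test_depth_one_identity(self):
        frags = make_frags([("chr1", i * 10, "c", f"u{i}", "p") for i in range(30)])
        assert len(qt.remove_high_pileup(frags, 10)) == 30


class TestBinMatrix:
    sizes = {"chr1": 20_000, "chr2": 10_000}

    def test_half_open_bin_boundary(self):
        frags = make_frags([("chr1", 4_999, "c", "u1", "p"),
                            ("chr1", 5_000, "c", "u2", "p")])
        mat = qt.build_bin_matrix(frags, self.sizes)
        row = np.asarray(mat.X.todense()).ravel()
        names = list(mat.var_names)
        assert row[names.index("chr1:0-5000")] == 1
        assert row[names.index("chr1:5000-10000")] == 1

    def test_column_conservation(self, rng):
        n = 500
        frags = make_frags([("chr2", int(rng.integers(0, 9_900)), "cellA",
                             f"u{i}", "p") for i in range(n)])
        mat = qt.build_bin_matrix(frags, self.sizes)
        assert mat.X.sum() == n
        assert qt.total_counts(mat)[0] == n

    def test_beyond_chromosome_end_rejected(self):
        frags = make_frags([("chr2", 10_050, "c", "u", "p")])
        with pytest.raises(InputError):
            qt.build_bin_matrix(frags, self.sizes)

    def test_bins_tile_without_gaps(self):
        bins = qt.make_bins(self.sizes, 5_000)
        for chrom, size in self.sizes.items():
            b = bins[bins.chrom == chrom]
            assert b.iloc[0].start == 0 and b.iloc[-1].end == size
            assert (b.start.to_numpy()[1:] == b.end.to_numpy()[:-1]).all()


class TestGeneMatrix:
    genes = pd.DataFrame({
        "gene_id": ["gA", "gB", "gC"], "chrom": ["chr1", "chr1", "chr2"],
        "start": [1_000, 1_800, 500], "end": [2_000, 2_600, 900],
        "strand": ["+", "-", "+"], "tss": [1_000, 2_599, 500],
    })

    def test_contained_record_counts_once(self):
        frags = make_frags([("chr1", 1_100, "c", "u", "p")])
        frags["end"] = 1_200
        mat, n_un = qt.build_gene_matrix(frags, self.genes)
        assert n_un == 0
        assert np.asarray(mat.X.todense()).ravel().tolist() == [1, 0, 0]

    def test_intergenic_record_reported(self):
        frags = make_frags([("chr2", 5_000, "c", "u", "p")])
        mat, n_un = qt.build_gene_matrix(frags, self.genes)
        assert n_un == 1 and mat.X.sum() == 0

    def test_overlap_assignment_matches_brute_force(self, rng):
        frags = make_frags([("chr1", int(rng.integers(0, 3_000)), "c",
                             f"u{i}", "p") for i in range(400)])
        mat, _ = qt.build_gene_matrix(frags, self.genes)
        got = np.asarray(mat.X.todense()).ravel()
        expected = np.zeros(3)
        for f in frags.itertuples():
            for j, g in enumerate(self.genes.itertuples()):
                if f.chrom == g.chrom and f.start < g.end and f.end > g.start:
                    expected[j] += 1
        assert got.tolist() == expected.tolist()

    def test_ambiguous_drop_policy(self):
        frags = make_frags([("chr1", 1_850, "c", "u", "p")])  # overlaps gA and gB
        mat_all, _ = qt.build_gene_matrix(frags, self.genes, ambiguous="count_all")
        mat_drop, _ = qt.build_gene_matrix(frags, self.genes, ambiguous="drop")
        assert mat_all.X.sum() == 2 and mat_drop.X.sum() == 0


def _matrix(counts):
    import anndata as ad
    import scipy.sparse as sp

    counts = np.asarray(counts)
    return ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(counts.shape[0])]),
        var=pd.DataFrame(index=[f"f{j}" for j in range(counts.shape[1])]),
    )


class TestCellFilters:
    def test_feature_count_boundaries(self):
        # cell 0: 199 RNA features -> removed; cell 1: exactly 200/500 -> kept
        rna = np.zeros((2, 250), dtype=int)
        rna[0, :199] = 1
        rna[1, :200] = 1
        dna = np.zeros((2, 600), dtype=int)
        dna[:, :500] = 1
        r, d, removed = qt.filter_low_coverage_cells(_matrix(rna), _matrix(dna))
        assert removed == ["c0"] and list(r.obs_names) == ["c1"]
        assert list(d.obs_names) == ["c1"]

    def test_dna_boundary(self):
        rna = np.zeros((2, 250), dtype=int)
        rna[:, :200] = 1
        dna = np.zeros((2, 600), dtype=int)
        dna[0, :499] = 1
        dna[1, :500] = 1
        _r, _d, removed = qt.filter_low_coverage_cells(_matrix(rna), _matrix(dna))
        assert removed == ["c0"]

    def test_all_above_thresholds_identity(self):
        rna = np.ones((3, 250), dtype=int)
        dna = np.ones((3, 600), dtype=int)
        r, d, removed = qt.filter_low_coverage_cells(_matrix(rna), _matrix(dna))
        assert removed == [] and r.n_obs == d.n_obs == 3

    def test_disjoint_cell_sets_rejected(self):
        rna = _matrix(np.ones((2, 10)))
        dna = _matrix(np.ones((2, 10)))
        dna.obs_names = ["x0", "x1"]
        with pytest.raises(InputError):
            qt.filter_low_coverage_cells(rna, dna)


class TestTopBinFilter:
    def test_exactly_two_of_hundred_removed_matching_sort(self, rng):
        counts = rng.integers(0, 50, size=(5, 100))
        mat = _matrix(counts)
        out = qt.filter_top_bins(mat, 0.02)
        assert out.n_vars == 98
        totals = counts.sum(axis=0)
        # brute-force: the two highest-total bins (later coordinate on ties)
        order = sorted(range(100), key=lambda j: (-totals[j], -j))
        expected_removed = {f"f{j}" for j in order[:2]}
        assert set(mat.var_names) - set(out.var_names) == expected_removed

    def test_fraction_zero_identity(self):
        mat = _matrix(np.arange(20).reshape(4, 5))
        assert qt.filter_top_bins(mat, 0.0).n_vars == 5

    def test_all_equal_removes_last_by_coordinate(self):
        mat = _matrix(np.ones((3, 10), dtype=int))
        out = qt.filter_top_bins(mat, 0.2)
        assert list(out.var_names) == [f"f{j}" for j in range(8)]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            qt.filter_top_bins(_matrix(np.ones((2, 4))), 1.0)


class TestBinarize:
    @given(st.lists(st.integers(min_value=0, max_value=9), min_size=6, max_size=24))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_binarize_is_indicator_and_idempotent(self, values):
        n = (len(values) // 3) * 3
        counts = np.asarray(values[:n]).reshape(3, -1)
        mat = _matrix(counts)
        out = qt.binarize(mat)
        dense = np.asarray(out.X.todense())
        assert set(np.unique(dense)) <= {0, 1}
        assert (dense == (counts > 0)).all()
        again = qt.binarize(out)
        assert (np.asarray(again.X.todense()) == dense).all()


class TestZeroNoisePipeline:
    def test_per_cell_bin_totals_equal_truth(self):
        from pairedtag import simulate as sim

        cfg = sim.zero_noise(sim.default_config(
            seed=77, n_cells_per_group=20, fragments_per_cell_dna=100,
            rna_counts_per_cell=50,
            groups=(sim.GroupSpec("control", "F", "H3K27me3"),)))
        truth = sim.simulate_cells(cfg)
        frags = truth.fragments_with_duplicates("DNA")
        frags = qt.remove_high_pileup(qt.deduplicate(qt.filter_mapq(frags, 10)), 10)
        mat = qt.build_bin_matrix(frags, truth.genome_lengths)
        truth_totals = truth.dna_fragments.groupby(
            truth.dna_fragments["cell"].astype(str), observed=True).size()
        got = pd.Series(qt.total_counts(mat), index=mat.obs_names)
        pd.testing.assert_series_equal(got.sort_index(), truth_totals.sort_index(),
                                       check_names=False, check_dtype=False)


class TestExactLocator:
    def test_reads_located_at_source(self, small_genome):
        genome, _cfg = small_genome
        reads = [("r1", genome["chr1"][500:560]), ("r2", genome["chr2"][100:160]),
                 ("r3", "N" * 60)]
        hits = qt.exact_match_locate(reads, genome)
        assert hits.loc[0, ["chrom", "start"]].tolist() == ["chr1", 500]
        assert hits.loc[1, ["chrom", "start"]].tolist() == ["chr2", 100]
        assert hits.loc[2, "chrom"] is None and hits.loc[2, "mapq"] == 0
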