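"""Region construction, cut counting, QC metrics, background calling, pseudobulk."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import chicdyn as cd
from chicdyn.quantify import CountMatrix, RegionSet


class TestMakeBins:
    def test_tiling_with_truncated_last_bin(self):
        rs = cd.make_bins({"chr1": 120_000}, 50_000)
        assert list(zip(rs.df.start, rs.df.end)) == [(0, 50_000), (50_000, 100_000),
                                                     (100_000, 120_000)]

    def test_width_equal_to_chromosome_gives_single_bin(self):
        rs = cd.make_bins({"chr1": 7_000}, 7_000)
        assert len(rs) == 1 and rs.df.end.iloc[0] == 7_000

    def test_default_width_is_50kb(self):
        import inspect
        assert inspect.signature(cd.make_bins).parameters["width"].default == 50_000

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError, match="empty genome"):
            cd.make_bins({}, 50_000)


class TestTssWindows:
    def test_default_halfwidth_5kb_window(self):
        tab = pd.DataFrame({"chrom": ["chr1"], "tss": [100_000], "strand": ["+"],
                            "gene": ["g1"]})
        rs = cd.make_tss_windows(tab)
        assert (rs.df.start.iloc[0], rs.df.end.iloc[0]) == (95_000, 105_000)

    def test_clipped_at_chromosome_start(self):
        tab = pd.DataFrame({"chrom": ["chr1"], "tss": [2_000], "strand": ["-"],
                            "gene": ["g1"]})
        rs = cd.make_tss_windows(tab, halfwidth=5_000)
        assert (rs.df.start.iloc[0], rs.df.end.iloc[0]) == (0, 7_000)

    def test_duplicate_genes_suffixed(self):
        tab = pd.DataFrame({"chrom": ["chr1"] * 2, "tss": [10_000, 40_000],
                            "strand": ["+", "+"], "gene": ["g", "g"]})
        rs = cd.make_tss_windows(tab)
        assert list(rs.ids) == ["g", "g.1"]

    def test_malformed_strand_rejected(self):
        tab = pd.DataFrame({"chrom": ["chr1"], "tss": [10_000], "strand": ["?"],
                            "gene": ["g"]})
        with pytest.raises(ValueError, match="strand"):
            cd.make_tss_windows(tab)


class TestCountCuts:
    def test_half_open_boundary(self, small_cuts, small_bins):
        mat = cd.count_cuts(small_cuts, small_bins)
        # the cut at exactly 50,000 belongs to [50000, 100000), not [0, 50000)
        first = np.flatnonzero((mat.regions.df.chrom == "chr1")
                               & (mat.regions.df.start == 0))[0]
        second = np.flatnonzero((mat.regions.df.chrom == "chr1")
                                & (mat.regions.df.start == 50_000))[0]
        assert mat.dense()[first].sum() == 1    # only the cut at pos 10
        assert mat.dense()[second].sum() == 3   # cuts at 50,000 (x2) and 99,999

    def test_total_conserved(self, small_cuts, small_bins):
        mat = cd.count_cuts(small_cuts, small_bins)
        assert mat.Y.sum() == small_cuts.total_events

    def test_no_cuts_gives_zero_matrix_with_registries(self, small_bins):
        empty = cd.CutTable(pd.DataFrame({"chrom": [], "pos": [], "cell": [],
                                          "count": []}))
        mat = cd.count_cuts(empty, small_bins, cells=["a"])
        assert mat.shape == (len(small_bins), 1) and mat.Y.nnz == 0

    def test_matches_brute_force_on_random_fixture(self, small_bins):
        rng = np.random.default_rng(7)
        n = 100
        df = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], n),
            "pos": rng.integers(0, 120_000, n),
            "cell": rng.choice(["a", "b", "c"], n),
            "count": rng.integers(1, 4, n),
        })
        cuts = cd.CutTable(df)
        mat = cd.count_cuts(cuts, small_bins, cells=["a", "b", "c"])
        # independent oracle: explicit double loop over cuts and regions
        expected = np.zeros(mat.shape, dtype=int)
        for _, cut in df.iterrows():
            for r, reg in small_bins.df.iterrows():
                if (cut.chrom == reg.chrom and reg.start <= cut.pos < reg.end):
                    expected[r, ["a", "b", "c"].index(cut.cell)] += cut["count"]
        np.testing.assert_array_equal(mat.dense(), expected)

    def test_unknown_chromosome_dropped_with_warning(self, small_bins):
        cuts = cd.CutTable(pd.DataFrame({"chrom": ["chrX"], "pos": [5],
                                         "cell": ["a"], "count": [2]}))
        with pytest.warns(UserWarning, match="dropped 2"):
            mat = cd.count_cuts(cuts, small_bins, cells=["a"])
        assert mat.Y.sum() == 0

    def test_overlapping_regions_rejected_unless_opted_in(self, small_cuts):
        df = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 25_000],
                           "end": [50_000, 75_000], "id": ["r1", "r2"]})
        rs = RegionSet(df)
        with pytest.raises(ValueError, match="overlap"):
            cd.count_cuts(small_cuts, rs)
        mat = cd.count_cuts(small_cuts, rs, overlap_policy="count_in_all")
        # cut at 10 counted once, cut at 50,000 counted once (only r2)
        assert mat.dense().sum() == 3


class TestFrip:
    def test_all_none_half(self, small_cuts, small_bins):
        whole = small_bins
        assert cd.fraction_in_peaks(small_cuts, whole) == 1.0
        nothing = RegionSet(pd.DataFrame({"chrom": ["chr9"], "start": [0],
                                          "end": [10], "id": ["x"]}))
        assert cd.fraction_in_peaks(small_cuts, nothing) == 0.0
        # hand count: peaks = chr1 only -> 4 of 9 events in peaks
        chr1 = RegionSet(pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                       "end": [120_000], "id": ["p"]}))
        assert cd.fraction_in_peaks(small_cuts, chr1) == pytest.approx(4 / 9)

    def test_per_cell_and_zero_total(self, small_cuts, small_bins):
        frip = cd.fraction_in_peaks(small_cuts, small_bins, per_cell=True)
        assert set(frip.index) == {"a", "b"}
        assert (frip == 1.0).all()
        empty = cd.CutTable(pd.DataFrame({"chrom": [], "pos": [], "cell": [],
                                          "count": []}))
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(cd.fraction_in_peaks(empty, small_bins))


class TestGini:
    def test_uniform_is_zero(self):
        assert cd.gini(np.full(10, 3.0)) == pytest.approx(0.0)

    def test_concentrated_vector_hand_value(self):
        # explicit pairwise-difference oracle: sum |xi-xj| = 60, 2 n^2 mean = 80
        assert cd.gini([0, 0, 0, 10]) == pytest.approx(0.75)

    def test_scale_invariance_and_range(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(1.0, size=50)
        assert cd.gini(x) == pytest.approx(cd.gini(10 * x))
        assert 0 <= cd.gini(x) < 1

    def test_all_zero_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert cd.gini([0, 0, 0]) == 0.0


class TestSignalEnrichment:
    def test_ratio_definition(self):
        # all cuts in regions covering 10% of the genome -> 10x
        cuts = cd.CutTable(pd.DataFrame({"chrom": ["chr1"] * 5, "pos": range(5),
                                         "cell": ["a"] * 5, "count": [1] * 5}))
        marked = RegionSet(pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                         "end": [100], "id": ["m"]}))
        assert cd.signal_enrichment(cuts, marked, genome_size=1_000) == pytest.approx(10.0)

    def test_whole_genome_is_one(self, small_cuts):
        whole = RegionSet(pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [0, 0],
                                        "end": [120_000, 120_000], "id": ["a", "b"]}))
        assert cd.signal_enrichment(small_cuts, whole, 240_000) == pytest.approx(1.0)

    def test_uniform_cuts_near_one(self):
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 100_000, 5_000)
        cuts = cd.CutTable(pd.DataFrame({"chrom": "chr1", "pos": pos,
                                         "cell": "a", "count": 1}))
        marked = RegionSet(pd.DataFrame({"chrom": ["chr1"], "start": [20_000],
                                         "end": [50_000], "id": ["m"]}))
        assert cd.signal_enrichment(cuts, marked, 100_000) == pytest.approx(1.0, abs=0.05)


class TestFilterCells:
    def _mat(self, totals):
        Y = sp.csr_matrix(np.array([totals]))
        rs = RegionSet(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                                     "id": ["r"]}))
        return CountMatrix(regions=rs, cells=[f"c{i}" for i in range(len(totals))], Y=Y)

    def test_zero_threshold_is_identity(self):
        mat = self._mat([5, 0, 3])
        out, rep = cd.filter_cells(mat, min_cuts=0)
        assert out.cells == mat.cells and rep.n_fail == 0

    def test_planted_low_depth_cells_removed(self):
        mat = self._mat([500, 2, 300, 1, 999])
        out, rep = cd.filter_cells(mat, min_cuts=100)
        assert out.cells == ["c0", "c2", "c4"]
        assert set(rep.per_cell.query("~`pass`").index) == {"c1", "c3"}

    def test_pass_plus_fail_conserved(self):
        mat = self._mat([1, 10, 100])
        _, rep = cd.filter_cells(mat, min_cuts=5)
        assert rep.n_pass + rep.n_fail == 3

    def test_all_removed_raises(self):
        with pytest.raises(ValueError, match="all .* removed|all 2 cells"):
            cd.filter_cells(self._mat([1, 2]), min_cuts=100)


class TestBinsAboveBackground:
    def test_bimodal_modes_recovered(self):
        rng = np.random.default_rng(3)
        low = rng.lognormal(np.log(10), 0.25, 400)
        high = rng.lognormal(np.log(100), 0.25, 400)
        sums = np.concatenate([low, high]).round().astype(int)
        truth = np.r_[np.zeros(400, bool), np.ones(400, bool)]
        rs = cd.make_bins({"chr1": 800 * 50_000}, 50_000)
        mat = CountMatrix(regions=rs, cells=["c"], Y=sp.csr_matrix(sums[:, None]))
        mask = cd.bins_above_background(mat)
        assert np.mean(mask != truth) <= 0.01

    def test_manual_cutoff_overrides(self):
        rs = cd.make_bins({"chr1": 3 * 50_000}, 50_000)
        mat = CountMatrix(regions=rs, cells=["c"],
                          Y=sp.csr_matrix(np.array([[1], [100], [10_000]])))
        mask = cd.bins_above_background(mat, manual_cutoff=np.log10(50))
        np.testing.assert_array_equal(mask, [False, True, True])

    def test_flat_distribution_keeps_all_with_warning(self):
        rs = cd.make_bins({"chr1": 4 * 50_000}, 50_000)
        mat = CountMatrix(regions=rs, cells=["c"],
                          Y=sp.csr_matrix(np.full((4, 1), 7)))
        with pytest.warns(UserWarning):
            mask = cd.bins_above_background(mat)
        assert mask.all()


class TestPseudobulk:
    def test_single_group_equals_row_sums(self, small_cuts, small_bins):
        mat = cd.count_cuts(small_cuts, small_bins)
        pb = cd.pseudobulk(mat, {c: "all" for c in mat.cells})
        np.testing.assert_array_equal(pb.loc["all"].to_numpy(), mat.region_totals())

    def test_singleton_groups_transpose(self, small_cuts, small_bins):
        mat = cd.count_cuts(small_cuts, small_bins)
        pb = cd.pseudobulk(mat, {c: c for c in mat.cells})
        np.testing.assert_array_equal(pb.to_numpy(), mat.dense().T)

    def test_total_conserved_random(self):
        rng = np.random.default_rng(5)
        Y = rng.poisson(2, size=(20, 30))
        rs = cd.make_bins({"chr1": 20 * 50_000}, 50_000)
        mat = CountMatrix(regions=rs, cells=[f"c{i}" for i in range(30)],
                          Y=sp.csr_matrix(Y))
        labels = {f"c{i}": f"g{i % 4}" for i in range(30)}
        assert cd.pseudobulk(mat, labels).to_numpy().sum() == Y.sum()

    def test_unknown_label_rejected(self, small_cuts, small_bins):
        mat = cd.count_cuts(small_cuts, small_bins)
        with pytest.raises(ValueError, match="without labels"):
            cd.pseudobulk(mat, {"a": "g"})
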