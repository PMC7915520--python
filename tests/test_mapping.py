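import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plastiqtl import mapping
from plastiqtl.mapping import (EmptyMapError, GeneticMap, bin_skeleton_markers,
                               build_map, cluster_linkage_groups,
                               distortion_chi2, estimate_rf_matrix,
                               map_diagnostics, order_and_space_markers,
                               physical_concordance, qc_filter_markers)
from plastiqtl.simulate import SimConfig, simulate_map_and_genotypes


def _geno(columns: dict[str, str]) -> pd.DataFrame:
    """Build a genotype frame from per-marker call strings ('ABN...')."""
    data = {}
    for marker, calls in columns.items():
        data[marker] = [np.nan if c == "N" else c for c in calls]
    n = len(next(iter(columns.values())))
    return pd.DataFrame(data, index=[f"L{i:03d}" for i in range(n)])


class TestQC:
    def test_missingness_rule(self):
        # 100 lines; marker m2 has 11% missing at a 10% threshold
        calls_ok = "AB" * 50
        calls_bad = "N" * 11 + "AB" * 44 + "A"
        geno = _geno({"m1": calls_ok, "m2": calls_bad})
        kept, report = qc_filter_markers(geno, max_missing=0.10)
        assert list(kept.columns) == ["m1"]
        assert report.loc["m2", "removed_missing"]

    def test_perfect_segregation_retained(self):
        geno = _geno({"m1": "AB" * 20, "m2": "AB" * 20})
        kept, report = qc_filter_markers(geno)
        assert report.loc["m1", "chi2"] == 0.0
        assert list(kept.columns) == ["m1", "m2"]

    def test_distortion_chi2_hand_computed(self):
        # 120 P1 vs 30 P2: chi2 = 45^2/75 * 2 = 54 > 35 -> removed
        geno = _geno({"m1": "A" * 120 + "B" * 30, "m2": "AB" * 75})
        chi = distortion_chi2(geno)
        assert np.isclose(chi.loc["m1", "chi2"], 54.0)
        kept, _ = qc_filter_markers(geno, max_distortion_chi2=35.0)
        assert list(kept.columns) == ["m2"]

    def test_all_removed_raises(self):
        geno = _geno({"m1": "A" * 40, "m2": "B" * 40})
        with pytest.raises(EmptyMapError):
            qc_filter_markers(geno, max_distortion_chi2=35.0)


class TestRFMatrix:
    def test_identical_columns_rf_zero(self):
        geno = _geno({"m1": "ABAB" * 10, "m2": "ABAB" * 10})
        rf = estimate_rf_matrix(geno)
        assert rf.loc("m1", "m2") == 0.0

    def test_complementary_columns_truncated(self):
        geno = _geno({"m1": "ABAB" * 10, "m2": "BABA" * 10})
        rf = estimate_rf_matrix(geno)
        assert rf.loc("m1", "m2") == 0.5
        assert rf.raw.loc["m1", "m2"] == 1.0

    def test_direct_count(self):
        # 150 lines, 15 recombinant -> RF 0.10
        a = "A" * 150
        b = "B" * 15 + "A" * 135
        rf = estimate_rf_matrix(_geno({"m1": a, "m2": b}))
        assert np.isclose(rf.loc("m1", "m2"), 0.10)
        assert rf.counts.loc["m1", "m2"] == 150

    def test_no_shared_lines_is_missing(self):
        geno = _geno({"m1": "ABN" * 4, "m2": "NNA" * 4})
        rf = estimate_rf_matrix(geno)
        assert np.isnan(rf.rf.loc["m1", "m2"])
        assert rf.counts.loc["m1", "m2"] == 0


class TestBinning:
    def test_three_identical_markers_one_skeleton(self):
        calls = "ABBA" * 10
        geno = _geno({"m2": calls, "m1": calls, "m3": calls})
        rf = estimate_rf_matrix(geno)
        skeleton, bins = bin_skeleton_markers(geno, rf)
        assert skeleton.shape[1] == 1
        assert bins == {"m1": ["m2", "m3"]}   # lexicographic tie-break

    def test_bin_count_equals_distinct_columns(self, small_population):
        _, _, geno = small_population
        # duplicate a few markers under new names
        dup = geno.iloc[:, :5].copy()
        dup.columns = [f"dup_{c}" for c in dup.columns]
        both = pd.concat([geno, dup], axis=1)
        rf = estimate_rf_matrix(both)
        skeleton, _ = bin_skeleton_markers(both, rf)
        n_distinct = both.T.drop_duplicates().shape[0]
        assert skeleton.shape[1] == n_distinct

    def test_missing_call_still_binned(self):
        # identical except one missing call: RF over shared lines is 0,
        # and the complete marker becomes the skeleton
        geno = _geno({"m1": "ABAB" * 10, "m2": "NBAB" + "ABAB" * 9})
        rf = estimate_rf_matrix(geno)
        skeleton, bins = bin_skeleton_markers(geno, rf)
        assert list(skeleton.columns) == ["m1"]
        assert bins == {"m1": ["m2"]}


class TestClustering:
    def test_two_chromosomes_two_groups(self):
        cfg = SimConfig(n_lines=300, n_chromosomes=2,
                        chrom_lengths_cM=[80, 80], chrom_names=["1A", "2A"],
                        marker_spacing_cM=8, seed=21)
        _, geno = simulate_map_and_genotypes(cfg)
        rf = estimate_rf_matrix(geno)
        groups = cluster_linkage_groups(geno, rf, rf_threshold=0.2)
        assert len(groups) == 2
        for grp in groups:
            chroms = {m.split("_")[0] for m in grp}
            assert len(chroms) == 1

    def test_end_to_end_merge_to_target(self):
        # one chromosome with a sparse middle region: adjacent RF ~0.25
        # splits it at threshold 0.2; target_groups=1 merges it back
        cfg = SimConfig(n_lines=400, n_chromosomes=1,
                        chrom_lengths_cM=[40.0], chrom_names=["1A"],
                        marker_spacing_cM=5.0, seed=22)
        mp, geno = simulate_map_and_genotypes(cfg)
        # drop middle markers to create a >30 cM gap (RF ~ 0.25)
        keep = [m for m, cm in zip(mp["marker"], mp["cM"])
                if cm <= 5 or cm >= 35]
        geno = geno[keep]
        rf = estimate_rf_matrix(geno)
        natural = cluster_linkage_groups(geno, rf, rf_threshold=0.10)
        assert len(natural) == 2
        merged = cluster_linkage_groups(geno, rf, rf_threshold=0.10,
                                        target_groups=1)
        assert len(merged) == 1

    def test_single_marker_group(self):
        geno = _geno({"m1": "AB" * 20, "m2": "AB" * 10 + "BA" * 10})
        rf = estimate_rf_matrix(geno)
        groups = cluster_linkage_groups(geno[["m1"]], rf, rf_threshold=0.2)
        assert groups == [["m1"]]


class TestOrdering:
    def test_three_marker_exhaustive(self):
        # RF(AB)=0.05, RF(BC)=0.05, RF(AC)=0.10: A-B-C is the unique
        # optimum among the 3 distinct orders
        n = 200
        a = ["A"] * n
        b = list(a)
        for i in range(10):
            b[i] = "B"
        c = list(b)
        for i in range(10, 20):
            c[i] = "B"
        geno = _geno({"A": "".join(a), "B": "".join(b), "C": "".join(c)})
        rf = estimate_rf_matrix(geno)
        ordered = order_and_space_markers(["B", "A", "C"], rf)
        assert list(ordered["marker"]) in (["A", "B", "C"], ["C", "B", "A"])
        # orientation tie-break: smallest identifier at the lower end
        assert list(ordered["marker"]) == ["A", "B", "C"]
        assert (ordered["cM"].diff().dropna() > 0).all()

    def test_order_recovery_on_simulated_chromosome(self):
        cfg = SimConfig(n_lines=1000, n_chromosomes=1,
                        chrom_lengths_cM=[90.0], chrom_names=["1A"],
                        marker_spacing_cM=10.0, seed=23)
        mp, geno = simulate_map_and_genotypes(cfg)
        rf = estimate_rf_matrix(geno)
        shuffled = list(np.random.default_rng(0).permutation(geno.columns))
        ordered = order_and_space_markers(shuffled, rf)
        truth_rank = {m: i for i, m in enumerate(mp["marker"])}
        rho = stats.spearmanr(
            [truth_rank[m] for m in ordered["marker"]],
            np.arange(len(ordered))).statistic
        assert abs(rho) >= 0.99

    def test_single_marker(self):
        geno = _geno({"m1": "AB" * 20, "m2": "AB" * 20})
        rf = estimate_rf_matrix(geno)
        ordered = order_and_space_markers(["m1"], rf)
        assert ordered["cM"].tolist() == [0.0]


@pytest.fixture(scope="module")
def built(small_population):
    _, mp, geno = small_population
    gmap = build_map(geno, target_groups=3)
    return geno, gmap


class TestDiagnostics:

    def test_group_recovery(self, built):
        geno, gmap = built
        assert len(gmap.groups) == 3
        for group in gmap.groups:
            chroms = {m.split("_")[0] for m in gmap.group_table(group)["marker"]}
            assert len(chroms) == 1

    def test_unit_denominator(self, built):
        geno, gmap = built
        diag = map_diagnostics(geno, gmap)
        assert diag.n_units == len(geno.index) * len(gmap.groups)
        assert diag.n_units_evaluated == diag.n_units  # no missing data
        assert 0 <= diag.nonrecombinant_proportion <= 1

    def test_nonrecombinant_unit_flagged(self):
        geno = _geno({"m1": "AABB", "m2": "ABBB", "m3": "ABBB"})
        gmap = GeneticMap(table=pd.DataFrame({
            "marker": ["m1", "m2", "m3"], "group": "g1",
            "order": [0, 1, 2], "cM": [0.0, 5.0, 10.0]}))
        diag = map_diagnostics(geno, gmap)
        flags = diag.nonrecombinant["g1"].tolist()
        # line 0 A,A,A -> True; line 1 A,B,B -> False; lines 2,3 BBB -> True
        assert flags == [True, False, True, True]

    def test_distortion_hand_case(self):
        # 90:60 at n=150 -> chi2 = 6.0, p ~ 0.0143 <= 0.05, favoring P1
        geno = _geno({"m1": "A" * 90 + "B" * 60, "m2": "AB" * 75})
        gmap = GeneticMap(table=pd.DataFrame({
            "marker": ["m1", "m2"], "group": "g1",
            "order": [0, 1], "cM": [0.0, 5.0]}))
        diag = map_diagnostics(geno, gmap, alpha=0.05)
        assert np.isclose(diag.distortion.loc["m1", "chi2"], 6.0)
        assert np.isclose(diag.distortion.loc["m1", "p"],
                          stats.chi2.sf(6.0, 1))
        assert diag.n_distorted == 1
        assert diag.distorted_by_parent == {"P1": 1, "P2": 0}

    def test_unit_with_single_call_excluded(self):
        geno = _geno({"m1": "ANNN", "m2": "ANNN"})
        gmap = GeneticMap(table=pd.DataFrame({
            "marker": ["m1", "m2"], "group": "g1",
            "order": [0, 1], "cM": [0.0, 5.0]}))
        diag = map_diagnostics(geno, gmap)
        assert diag.n_units == 4
        assert diag.n_units_evaluated == 1


class TestPhysicalConcordance:
    def _map(self, markers):
        return GeneticMap(table=pd.DataFrame({
            "marker": markers, "group": "g1",
            "order": np.arange(len(markers)),
            "cM": np.arange(len(markers), dtype=float)}))

    def test_collinear_and_reversed(self):
        markers = [f"m{i}" for i in range(10)]
        gmap = self._map(markers)
        anchors = pd.DataFrame({"marker": markers, "chrom": "1A",
                                "bp": np.arange(1, 11) * 1000})
        assert np.isclose(physical_concordance(gmap, anchors)["g1"], 1.0)
        reversed_anchors = anchors.assign(bp=anchors["bp"].iloc[::-1].values)
        assert np.isclose(physical_concordance(gmap, reversed_anchors)["g1"],
                          1.0)

    def test_one_swap_matches_formula(self):
        markers = [f"m{i}" for i in range(10)]
        gmap = self._map(markers)
        bp = np.arange(1, 11) * 1000
        bp[3], bp[4] = bp[4], bp[3]
        anchors = pd.DataFrame({"marker": markers, "chrom": "1A", "bp": bp})
        got = physical_concordance(gmap, anchors)["g1"]
        expected = abs(stats.spearmanr(np.arange(10), bp).statistic)
        assert np.isclose(got, expected)

    def test_too_few_anchors_skipped(self):
        gmap = self._map([f"m{i}" for i in range(5)])
        anchors = pd.DataFrame({"marker": ["m0", "m1"], "chrom": "1A",
                                "bp": [100, 200]})
        assert physical_concordance(gmap, anchors) == {}
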