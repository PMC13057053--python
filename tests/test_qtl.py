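"""Kosambi functions, single-marker scan, thresholds, intervals, QTL calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from germqtl import (
    GeneticMap,
    GenotypeMatrix,
    call_qtls,
    classify_strength,
    kosambi,
    map_summary,
    permutation_threshold,
    single_marker_scan,
    support_interval,
)
from germqtl.errors import DataWarning, InvalidInputError
from germqtl.qtl import Chromosome, Marker, ScanResult, lod_to_pve


def make_map(positions, chrom="1A"):
    return GeneticMap([Chromosome(
        chrom, [Marker(f"{chrom}_M{i + 1}", p) for i, p in enumerate(positions)])])


def make_geno(codes, chrom="1A"):
    codes = np.asarray(codes, dtype=float)
    return GenotypeMatrix(
        [f"L{i}" for i in range(codes.shape[0])],
        [f"{chrom}_M{i + 1}" for i in range(codes.shape[1])], codes)


class TestKosambi:
    def test_zero(self):
        assert kosambi(0.0, "r_to_d") == 0.0

    def test_quarter(self):
        assert kosambi(0.25, "r_to_d") == pytest.approx(25 * math.log(3), rel=1e-12)

    def test_saturation(self):
        assert kosambi(200.0, "d_to_r") == pytest.approx(0.5, abs=1e-3)

    def test_invalid_r(self):
        with pytest.raises(InvalidInputError):
            kosambi(0.5, "r_to_d")

    @given(st.floats(0, 0.499))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_round_trip(self, r):
        assert kosambi(kosambi(r, "r_to_d"), "d_to_r") == pytest.approx(
            r, abs=1e-12)


class TestSingleMarkerScan:
    def test_hand_least_squares_fixture(self):
        geno = make_geno([[1], [1], [-1], [-1]])
        res = single_marker_scan(geno, make_map([0.0]), [2.0, 1.0, 0.0, 1.0],
                                 min_lines=2)
        rec = res.records.iloc[0]
        assert rec["add"] == pytest.approx(0.5)
        assert rec["lod"] == pytest.approx(2 * math.log10(2), rel=1e-12)
        assert rec["pve"] == pytest.approx(50.0)

    def test_constant_phenotype_null(self):
        geno = make_geno([[1], [1], [-1], [-1]] * 3)
        res = single_marker_scan(geno, make_map([0.0]), [2.0] * 12)
        assert res.records["lod"].iloc[0] == 0.0
        assert res.records["pve"].iloc[0] == 0.0

    def test_flipping_codes_negates_add_only(self, rng):
        codes = rng.choice([-1.0, 1.0], size=(30, 5))
        y = rng.normal(0, 1, 30) + codes[:, 2]
        gmap = make_map([0, 10, 20, 30, 40])
        a = single_marker_scan(make_geno(codes), gmap, y)
        b = single_marker_scan(make_geno(-codes), gmap, y)
        assert np.allclose(a.records["lod"], b.records["lod"])
        assert np.allclose(a.records["pve"], b.records["pve"])
        assert np.allclose(a.records["add"], -b.records["add"])

    def test_monomorphic_and_sparse_markers_skipped(self, rng):
        codes = rng.choice([-1.0, 1.0], size=(20, 3))
        codes[:, 1] = 1.0                      # monomorphic
        codes[:15, 2] = np.nan                 # only 5 usable lines
        res = single_marker_scan(make_geno(codes), make_map([0, 5, 10]),
                                 rng.normal(size=20))
        assert res.skipped == ["1A_M2", "1A_M3"]
        assert list(res.records["marker"]) == ["1A_M1"]

    def test_perfect_fit_hits_ceiling(self):
        codes = np.array([[1.0], [1.0], [-1.0], [-1.0]] * 4)
        y = codes[:, 0] * 2.0 + 7.0
        res = single_marker_scan(make_geno(codes), make_map([0.0]), y)
        assert res.records["lod"].iloc[0] == 50.0

    def test_lod_pve_link(self, default_dataset):
        tt_y = np.random.default_rng(1).normal(size=63)
        res = single_marker_scan(default_dataset.geno, default_dataset.gmap,
                                 tt_y)
        rec = res.records
        implied = lod_to_pve(rec["lod"].to_numpy(), rec["n"].to_numpy())
        assert np.allclose(rec["pve"].to_numpy(), implied, atol=1e-9)

    def test_line_order_invariance(self, rng):
        codes = rng.choice([-1.0, 1.0], size=(25, 4))
        y = rng.normal(size=25)
        gmap = make_map([0, 1, 2, 3])
        a = single_marker_scan(make_geno(codes), gmap, y)
        perm = rng.permutation(25)
        b = single_marker_scan(make_geno(codes[perm]), gmap, y[perm])
        assert np.allclose(a.records["lod"], b.records["lod"])


class TestPermutationThreshold:
    def test_constant_phenotype_zero(self, rng):
        codes = rng.choice([-1.0, 1.0], size=(20, 10))
        gmap = make_map(np.linspace(0, 90, 10))
        thr = permutation_threshold(make_geno(codes), gmap, np.ones(20),
                                    n_perm=100, seed=1)
        assert thr == 0.0

    def test_seed_determinism(self, rng):
        codes = rng.choice([-1.0, 1.0], size=(30, 40))
        gmap = make_map(np.linspace(0, 200, 40))
        y = rng.normal(size=30)
        args = dict(n_perm=200, alpha=0.05)
        t1 = permutation_threshold(make_geno(codes), gmap, y, seed=7, **args)
        t2 = permutation_threshold(make_geno(codes), gmap, y, seed=7, **args)
        t3 = permutation_threshold(make_geno(codes), gmap, y, seed=8, **args)
        assert t1 == t2
        assert t1 != t3

    def test_missing_data_fallback_matches_contract(self, rng):
        codes = rng.choice([-1.0, 1.0], size=(30, 8))
        codes[0, 0] = np.nan
        gmap = make_map(np.linspace(0, 80, 8))
        y = rng.normal(size=30)
        thr = permutation_threshold(make_geno(codes), gmap, y, n_perm=100, seed=3)
        assert thr > 0


class TestSupportInterval:
    def profile(self, positions, lods, chrom="1A"):
        rec = pd.DataFrame({
            "marker": [f"{chrom}_M{i + 1}" for i in range(len(positions))],
            "chrom": chrom, "pos_cM": positions, "n": 63,
            "lod": lods, "pve": 0.0, "add": 0.0})
        return ScanResult(records=rec)

    def test_single_marker_chromosome(self):
        scan = self.profile([12.0], [4.0])
        assert support_interval(scan, "1A_M1") == (12.0, 12.0)

    def test_symmetric_profile(self):
        scan = self.profile([0, 10, 20, 30, 40], [1, 2, 4, 2, 1])
        left, right = support_interval(scan, "1A_M3")
        assert (left, right) == pytest.approx((15.0, 25.0))

    def test_piecewise_linear_hand_interpolation(self):
        # cut at 5-1=4: left between (10,3) and (20,5): 10+(5-4)/(5-3)*10=15
        # right between (35,5) and (50,2): 35+(5-4)/(5-2)*15=40
        scan = self.profile([0, 10, 20, 35, 50], [1, 3, 5, 5, 2])
        left, right = support_interval(scan, "1A_M3")
        assert left == pytest.approx(15.0)
        assert right == pytest.approx(40.0)

    def test_truncated_at_chromosome_ends(self):
        scan = self.profile([0, 10, 20], [3.8, 3.9, 4.0])
        assert support_interval(scan, "1A_M3") == (0.0, 20.0)


class TestCallQtls:
    def test_classification_rule(self):
        assert classify_strength(21.72) == "very_strong"
        assert classify_strength(20.0) == "very_strong"
        assert classify_strength(15.0) == "major"
        assert classify_strength(10.0) == "major"
        assert classify_strength(3.45) == "minor"

    def scan_and_map(self, lods, positions=None):
        positions = positions or list(range(0, 10 * len(lods), 10))
        gmap = make_map(positions, chrom="3B")
        rec = pd.DataFrame({
            "marker": [m.name for m in gmap.chromosomes[0].markers],
            "chrom": "3B", "pos_cM": positions, "n": 63, "lod": lods,
            "pve": [lod_to_pve(l, 63) for l in lods], "add": 0.5})
        return ScanResult(records=rec), gmap

    def test_adjacent_significant_markers_merge(self):
        scan, gmap = self.scan_and_map([0.5, 3.0, 3.5, 2.8, 0.4],
                                       [0, 10, 11, 12, 30])
        calls = call_qtls(scan, 2.0, "FW", "D", gmap)
        assert len(calls) == 1
        call = calls[0]
        assert call.qtl_id == "QFW_D3B"
        assert call.peak_pos == 11
        assert call.left_marker == "3B_M2" and call.right_marker == "3B_M4"
        assert call.ci_left <= call.peak_pos <= call.ci_right
        assert call.environment == "Drought"

    def test_disjoint_peaks_stay_separate(self):
        scan, gmap = self.scan_and_map(
            [4.0, 0.2, 0.1, 0.2, 4.5], [0, 40, 80, 120, 160])
        calls = call_qtls(scan, 2.0, "SL", "DN", gmap)
        assert len(calls) == 2
        assert {c.qtl_id for c in calls} == {"QSL_DN3B"}

    def test_no_significant_markers(self):
        scan, gmap = self.scan_and_map([0.5, 1.0, 0.8])
        assert call_qtls(scan, 2.0, "FW", "C", gmap) == []

    def test_unknown_environment_rejected(self):
        scan, gmap = self.scan_and_map([3.0, 0.1])
        with pytest.raises(InvalidInputError):
            call_qtls(scan, 2.0, "FW", "X", gmap)


class TestMapSummary:
    def test_single_chromosome_density(self):
        gmap = make_map(list(np.linspace(0, 100, 10)))
        out = map_summary(gmap)
        row = out[out["kind"] == "chromosome"].iloc[0]
        assert row["n_markers"] == 10
        assert row["length_cM"] == pytest.approx(100.0)
        assert row["density"] == pytest.approx(0.10)

    def test_rollup_conventions_differ(self):
        cl = [("1A", 10, 100.0), ("2A", 40, 100.0)]
        dsum = map_summary(counts_lengths=cl)
        ratio = map_summary(counts_lengths=cl, rollup="ratio")
        a_sum = dsum[dsum["group"] == "A"]["density"].iloc[0]
        a_ratio = ratio[ratio["group"] == "A"]["density"].iloc[0]
        assert a_sum == pytest.approx(0.1 + 0.4)
        assert a_ratio == pytest.approx(50 / 200)

    def test_zero_length_chromosome_flagged(self):
        with pytest.warns(DataWarning):
            out = map_summary(counts_lengths=[("1A", 3, 0.0)])
        assert math.isnan(out["density"].iloc[0])
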