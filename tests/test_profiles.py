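"""Binning arithmetic: scaled bodies, fixed flanks, missing-data policy."""

import numpy as np
import pytest

from cgimeth.profiles import (
    ProfileMatrix,
    bin_edges,
    bin_region_signal,
    build_profile_matrix,
    difference_matrix,
    group_average_profile,
    impute_profile_rows,
    region_mean_signal,
)
from cgimeth.track_io import GenomicInterval, PointSignal, SignalTrack


def _points(pos, values, chrom="chr1"):
    return PointSignal({chrom: (np.asarray(pos), np.asarray(values))})


def _track(records):
    return SignalTrack.from_records(records)


class TestBinEdges:
    def test_remainder_goes_to_leftmost_bins(self):
        edges = bin_edges(0, 7, 3)
        assert list(np.diff(edges)) == [3, 2, 2]

    def test_region_shorter_than_bins_yields_empty_bins(self):
        edges = bin_edges(0, 2, 5)
        assert list(np.diff(edges)) == [1, 1, 0, 0, 0]


class TestBinRegionSignal:
    def test_constant_beta_fills_all_bins(self):
        region = GenomicInterval("chr1", 0, 200, "+")
        sig = _points(np.arange(0, 200, 5), np.full(40, 0.8))
        out = bin_region_signal(sig, region, 20)
        assert np.allclose(out, 0.8)

    def test_alternating_zero_one_averages_to_half(self):
        # region [0, 40), a CpG at every bp with beta 0,1,0,1,...; 2-bp bins
        region = GenomicInterval("chr1", 0, 40, "+")
        sig = _points(np.arange(40), np.arange(40) % 2)
        out = bin_region_signal(sig, region, 20)
        assert np.allclose(out, 0.5)

    def test_minus_strand_orientation_reverses(self):
        pos = np.arange(0, 100, 5)
        values = np.linspace(0, 1, len(pos))
        plus = GenomicInterval("chr1", 0, 100, "+")
        minus = GenomicInterval("chr1", 0, 100, "-")
        sig = _points(pos, values)
        fwd = bin_region_signal(sig, plus, 10, orient_by_strand=True)
        rev = bin_region_signal(sig, minus, 10, orient_by_strand=True)
        assert np.allclose(rev, fwd[::-1])

    def test_empty_bins_are_missing_and_empty_region_warns(self):
        region = GenomicInterval("chr1", 0, 100, "+")
        sig = _points([5], [0.4])
        out = bin_region_signal(sig, region, 10)
        assert out[0] == pytest.approx(0.4)
        assert np.isnan(out[1:]).all()
        with pytest.warns(UserWarning, match="no signal"):
            out = bin_region_signal(_points([], []), region, 10)
        assert np.isnan(out).all()

    def test_step_signal_uses_coverage_weighted_mean_with_zero_fill(self):
        track = _track([("chr1", 0, 5, 4.0)])
        region = GenomicInterval("chr1", 0, 10, "+")
        out = bin_region_signal(track, region, 1)
        assert out[0] == pytest.approx(2.0)


class TestBuildProfileMatrix:
    def test_no_flanks_gives_body_only_columns(self):
        regions = {"r1": GenomicInterval("chr1", 0, 100, "+")}
        m = build_profile_matrix(regions, _track([("chr1", 0, 100, 2.0)]), 20)
        assert m.values.shape == (1, 20)
        assert np.allclose(m.values, 2.0)

    def test_flank_signal_exceeds_body_signal_when_planted(self):
        # flanks carry 5x the body signal
        records = [("chr1", 0, 100, 5.0), ("chr1", 100, 200, 1.0), ("chr1", 200, 300, 5.0)]
        regions = {"r1": GenomicInterval("chr1", 100, 200, "+")}
        m = build_profile_matrix(
            regions, _track(records), n_body_bins=10, flank_bp=100, n_flank_bins=5
        )
        row = m.values[0]
        flanks = np.r_[row[:5], row[-5:]]
        assert flanks.mean() > row[5:15].mean()

    def test_duplicate_region_ids_rejected(self):
        ivs = [
            GenomicInterval("chr1", 0, 10, "+", "dup"),
            GenomicInterval("chr1", 20, 30, "+", "dup"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            build_profile_matrix(ivs, _track([("chr1", 0, 30, 1.0)]), 5)

    def test_permutation_equivariance(self):
        track = _track([("chr1", 0, 1000, 1.0), ("chr1", 1000, 2000, 3.0)])
        a = GenomicInterval("chr1", 0, 500, "+", "a")
        b = GenomicInterval("chr1", 1200, 1800, "+", "b")
        m1 = build_profile_matrix({"a": a, "b": b}, track, 10)
        m2 = build_profile_matrix({"b": b, "a": a}, track, 10)
        assert np.allclose(m1.row("a"), m2.row("a"))
        assert np.allclose(m1.row("b"), m2.row("b"))

    def test_strand_symmetry_on_reversed_signal(self):
        # reversing both the strand and the underlying signal leaves rows unchanged
        n = 100
        rng = np.random.default_rng(0)
        values = rng.random(n)
        fwd = _points(np.arange(n), values)
        rev = _points(np.arange(n), values[::-1])
        plus = {"r": GenomicInterval("chr1", 0, n, "+")}
        minus = {"r": GenomicInterval("chr1", 0, n, "-")}
        m_plus = build_profile_matrix(plus, fwd, 10, orient_by_strand=True)
        m_minus = build_profile_matrix(minus, rev, 10, orient_by_strand=True)
        assert np.allclose(m_plus.values, m_minus.values)

    def test_binning_conserves_region_mean_of_step_signal(self):
        rng = np.random.default_rng(3)
        start, end = 37, 1023
        edges = np.sort(rng.choice(np.arange(start + 1, end), size=30, replace=False))
        bounds = np.r_[start, edges, end]
        records = [
            ("chr1", int(s), int(e), float(v))
            for s, e, v in zip(bounds[:-1], bounds[1:], rng.random(len(bounds) - 1) * 5)
        ]
        track = _track(records)
        region = GenomicInterval("chr1", start, end, "+")
        n_bins = 20
        out = bin_region_signal(track, region, n_bins)
        widths = np.diff(bin_edges(start, end, n_bins))
        weighted = np.sum(out * widths) / widths.sum()
        assert weighted == pytest.approx(track.mean_over("chr1", start, end), abs=1e-9)

    def test_equal_cpg_bins_conserve_unweighted_mean(self):
        rng = np.random.default_rng(4)
        pos = np.arange(0, 200, 5)  # 2 CpGs per 10-bp bin
        values = rng.random(len(pos))
        sig = _points(pos, values)
        region = GenomicInterval("chr1", 0, 200, "+")
        out = bin_region_signal(sig, region, 20)
        assert out.mean() == pytest.approx(values.mean(), abs=1e-12)


class TestDifferenceMatrix:
    def _pair(self):
        ids = ["r1", "r2"]
        a = ProfileMatrix(ids, [[0.9, 0.5], [0.3, np.nan]], 0, 2, "beta")
        b = ProfileMatrix(ids, [[0.2, 0.5], [0.3, 0.1]], 0, 2, "beta")
        return a, b

    def test_entrywise_difference_and_missing_propagation(self):
        a, b = self._pair()
        d = difference_matrix(a, b)
        assert d.signal_kind == "beta_difference"
        assert d.values[0, 0] == pytest.approx(0.7)
        assert d.values[0, 1] == pytest.approx(0.0)
        assert np.isnan(d.values[1, 1])

    def test_identity_gives_zeros(self):
        a, _ = self._pair()
        d = difference_matrix(a, a)
        assert np.allclose(d.values[np.isfinite(d.values)], 0.0)

    def test_layout_mismatch_rejected(self):
        a, _ = self._pair()
        c = ProfileMatrix(["r1", "r2"], [[0.1], [0.2]], 0, 1, "beta")
        with pytest.raises(ValueError):
            difference_matrix(a, c)


class TestGroupAverage:
    M = ProfileMatrix(
        ["a", "b", "c"],
        [[0.2, np.nan, 0.4], [np.nan, 0.6, 0.8], [0.4, 0.2, np.nan]],
        0,
        3,
        "beta",
    )

    def test_single_member_returns_row(self):
        assert np.allclose(
            group_average_profile(self.M, ["b"]), [np.nan, 0.6, 0.8], equal_nan=True
        )

    def test_mean_of_two_rows(self):
        m = ProfileMatrix(["a", "b"], [[0.2, 0.2], [0.4, 0.4]], 0, 2, "beta")
        assert np.allclose(group_average_profile(m, ["a", "b"]), [0.3, 0.3])

    def test_disjoint_missing_patterns_hand_enumerated(self):
        out = group_average_profile(self.M, ["a", "b", "c"])
        assert out[0] == pytest.approx((0.2 + 0.4) / 2)
        assert out[1] == pytest.approx((0.6 + 0.2) / 2)
        assert out[2] == pytest.approx((0.4 + 0.8) / 2)

    def test_empty_member_set_is_error(self):
        with pytest.raises(ValueError):
            group_average_profile(self.M, [])


class TestRegionMean:
    def test_constant_track(self):
        track = _track([("chr1", 0, 100, 2.0)])
        assert region_mean_signal(track, GenomicInterval("chr1", 0, 100, "+")) == 2.0

    def test_half_covered_weighted_mean(self):
        track = _track([("chr1", 0, 50, 4.0)])
        assert region_mean_signal(track, GenomicInterval("chr1", 0, 100, "+")) == 2.0

    def test_empty_track_zero_fill(self):
        track = _track([("chr2", 0, 10, 1.0)])
        assert region_mean_signal(track, GenomicInterval("chr1", 0, 100, "+")) == 0.0


class TestImputeAndSerialize:
    def test_rows_over_missing_threshold_dropped_and_rest_interpolated(self):
        m = ProfileMatrix(
            ["keep", "drop"],
            [[0.0, np.nan, 1.0, 1.0], [np.nan, np.nan, np.nan, 0.4]],
            0,
            4,
            "beta",
        )
        out, dropped = impute_profile_rows(m, max_missing_frac=0.25)
        assert dropped == ["drop"]
        assert np.allclose(out.row("keep"), [0.0, 0.5, 1.0, 1.0])

    def test_edge_gaps_take_nearest_value(self):
        m = ProfileMatrix(["r"], [[np.nan, 0.4, 0.6, 0.6]], 0, 4, "beta")
        out, _ = impute_profile_rows(m, max_missing_frac=0.5)
        assert out.row("r")[0] == pytest.approx(0.4)

    def test_tsv_round_trip(self, tmp_path):
        m = ProfileMatrix(
            ["r1", "r2"],
            np.array([[0.1, 0.2, 0.3, np.nan], [0.5, 0.6, 0.7, 0.8]]),
            1,
            2,
            "beta",
            flank_bp=100,
            oriented=True,
        )
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        m2 = ProfileMatrix.from_tsv(p)
        assert m2.region_ids == m.region_ids
        assert m2.bin_labels() == ["u1", "b1", "b2", "d1"]
        assert np.allclose(m2.values, m.values, equal_nan=True)
        assert (m2.n_flank_bins, m2.n_body_bins, m2.signal_kind) == (1, 2, "beta")
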