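"""Clonal-coverage tracks, log2 ratio segmentation, boundary ratio, DLRS."""

import numpy as np
import pytest

from conftest import make_pair
from liwgs import cnv_caller as cnv
from liwgs.alignment_io import InsertSizeProfile
from liwgs.cnv_caller import CnvSegment, CoverageTrack, RatioTrack
from liwgs.errors import EmptyTrackError, InsufficientDataError, ValidationError


def track_from_values(values, chrom="1", window=2000, step=None, raw=None):
    values = np.asarray(values, dtype=float)
    raw = np.ones_like(values) if raw is None else np.asarray(raw)
    return RatioTrack(
        chrom=chrom,
        window_size=window,
        step=step or window,
        log2=values,
        depth_zero=np.zeros(values.size, dtype=bool),
    )


class TestCoverageTrack:
    def test_fragment_spanning_two_windows_counts_in_both(self):
        pairs = [make_pair(pos_a=1500, insert_size=1000)]  # spans 1500..2499
        tracks = cnv.clonal_coverage_track(pairs, {"1": 10_000}, window_size=2000)
        assert list(tracks["1"].raw) == [1, 1, 0, 0, 0]

    def test_normalised_mean_is_one(self):
        rng = np.random.default_rng(0)
        pairs = [
            make_pair(fragment_id=str(i), pos_a=int(p), insert_size=900)
            for i, p in enumerate(rng.integers(1, 99_000, 500))
        ]
        tracks = cnv.clonal_coverage_track(pairs, {"1": 100_000})
        assert tracks["1"].values.mean() == pytest.approx(1.0, abs=1e-9)

    def test_raw_counts_match_brute_force_recount(self):
        rng = np.random.default_rng(1)
        pairs = [
            make_pair(fragment_id=str(i), pos_a=int(p), insert_size=int(s))
            for i, (p, s) in enumerate(
                zip(rng.integers(1, 45_000, 300), rng.integers(200, 5000, 300))
            )
        ]
        tracks = cnv.clonal_coverage_track(pairs, {"1": 50_000}, window_size=2000)
        # independent O(pairs x windows) recount
        for w in range(tracks["1"].raw.size):
            lo, hi = w * 2000 + 1, min((w + 1) * 2000, 50_000)
            expected = sum(
                1 for p in pairs if p.pos_a <= hi and p.pos_a + p.insert_size - 1 >= lo
            )
            assert tracks["1"].raw[w] == expected

    def test_interchromosomal_and_long_span_pairs_excluded(self):
        pairs = [
            make_pair(fragment_id="ok", pos_a=100, insert_size=900),
            make_pair(fragment_id="far", pos_a=100, insert_size=50_000),
            make_pair(fragment_id="inter", chrom_a="1", chrom_b="2", pos_a=100, pos_b=100),
        ]
        tracks = cnv.clonal_coverage_track(
            pairs, {"1": 100_000, "2": 100_000}, max_span=1100
        )
        assert tracks["1"].raw.sum() == 1

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyTrackError):
            cnv.clonal_coverage_track([], {"1": 100_000})

    def test_overlap_count_exceeds_point_coverage_by_window_factor(self):
        # fragments overlapping a window ~ C * (window + insert - 1) / insert
        rng = np.random.default_rng(2)
        genome, insert, coverage = 1_000_000, 900, 30
        n = round(coverage * genome / insert)
        pairs = [
            make_pair(fragment_id=str(i), pos_a=int(p), insert_size=insert)
            for i, p in enumerate(rng.integers(1, genome - insert, n))
        ]
        tracks = cnv.clonal_coverage_track(pairs, {"1": genome})
        inner = tracks["1"].raw[5:-5]
        expected = coverage * (2000 + insert - 1) / insert
        assert inner.mean() == pytest.approx(expected, rel=0.02)


class TestRatioTrack:
    def cov(self, values, raw=None, chrom="1"):
        values = np.asarray(values, dtype=float)
        raw = values.copy() if raw is None else np.asarray(raw)
        return {chrom: CoverageTrack(chrom=chrom, window_size=2000, step=2000, raw=raw, values=values)}

    def test_identical_tracks_give_zero(self):
        t = self.cov([1.0, 1.2, 0.8])
        ratio = cnv.log2_ratio_track(t, self.cov([1.0, 1.2, 0.8]))
        assert np.allclose(ratio["1"].log2, 0.0, atol=1e-5)

    def test_halved_tumor_gives_minus_one(self):
        ratio = cnv.log2_ratio_track(self.cov([0.5, 0.5]), self.cov([1.0, 1.0]))
        assert ratio["1"].log2 == pytest.approx([-1.0, -1.0], abs=1e-5)

    def test_zero_normal_masked(self):
        ratio = cnv.log2_ratio_track(
            self.cov([1.0, 1.0], raw=[5, 5]), self.cov([1.0, 0.0], raw=[5, 0])
        )
        assert np.isnan(ratio["1"].log2[1])

    def test_grid_mismatch_rejected(self):
        t = self.cov([1.0, 1.0])
        n = self.cov([1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            cnv.log2_ratio_track(t, n)


class TestSegmentation:
    def test_flat_track_yields_no_segments(self):
        track = track_from_values(np.zeros(100))
        assert cnv.call_cnv_segments({"1": track}) == []

    def test_run_coordinates_and_mean(self):
        values = np.zeros(50)
        values[10:20] = -1.234
        segs = cnv.call_cnv_segments({"1": track_from_values(values)}, min_windows=5)
        assert len(segs) == 1
        s = segs[0]
        assert s.direction == "loss"
        assert s.start == 10 * 2000 + 1
        assert s.end == 19 * 2000 + 2000 + 1
        assert s.length == 10 * 2000
        assert s.n_windows == 10
        assert s.log2_ratio == pytest.approx(-1.234)

    def test_alternating_signs_break_runs(self):
        values = np.tile([0.8, -0.8], 10)
        assert cnv.call_cnv_segments({"1": track_from_values(values)}, min_windows=2) == []

    def test_short_runs_suppressed_by_min_windows(self):
        values = np.zeros(30)
        values[5:9] = 1.0
        assert cnv.call_cnv_segments({"1": track_from_values(values)}, min_windows=5) == []
        assert len(cnv.call_cnv_segments({"1": track_from_values(values)}, min_windows=4)) == 1

    def test_segment_length_is_end_minus_start(self):
        # the length convention used in reporting: length == end - start
        s = CnvSegment(
            chrom="3", start=51_996_100, end=52_507_500, direction="loss",
            log2_ratio=-0.819, n_windows=0,
        )
        assert s.length == 511_400


class TestBoundaryRatio:
    PROF = InsertSizeProfile(
        n_pairs=1000, median=900.0, mean=900.0, sd=64.0, range_low=700.0, range_high=1100.0
    )
    SEG = CnvSegment(
        chrom="1", start=10_001, end=20_001, direction="loss", log2_ratio=-1.0, n_windows=5
    )

    def test_no_pairs_at_boundary_is_missing_not_zero(self):
        pairs = [make_pair(pos_a=50_000)]
        assert cnv.boundary_anomalous_ratio(self.SEG, pairs, self.PROF) is None

    def test_ratio_counts_anomalous_fraction(self):
        pairs = [
            make_pair(fragment_id="a", pos_a=9_800, insert_size=900),  # concordant at boundary
            make_pair(fragment_id="b", pos_a=9_900, insert_size=900),
            make_pair(fragment_id="c", pos_a=9_850, insert_size=10_600),  # jumps the segment
        ]
        ratio = cnv.boundary_anomalous_ratio(self.SEG, pairs, self.PROF)
        assert ratio == pytest.approx(1 / 3)

    def test_diploid_concordant_neighbourhood_is_zero(self):
        pairs = [
            make_pair(fragment_id=str(i), pos_a=9_000 + 50 * i, insert_size=900) for i in range(40)
        ]
        assert cnv.boundary_anomalous_ratio(self.SEG, pairs, self.PROF) == 0.0


class TestDlrs:
    def test_constant_track_is_zero(self):
        result = cnv.dlrs(track_from_values(np.full(500, 0.7)), point_spacing=2000, smoothing_window=0)
        assert result.value == pytest.approx(0.0, abs=1e-12)

    def test_iid_gaussian_recovers_sigma(self):
        # var(diff of iid) = 2 sigma^2, so sd(diff)/sqrt(2) estimates sigma
        rng = np.random.default_rng(3)
        sigma = 0.25
        track = track_from_values(rng.normal(0, sigma, 10_000))
        result = cnv.dlrs(track, point_spacing=2000, smoothing_window=0)
        assert result.value == pytest.approx(sigma, rel=0.05)
        assert result.n_points == 10_000

    def test_smoothing_reduces_noise(self):
        rng = np.random.default_rng(4)
        track = track_from_values(rng.normal(0, 0.2, 5000))
        raw = cnv.dlrs(track, point_spacing=80_000, smoothing_window=0)
        smooth = cnv.dlrs(track, point_spacing=80_000, smoothing_window=19_000)
        assert smooth.value < raw.value

    def test_invariant_under_constant_shift(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 0.1, 4000)
        a = cnv.dlrs(track_from_values(values), point_spacing=2000, smoothing_window=0)
        b = cnv.dlrs(track_from_values(values + 3.7), point_spacing=2000, smoothing_window=0)
        assert b.value == pytest.approx(a.value, abs=1e-12)

    def test_insensitive_to_copy_number_steps(self):
        # a genuine copy-number step contributes one outlier difference, so
        # DLRS stays close to the per-point noise
        rng = np.random.default_rng(6)
        noise = rng.normal(0, 0.1, 2000)
        stepped = noise.copy()
        stepped[1000:] -= 1.0
        a = cnv.dlrs(track_from_values(noise), point_spacing=2000, smoothing_window=0)
        b = cnv.dlrs(track_from_values(stepped), point_spacing=2000, smoothing_window=0)
        assert b.value == pytest.approx(a.value, rel=0.25)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            cnv.dlrs(track_from_values([0.1, 0.2]), point_spacing=2000, smoothing_window=0)

    def test_point_spacing_resamples(self):
        rng = np.random.default_rng(7)
        track = track_from_values(rng.normal(0, 0.1, 4000))
        result = cnv.dlrs(track, point_spacing=80_000, smoothing_window=0)
        assert result.n_points == 100  # every 40th 2-kb window


class TestSegmentAnnotation:
    BED = [("1", 12_000, 14_000, "G1"), ("1", 16_000, 18_000, "G2"), ("2", 0, 1000, "G3")]

    def test_segment_containing_two_genes(self):
        seg = CnvSegment(
            chrom="1", start=10_001, end=20_001, direction="loss", log2_ratio=-1.0, n_windows=5
        )
        [annotated] = cnv.annotate_genes([seg], self.BED, flag_list={"G2", "G3"})
        assert annotated.genes == ("G1", "G2")
        assert annotated.flagged_genes == ("G2",)

    def test_zero_overlap_segment_empty(self):
        seg = CnvSegment(
            chrom="1", start=40_001, end=50_001, direction="gain", log2_ratio=1.0, n_windows=5
        )
        [annotated] = cnv.annotate_genes([seg], self.BED)
        assert annotated.genes == ()
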