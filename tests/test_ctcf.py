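import numpy as np
import pandas as pd
import pytest

from mvhic.ctcf import (
    FACTORS,
    PeakTrack,
    assign_anchor_motif,
    ctcf_validated,
    expand_window,
    peak_associated,
    read_bed,
    read_fimo,
    validation_report,
)
from mvhic.loops import LoopSet
from mvhic.synthetic import SyntheticSpec, generate_annotations, generate_pair, write_annotations


def track(factor, intervals, chrom="chrS"):
    frame = pd.DataFrame(intervals, columns=["start", "end"])
    frame.insert(0, "chrom", chrom)
    return PeakTrack(factor=factor, intervals=frame)


def loops_from(pixels, chrom="chrS", resolution=10_000):
    return LoopSet.from_pixels(pixels, chrom=chrom, resolution=resolution)


class TestExpandWindow:
    def test_symmetric_expansion_example(self):
        assert expand_window(100_000, 110_000, 15_000) == (97_500, 112_500)

    def test_wide_enough_window_untouched(self):
        assert expand_window(0, 20_000, 15_000) == (0, 20_000)


class TestPeakAssociated:
    def full_tracks(self, anchors, resolution=10_000):
        iv = [(b * resolution + 4_000, b * resolution + 6_000) for b in anchors]
        return [track(f, iv) for f in FACTORS]

    def test_all_factors_both_anchors_kept(self):
        loops = loops_from([(10, 30)])
        out = peak_associated(loops, self.full_tracks([10, 30]))
        assert out.pixels() == {(10, 30)}

    def test_missing_factor_errors_with_names(self):
        loops = loops_from([(10, 30)])
        tracks = self.full_tracks([10, 30])[:2]  # drop RAD21
        with pytest.raises(ValueError, match="RAD21"):
            peak_associated(loops, tracks)

    def test_one_anchor_unsupported_drops_loop(self):
        loops = loops_from([(10, 30)])
        out = peak_associated(loops, self.full_tracks([10]))  # no peak near bin 30
        assert len(out) == 0

    def test_any_replicate_satisfies_factor(self):
        loops = loops_from([(10, 30)])
        tracks = self.full_tracks([10, 30])
        # split CTCF support across two replicates
        ctcf_a = track("CTCF", [(104_000, 106_000)])
        ctcf_b = track("CTCF", [(304_000, 306_000)])
        out = peak_associated(loops, [ctcf_a, ctcf_b] + tracks[1:])
        assert len(out) == 1

    def test_matches_brute_force_overlap_oracle(self, rng):
        res = 10_000
        pix = [(int(i), int(i + d)) for i, d in zip(rng.integers(5, 80, 15),
                                                    rng.integers(3, 15, 15))]
        loops = loops_from(pix)
        peaks = [(int(p), int(p) + 800) for p in rng.integers(0, 95 * res, 60)]
        tracks = [track(f, peaks) for f in FACTORS]
        got = peak_associated(loops, tracks, min_window=15_000).pixels()

        def win(b):
            s, e = b * res, (b + 1) * res
            return expand_window(s, e, 15_000)

        expect = set()
        for i, j in loops.pixels():
            li, ri = win(i), win(j)
            ok_l = any(s < li[1] and e > li[0] for s, e in peaks)
            ok_r = any(s < ri[1] and e > ri[0] for s, e in peaks)
            if ok_l and ok_r:
                expect.add((i, j))
        assert got == expect

    def test_adding_peaks_never_decreases_association(self, rng):
        loops = loops_from([(10, 30), (40, 70), (15, 55)])
        base_iv = [(104_000, 106_000), (304_000, 306_000)]
        more_iv = base_iv + [(404_000, 406_000), (704_000, 706_000), (154_000, 156_000), (554_000, 556_000)]
        base = peak_associated(loops, [track(f, base_iv) for f in FACTORS])
        more = peak_associated(loops, [track(f, more_iv) for f in FACTORS])
        assert base.pixels() <= more.pixels()


class TestMotifAssignment:
    def hits(self, rows):
        return pd.DataFrame(rows, columns=["motif_id", "chrom", "start", "end", "strand",
                                           "score", "pvalue"])

    def test_single_hit_returned(self):
        hits = self.hits([("CTCF", "chrS", 100_500, 100_519, "+", 8.0, 1e-6)])
        got = assign_anchor_motif((100_000, 110_000), hits, "chrS")
        assert got is not None and got.score == 8.0

    def test_argmax_score(self):
        hits = self.hits([
            ("CTCF", "chrS", 100_500, 100_519, "+", 8.1, 1e-6),
            ("CTCF", "chrS", 105_000, 105_019, "-", 12.3, 1e-6),
        ])
        got = assign_anchor_motif((100_000, 110_000), hits, "chrS")
        assert got.score == 12.3 and got.strand == "-"

    def test_tie_breaks_to_leftmost_start(self):
        hits = self.hits([
            ("CTCF", "chrS", 105_000, 105_019, "-", 9.0, 1e-6),
            ("CTCF", "chrS", 100_500, 100_519, "+", 9.0, 1e-6),
        ])
        got = assign_anchor_motif((100_000, 110_000), hits, "chrS")
        # oracle: stable sort by (-score, start) -> first row
        rows = sorted(hits.itertuples(), key=lambda r: (-r.score, r.start))
        assert got.start == rows[0].start == 100_500

    def test_empty_region_returns_none(self):
        hits = self.hits([("CTCF", "chrS", 900_000, 900_019, "+", 9.0, 1e-6)])
        assert assign_anchor_motif((100_000, 110_000), hits, "chrS") is None


class TestConvergence:
    @pytest.mark.parametrize(
        "left,right,expected",
        [("+", "-", True), ("-", "+", False), ("+", "+", False), ("-", "-", False)],
    )
    def test_orientation_combinations(self, left, right, expected):
        lm = pd.Series({"strand": left})
        rm = pd.Series({"strand": right})
        assert ctcf_validated(lm, rm) is expected

    def test_missing_motif_not_validated(self):
        assert ctcf_validated(None, pd.Series({"strand": "-"})) is False


class TestValidationReport:
    def test_half_convergent_gives_fifty_percent(self):
        spec = SyntheticSpec(n_bins=300, n_loops=20, convergent_fraction=0.5,
                             loop_distance=(20, 120), decoy_peaks=0, decoy_motifs=0, seed=9)
        _, _, truth = generate_pair(spec)
        tracks, motifs = generate_annotations(spec, truth)
        loops = loops_from(zip(truth.bin_i, truth.bin_j))
        report = validation_report(loops, tracks, motifs)
        assert report.peak_associated == 20
        assert report.ctcf_validated == 10
        assert report.validation_rate == pytest.approx(0.5)

    def test_all_convergent_gives_full_rate(self):
        spec = SyntheticSpec(n_bins=200, n_loops=6, convergent_fraction=1.0,
                             loop_distance=(20, 100), seed=3)
        _, _, truth = generate_pair(spec)
        tracks, motifs = generate_annotations(spec, truth)
        loops = loops_from(zip(truth.bin_i, truth.bin_j))
        report = validation_report(loops, tracks, motifs)
        assert report.validation_rate == pytest.approx(1.0)

    def test_no_peaks_means_no_association(self):
        loops = loops_from([(10, 30)])
        empty = [track(f, []) for f in FACTORS]
        hits = pd.DataFrame(columns=["motif_id", "chrom", "start", "end", "strand",
                                     "score", "pvalue"])
        report = validation_report(loops, empty, hits)
        assert report.peak_associated == 0 and report.validation_rate == 0.0

    def test_containment_invariant(self):
        spec = SyntheticSpec(n_bins=200, n_loops=8, convergent_fraction=0.5,
                             loop_distance=(20, 100), seed=11)
        _, _, truth = generate_pair(spec)
        tracks, motifs = generate_annotations(spec, truth)
        loops = loops_from(zip(truth.bin_i, truth.bin_j))
        report = validation_report(loops, tracks, motifs)
        assert report.ctcf_validated <= report.peak_associated <= report.total_loops


class TestFileFormats:
    def test_bed_and_fimo_round_trip(self, tmp_path):
        spec = SyntheticSpec(n_bins=200, n_loops=5, loop_distance=(20, 100), seed=13)
        _, _, truth = generate_pair(spec)
        tracks, motifs = generate_annotations(spec, truth)
        paths = write_annotations(tmp_path, tracks, motifs)
        back = read_bed(paths["CTCF"], factor="CTCF")
        assert len(back.intervals) == len(tracks[0].intervals)
        hits = read_fimo(paths["motifs"])
        # coordinates survive the 1-based FIMO dialect round trip
        merged = hits.sort_values(["start"]).reset_index(drop=True)
        orig = motifs.sort_values(["start"]).reset_index(drop=True)
        np.testing.assert_array_equal(merged.start.to_numpy(), orig.start.to_numpy())
        np.testing.assert_array_equal(merged.end.to_numpy(), orig.end.to_numpy())

    def test_fimo_pvalue_filter_monotone(self, tmp_path):
        """A looser p threshold never yields fewer assignable hits."""
        spec = SyntheticSpec(n_bins=200, n_loops=5, loop_distance=(20, 100),
                             decoy_motifs=30, seed=14)
        _, _, truth = generate_pair(spec)
        tracks, motifs = generate_annotations(spec, truth)
        paths = write_annotations(tmp_path, tracks, motifs)
        strict = read_fimo(paths["motifs"], p_threshold=1e-6)
        loose = read_fimo(paths["motifs"], p_threshold=1e-4)
        assert len(strict) <= len(loose)
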