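import itertools

import numpy as np
import pytest

from restcobind.intervals import GenomicInterval, GenomeLayout
from restcobind.signals import (
    ConservationTrack,
    mean_conservation,
    paired_signal_test,
    profile_matrix,
    site_intensity,
    threshold_mask,
    vertical_section,
)
from restcobind.tags import TagAlignment, tag_frame


def tags_at(positions, strand="+", chrom="chr1", sample="s"):
    return tag_frame(
        [TagAlignment(chrom, int(p), strand, sample) for p in positions]
    )


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestSiteIntensity:
    def test_equal_counts_equal_depths(self):
        chip = tags_at(range(1_000, 1_100))
        inp = tags_at(range(1_000, 1_100), strand="-")
        assert site_intensity(chip, inp, iv(1_000, 1_100)) == pytest.approx(1.0)

    def test_twofold_enrichment(self):
        site = iv(0, 1_000)
        chip = tags_at(list(range(500)) * 2)  # 1000 tags in site
        inp = tags_at(range(500))  # 500 in site
        # equal depths forced explicitly
        got = site_intensity(chip, inp, site, chip_depth=10_000,
                             input_depth=10_000)
        assert got == pytest.approx(2.0, rel=0.01)

    def test_planted_site_beats_background(self, small_result,
                                           small_fixture_dir):
        from restcobind.simulate import load_fixture
        from scipy import stats

        fix = load_fixture(small_fixture_dir)
        sites = small_result.sites["ES"]
        # intensities of detected sites must exceed random background spans
        rng = np.random.default_rng(0)
        rest = fix.tags("Rest_ES")
        inp = fix.tags("Input_ES")
        site_vals = [
            site_intensity(rest, inp, s.interval) for s in sites[:10]
        ]
        bg_vals = [
            site_intensity(
                rest, inp, iv(int(p), int(p) + 300)
            )
            for p in rng.integers(0, 900_000, size=30)
        ]
        p = stats.mannwhitneyu(site_vals, bg_vals, alternative="greater").pvalue
        assert p < 0.01


class TestProfileMatrix:
    def test_no_tags_gives_flat_unit_row(self):
        prof = profile_matrix([iv(10_000, 10_300)], tags_at([]), tags_at([]),
                              half_width=500)
        assert prof.matrix.shape == (1, 1001)
        # with pseudocounts on both sides an empty window normalises to 1
        assert np.allclose(prof.matrix, 1.0)

    def test_planted_symmetric_enrichment_peaks_at_anchor(self):
        rng = np.random.default_rng(30)
        center = 50_000
        pos = rng.normal(center, 30, size=2_000).astype(int)
        strands = np.where(rng.random(2_000) < 0.5, "+", "-")
        chip = tag_frame(
            [TagAlignment("chr1", int(p), s, "c") for p, s in zip(pos, strands)]
        )
        inp = tags_at(rng.integers(0, 100_000, size=50_000), strand="-")
        prof = profile_matrix([iv(center - 150, center + 150)], chip, inp,
                              half_width=500, extension=20)
        argmax = prof.offsets[np.argmax(prof.matrix[0])]
        assert abs(argmax) <= 50

    def test_rows_sorted_by_descending_score(self):
        sites = [iv(1_000, 1_300), iv(5_000, 5_300), iv(9_000, 9_300)]
        prof = profile_matrix(sites, tags_at([]), tags_at([]),
                              sort_scores=[1.0, 3.0, 2.0], half_width=10)
        assert prof.site_ids[0].startswith("site_1:")
        assert prof.site_ids[1].startswith("site_2:")

    def test_chromosome_edge_rows_flagged(self):
        genome = GenomeLayout({"chr1": 600})
        prof = profile_matrix([iv(0, 300)], tags_at([]), tags_at([]),
                              half_width=500, genome=genome)
        assert prof.clipped == [True]


class TestThresholdMask:
    def _profile(self, matrix):
        from restcobind.signals import SignalProfile

        matrix = np.asarray(matrix, dtype=float)
        return SignalProfile(
            site_ids=[f"s{i}" for i in range(matrix.shape[0])],
            factor="x",
            matrix=matrix,
            offsets=np.arange(matrix.shape[1]),
        )

    def test_boundary_is_strict(self):
        prof = self._profile([[24.9, 25.0, 25.1]])
        assert threshold_mask(prof, 25).tolist() == [[False, False, True]]

    def test_background_all_false(self):
        prof = self._profile(np.ones((3, 5)))
        assert not threshold_mask(prof, 25).any()

    def test_matches_elementwise_oracle_and_monotone(self):
        rng = np.random.default_rng(31)
        matrix = rng.uniform(0, 60, size=(20, 40))
        prof = self._profile(matrix)
        mask = threshold_mask(prof, 25)
        assert (mask == (matrix > 25)).all()
        denser = threshold_mask(prof, 10).sum()
        sparser = threshold_mask(prof, 40).sum()
        assert denser >= mask.sum() >= sparser


class TestVerticalSection:
    def _profile(self, matrix, factor="f"):
        from restcobind.signals import SignalProfile

        matrix = np.asarray(matrix, dtype=float)
        return SignalProfile(
            site_ids=[f"s{i}" for i in range(matrix.shape[0])],
            factor=factor,
            matrix=matrix,
            offsets=np.arange(matrix.shape[1]),
        )

    def test_single_row_is_identity(self):
        row = [1.0, 2.0, 3.0]
        curves = vertical_section([self._profile([row])])
        assert curves["f"].tolist() == row

    def test_matches_columnwise_mean_oracle(self):
        rng = np.random.default_rng(32)
        matrix = rng.uniform(0, 5, size=(30, 11))
        curves = vertical_section([self._profile(matrix)])
        assert np.allclose(curves["f"], matrix.mean(axis=0))

    def test_empty_profile_is_error(self):
        with pytest.raises(ValueError):
            vertical_section([])
        with pytest.raises(ValueError):
            vertical_section([self._profile(np.empty((0, 3)))])


def exact_wilcoxon_p(diffs):
    """Enumeration oracle: all 2^n sign assignments of the ranked |d|
    (average ranks for ties)."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = np.array(
        [sum(r for r, s in zip(ranks, signs) if s)
         for signs in itertools.product([False, True], repeat=n)]
    )
    p = 2 * min((total <= w_obs).mean(), (total >= w_obs).mean())
    return min(p, 1.0)


class TestPairedSignalTest:
    def test_identical_vectors(self):
        with pytest.warns(UserWarning):
            assert paired_signal_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_n6_all_positive_exact(self):
        a = [10, 11, 12, 13, 14, 15]
        b = [1, 2, 3, 4, 5, 6]
        assert paired_signal_test(a, b) == pytest.approx(2 / 64)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_matches_enumeration_for_small_n(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            a = rng.normal(0, 1, size=n)
            b = rng.normal(0.3, 1, size=n)
            expected = exact_wilcoxon_p(a - b)
            assert paired_signal_test(a, b) == pytest.approx(expected)

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(33)
        base = rng.normal(0, 1, size=200)
        noise = rng.normal(0, 1, size=200)
        pvals = [
            paired_signal_test(base + shift + noise, base)
            for shift in (0.02, 0.3, 1.0)
        ]
        assert pvals[0] > pvals[1] > pvals[2]


class TestConservation:
    def _constant_track(self, score, start=0, end=10_000):
        track = ConservationTrack()
        track.add_interval("chr1", start, end, score)
        return track

    def test_constant_tracks(self):
        site = iv(4_000, 4_300)
        assert mean_conservation(site, self._constant_track(1.0)) == 1.0
        assert mean_conservation(site, self._constant_track(0.0)) == 0.0

    def test_step_track_oracle(self):
        anchor = iv(4_000, 4_300).midpoint  # 4150
        track = ConservationTrack()
        track.add_interval("chr1", 0, anchor, 1.0)  # left half only
        got = mean_conservation(iv(4_000, 4_300), track, half=50)
        window = track.window_scores("chr1", anchor - 50, anchor + 51)
        assert got == pytest.approx(window.mean())
        assert got == pytest.approx(50 / 101)

    def test_missing_bases_score_zero(self):
        track = self._constant_track(0.8, start=0, end=160)
        # window [100, 201) extends past coverage; absent bases count as zero
        got = mean_conservation(iv(50, 250), track, half=50)
        assert 0 < got < 0.8

    def test_scores_validated(self):
        track = ConservationTrack()
        with pytest.raises(ValueError):
            track.add_interval("chr1", 0, 10, 1.5)

    def test_bedgraph_roundtrip(self, tmp_path):
        track = ConservationTrack()
        track.add_interval("chr1", 0, 100, 0.1)
        track.add_interval("chr1", 100, 200, 0.9)
        path = tmp_path / "cons.bedgraph"
        track.to_bedgraph(path)
        back = ConservationTrack.from_bedgraph(path)
        assert np.allclose(
            back.window_scores("chr1", 50, 150),
            track.window_scores("chr1", 50, 150),
        )
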