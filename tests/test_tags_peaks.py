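import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from restcobind.intervals import GenomeLayout, GenomicInterval
from restcobind.tags import (
    PeakCall,
    TagAlignment,
    coverage_pileup,
    filter_duplicates,
    filter_peaks_by_pvalue,
    match_depth,
    read_narrowpeak,
    read_tags_bed,
    score_candidate_peaks,
    tag_frame,
    write_narrowpeak,
    write_tags_bed,
)


def tags_at(positions, strand="+", chrom="chr1", sample="s"):
    return tag_frame(
        [TagAlignment(chrom, p, strand, sample) for p in positions]
    )


class TestFilterDuplicates:
    def test_identical_tags_collapse(self):
        frame = tags_at([100, 100, 100])
        assert len(filter_duplicates(frame)) == 1

    def test_opposite_strands_are_distinct(self):
        frame = tag_frame(
            [TagAlignment("chr1", 100, "+", "s"), TagAlignment("chr1", 100, "-", "s")]
        )
        assert len(filter_duplicates(frame)) == 2

    def test_random_multiset_matches_set_oracle(self):
        rng = np.random.default_rng(1)
        records = [
            TagAlignment(
                f"chr{rng.integers(1, 3)}", int(rng.integers(0, 50)),
                "+" if rng.random() < 0.5 else "-", "s",
            )
            for _ in range(10_000)
        ]
        expected = len(set(records))
        assert len(filter_duplicates(tag_frame(records))) == expected

    def test_idempotent(self):
        frame = tags_at(np.random.default_rng(2).integers(0, 30, 500))
        once = filter_duplicates(frame)
        twice = filter_duplicates(once)
        pd.testing.assert_frame_equal(once, twice)


class TestMatchDepth:
    def test_within_tolerance_untouched(self):
        chip, inp = tags_at(range(100)), tags_at(range(100), strand="-")
        chip2, inp2 = match_depth(chip, inp, seed=0)
        assert len(chip2) == 100 and len(inp2) == 100

    def test_larger_library_subsampled_to_tolerance(self):
        chip, inp = tags_at(range(200)), tags_at(range(100), strand="-")
        chip2, inp2 = match_depth(chip, inp, tolerance=0.10, seed=0)
        assert len(inp2) == 100
        s = len(chip2)
        assert s <= 200 and (s - 100) / s <= 0.10
        # largest size satisfying the inequality
        assert s == 111

    def test_deterministic_given_seed(self):
        chip, inp = tags_at(range(500)), tags_at(range(100), strand="-")
        a = match_depth(chip, inp, seed=7)[0]
        b = match_depth(chip, inp, seed=7)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_empty_library_is_an_error(self):
        with pytest.raises(ValueError):
            match_depth(tags_at([]), tags_at(range(10)), seed=0)

    @settings(derandomize=True, max_examples=100)
    @given(n_chip=st.integers(1, 2_000), n_input=st.integers(1, 2_000))
    def test_never_grows_and_always_within_tolerance(self, n_chip, n_input):
        chip, inp = tags_at(range(n_chip)), tags_at(range(n_input), strand="-")
        chip2, inp2 = match_depth(chip, inp, tolerance=0.10, seed=3)
        a, b = len(chip2), len(inp2)
        assert a <= n_chip and b <= n_input
        assert abs(a - b) / max(a, b) <= 0.10
        assert min(a, b) == min(n_chip, n_input)  # smaller side untouched


class TestPeakFilter:
    def test_strict_threshold(self):
        peaks = [
            PeakCall(GenomicInterval("chr1", 0, 10), pvalue=p)
            for p in (1e-12, 1e-10, 1e-9)
        ]
        kept = filter_peaks_by_pvalue(peaks, 1e-10)
        assert [p.pvalue for p in kept] == [1e-12]

    def test_empty_and_missing_pvalue(self):
        assert filter_peaks_by_pvalue([], 1e-10) == []
        with pytest.raises(ValueError):
            filter_peaks_by_pvalue([PeakCall(GenomicInterval("chr1", 0, 10))])

    def test_random_peaks_match_linear_oracle(self):
        rng = np.random.default_rng(4)
        pvals = 10.0 ** rng.uniform(-15, 0, size=1_000)
        peaks = [
            PeakCall(GenomicInterval("chr1", i, i + 1), pvalue=float(p))
            for i, p in enumerate(pvals)
        ]
        kept = filter_peaks_by_pvalue(peaks, 1e-10)
        assert len(kept) == int((pvals < 1e-10).sum())
        # input order preserved
        assert [p.interval.start for p in kept] == sorted(
            p.interval.start for p in kept
        )


class TestCoveragePileup:
    def test_single_plus_tag_extension(self):
        window = GenomicInterval("chr1", 100, 110)
        cov = coverage_pileup(tags_at([100]), window, extension=5)
        assert cov.tolist() == [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]

    def test_minus_tag_covers_upstream(self):
        window = GenomicInterval("chr1", 100, 110)
        cov = coverage_pileup(tags_at([104], strand="-"), window, extension=5)
        assert cov.tolist() == [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]

    def test_no_tags_zero_vector(self):
        window = GenomicInterval("chr1", 0, 50)
        assert coverage_pileup(tags_at([]), window).sum() == 0

    def test_matches_brute_force_membership(self):
        rng = np.random.default_rng(5)
        positions = rng.integers(0, 1_000, size=500)
        strands = np.where(rng.random(500) < 0.5, "+", "-")
        records = [
            TagAlignment("chr1", int(p), s, "s")
            for p, s in zip(positions, strands)
        ]
        window = GenomicInterval("chr1", 200, 700)
        ext = 20
        cov = coverage_pileup(tag_frame(records), window, extension=ext)
        for i in range(0, 500, 37):  # spot-check positions
            x = window.start + i
            expected = sum(
                1 for t in records
                if (t.strand == "+" and t.pos5 <= x < t.pos5 + ext)
                or (t.strand == "-" and t.pos5 - ext + 1 <= x <= t.pos5)
            )
            assert cov[i] == expected


class TestStandInCaller:
    GENOME = GenomeLayout({"chr1": 200_000})

    def _uniform(self, rng, n, sample):
        pos = rng.integers(0, 200_000, size=n)
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        return tag_frame(
            [TagAlignment("chr1", int(p), s, sample) for p, s in zip(pos, strands)]
        )

    def test_null_background_yields_at_most_one_peak(self):
        rng = np.random.default_rng(6)
        chip = self._uniform(rng, 10_000, "chip")
        inp = self._uniform(rng, 10_000, "input")
        peaks = score_candidate_peaks(chip, inp, self.GENOME, p_threshold=1e-10)
        assert len(peaks) <= 1

    def test_planted_site_found_and_direction_matters(self):
        rng = np.random.default_rng(7)
        chip = self._uniform(rng, 10_000, "chip")
        inp = self._uniform(rng, 10_000, "input")
        # 50x local enrichment over 300 b centred at 100,000
        extra = 50 * 300 * 10_000 // 200_000  # ~750 extra tags
        planted = tag_frame(
            [
                TagAlignment("chr1", int(p), "+", "chip")
                for p in rng.integers(99_850, 100_150, size=extra)
            ]
        )
        chip_enriched = pd.concat([chip, planted], ignore_index=True)
        peaks = score_candidate_peaks(chip_enriched, inp, self.GENOME,
                                      p_threshold=1e-10)
        assert len(peaks) == 1
        assert peaks[0].interval.start <= 100_000 < peaks[0].interval.end
        # exchanging chip and input must not report the depleted site
        swapped = score_candidate_peaks(inp, chip_enriched, self.GENOME,
                                        p_threshold=1e-10)
        assert all(
            not (p.interval.start <= 100_000 < p.interval.end) for p in swapped
        )

    def test_extreme_enrichment_with_sparse_input(self):
        chip = tags_at([5_000] * 200, sample="chip")
        inp = self._uniform(np.random.default_rng(8), 200, "input")
        peaks = score_candidate_peaks(chip, inp, self.GENOME, p_threshold=1e-10)
        assert len(peaks) == 1
        assert peaks[0].summit == 5_000


class TestIO:
    def test_tags_bed_roundtrip(self, tmp_path):
        frame = tag_frame(
            [TagAlignment("chr1", 10, "+", "a"), TagAlignment("chr2", 99, "-", "a")]
        )
        path = tmp_path / "t.bed"
        write_tags_bed(frame, path)
        back = read_tags_bed(path, sample_id="a")
        pd.testing.assert_frame_equal(back, frame)

    def test_narrowpeak_roundtrip(self, tmp_path):
        peaks = [
            PeakCall(GenomicInterval("chr1", 100, 400), pvalue=1e-20, summit=250,
                     sample_id="x"),
            PeakCall(GenomicInterval("chr2", 0, 300), pvalue=1e-50, summit=10,
                     sample_id="y"),
        ]
        path = tmp_path / "p.narrowPeak"
        write_narrowpeak(peaks, path)
        back = read_narrowpeak(path)
        for orig, rec in zip(peaks, back):
            assert rec.interval == orig.interval
            assert rec.summit == orig.summit
            assert rec.pvalue == pytest.approx(orig.pvalue, rel=1e-6)
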