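"""Binding-intensity quantification, site-anchored signal profiles, paired
signal tests, and conservation scoring at binding sites.

Intensities are input-normalised ChIP tag counts with a pseudocount of 1
on both sides of the ratio (division by zero is impossible at tag-sparse
sites).  Profiles are per-position input-normalised coverage over a
+/- 500 base window around each site's anchor (peak summit when known,
interval midpoint otherwise); rows are sorted by descending Rest binding
intensity to mirror the conventional heat-map ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cobinding import ClassifiedSite
from .intervals import GenomicInterval, GenomeLayout, PathLike
from .tags import coverage_pileup, count_tags_in, tag_frame


def site_intensity(
    chip_tags,
    input_tags,
    site: GenomicInterval,
    pseudocount: float = 1.0,
    chip_depth: Optional[int] = None,
    input_depth: Optional[int] = None,
) -> float:
    """ChIP tag count in ``site`` normalised to the input tag count.

    The input count is scaled by the library-depth ratio so unmatched
    libraries still compare like-for-like; depth-matched libraries scale
    by ~1.
    """
    chip_tags = tag_frame(chip_tags)
    input_tags = tag_frame(input_tags)
    chip_depth = chip_depth if chip_depth is not None else len(chip_tags)
    input_depth = input_depth if input_depth is not None else len(input_tags)
    scale = chip_depth / input_depth if input_depth else 1.0
    c = count_tags_in(chip_tags, site)
    i = count_tags_in(input_tags, site)
    return (c + pseudocount) / (i * scale + pseudocount)


@dataclass
class SignalProfile:
    """Per-site, per-position input-normalised signal matrix.

    ``matrix[i, j]`` is the normalised intensity of factor ``factor`` at
    offset ``offsets[j]`` (in -half_width..+half_width) from the anchor of
    site ``site_ids[i]``.  ``clipped`` flags rows whose window ran off a
    chromosome end and was zero-padded.
    """

    site_ids: List[str]
    factor: str
    matrix: np.ndarray
    offsets: np.ndarray
    clipped: List[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.offsets.size:
            raise ValueError("matrix column count must match offsets")


def _anchored_window(anchor: int, half_width: int) -> tuple:
    return anchor - half_width, anchor + half_width + 1


def profile_matrix(
    sites: Sequence[Union[ClassifiedSite, GenomicInterval]],
    chip_tags,
    input_tags,
    factor: str = "",
    half_width: int = 500,
    extension: int = 200,
    pseudocount: float = 1.0,
    genome: Optional[GenomeLayout] = None,
    sort_scores: Optional[Sequence[float]] = None,
    chip_depth: Optional[int] = None,
    input_depth: Optional[int] = None,
) -> SignalProfile:
    """Input-normalised coverage profile around each site anchor.

    Row i covers ``[anchor-half_width, anchor+half_width]`` (2*half_width+1
    columns).  Each position holds ``(chip+c) / (scaled_input+c)``.  When
    ``sort_scores`` is given (Rest site intensities in the standard layout)
    rows are ordered by descending score; otherwise input order is kept.
    Windows extending past a chromosome end are zero-padded and flagged.
    """
    chip_tags = tag_frame(chip_tags)
    input_tags = tag_frame(input_tags)
    chip_depth = chip_depth if chip_depth is not None else len(chip_tags)
    input_depth = input_depth if input_depth is not None else len(input_tags)
    scale = chip_depth / input_depth if input_depth else 1.0

    width = 2 * half_width + 1
    rows, ids, clipped = [], [], []
    for k, site in enumerate(sites):
        if isinstance(site, ClassifiedSite):
            iv, anchor = site.interval, site.anchor
        else:
            iv, anchor = site, site.midpoint
        lo, hi = _anchored_window(anchor, half_width)
        chrom_size = genome.chrom_sizes.get(iv.chrom) if genome else None
        qlo = max(lo, 0)
        qhi = min(hi, chrom_size) if chrom_size is not None else hi
        was_clipped = qlo != lo or qhi != hi
        chip_row = np.zeros(width)
        in_row = np.zeros(width)
        if qhi > qlo:
            window = GenomicInterval(iv.chrom, qlo, qhi)
            chip_row[qlo - lo : qhi - lo] = coverage_pileup(chip_tags, window, extension)
            in_row[qlo - lo : qhi - lo] = coverage_pileup(input_tags, window, extension)
        rows.append((chip_row + pseudocount) / (in_row * scale + pseudocount))
        ids.append(f"site_{k}:{iv.chrom}:{iv.start}-{iv.end}")
        clipped.append(was_clipped)

    matrix = np.array(rows) if rows else np.empty((0, width))
    order = np.arange(len(rows))
    if sort_scores is not None and len(rows):
        scores = np.asarray(list(sort_scores), dtype=float)
        if scores.size != len(rows):
            raise ValueError("sort_scores length must match number of sites")
        order = np.argsort(-scores, kind="stable")
    return SignalProfile(
        site_ids=[ids[i] for i in order],
        factor=factor,
        matrix=matrix[order],
        offsets=np.arange(-half_width, half_width + 1),
        clipped=[clipped[i] for i in order],
    )


def threshold_mask(profile: SignalProfile, fold: float = 25.0) -> np.ndarray:
    """Boolean matrix: True where normalised intensity strictly exceeds
    ``fold`` (the heat-map colouring rule)."""
    return profile.matrix > fold


def vertical_section(
    profiles: Sequence[SignalProfile],
) -> Dict[str, np.ndarray]:
    """Column-wise mean curve (over sites) for each factor's profile."""
    if not profiles:
        raise ValueError("no profiles given")
    out: Dict[str, np.ndarray] = {}
    for p in profiles:
        if p.matrix.shape[0] == 0:
            raise ValueError(f"profile {p.factor!r} has no sites")
        out[p.factor] = p.matrix.mean(axis=0)
    return out


def paired_signal_test(
    values_a: Sequence[float], values_b: Sequence[float], exact_max_n: int = 25
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for site-paired signals.

    Uses the exact null distribution when the number of non-zero
    differences is <= ``exact_max_n`` (and no tied |differences| prevent
    it), otherwise the normal approximation with continuity correction.
    All-zero differences return p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    has_ties = np.unique(np.abs(nz)).size != nz.size
    if nz.size <= exact_max_n and not has_ties:
        res = stats.wilcoxon(
            a, b, zero_method="wilcox", correction=False,
            alternative="two-sided", method="exact",
        )
        return float(min(res.pvalue, 1.0))
    if nz.size <= 14:
        # tied |differences| at small n: exact conditional null by sign
        # enumeration with average ranks
        return _exact_signed_rank_with_ties(nz)
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=True,
        alternative="two-sided", method="approx",
    )
    return float(min(res.pvalue, 1.0))


def _exact_signed_rank_with_ties(nz: np.ndarray) -> float:
    n = nz.size
    ranks = stats.rankdata(np.abs(nz))
    w_obs = ranks[nz > 0].sum()
    signs = (
        np.arange(2**n)[:, None] >> np.arange(n)
    ) & 1  # all sign assignments
    w_all = signs @ ranks
    p = 2 * min((w_all <= w_obs + 1e-9).mean(), (w_all >= w_obs - 1e-9).mean())
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------


class ConservationTrack:
    """Per-base conservation probabilities in [0, 1], sparse over the genome.

    Bases absent from the track score 0 (the convention for unalignable
    regions) and still count in window means.
    """

    def __init__(self) -> None:
        self._chroms: Dict[str, tuple] = {}  # chrom -> (starts, ends, scores)
        self._builder: Dict[str, List[tuple]] = {}

    def add_interval(self, chrom: str, start: int, end: int, score: float) -> None:
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"conservation score {score} outside [0, 1]")
        if end <= start:
            raise ValueError("empty conservation interval")
        self._builder.setdefault(chrom, []).append((start, end, score))
        self._chroms.pop(chrom, None)

    def _compiled(self, chrom: str):
        if chrom not in self._chroms:
            spans = sorted(self._builder.get(chrom, []))
            starts = np.array([s for s, _, _ in spans], dtype=np.int64)
            ends = np.array([e for _, e, _ in spans], dtype=np.int64)
            scores = np.array([v for _, _, v in spans], dtype=float)
            self._chroms[chrom] = (starts, ends, scores)
        return self._chroms[chrom]

    def window_scores(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base scores over [start, end); uncovered bases are 0."""
        out = np.zeros(end - start)
        starts, ends, scores = self._compiled(chrom)
        if starts.size == 0:
            return out
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], scores[lo:hi]):
            a, b = max(s, start), min(e, end)
            if b > a:
                out[a - start : b - start] = v
        return out

    @classmethod
    def from_bedgraph(cls, path: PathLike) -> "ConservationTrack":
        track = cls()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, score = line.split("\t")[:4]
                track.add_interval(chrom, int(start), int(end), float(score))
        return track

    def to_bedgraph(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._builder):
                for start, end, score in sorted(self._builder[chrom]):
                    fh.write(f"{chrom}\t{start}\t{end}\t{score:.6g}\n")


def mean_conservation(
    site: Union[ClassifiedSite, GenomicInterval],
    track: ConservationTrack,
    half: int = 50,
) -> float:
    """Mean conservation over the 2*half+1 bases centred on the site anchor."""
    if isinstance(site, ClassifiedSite):
        iv, anchor = site.interval, site.anchor
    else:
        iv, anchor = site, site.midpoint
    lo, hi = anchor - half, anchor + half + 1
    if lo < 0:
        # clip at the chromosome start; absent bases contribute 0 over the
        # full nominal window length
        scores = track.window_scores(iv.chrom, 0, hi)
        return float(scores.sum() / (hi - lo))
    return float(track.window_scores(iv.chrom, lo, hi).mean())


def write_profile_tsv(profile: SignalProfile, path: PathLike) -> None:
    frame = pd.DataFrame(profile.matrix, index=profile.site_ids,
                         columns=profile.offsets)
    frame.index.name = "site"
    frame.to_csv(path, sep="\t", float_format="%.6g")


def write_mask_tsv(mask: np.ndarray, profile: SignalProfile, path: PathLike) -> None:
    frame = pd.DataFrame(mask.astype(int), index=profile.site_ids,
                         columns=profile.offsets)
    frame.index.name = "site"
    frame.to_csv(path, sep="\t")
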