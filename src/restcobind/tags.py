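"""Tag-level preprocessing and peak handling.

A "tag" is the 5'-most mapped base of a uniquely mapped sequencing read.
Collections of tags are held as pandas DataFrames with columns
``chrom, pos5, strand, sample_id`` (one row per tag), which keeps
duplicate filtering, depth matching and pileups vectorised at the
multi-million-tag scale the assays produce.

The module also carries the peak layer: p-value filtering of externally
called peaks and a deliberately minimal sliding-window Poisson scorer
used to exercise the pipeline on synthetic data.  The scorer is a local
lambda ChIP-vs-input test, not a reimplementation of a production peak
caller (no fragment-model building, no FDR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, GenomeLayout, PathLike

TAG_COLUMNS = ["chrom", "pos5", "strand", "sample_id"]


class TagAlignment(NamedTuple):
    """One uniquely mapped tag, reduced to its 5'-most base."""

    chrom: str
    pos5: int
    strand: str
    sample_id: str = ""


def tag_frame(tags: Union[pd.DataFrame, Iterable[TagAlignment]]) -> pd.DataFrame:
    """Coerce an iterable of :class:`TagAlignment` (or a frame) to the
    canonical tag DataFrame."""
    if isinstance(tags, pd.DataFrame):
        missing = [c for c in TAG_COLUMNS if c not in tags.columns]
        if missing:
            raise ValueError(f"tag frame missing columns {missing}")
        return tags
    frame = pd.DataFrame(list(tags), columns=TAG_COLUMNS)
    if len(frame) and ((frame["pos5"] < 0).any() or ~frame["strand"].isin(["+", "-"]).all()):
        raise ValueError("tags must have pos5 >= 0 and strand in {+, -}")
    return frame


def empty_tag_frame() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                         zip(TAG_COLUMNS, [str, np.int64, str, str])})


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_duplicates(tags: Union[pd.DataFrame, Iterable[TagAlignment]]) -> pd.DataFrame:
    """Keep at most one tag per (chrom, pos5, strand, sample_id).

    Idempotent; the result is sorted by key so it is independent of input
    order.
    """
    frame = tag_frame(tags)
    out = frame.drop_duplicates(subset=TAG_COLUMNS)
    return out.sort_values(TAG_COLUMNS, kind="mergesort").reset_index(drop=True)


def match_depth(
    chip: pd.DataFrame,
    input_: pd.DataFrame,
    tolerance: float = 0.10,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly subsample the larger library until depths agree within
    ``tolerance`` (relative to the larger post-matching count).

    The smaller library is never touched.  The larger one is downsampled
    without replacement to ``floor(smaller / (1 - tolerance))`` (capped at
    its own size), the largest size still satisfying
    ``(s - smaller) / s <= tolerance``.  Same seed, same inputs => same
    output rows.
    """
    chip = tag_frame(chip)
    input_ = tag_frame(input_)
    if len(chip) == 0 or len(input_) == 0:
        raise ValueError("depth matching requires non-empty chip and input libraries")
    n_chip, n_input = len(chip), len(input_)
    small, large = min(n_chip, n_input), max(n_chip, n_input)
    if (large - small) / large <= tolerance:
        return chip, input_
    target = min(large, int(small / (1.0 - tolerance)))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(large, size=target, replace=False))
    if n_chip >= n_input:
        return chip.iloc[keep].reset_index(drop=True), input_
    return chip, input_.iloc[keep].reset_index(drop=True)


def coverage_pileup(
    tags: Union[pd.DataFrame, Iterable[TagAlignment]],
    window: GenomicInterval,
    extension: int = 200,
) -> np.ndarray:
    """Per-position count of extended tags covering ``window``.

    Each tag is extended to its putative fragment: ``[pos5, pos5+extension)``
    on '+', ``(pos5-extension, pos5]`` on '-'.  Returns a vector of length
    ``window.length``.
    """
    if extension < 1:
        raise ValueError("extension must be >= 1")
    frame = tag_frame(tags)
    cov = np.zeros(window.length, dtype=np.int64)
    sub = frame[frame["chrom"] == window.chrom]
    if len(sub) == 0:
        return cov
    pos = sub["pos5"].to_numpy(dtype=np.int64)
    plus = (sub["strand"] == "+").to_numpy()
    starts = np.where(plus, pos, pos - extension + 1)
    ends = starts + extension  # half-open fragment span
    lo = np.clip(starts - window.start, 0, window.length)
    hi = np.clip(ends - window.start, 0, window.length)
    mask = hi > lo
    diff = np.zeros(window.length + 1, dtype=np.int64)
    np.add.at(diff, lo[mask], 1)
    np.add.at(diff, hi[mask], -1)
    return np.cumsum(diff[:-1])


def count_tags_in(frame: pd.DataFrame, iv: GenomicInterval) -> int:
    """Number of tag 5' positions falling inside ``iv``."""
    sub = frame[frame["chrom"] == iv.chrom]
    if len(sub) == 0:
        return 0
    pos = sub["pos5"].to_numpy()
    return int(((pos >= iv.start) & (pos < iv.end)).sum())


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakCall:
    """A called binding site with its significance."""

    interval: GenomicInterval
    pvalue: Optional[float] = None
    summit: Optional[int] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pvalue is not None and not (0 < self.pvalue <= 1):
            raise ValueError(f"pvalue must be in (0, 1], got {self.pvalue}")
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError("summit must lie within the peak interval")

    @property
    def anchor(self) -> int:
        """Profile/conservation anchor: summit when known, else midpoint."""
        return self.summit if self.summit is not None else self.interval.midpoint


def filter_peaks_by_pvalue(
    peaks: Sequence[PeakCall], threshold: float = 1e-10
) -> List[PeakCall]:
    """Keep peaks with ``pvalue < threshold`` (strict), preserving order."""
    for p in peaks:
        if p.pvalue is None:
            raise ValueError(f"peak {p.interval} has no p-value")
    return [p for p in peaks if p.pvalue < threshold]


def score_candidate_peaks(
    chip: pd.DataFrame,
    input_: pd.DataFrame,
    genome: GenomeLayout,
    window_size: int = 300,
    step: int = 100,
    p_threshold: float = 1e-10,
    sample_id: str = "",
) -> List[PeakCall]:
    """Minimal sliding-window enrichment scorer for synthetic data.

    Fixed windows of ``window_size`` every ``step`` bases are scored by the
    Poisson upper tail of the ChIP tag count against an expectation taken
    from the input in the same window (scaled to ChIP depth) floored at the
    genome-wide ChIP rate.  Overlapping significant windows are merged; the
    summit is the position of maximum ChIP 5'-tag pileup in the merged span.
    """
    if genome.total_length <= 0:
        raise ValueError("genome has zero length")
    chip = tag_frame(chip)
    input_ = tag_frame(input_)
    n_chip = len(chip)
    n_input = len(input_)
    depth_ratio = n_chip / n_input if n_input else 0.0
    genome_rate = n_chip / genome.total_length  # tags per base

    peaks: List[PeakCall] = []
    for chrom, size in genome.chrom_sizes.items():
        cpos = np.sort(chip.loc[chip["chrom"] == chrom, "pos5"].to_numpy())
        if cpos.size == 0:
            continue
        ipos = np.sort(input_.loc[input_["chrom"] == chrom, "pos5"].to_numpy())
        starts = np.arange(0, max(size - window_size, 0) + 1, step, dtype=np.int64)
        ends = np.minimum(starts + window_size, size)
        k = np.searchsorted(cpos, ends) - np.searchsorted(cpos, starts)
        k_in = np.searchsorted(ipos, ends) - np.searchsorted(ipos, starts)
        lam = np.maximum(k_in * depth_ratio, genome_rate * (ends - starts))
        with np.errstate(divide="ignore"):
            pvals = stats.poisson.sf(k - 1, lam)
        sig = np.flatnonzero((pvals < p_threshold) & (k > 0))
        if sig.size == 0:
            continue
        # merge windows sharing >= 1 base
        runs: List[Tuple[int, int, float]] = []
        run_start, run_end, run_p = starts[sig[0]], ends[sig[0]], pvals[sig[0]]
        for idx in sig[1:]:
            if starts[idx] < run_end:
                run_end = max(run_end, ends[idx])
                run_p = min(run_p, pvals[idx])
            else:
                runs.append((run_start, run_end, run_p))
                run_start, run_end, run_p = starts[idx], ends[idx], pvals[idx]
        runs.append((run_start, run_end, run_p))
        for mstart, mend, mp in runs:
            span = GenomicInterval(chrom, int(mstart), int(mend))
            inside = cpos[(cpos >= mstart) & (cpos < mend)]
            if inside.size:
                vals, counts = np.unique(inside, return_counts=True)
                summit = int(vals[np.argmax(counts)])
            else:  # pragma: no cover - sig windows always contain tags
                summit = span.midpoint
            peaks.append(
                PeakCall(span, pvalue=max(float(mp), 1e-300), summit=summit,
                         sample_id=sample_id)
            )
    return peaks


# ---------------------------------------------------------------------------
# I/O: BED6 tags, narrowPeak peaks, bedGraph pileups
# ---------------------------------------------------------------------------

def read_tags_bed(path: PathLike, sample_id: str = "") -> pd.DataFrame:
    """Read tags from BED6 (pos5 = start on '+', end-1 on '-')."""
    rows = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    pos5 = np.where(rows["strand"] == "+", rows["start"], rows["end"] - 1)
    return pd.DataFrame(
        {
            "chrom": rows["chrom"],
            "pos5": pos5.astype(np.int64),
            "strand": rows["strand"],
            "sample_id": sample_id if sample_id else rows["name"].astype(str),
        }
    )


def write_tags_bed(tags: pd.DataFrame, path: PathLike) -> None:
    frame = tag_frame(tags)
    pd.DataFrame(
        {
            "chrom": frame["chrom"].to_numpy(),
            "start": frame["pos5"].to_numpy(),
            "end": frame["pos5"].to_numpy() + 1,
            "name": frame["sample_id"].to_numpy(),
            "score": 0,
            "strand": frame["strand"].to_numpy(),
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: PathLike, sample_id: str = "") -> List[PeakCall]:
    """Read 10-column narrowPeak; column 8 holds -log10(p)."""
    peaks: List[PeakCall] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            neglog_p = float(f[7])
            summit_off = int(f[9])
            peaks.append(
                PeakCall(
                    GenomicInterval(chrom, start, end),
                    pvalue=min(10.0 ** (-neglog_p), 1.0) if neglog_p >= 0 else None,
                    summit=start + summit_off if summit_off >= 0 else None,
                    sample_id=sample_id or f[3],
                )
            )
    return peaks


def write_narrowpeak(peaks: Sequence[PeakCall], path: PathLike) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            neglog_p = -math.log10(p.pvalue) if p.pvalue else -1.0
            summit_off = p.summit - p.interval.start if p.summit is not None else -1
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.sample_id or f"peak_{i}",
                        "0",
                        ".",
                        "0",
                        f"{neglog_p:.6g}",
                        "-1",
                        str(summit_off),
                    ]
                )
                + "\n"
            )


def write_bedgraph(
    chrom: str, start: int, values: np.ndarray, path: PathLike, mode: str = "w"
) -> None:
    """Write a per-position vector as run-length-compressed bedGraph."""
    values = np.asarray(values)
    with open(path, mode) as fh:
        if values.size == 0:
            return
        change = np.flatnonzero(np.diff(values)) + 1
        bounds = np.concatenate(([0], change, [values.size]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            v = values[lo]
            fh.write(f"{chrom}\t{start + lo}\t{start + hi}\t{v:.6g}\n")
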