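"""Co-occupancy classification of Rest peaks and cross-cell comparison.

Every Rest peak is assigned one of four combinatorial classes by >= 1-base
overlap with Sin3A and Lsd1 peaks: R+/S+/L+, R+/S+/L-, R+/S-/L+ and
R+/S-/L- (Rest alone).  Rest-alone sites are conventionally dropped before
downstream analysis: they carry no catalytic corepressor subunit and show
the weakest binding signals.  Cross-cell comparison then labels each
remaining site "common" (its Rest peak overlaps a Rest peak of the other
cell state) or "unique", counted per reference cell — one peak may overlap
several peaks on the other side, so the two common counts can differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .intervals import OverlapIndex
from .tags import PeakCall


class CobindClass(str, Enum):
    """Combinatorial Sin3A/Lsd1 co-binding class of a Rest peak."""

    SpLp = "R+/S+/L+"
    SpLm = "R+/S+/L-"
    SmLp = "R+/S-/L+"
    SmLm = "R+/S-/L-"

    @staticmethod
    def from_flags(has_sin3a: bool, has_lsd1: bool) -> "CobindClass":
        return {
            (True, True): CobindClass.SpLp,
            (True, False): CobindClass.SpLm,
            (False, True): CobindClass.SmLp,
            (False, False): CobindClass.SmLm,
        }[(has_sin3a, has_lsd1)]


#: Classes retained after dropping Rest-alone sites, in reporting order.
NON_REST_ONLY = (CobindClass.SpLp, CobindClass.SpLm, CobindClass.SmLp)


@dataclass
class ClassifiedSite:
    """A Rest peak with its co-binding class and comparison annotations."""

    rest_peak: PeakCall
    cobind: CobindClass
    cell: str = ""
    specificity: Optional[str] = None  # "unique" | "common", set by compare_cells
    partner_peaks: Dict[str, List[PeakCall]] = field(default_factory=dict)
    genes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        has_s = bool(self.partner_peaks.get("Sin3A"))
        has_l = bool(self.partner_peaks.get("Lsd1"))
        if self.partner_peaks and CobindClass.from_flags(has_s, has_l) != self.cobind:
            raise ValueError(
                f"cobind class {self.cobind.value} inconsistent with partners"
            )

    @property
    def interval(self):
        return self.rest_peak.interval

    @property
    def anchor(self) -> int:
        return self.rest_peak.anchor


def classify_cobinding(
    rest: Sequence[PeakCall],
    sin3a: Sequence[PeakCall],
    lsd1: Sequence[PeakCall],
    cell: str = "",
) -> List[ClassifiedSite]:
    """Assign each Rest peak its co-binding class.

    The output is an exhaustive, exclusive partition: exactly one
    :class:`ClassifiedSite` per input Rest peak.  A Rest peak overlapping
    several Sin3A (or Lsd1) peaks yields a single site with all partners
    listed.
    """
    s_index = OverlapIndex()
    for p in sin3a:
        s_index.add(p.interval, p)
    l_index = OverlapIndex()
    for p in lsd1:
        l_index.add(p.interval, p)

    sites: List[ClassifiedSite] = []
    for peak in rest:
        s_hits = [d for _, d in s_index.query_with_data(peak.interval)]
        l_hits = [d for _, d in l_index.query_with_data(peak.interval)]
        partners: Dict[str, List[PeakCall]] = {}
        if s_hits:
            partners["Sin3A"] = s_hits
        if l_hits:
            partners["Lsd1"] = l_hits
        sites.append(
            ClassifiedSite(
                rest_peak=peak,
                cobind=CobindClass.from_flags(bool(s_hits), bool(l_hits)),
                cell=cell,
                partner_peaks=partners,
            )
        )
    return sites


def drop_rest_only(sites: Iterable[ClassifiedSite]) -> List[ClassifiedSite]:
    """Remove R+/S-/L- (Rest-alone) sites, preserving order."""
    return [s for s in sites if s.cobind != CobindClass.SmLm]


@dataclass
class CellComparison:
    """Partition of two cell states' site lists by Rest-peak overlap."""

    a_unique: List[ClassifiedSite]
    common_a: List[ClassifiedSite]
    common_b: List[ClassifiedSite]
    b_unique: List[ClassifiedSite]


def compare_cells(
    sites_a: Sequence[ClassifiedSite], sites_b: Sequence[ClassifiedSite]
) -> CellComparison:
    """Label sites common/unique by Rest-peak overlap across cell states.

    Commonality is judged on the Rest peak alone — the Sin3A/Lsd1 class of
    a common site may differ between the two cells (component switching at
    retained sites).  Counts are per reference cell: a site of A is
    ``common_a`` iff it overlaps >= 1 Rest peak of B, and symmetrically,
    so ``len(common_a) != len(common_b)`` is possible and expected.
    ``specificity`` is set in place on every site.
    """
    index_b = OverlapIndex(s.interval for s in sites_b)
    index_a = OverlapIndex(s.interval for s in sites_a)

    a_unique, common_a = [], []
    for s in sites_a:
        if index_b.any_overlap(s.interval):
            s.specificity = "common"
            common_a.append(s)
        else:
            s.specificity = "unique"
            a_unique.append(s)
    b_unique, common_b = [], []
    for s in sites_b:
        if index_a.any_overlap(s.interval):
            s.specificity = "common"
            common_b.append(s)
        else:
            s.specificity = "unique"
            b_unique.append(s)
    return CellComparison(a_unique, common_a, common_b, b_unique)


def largest_remainder_percents(counts: Sequence[int]) -> List[int]:
    """Integer percentages of a whole that sum to exactly 100.

    Floors each share, then hands the remaining points to the largest
    fractional remainders (ties: larger count first, then position).
    """
    total = sum(counts)
    if total == 0:
        return [0] * len(counts)
    exact = [100.0 * c / total for c in counts]
    floors = [int(x) for x in exact]
    leftover = 100 - sum(floors)
    order = sorted(
        range(len(counts)),
        key=lambda i: (-(exact[i] - floors[i]), -counts[i], i),
    )
    for i in order[:leftover]:
        floors[i] += 1
    return floors


def composition_from_counts(
    counts: Mapping[CobindClass, int]
) -> Dict[CobindClass, Tuple[int, int]]:
    """Class -> (count, integer percent of the non-Rest-alone total)."""
    ordered = [counts.get(c, 0) for c in NON_REST_ONLY]
    if sum(ordered) == 0:
        warnings.warn("composition of empty site list; percents reported as 0")
    pcts = largest_remainder_percents(ordered)
    return {c: (n, p) for c, n, p in zip(NON_REST_ONLY, ordered, pcts)}


def composition_percentages(
    sites: Sequence[ClassifiedSite],
) -> Dict[CobindClass, Tuple[int, int]]:
    """Count and integer-percent composition over the three retained classes.

    Input must already be Rest-alone-filtered (:func:`drop_rest_only`).
    """
    counts = {c: 0 for c in NON_REST_ONLY}
    for s in sites:
        if s.cobind == CobindClass.SmLm:
            raise ValueError("composition_percentages expects drop_rest_only output")
        counts[s.cobind] += 1
    return composition_from_counts(counts)
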