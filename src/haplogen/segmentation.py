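"""Hotspot filtering and hotspot-delimited segmentation of variant lists.

Recombination hotspots delimit blocks of variants that tend to be co-inherited,
so splitting a chromosome at hotspots preserves within-section linkage and makes
each section independently compressible.  Segmentation enforces a minimum and a
maximum number of mutations per section: runs too short to stand alone are
merged backward into the previous section (the delimiting hotspot is "ignored"),
and runs that reach the maximum are closed early at an "artificial hotspot".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import HaplotypeMatrix, HotspotSet, RecombMap

__all__ = [
    "SegmentationConfig",
    "Section",
    "SegmentationPlan",
    "filter_hotspots",
    "segment_by_hotspots",
    "segment_naive",
    "flag_split_bins",
]

REAL_HOTSPOT = "real_hotspot"
ARTIFICIAL_HOTSPOT = "artificial_hotspot"
CHROMOSOME_END = "chromosome_end"


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds for hotspot filtering and section building.

    rate_threshold: minimum recombination rate (cM/Mb) for an interval to count
        as a hotspot; intervals at or below it are discarded.
    proximity_radius: loci within this many bp of a stronger retained hotspot
        are treated as diffuse signal of the same event and dropped.
    min_mutations / max_mutations: bounds on the number of variants per section.
    """

    rate_threshold: float = 5.0
    proximity_radius: int = 5000
    min_mutations: int = 500
    max_mutations: int = 5000

    def __post_init__(self) -> None:
        if not (0 < self.min_mutations <= self.max_mutations):
            raise ValueError("need 0 < min_mutations <= max_mutations")
        if self.proximity_radius < 0:
            raise ValueError("proximity_radius must be >= 0")


@dataclass(frozen=True)
class Section:
    """Half-open variant-index range [start, end) with right-boundary provenance."""

    start: int
    end: int
    kind: str  # real_hotspot | artificial_hotspot | chromosome_end
    boundary_position: int  # bp position of the right boundary

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentationPlan:
    sections: list[Section] = field(default_factory=list)
    n_artificial: int = 0
    n_ignored_hotspots: int = 0

    def __len__(self) -> int:
        return len(self.sections)

    def validate(self, n_variants: int) -> None:
        """Check the sections are disjoint, contiguous, and cover [0, n_variants)."""
        if not self.sections:
            if n_variants != 0:
                raise ValueError("empty plan for a non-empty variant list")
            return
        if self.sections[0].start != 0:
            raise ValueError("plan must start at variant index 0")
        for prev, cur in zip(self.sections, self.sections[1:]):
            if cur.start != prev.end:
                raise ValueError(f"gap or overlap between sections at index {prev.end}")
        if self.sections[-1].end != n_variants:
            raise ValueError("plan does not cover all variants")
        for sec in self.sections:
            if sec.start >= sec.end:
                raise ValueError("empty section")


def filter_hotspots(rmap: RecombMap, cfg: SegmentationConfig = SegmentationConfig()) -> HotspotSet:
    """Reduce a recombination map to well-separated single-base hotspot loci.

    Intervals with rate <= ``rate_threshold`` are removed, survivors are reduced
    to their centre base, and any centre within ``proximity_radius`` of an
    already-retained higher-intensity locus is discarded (equal intensities are
    broken toward the smaller position).
    """
    keep = rmap.rates > cfg.rate_threshold
    centres = (rmap.starts[keep] + rmap.ends[keep]) // 2
    rates = rmap.rates[keep]
    # Greedy pruning by descending intensity; stable position tie-break.
    order = np.lexsort((centres, -rates))
    retained_pos: list[int] = []
    retained_rate: list[float] = []
    for idx in order:
        pos = int(centres[idx])
        if any(abs(pos - rp) <= cfg.proximity_radius for rp in retained_pos):
            continue
        retained_pos.append(pos)
        retained_rate.append(float(rates[idx]))
    by_pos = np.argsort(retained_pos, kind="stable")
    return HotspotSet(
        positions=np.asarray(retained_pos, dtype=np.int64)[by_pos],
        intensities=np.asarray(retained_rate, dtype=float)[by_pos],
    )


def segment_by_hotspots(
    hm: HaplotypeMatrix,
    hotspots: HotspotSet,
    cfg: SegmentationConfig = SegmentationConfig(),
    merge_mode: str = "backward",
) -> SegmentationPlan:
    """Split the variant list into hotspot-delimited sections.

    Left-to-right scan accumulating variants.  Crossing a hotspot closes the
    current run as a section if it holds at least ``min_mutations`` variants;
    otherwise the hotspot is counted as ignored and, with
    ``merge_mode="backward"`` (default), the run is appended to the previously
    closed section and accumulation restarts empty after the hotspot (with no
    previous section the run stays open); with ``merge_mode="forward"`` the
    run simply stays open across the ignored hotspot.  A run reaching
    ``max_mutations`` is closed immediately at an artificial hotspot placed
    midway to the next variant.  A hotspot lying exactly on a variant position
    falls after that variant.
    """
    if merge_mode not in ("backward", "forward"):
        raise ValueError("merge_mode must be 'backward' or 'forward'")
    m = hm.n_variants
    plan = SegmentationPlan()
    if m == 0:
        return plan
    pos = hm.positions
    hpos = hotspots.positions
    sections: list[Section] = []
    start = 0  # start of the open run
    h = int(np.searchsorted(hpos, pos[0]))  # skip hotspots before the first variant
    for i in range(m):
        count = i - start + 1
        if count == cfg.max_mutations:
            boundary = int((pos[i] + pos[i + 1]) // 2) if i + 1 < m else int(pos[i])
            sections.append(Section(start, i + 1, ARTIFICIAL_HOTSPOT, boundary))
            plan.n_artificial += 1
            start = i + 1
        # hotspots lying in [pos[i], pos[i+1]) are crossed after variant i
        limit = pos[i + 1] if i + 1 < m else None
        while h < len(hpos) and (limit is None or hpos[h] < limit):
            if limit is None and i == m - 1:
                # hotspots at/after the last variant never delimit anything
                h = len(hpos)
                break
            count = i + 1 - start
            if count >= cfg.min_mutations:
                sections.append(Section(start, i + 1, REAL_HOTSPOT, int(hpos[h])))
                start = i + 1
            elif count == 0:
                plan.n_ignored_hotspots += 1
            elif merge_mode == "backward" and sections:
                prev = sections[-1]
                sections[-1] = Section(prev.start, i + 1, REAL_HOTSPOT, int(hpos[h]))
                plan.n_ignored_hotspots += 1
                start = i + 1
            else:
                # forward mode, or no previous section: the run stays open
                plan.n_ignored_hotspots += 1
            h += 1
    if start < m:
        if sections and (m - start) < cfg.min_mutations:
            prev = sections[-1]
            sections[-1] = Section(prev.start, m, CHROMOSOME_END, int(pos[-1]))
        else:
            sections.append(Section(start, m, CHROMOSOME_END, int(pos[-1])))
    plan.sections = sections
    plan.validate(m)
    return plan


def segment_naive(hm: HaplotypeMatrix, bin_size: int) -> SegmentationPlan:
    """Contiguous equal-size bins of ``bin_size`` variants (short tail allowed)."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    m = hm.n_variants
    sections = []
    for start in range(0, m, bin_size):
        end = min(start + bin_size, m)
        kind = CHROMOSOME_END if end == m else ARTIFICIAL_HOTSPOT
        boundary = int((hm.positions[end - 1] + hm.positions[end]) // 2) if end < m else int(hm.positions[-1])
        sections.append(Section(start, end, kind, boundary))
    plan = SegmentationPlan(sections=sections)
    plan.validate(m)
    return plan


def flag_split_bins(plan: SegmentationPlan, hm: HaplotypeMatrix, hotspots: HotspotSet) -> np.ndarray:
    """Per-section flag: does a hotspot lie strictly inside the section's span?

    Used to stratify reconstruction accuracy of naive bins into hotspot-split
    vs intact bins; hotspots exactly on the first or last variant do not count.
    """
    plan.validate(hm.n_variants)
    flags = np.zeros(len(plan.sections), dtype=bool)
    for k, sec in enumerate(plan.sections):
        first = hm.positions[sec.start]
        last = hm.positions[sec.end - 1]
        flags[k] = bool(np.any((hotspots.positions > first) & (hotspots.positions < last)))
    return flags
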