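"""Hotspot filtering and section building, checked against a brute-force scan."""

import numpy as np
import pytest

from haplogen.io_formats import HotspotSet, RecombMap
from haplogen.segmentation import (
    SegmentationConfig,
    filter_hotspots,
    flag_split_bins,
    segment_by_hotspots,
    segment_naive,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Independent oracle: a deliberately naive re-implementation of the scan.

def oracle_segment(positions, hotspot_positions, min_mut, max_mut):
    """Plain-python scan; returns (section index ranges, n_artificial, n_ignored)."""
    m = len(positions)
    if m == 0:
        return [], 0, 0
    hps = [h for h in hotspot_positions if h >= positions[0]]
    sections = []
    n_art = n_ign = 0
    start = 0
    h = 0
    for i in range(m):
        if i - start + 1 == max_mut:
            sections.append((start, i + 1))
            n_art += 1
            start = i + 1
        if i + 1 < m:
            while h < len(hps) and hps[h] < positions[i + 1]:
                count = i + 1 - start
                if count >= min_mut:
                    sections.append((start, i + 1))
                    start = i + 1
                elif count == 0:
                    n_ign += 1
                elif sections:
                    sections[-1] = (sections[-1][0], i + 1)
                    n_ign += 1
                    start = i + 1
                else:
                    n_ign += 1
                h += 1
    if start < m:
        if sections and m - start < min_mut:
            sections[-1] = (sections[-1][0], m)
        else:
            sections.append((start, m))
    return sections, n_art, n_ign


def oracle_prune(centres, rates, radius):
    """Brute-force proximity pruning: keep by descending rate, earlier position first."""
    order = sorted(range(len(centres)), key=lambda i: (-rates[i], centres[i]))
    kept = []
    for i in order:
        if all(abs(centres[i] - centres[j]) > radius for j in kept):
            kept.append(i)
    return sorted(centres[i] for i in kept)


class TestFilterHotspots:
    def test_rate_threshold_is_exclusive(self):
        """Intervals at or below the threshold are removed; only rate > 5 survives."""
        rmap = RecombMap("chr1", starts=[100, 300, 500], ends=[200, 400, 600],
                         rates=[3.0, 5.0, 6.0])
        hs = filter_hotspots(rmap, SegmentationConfig(min_mutations=1))
        assert hs.positions.tolist() == [550]
        assert hs.intensities.tolist() == [6.0]

    def test_weaker_locus_near_stronger_is_pruned(self):
        rmap = RecombMap("chr1",
                         starts=[50, 3950, 19950], ends=[150, 4050, 20050],
                         rates=[10.0, 8.0, 6.0])
        hs = filter_hotspots(rmap, SegmentationConfig(min_mutations=1))
        assert hs.positions.tolist() == [100, 20000]

    def test_equal_intensity_tie_retains_earlier_position(self):
        rmap = RecombMap("chr1", starts=[950, 2950], ends=[1050, 3050], rates=[8.0, 8.0])
        hs = filter_hotspots(rmap, SegmentationConfig(min_mutations=1))
        assert hs.positions.tolist() == [1000]

    def test_empty_map_gives_empty_set(self):
        assert len(filter_hotspots(RecombMap("chr1"), SegmentationConfig(min_mutations=1))) == 0

    def test_pruning_matches_brute_force_and_invariants(self, rng):
        """No retained pair within the radius; every discarded locus has a stronger
        (or equal, earlier) retained locus within the radius."""
        cfg = SegmentationConfig(min_mutations=1, proximity_radius=5000)
        for _ in range(50):
            k = rng.integers(1, 30)
            centres = np.sort(rng.choice(np.arange(100, 100000, 100), size=k, replace=False))
            rates = rng.uniform(5.1, 20.0, size=k).round(1)
            rmap = RecombMap("chr1", starts=centres - 50, ends=centres + 50, rates=rates)
            hs = filter_hotspots(rmap, cfg)
            assert hs.positions.tolist() == oracle_prune(centres, rates, cfg.proximity_radius)
            gaps = np.diff(hs.positions)
            assert np.all(gaps > cfg.proximity_radius)
            for c, r in zip(centres, rates):
                if c not in hs.positions:
                    near = np.abs(hs.positions - c) <= cfg.proximity_radius
                    assert np.any(hs.intensities[near] >= r)


class TestSegmentByHotspots:
    def test_no_hotspots_gives_single_terminal_section(self):
        hm = make_matrix(np.zeros((2, 10), dtype=np.uint8), positions=range(1, 11))
        plan = segment_by_hotspots(hm, HotspotSet(), SegmentationConfig(min_mutations=2, max_mutations=20))
        assert [(s.start, s.end, s.kind) for s in plan.sections] == [(0, 10, "chromosome_end")]

    def test_hotspot_between_variants_splits_sections(self):
        hm = make_matrix(np.zeros((2, 10), dtype=np.uint8), positions=range(1, 11))
        hs = HotspotSet(positions=[5], intensities=[9.0])  # paired with pos 5/6 boundary
        plan = segment_by_hotspots(hm, hs, SegmentationConfig(min_mutations=2, max_mutations=20))
        assert [(s.start, s.end, s.kind) for s in plan.sections] == [
            (0, 5, "real_hotspot"), (5, 10, "chromosome_end")]

    def test_max_mutations_creates_artificial_hotspots(self):
        hm = make_matrix(np.zeros((2, 12), dtype=np.uint8), positions=range(1, 13))
        plan = segment_by_hotspots(hm, HotspotSet(), SegmentationConfig(min_mutations=2, max_mutations=5))
        assert [s.length for s in plan.sections] == [5, 5, 2]
        assert plan.n_artificial == 2
        assert [s.kind for s in plan.sections] == [
            "artificial_hotspot", "artificial_hotspot", "chromosome_end"]

    def test_short_final_run_merges_backward(self):
        hm = make_matrix(np.zeros((2, 11), dtype=np.uint8), positions=range(1, 12))
        plan = segment_by_hotspots(hm, HotspotSet(), SegmentationConfig(min_mutations=2, max_mutations=10))
        assert [(s.start, s.end, s.kind) for s in plan.sections] == [(0, 11, "chromosome_end")]

    def test_empty_matrix_gives_empty_plan(self):
        hm = make_matrix(np.zeros((2, 0), dtype=np.uint8))
        plan = segment_by_hotspots(hm, HotspotSet(), SegmentationConfig(min_mutations=1))
        assert len(plan) == 0

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        """100 random instances (M <= 200): exact agreement with the naive scan."""
        for _ in range(100):
            m = int(rng.integers(0, 200))
            positions = np.sort(rng.choice(np.arange(1, 5000), size=m, replace=False))
            hm = make_matrix(np.zeros((2, m), dtype=np.uint8), positions=positions)
            n_hs = int(rng.integers(0, 12))
            hps = np.sort(rng.choice(np.arange(1, 5100), size=n_hs, replace=False))
            hs = HotspotSet(positions=hps, intensities=np.full(n_hs, 9.0))
            min_mut = int(rng.integers(1, 30))
            max_mut = min_mut + int(rng.integers(0, 60))
            cfg = SegmentationConfig(min_mutations=min_mut, max_mutations=max_mut)
            plan = segment_by_hotspots(hm, hs, cfg)
            ranges, n_art, n_ign = oracle_segment(positions.tolist(), hps.tolist(), min_mut, max_mut)
            assert [(s.start, s.end) for s in plan.sections] == ranges
            assert plan.n_artificial == n_art
            assert plan.n_ignored_hotspots == n_ign
            plan.validate(m)  # partition: disjoint, contiguous, covering
            if len(plan.sections) > 1:
                assert all(s.length >= min_mut for s in plan.sections[:-1])
            # a closed section can only exceed max_mutations through backward
            # merges of sub-minimum runs, each adding at most min_mutations - 1
            for s in plan.sections:
                if s.length > max_mut:
                    excess = s.length - max_mut
                    assert plan.n_ignored_hotspots + 1 >= excess / max(1, min_mut - 1)

    def test_forward_merge_mode_keeps_run_open_across_ignored_hotspot(self):
        """backward: the short run joins the previous section; forward: it keeps
        accumulating and the next hotspot can close a larger section."""
        hm = make_matrix(np.zeros((2, 12), dtype=np.uint8), positions=range(1, 13))
        hs = HotspotSet(positions=[4, 6, 10], intensities=[9.0, 9.0, 9.0])
        cfg = SegmentationConfig(min_mutations=3, max_mutations=20)
        backward = segment_by_hotspots(hm, hs, cfg, merge_mode="backward")
        forward = segment_by_hotspots(hm, hs, cfg, merge_mode="forward")
        # hotspot at 4 closes [0,4); at 6 the run holds 2 < 3 variants; the
        # final sub-minimum run [10,12) merges backward in both modes
        assert [(s.start, s.end) for s in backward.sections] == [(0, 6), (6, 12)]
        assert [(s.start, s.end) for s in forward.sections] == [(0, 4), (4, 12)]
        assert backward.n_ignored_hotspots == 1
        assert forward.n_ignored_hotspots == 1

    def test_invalid_merge_mode_rejected(self):
        hm = make_matrix(np.zeros((2, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="merge_mode"):
            segment_by_hotspots(hm, HotspotSet(), SegmentationConfig(min_mutations=1),
                                merge_mode="sideways")

    def test_raising_min_mutations_never_increases_section_count(self, rng):
        for _ in range(40):
            m = int(rng.integers(10, 150))
            positions = np.sort(rng.choice(np.arange(1, 3000), size=m, replace=False))
            hm = make_matrix(np.zeros((2, m), dtype=np.uint8), positions=positions)
            n_hs = int(rng.integers(0, 10))
            hps = np.sort(rng.choice(np.arange(1, 3100), size=n_hs, replace=False))
            hs = HotspotSet(positions=hps, intensities=np.full(n_hs, 9.0))
            max_mut = 80
            counts = [len(segment_by_hotspots(hm, hs, SegmentationConfig(
                min_mutations=mn, max_mutations=max_mut))) for mn in (2, 5, 10, 20)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSegmentNaive:
    @pytest.mark.parametrize("m,bin_size,expected", [
        (10, 4, [4, 4, 2]),
        (10, 10, [10]),
        (0, 3, []),
    ])
    def test_bin_lengths(self, m, bin_size, expected):
        hm = make_matrix(np.zeros((2, m), dtype=np.uint8), positions=range(1, m + 1))
        plan = segment_naive(hm, bin_size)
        assert [s.length for s in plan.sections] == expected
        assert plan.n_artificial == 0 and plan.n_ignored_hotspots == 0

    def test_bin_size_below_one_rejected(self):
        hm = make_matrix(np.zeros((2, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            segment_naive(hm, 0)


class TestFlagSplitBins:
    def test_interior_hotspot_flags_section(self):
        hm = make_matrix(np.zeros((2, 10), dtype=np.uint8), positions=range(1, 101, 10))
        plan = segment_naive(hm, 10)
        assert flag_split_bins(plan, hm, HotspotSet(positions=[50], intensities=[9.0])).tolist() == [True]

    def test_hotspot_on_last_variant_is_not_interior(self):
        hm = make_matrix(np.zeros((2, 10), dtype=np.uint8), positions=range(1, 101, 10))
        plan = segment_naive(hm, 10)
        assert flag_split_bins(plan, hm, HotspotSet(positions=[91], intensities=[9.0])).tolist() == [False]

    def test_no_hotspots_means_no_flags(self):
        hm = make_matrix(np.zeros((2, 10), dtype=np.uint8))
        plan = segment_naive(hm, 5)
        assert not flag_split_bins(plan, hm, HotspotSet()).any()
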