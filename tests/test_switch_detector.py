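"""Physical coverage, suspicious intervals, and switch confirmation."""

from __future__ import annotations

import numpy as np
import pytest

from diphase.model import Block, CoverageProfile, SuspiciousInterval, SwitchPoint
from diphase.placement import mince, Placement
from diphase.simulate import simulate_switch_replicate
from diphase.switch_detector import (call_switch, confirm_switches,
                                     detect_candidates, physical_coverage,
                                     split_blocks, suspicious_intervals)

PAIRING = {"hapA": "hapB", "hapB": "hapA"}


class TestPhysicalCoverage:
    def test_pair_covers_outer_span(self):
        prof, _ = physical_coverage([("r", 100, 200, "r", 400, 500)], "r", 1000,
                                    bin_size=100)
        assert prof.counts.tolist() == [0, 1, 1, 1, 1, 0, 0, 0, 0, 0]

    def test_no_pairs_gives_zero_profile(self):
        prof, _ = physical_coverage([], "r", 500, bin_size=100)
        assert prof.counts.tolist() == [0] * 5

    def test_cross_ref_pairs_skipped_and_counted(self):
        _, skipped = physical_coverage([("r", 0, 10, "other", 0, 10)], "r", 100)
        assert skipped == 1

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(0)
        L, bs = 10_000, 250
        pairs = []
        for _ in range(50):
            s1 = int(rng.integers(0, L - 600))
            s2 = int(rng.integers(s1, min(L - 300, s1 + 3000)))
            pairs.append(("r", s1, s1 + 300, "r", s2, s2 + 300))
        prof, _ = physical_coverage(pairs, "r", L, bin_size=bs)
        base = np.zeros(L, dtype=int)
        for _, s1, e1, _, s2, e2 in pairs:
            base[min(s1, s2):max(e1, e2)] += 1
        # a bin counts every pair overlapping it
        expected = [sum(1 for _, s1, e1, _, s2, e2 in pairs
                        if min(s1, s2) < (i + 1) * bs and max(e1, e2) > i * bs)
                    for i in range(L // bs)]
        assert prof.counts.tolist() == expected
        assert base.sum() == sum(max(e1, e2) - min(s1, s2)
                                 for _, s1, e1, _, s2, e2 in pairs)


def profile(counts, bin_size=1000):
    return CoverageProfile("hapA", bin_size, np.asarray(counts))


class TestSuspiciousIntervals:
    def test_flat_coverage_produces_nothing(self):
        prof = profile([30] * 100)
        assert suspicious_intervals(prof, [5, 10, 15]) == []

    def test_single_dip_reported_for_every_threshold(self):
        counts = [30] * 100
        counts[40:45] = [2] * 5
        ivs = suspicious_intervals(profile(counts), [5, 10])
        assert [(iv.start, iv.end) for iv in ivs] == [(40_000, 45_000)] * 2

    def test_longest_run_wins_per_threshold(self):
        counts = [30] * 100
        counts[20:23] = [1] * 3
        counts[60:67] = [1] * 7
        ivs = suspicious_intervals(profile(counts), [10])
        assert [(iv.start, iv.end) for iv in ivs] == [(60_000, 67_000)]

    def test_end_margins_excluded(self):
        counts = [0] * 5 + [30] * 90 + [0] * 5
        assert suspicious_intervals(profile(counts), [10], end_margin_bins=10) == []


def iv(s, e, t=10):
    return SuspiciousInterval("hapA", s, e, t)


class TestCallSwitch:
    def test_deepest_stab_region_midpoint(self):
        sp = call_switch([iv(100, 200), iv(120, 180), iv(150, 300)], 3,
                         min_support=3)
        assert sp.position == 165 and sp.support == 3

    def test_matches_brute_force_stabbing(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            ivs = []
            for _ in range(int(rng.integers(1, 8))):
                s = int(rng.integers(0, 500))
                ivs.append(iv(s, s + int(rng.integers(10, 300))))
            sp = call_switch(ivs, len(ivs), min_support=1)
            coords = sorted({x for i in ivs for x in (i.start, i.end)})
            best = max(sum(1 for i in ivs if i.start <= c < i.end)
                       for c in coords)
            assert sp.support == best
            stab_at = sum(1 for i in ivs if i.start <= sp.position < i.end)
            assert stab_at == best

    def test_insufficient_support_returns_none(self):
        assert call_switch([iv(100, 200)], 4, min_support=2) is None

    def test_empty_input_returns_none(self):
        assert call_switch([], 4) is None


class TestConfirm:
    def cand(self, ref, pos):
        return SwitchPoint(ref, pos, 5)

    def test_matching_candidates_confirm_each_other(self):
        cands = {"hapA": self.cand("hapA", 50_000), "hapB": self.cand("hapB", 51_000)}
        assert len(confirm_switches(cands, PAIRING)) == 2

    def test_lone_candidate_filtered(self):
        assert confirm_switches({"hapA": self.cand("hapA", 50_000)}, PAIRING) == []

    def test_distant_partner_candidate_not_corresponding(self):
        cands = {"hapA": self.cand("hapA", 50_000), "hapB": self.cand("hapB", 500_000)}
        assert confirm_switches(cands, PAIRING) == []

    def test_no_candidates(self):
        assert confirm_switches({}, PAIRING) == []

    def test_unpaired_block_raises(self):
        with pytest.raises(ValueError, match="unpaired"):
            confirm_switches({"coll": self.cand("coll", 10)}, {})


class TestReplicates:
    """Seeded cis-dominant simulations: recovery near truth, no false calls."""

    def test_injected_switch_recovered_within_tolerance(self):
        hits = 0
        for seed in range(20):
            L = 1_000_000
            sw = int(np.random.default_rng(seed).integers(150_000, 850_000))
            pairs = simulate_switch_replicate(L, coverage=35, switch_pos=sw,
                                              seed=seed)
            by = {}
            for p in pairs:
                by.setdefault(p[0], []).append(p)
            conf = confirm_switches(detect_candidates(by, {"hapA": L, "hapB": L}),
                                    PAIRING)
            if conf and all(abs(s.position - sw) <= 5000 for s in conf):
                hits += 1
        assert hits >= 18

    def test_flat_coverage_yields_no_confirmed_switches(self):
        for seed in range(20):
            L = 1_000_000
            pairs = simulate_switch_replicate(L, coverage=35, switch_pos=None,
                                              seed=seed + 4000)
            by = {}
            for p in pairs:
                by.setdefault(p[0], []).append(p)
            assert confirm_switches(detect_candidates(by, {"hapA": L, "hapB": L}),
                                    PAIRING) == []


class TestSplitBlocks:
    def make_blocks(self, strand="+"):
        placements = [Placement("alt1", "ctg", 1000, 9000, 0, 8000, strand)]
        return mince({"ctg": 10_000}, placements, min_block_len=500)

    def test_forward_split_pairs_left_with_left(self):
        blocks, pairing = self.make_blocks("+")
        conf = [SwitchPoint("ctg:1000-9000", 3000, 5, confirmed=True),
                SwitchPoint("alt1:0-8000", 3100, 5, confirmed=True)]
        nb, npair = split_blocks(blocks, pairing, conf)
        h2 = sorted([b for b in nb if b.role == "hap2"], key=lambda b: b.start)
        assert [(b.start, b.end) for b in h2] == [(1000, 4000), (4000, 9000)]
        left_partner = npair[h2[0].block_id]
        h1 = {b.block_id: b for b in nb if b.role == "hap1"}
        assert (h1[left_partner].src_start, h1[left_partner].src_end) == (0, 3100)

    def test_reverse_split_pairs_left_with_right(self):
        blocks, pairing = self.make_blocks("-")
        conf = [SwitchPoint("ctg:1000-9000", 3000, 5, confirmed=True),
                SwitchPoint("alt1:0-8000", 5000, 5, confirmed=True)]
        nb, npair = split_blocks(blocks, pairing, conf)
        h2 = sorted([b for b in nb if b.role == "hap2"], key=lambda b: b.start)
        h1 = {b.block_id: b for b in nb if b.role == "hap1"}
        left_partner = h1[npair[h2[0].block_id]]
        # primary left sub-block pairs with the alternate's right span
        assert (left_partner.src_start, left_partner.src_end) == (5000, 8000)

    def test_sub_blocks_remember_parent(self):
        blocks, pairing = self.make_blocks("+")
        conf = [SwitchPoint("ctg:1000-9000", 3000, 5, confirmed=True),
                SwitchPoint("alt1:0-8000", 3000, 5, confirmed=True)]
        nb, _ = split_blocks(blocks, pairing, conf)
        subs = [b for b in nb if b.parent_id]
        assert len(subs) == 4
        assert {b.parent_id for b in subs} == {"ctg:1000-9000", "alt1:0-8000"}
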