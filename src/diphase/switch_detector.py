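"""Haplotype-switch detection from dips in Hi-C physical coverage.

Hi-C cis contacts dominate trans contacts, so a switch of parental origin
inside a haplotig starves the region around the switch point of same-ref
mate-pairs: physical coverage (the span from the leftmost fragment start to
the rightmost fragment end of a pair) dips sharply. Candidate switch points
are located by intersecting, across a ladder of coverage cutoffs, the
longest low-coverage interval found at each cutoff. A candidate is only
confirmed when the partner block on the other haplotype shows a candidate
too; confirmed switches split both blocks into paired sub-blocks.
"""

from __future__ import annotations

import math

import numpy as np

from .model import Block, CoverageProfile, SuspiciousInterval, SwitchPoint

DEFAULT_BIN_SIZE = 1000
END_MARGIN_BINS = 10  # coverage decays naturally at contig ends; ignore them
THRESHOLD_FRACTIONS = tuple(f / 10 for f in range(1, 10))  # 10% .. 90% of median
DEEP_FRACTION = 0.5  # the dip must reach below this fraction of the median
CONFIRM_TOLERANCE = 5_000  # bases; partner switch must correspond positionally


def physical_coverage(pairs, ref: str, ref_length: int,
                      bin_size: int = DEFAULT_BIN_SIZE) -> tuple[CoverageProfile, int]:
    """Binned physical coverage of same-ref mate-pairs on one minced sequence.

    ``pairs`` yields (ref1, start1, end1, ref2, start2, end2); pairs whose
    mates sit on different refs are skipped and counted. Each pair increments
    every bin overlapped by [min(start), max(end)).
    """
    n_bins = max(1, math.ceil(ref_length / bin_size))
    diff = np.zeros(n_bins + 1, dtype=np.int64)
    skipped = 0
    for r1, s1, e1, r2, s2, e2 in pairs:
        if r1 != ref or r2 != ref:
            skipped += 1
            continue
        lo = min(s1, s2) // bin_size
        hi = (max(e1, e2) - 1) // bin_size + 1
        diff[min(lo, n_bins)] += 1
        diff[min(hi, n_bins)] -= 1
    counts = np.cumsum(diff[:-1])
    return CoverageProfile(ref=ref, bin_size=bin_size, counts=counts), skipped


def default_thresholds(profile: CoverageProfile) -> list[float]:
    """Cutoff ladder: 10%..90% of the median non-zero bin coverage."""
    nz = profile.counts[profile.counts > 0]
    if nz.size == 0:
        return []
    med = float(np.median(nz))
    return [f * med for f in THRESHOLD_FRACTIONS if f * med > 0]


def suspicious_intervals(profile: CoverageProfile, thresholds,
                         end_margin_bins: int = END_MARGIN_BINS) -> list[SuspiciousInterval]:
    """Per cutoff, the longest run of bins below it (leftmost on ties)."""
    counts = profile.counts
    n = counts.size
    lo, hi = end_margin_bins, n - end_margin_bins
    if hi <= lo:
        return []
    out: list[SuspiciousInterval] = []
    for t in thresholds:
        below = counts[lo:hi] < t
        if not below.any():
            continue
        # run-length encode the boolean mask
        edges = np.flatnonzero(np.diff(np.concatenate(([False], below, [False])).astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        k = int(np.argmax(ends - starts))  # argmax is leftmost on ties
        out.append(SuspiciousInterval(
            ref=profile.ref,
            start=(lo + int(starts[k])) * profile.bin_size,
            end=(lo + int(ends[k])) * profile.bin_size,
            threshold=float(t),
        ))
    return out


def call_switch(intervals: list[SuspiciousInterval], n_thresholds: int,
                min_support: int | None = None) -> SwitchPoint | None:
    """Stab the intervals: the deepest-covered region marks the switch.

    The point maximizing the number of covering intervals is found by an
    endpoint sweep; if the maximum reaches ``min_support`` (default: half the
    cutoffs, rounded up) the switch point is the midpoint of the leftmost
    deepest region.
    """
    if not intervals:
        return None
    if min_support is None:
        min_support = math.ceil(n_thresholds / 2)
    events = sorted([(iv.start, 1) for iv in intervals] + [(iv.end, -1) for iv in intervals])
    depth = best = 0
    best_start = best_end = None
    for pos, delta in events:
        if delta < 0 and depth == best and best_start is not None and best_end is None:
            best_end = pos
        depth += delta
        if depth > best:
            best = depth
            best_start, best_end = pos, None
    if best_end is None:
        best_end = best_start
    if best < min_support:
        return None
    position = (best_start + best_end) // 2
    return SwitchPoint(ref=intervals[0].ref, position=position, support=best)


def detect_candidates(pairs_by_ref: dict[str, list], ref_lengths: dict[str, int],
                      bin_size: int = DEFAULT_BIN_SIZE,
                      min_support: int | None = None,
                      min_interior_bins: int = 10) -> dict[str, SwitchPoint]:
    """Run coverage -> intervals -> stabbing on every minced haplotig.

    Physical coverage ramps up over roughly one pair span from each sequence
    end; the excluded end margin therefore adapts to a high quantile of the
    ref's own physical spans (plus END_MARGIN_BINS), and refs too short to
    leave an interior are skipped.
    """
    candidates: dict[str, SwitchPoint] = {}
    for ref, length in ref_lengths.items():
        pairs = pairs_by_ref.get(ref, ())
        profile, _ = physical_coverage(pairs, ref, length, bin_size)
        spans = [max(e1, e2) - min(s1, s2) for _, s1, e1, _, s2, e2 in pairs]
        margin = END_MARGIN_BINS
        if spans:
            ramp = float(np.quantile(spans, 0.9))
            margin += math.ceil(ramp / bin_size)
        if profile.counts.size - 2 * margin < min_interior_bins:
            continue
        thresholds = default_thresholds(profile)
        if not thresholds:
            continue
        ivals = suspicious_intervals(profile, thresholds, end_margin_bins=margin)
        sp = call_switch(ivals, len(thresholds), min_support)
        if sp is None:
            continue
        # a genuine switch starves the region of cis pairs: coverage near the
        # called point must drop well below typical, not merely below a rung
        nz = profile.counts[profile.counts > 0]
        deepest = DEEP_FRACTION * float(np.median(nz))
        b = sp.position // bin_size
        window = profile.counts[max(0, b - 2):b + 3]
        if window.size and window.min() < deepest:
            candidates[ref] = sp
    return candidates


def confirm_switches(candidates: dict[str, SwitchPoint], pairing: dict[str, str],
                     blocks: dict[str, Block] | None = None,
                     tolerance: int = CONFIRM_TOLERANCE) -> list[SwitchPoint]:
    """Keep candidates whose partner block shows a corresponding candidate.

    A switch of parental origin affects both sequences of a block at the
    homologous position, so the partner's candidate must land at the
    corresponding coordinate (mirrored for reverse-strand placements) within
    ``tolerance``; independent noise dips on the two sequences almost never
    align. Without block records both sequences are assumed co-oriented and
    equal-length.
    """
    confirmed = []
    for ref, sp in sorted(candidates.items()):
        partner = pairing.get(ref)
        if partner is None:
            raise ValueError(f"switch on unpaired block {ref}")
        mate = candidates.get(partner)
        sp.confirmed = False
        if mate is not None:
            expected = sp.position
            if blocks is not None:
                b = blocks[ref]
                if b.strand == "-" or blocks[partner].strand == "-":
                    expected = (blocks[partner].src_end - blocks[partner].src_start
                                - sp.position)
            sp.confirmed = abs(mate.position - expected) <= tolerance
        if sp.confirmed:
            confirmed.append(sp)
    return confirmed


def split_blocks(blocks: list[Block], pairing: dict[str, str],
                 confirmed: list[SwitchPoint]) -> tuple[list[Block], dict[str, str]]:
    """Split both blocks of each confirmed switch into paired sub-blocks.

    The hap2 block splits at its own switch point (primary coordinates), the
    hap1 partner at its own (alternate coordinates). Left/left pairing for
    forward placements; reversed for '-' strand, where the alternate's left
    end aligns to the primary's right end. Sub-blocks remember their parent
    so a later same-phase decision can undo the split.
    """
    by_id = {b.block_id: b for b in blocks}
    switch_at = {sp.ref: sp.position for sp in confirmed if sp.confirmed}
    handled: set[str] = set()
    new_blocks: list[Block] = []
    new_pairing = dict(pairing)

    def subblock(parent: Block, lo: int, hi: int) -> Block:
        if parent.role == "hap2":
            bid = f"{parent.contig}:{lo}-{hi}"
            return Block(bid, parent.contig, lo, hi, "hap2", None, parent.source,
                         lo, hi, parent.strand, parent_id=parent.block_id)
        bid = f"{parent.source}:{lo}-{hi}"
        return Block(bid, parent.contig, parent.start, parent.end, "hap1", None,
                     parent.source, lo, hi, parent.strand, parent_id=parent.block_id)

    for b in blocks:
        if b.block_id in handled:
            continue
        pos = switch_at.get(b.block_id)
        partner_id = b.partner_id
        if pos is None or partner_id is None or partner_id not in switch_at:
            new_blocks.append(b)
            continue
        partner = by_id[partner_id]
        h2, h1 = (b, partner) if b.role == "hap2" else (partner, b)
        cut2 = h2.src_start + switch_at[h2.block_id]
        cut1 = h1.src_start + switch_at[h1.block_id]
        if not (h2.src_start < cut2 < h2.src_end and h1.src_start < cut1 < h1.src_end):
            new_blocks.append(b)  # degenerate cut at a block edge: leave intact
            continue
        handled.update((h1.block_id, h2.block_id))
        s2l = subblock(h2, h2.src_start, cut2)
        s2r = subblock(h2, cut2, h2.src_end)
        s1l = subblock(h1, h1.src_start, cut1)
        s1r = subblock(h1, cut1, h1.src_end)
        if h1.strand == "+":
            links = [(s1l, s2l), (s1r, s2r)]
        else:
            links = [(s1l, s2r), (s1r, s2l)]
        for sub1, sub2 in links:
            sub1.partner_id, sub2.partner_id = sub2.block_id, sub1.block_id
            sub1.start, sub1.end = sub2.start, sub2.end
            new_pairing[sub1.block_id] = sub2.block_id
            new_pairing[sub2.block_id] = sub1.block_id
        del new_pairing[h1.block_id], new_pairing[h2.block_id]
        new_blocks.extend([x for pair in links for x in pair])
    # preserve primary-coordinate order of the tiling
    new_blocks.sort(key=lambda b: (b.contig, b.start, b.role, b.src_start))
    return new_blocks, new_pairing


def write_switch_bed(path, switches: list[SwitchPoint]) -> None:
    with open(path, "w") as fh:
        for sp in switches:
            fh.write(f"{sp.ref}\t{sp.position}\t{sp.position + 1}"
                     f"\t{sp.support}\t{int(sp.confirmed)}\n")
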