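"""Alternate-contig placement: co-linear chaining, containment filtering, mincing.

An alternate contig aligned to its primary contig may break into several PAF
segments. Segments are chained by a dynamic program that maximizes total
aligned length minus the gaps between consecutive members on the primary
contig; the best chain defines the contig's placement. Placements partition
("mince") each primary contig into heterozygous blocks -- the placed span
(hap2, primary side) paired with the placing alternate span (hap1) -- and
collapsed blocks where no alternate sequence landed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import AlignedSegment, Block, Chain


def chain_segments(segments: list[AlignedSegment]) -> Chain:
    """Optimally chain alignment segments of one alternate contig.

    The score of a chain ending at segment i is

        f(i) = max( max_{j<i} { f(j) + |S_i| - gap(j, i) },  |S_i| )

    where |S_i| is the aligned length of segment i and gap(j, i) is the
    distance on the primary contig between the end of j and the start of i,
    clamped to 0 when the segments overlap. Backtracking follows the optimal
    predecessor P(i) (P(i) = 0 when the segment starts its own chain).
    Ties in the argmax prefer the smallest j, so the result is deterministic.
    """
    if not segments:
        raise ValueError("no segments")
    if len({s.query_name for s in segments}) != 1:
        raise ValueError("mixed queries")
    if len({s.target_name for s in segments}) != 1:
        raise ValueError("mixed targets")

    order = sorted(range(len(segments)), key=lambda k: (segments[k].target_start,
                                                        segments[k].target_end))
    segs = [segments[k] for k in order]
    n = len(segs)
    f = [0] * n
    pred = [0] * n  # 1-based; 0 = no predecessor
    for i in range(n):
        best = segs[i].aln_len
        best_j = 0
        for j in range(i):
            gap = max(0, segs[i].target_start - segs[j].target_end)
            cand = f[j] + segs[i].aln_len - gap
            if cand > best:  # strict: ties keep the smaller j / the no-predecessor case
                best = cand
                best_j = j + 1
        f[i] = best
        pred[i] = best_j

    end = max(range(n), key=lambda i: (f[i], -i))  # leftmost argmax
    members = []
    i = end
    while True:
        members.append(i)
        if pred[i] == 0:
            break
        i = pred[i] - 1
    members.reverse()
    return Chain(segment_indices=[order[i] for i in members], score=f[end],
                 predecessors=pred)


def filter_contained(segments: list[AlignedSegment]) -> list[AlignedSegment]:
    """Drop segments whose target interval is contained in a retained one.

    Byte-identical records keep their first copy in sort order. Idempotent.
    """
    ordered = sorted(segments, key=lambda s: (s.target_name, s.target_start,
                                              -s.target_end))
    kept: list[AlignedSegment] = []
    for seg in ordered:
        contained = False
        for other in kept:
            if (other.target_name == seg.target_name
                    and other.target_start <= seg.target_start
                    and seg.target_end <= other.target_end):
                contained = True
                break
        if not contained:
            kept.append(seg)
    return kept


@dataclass
class Placement:
    """A chained alternate-contig placement on one primary contig."""

    alt_name: str
    target_name: str
    target_start: int
    target_end: int
    query_start: int
    query_end: int
    strand: str


def chain_to_placement(segments: list[AlignedSegment], chain: Chain) -> Placement:
    members = [segments[i] for i in chain.segment_indices]
    return Placement(
        alt_name=members[0].query_name,
        target_name=members[0].target_name,
        target_start=min(m.target_start for m in members),
        target_end=max(m.target_end for m in members),
        query_start=min(m.query_start for m in members),
        query_end=max(m.query_end for m in members),
        strand=members[0].strand,
    )


def resolve_placements(segments: list[AlignedSegment]) -> tuple[list[Placement], list[AlignedSegment]]:
    """Group segments by (query, target), filter containment, chain each group.

    Returns the placements and the chain-retained segments (used downstream
    for the position map).
    """
    groups: dict[tuple[str, str], list[AlignedSegment]] = {}
    for seg in segments:
        groups.setdefault((seg.query_name, seg.target_name), []).append(seg)
    placements = []
    retained: list[AlignedSegment] = []
    for key in sorted(groups):
        segs = filter_contained(groups[key])
        chain = chain_segments(segs)
        placements.append(chain_to_placement(segs, chain))
        retained.extend(segs[i] for i in chain.segment_indices)
    return placements, retained


def mince(primary_lengths: dict[str, int], placements: list[Placement],
          min_block_len: int = 1000) -> tuple[list[Block], dict[str, str]]:
    """Partition primary contigs into hap1/hap2/collapsed blocks.

    Overlapping placements from different alternate contigs are resolved by
    truncating the later-starting one at the earlier one's end (the query
    span is trimmed by the same number of bases); residues shorter than
    ``min_block_len`` fall back to collapsed sequence. The returned blocks
    tile every contig: hap2 + collapsed spans are disjoint and cover [0, L).
    ``pairing`` maps hap1 block ids to hap2 block ids and back.
    """
    by_contig: dict[str, list[Placement]] = {c: [] for c in primary_lengths}
    for p in placements:
        if p.target_name not in primary_lengths:
            raise ValueError(f"unknown contig {p.target_name}")
        if p.target_end > primary_lengths[p.target_name]:
            raise ValueError("placement out of bounds")
        by_contig[p.target_name].append(p)

    blocks: list[Block] = []
    pairing: dict[str, str] = {}
    for contig in sorted(primary_lengths):
        length = primary_lengths[contig]
        todo = sorted(by_contig[contig], key=lambda p: (p.target_start, p.target_end))
        resolved: list[Placement] = []
        cursor = 0
        for p in todo:
            ts, te = p.target_start, p.target_end
            if ts < cursor:  # overlap with the previous placement: truncate
                trim = cursor - ts
                ts = cursor
                if p.strand == "+":
                    p = Placement(p.alt_name, p.target_name, ts, te,
                                  min(p.query_start + trim, p.query_end - 1), p.query_end,
                                  p.strand)
                else:
                    p = Placement(p.alt_name, p.target_name, ts, te,
                                  p.query_start, max(p.query_end - trim, p.query_start + 1),
                                  p.strand)
            if te - ts < min_block_len or te <= ts:
                continue  # degenerate residue -> collapsed
            resolved.append(p)
            cursor = te

        pos = 0
        for p in resolved:
            if p.target_start > pos:
                cid = f"{contig}:{pos}-{p.target_start}"
                blocks.append(Block(cid, contig, pos, p.target_start, "collapsed",
                                    None, contig))
            h2_id = f"{contig}:{p.target_start}-{p.target_end}"
            h1_id = f"{p.alt_name}:{p.query_start}-{p.query_end}"
            blocks.append(Block(h2_id, contig, p.target_start, p.target_end, "hap2",
                                h1_id, contig))
            blocks.append(Block(h1_id, contig, p.target_start, p.target_end, "hap1",
                                h2_id, p.alt_name, p.query_start, p.query_end,
                                p.strand))
            pairing[h1_id] = h2_id
            pairing[h2_id] = h1_id
            pos = p.target_end
        if pos < length:
            cid = f"{contig}:{pos}-{length}"
            blocks.append(Block(cid, contig, pos, length, "collapsed", None, contig))
    return blocks, pairing


def block_sequence(block: Block, primary: dict[str, str], alternate: dict[str, str]) -> str:
    """The minced sequence of a block, in the source sequence's own orientation."""
    src = alternate if block.role == "hap1" else primary
    return src[block.source][block.src_start:block.src_end]


def write_blocks_bed(path, blocks: list[Block]) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write("\t".join([
                b.contig, str(b.start), str(b.end), b.block_id, b.role,
                b.partner_id or ".", b.source, str(b.src_start), str(b.src_end),
                b.strand, b.parent_id or ".",
            ]) + "\n")


def read_blocks_bed(path) -> list[Block]:
    blocks = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            blocks.append(Block(
                block_id=f[3], contig=f[0], start=int(f[1]), end=int(f[2]),
                role=f[4], partner_id=None if f[5] == "." else f[5], source=f[6],
                src_start=int(f[7]), src_end=int(f[8]), strand=f[9],
                parent_id=None if f[10] == "." else f[10],
            ))
    return blocks


def write_pairing(path, pairing: dict[str, str], blocks: list[Block]) -> None:
    hap1 = {b.block_id for b in blocks if b.role == "hap1"}
    with open(path, "w") as fh:
        for h1 in sorted(k for k in pairing if k in hap1):
            fh.write(f"{h1}\t{pairing[h1]}\n")


def read_pairing(path) -> dict[str, str]:
    pairing: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            h1, h2 = line.split()
            pairing[h1] = h2
            pairing[h2] = h1
    return pairing
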