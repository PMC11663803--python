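"""Assemble two full-length haplotype sequences per contig from phased blocks.

For a block with phase +1 the primary span goes to the contig's haplotype 1
and the partner alternate span to haplotype 2; phase -1 swaps them.
Collapsed spans are copied into both haplotypes. Reverse-strand alternate
spans are reverse-complemented so every emitted haplotype reads in primary
coordinates. Adjacent segments are butt-joined (the primary tiling is
contiguous); alternate spans may differ in length from their primary
partner, so the two haplotypes of a contig can differ in length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fastaio import write_fasta
from .model import Block, revcomp


@dataclass
class PlanSegment:
    block_id: str
    source: str
    src_start: int
    src_end: int
    strand: str
    kind: str  # 'primary_span' | 'alternate_span' | 'collapsed'


def build_plans(blocks: list[Block], theta: dict[str, int],
                pairing: dict[str, str]) -> dict[str, tuple[list[PlanSegment], list[PlanSegment]]]:
    """Per contig, the ordered segment lists of haplotype 1 and haplotype 2."""
    by_id = {b.block_id: b for b in blocks}
    plans: dict[str, tuple[list[PlanSegment], list[PlanSegment]]] = {}
    tiling = sorted((b for b in blocks if b.role in ("hap2", "collapsed")),
                    key=lambda b: (b.contig, b.start))
    for b in tiling:
        p1, p2 = plans.setdefault(b.contig, ([], []))
        if b.role == "collapsed":
            seg = PlanSegment(b.block_id, b.source, b.src_start, b.src_end, "+",
                              "collapsed")
            p1.append(seg)
            p2.append(seg)
            continue
        if b.block_id not in theta:
            raise ValueError(f"unphased block {b.block_id}")
        partner = by_id[pairing[b.block_id]]
        prim = PlanSegment(b.block_id, b.source, b.src_start, b.src_end, "+",
                           "primary_span")
        alt = PlanSegment(partner.block_id, partner.source, partner.src_start,
                          partner.src_end, partner.strand, "alternate_span")
        if theta[b.block_id] == 1:
            p1.append(prim)
            p2.append(alt)
        else:
            p1.append(alt)
            p2.append(prim)
    return plans


def render(plan: list[PlanSegment], primary: dict[str, str],
           alternate: dict[str, str]) -> str:
    parts = []
    for seg in plan:
        pool = alternate if seg.kind == "alternate_span" else primary
        if seg.source not in pool:
            raise KeyError(f"missing sequence {seg.source}")
        s = pool[seg.source][seg.src_start:seg.src_end]
        parts.append(revcomp(s) if seg.strand == "-" else s)
    return "".join(parts)


def emit_fasta(plans, primary: dict[str, str], alternate: dict[str, str],
               groups: dict[str, str], out_dir) -> dict:
    """Write hap1.final.fasta / hap2.final.fasta grouped by contig clustering.

    A contig's haplotype 1 lands in hap1.final.fasta when the clustering put
    it in group H1, otherwise in hap2.final.fasta (and vice versa), so each
    file holds one parental haplotype genome-wide.
    """
    from pathlib import Path
    out_dir = Path(out_dir)
    files: dict[str, list] = {"H1": [], "H2": []}
    plan_rows = []
    stats = {"h1_bases": 0, "h2_bases": 0, "contigs": 0}
    for contig in sorted(plans):
        p1, p2 = plans[contig]
        g1 = groups.get(contig, "H1")
        g2 = "H2" if g1 == "H1" else "H1"
        for hap, plan, grp in ((1, p1, g1), (2, p2, g2)):
            seq = render(plan, primary, alternate)
            files[grp].append((f"{contig}_h{hap} group={grp}", seq))
            stats["h1_bases" if grp == "H1" else "h2_bases"] += len(seq)
            offset = 0
            for seg in plan:
                plan_rows.append((f"{contig}_h{hap}", offset,
                                  offset + seg.src_end - seg.src_start,
                                  seg.block_id, seg.kind, seg.strand, grp))
                offset += seg.src_end - seg.src_start
        stats["contigs"] += 1
    write_fasta(out_dir / "hap1.final.fasta", files["H1"])
    write_fasta(out_dir / "hap2.final.fasta", files["H2"])
    with open(out_dir / "plan.bed", "w") as fh:
        for row in plan_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    return stats
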