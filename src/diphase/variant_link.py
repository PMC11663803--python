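"""Position maps between alternate and primary contigs, and reciprocal SNP validation.

Heterozygous SNPs are called independently on the primary and the alternate
assembly. Because the two assemblies carry opposite haplotypes over a placed
block, a genuine heterozygous site shows up twice with swapped alleles: the
ALT allele called on the primary equals the alternate contig's base, and the
ALT allele called on the alternate equals the primary's base. Only sites
satisfying both directions are kept; everything else (sequencing artefacts,
homozygous calls, collapsed-region calls) is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from .model import AlignedSegment, Block, SnpPair, COMPLEMENT
from .pafio import parse_cigar

_SNV_BASES = frozenset("ACGT")


@dataclass
class MapEntry:
    alt_contig: str
    x_a: int
    primary_contig: str
    x_p: int
    b_a: str  # alternate base, complemented into primary orientation on '-' placements
    b_p: str
    strand: str


class PositionMap:
    """Per-base correspondence between alternate and primary contigs."""

    def __init__(self, entries: list[MapEntry]):
        self.entries = entries
        self.by_primary = {(e.primary_contig, e.x_p): e for e in entries}
        self.by_alt = {(e.alt_contig, e.x_a): e for e in entries}


def build_position_map(segments: list[AlignedSegment], primary: dict[str, str],
                       alternate: dict[str, str]) -> PositionMap:
    """Walk each placement CIGAR and record every aligned match/mismatch column.

    Insertions and deletions contribute no entries. For reverse-strand
    placements the alternate base is complemented so that both recorded bases
    are in primary-contig orientation.
    """
    entries: list[MapEntry] = []
    for seg in segments:
        if seg.cigar is None:
            raise ValueError("cigar inconsistent: missing cg tag")
        tseq = primary[seg.target_name]
        qseq = alternate[seg.query_name]
        tpos = seg.target_start
        # on '-' the CIGAR walks the query from its right end leftwards
        qpos = seg.query_start if seg.strand == "+" else seg.query_end - 1
        step = 1 if seg.strand == "+" else -1
        for n, op in parse_cigar(seg.cigar):
            if op in "M=X":
                for k in range(n):
                    xp, xa = tpos + k, qpos + step * k
                    if xp >= len(tseq) or xa < 0 or xa >= len(qseq):
                        raise ValueError("cigar inconsistent")
                    b_a = qseq[xa]
                    if seg.strand == "-":
                        b_a = b_a.translate(COMPLEMENT)
                    entries.append(MapEntry(seg.query_name, xa, seg.target_name,
                                            xp, b_a, tseq[xp], seg.strand))
                tpos += n
                qpos += step * n
            elif op in "DN":
                tpos += n
            elif op == "I":
                qpos += step * n
            elif op in "SH":
                pass
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")
        if tpos != seg.target_end:
            raise ValueError("cigar inconsistent")
    return PositionMap(entries)


def _read_snvs(vcf_path) -> tuple[dict[tuple[str, int], list[str]], int]:
    """ALT alleles per (contig, 0-based position); multiallelic records split."""
    calls: dict[tuple[str, int], list[str]] = {}
    skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if rec.ref is None or len(rec.ref) != 1 or rec.ref not in _SNV_BASES:
                skipped += 1
                continue
            for alt in rec.alts or ():
                if len(alt) == 1 and alt in _SNV_BASES:
                    calls.setdefault((rec.contig, rec.pos - 1), []).append(alt)
                else:
                    skipped += 1
    return calls, skipped


def cross_validate_snps(primary_vcf, alternate_vcf,
                        posmap: PositionMap) -> tuple[list[SnpPair], dict]:
    """Keep SNP pairs where ALT_p equals B_a and ALT_a equals B_p.

    Alleles on reverse-strand placements are compared in primary orientation
    (ALT_a is complemented before the check). Sites called on only one
    assembly or outside any placement are discarded and counted.
    """
    p_calls, p_skip = _read_snvs(primary_vcf)
    a_calls, a_skip = _read_snvs(alternate_vcf)
    pairs: list[SnpPair] = []
    stats = {"primary_calls": len(p_calls), "alternate_calls": len(a_calls),
             "non_snv_skipped": p_skip + a_skip, "unmapped": 0, "retained": 0,
             "discarded": 0}
    for (contig, x_p), alts_p in sorted(p_calls.items()):
        entry = posmap.by_primary.get((contig, x_p))
        if entry is None:
            stats["unmapped"] += 1
            continue
        alts_a = a_calls.get((entry.alt_contig, entry.x_a))
        if not alts_a:
            stats["discarded"] += 1
            continue
        if entry.strand == "-":
            alts_a_oriented = [a.translate(COMPLEMENT) for a in alts_a]
        else:
            alts_a_oriented = list(alts_a)
        hit_p = entry.b_a in alts_p
        hit_a = entry.b_p in alts_a_oriented
        if hit_p and hit_a:
            stats["retained"] += 1
            pairs.append(SnpPair(contig, x_p, entry.alt_contig, entry.x_a,
                                 entry.b_a, alts_a[alts_a_oriented.index(entry.b_p)],
                                 retained=True))
        else:
            stats["discarded"] += 1
    return pairs, stats


def lift_to_minced(pairs: list[SnpPair], blocks: list[Block]) -> dict[str, list[int]]:
    """Project retained SNP positions onto minced block coordinates.

    Each retained pair yields a position on the hap2 block containing x_p and
    one on the hap1 block containing x_a; SNPs falling in collapsed spans
    (possible after placement truncation) are dropped.
    """
    hap2 = {}
    hap1 = {}
    for b in blocks:
        if b.role == "hap2":
            hap2.setdefault(b.contig, []).append(b)
        elif b.role == "hap1":
            hap1.setdefault(b.source, []).append(b)
    out: dict[str, set[int]] = {}
    for p in pairs:
        for b in hap2.get(p.primary_contig, ()):
            if b.start <= p.x_p < b.end:
                out.setdefault(b.block_id, set()).add(p.x_p - b.start)
                break
        for b in hap1.get(p.alt_contig, ()):
            if b.src_start <= p.x_a < b.src_end:
                out.setdefault(b.block_id, set()).add(p.x_a - b.src_start)
                break
    return {ref: sorted(v) for ref, v in out.items()}


def write_snp_tsv(path, pairs: list[SnpPair]) -> None:
    with open(path, "w") as fh:
        fh.write("#primary_contig\tx_p\talt_contig\tx_a\talt_p\talt_a\n")
        for p in pairs:
            fh.write(f"{p.primary_contig}\t{p.x_p}\t{p.alt_contig}\t{p.x_a}"
                     f"\t{p.alt_p}\t{p.alt_a}\n")


def read_snp_tsv(path) -> list[SnpPair]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            c, xp, a, xa, ap, aa = line.split()
            pairs.append(SnpPair(c, int(xp), a, int(xa), ap, aa, retained=True))
    return pairs
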