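"""SNP-aware filtering of Hi-C mate-pair alignments.

A Hi-C alignment is informative if it is either confidently placed
(mapping quality strictly above ``q``, default 10, and NM edit distance
strictly below ``e``, default 5) or anchored by at least one reciprocally
validated heterozygous SNP inside an aligned column. A mate-pair survives
only when both of its reads pass; surviving pairs feed switch detection and
phasing. With no SNPs the filter reduces to the plain MAPQ/edit-distance
baseline.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from typing import Iterator

import pysam

from .model import HiCAlignment, HiCMatePair

PREFILTER_MASK = 0x4 | 0x8 | 0x100 | 0x800  # unmapped, mate-unmapped, secondary, supplementary
DEFAULT_MAPQ = 10
DEFAULT_EDIT_DIST = 5


def _to_alignment(rec: pysam.AlignedSegment) -> HiCAlignment:
    nm = rec.get_tag("NM") if rec.has_tag("NM") else -1
    ref_blocks = tuple(rec.get_blocks())  # M-run intervals on the reference
    return HiCAlignment(
        read_name=rec.query_name,
        mate=2 if rec.is_read2 else 1,
        ref=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        mapq=rec.mapping_quality,
        edit_distance=nm,
        ref_blocks=ref_blocks,
    )


def prefilter_records(sam_path) -> tuple[list[HiCMatePair], dict]:
    """Drop masked records and group the rest into mate-pairs by read name.

    Records with any of the unmapped/mate-unmapped/secondary/supplementary
    flags (mask 2316) are removed. The input must be name-grouped; a name
    recurring after an intervening different name raises. Names that do not
    yield exactly one surviving record per mate are discarded and counted.
    """
    pairs: list[HiCMatePair] = []
    stats = {"records": 0, "masked": 0, "incomplete_pairs": 0, "pairs": 0}
    seen: set[str] = set()
    current: str | None = None
    bucket: list[HiCAlignment] = []

    def flush():
        if current is None:
            return
        mates = {a.mate for a in bucket}
        if len(bucket) == 2 and mates == {1, 2}:
            a1, a2 = sorted(bucket, key=lambda a: a.mate)
            pairs.append(HiCMatePair(current, a1, a2))
            stats["pairs"] += 1
        else:
            stats["incomplete_pairs"] += 1

    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for rec in sam:
            name = rec.query_name
            if name != current:
                if name in seen:
                    raise ValueError("name grouping required")
                flush()
                if current is not None:
                    seen.add(current)
                current = name
                bucket = []
            stats["records"] += 1
            if rec.flag & PREFILTER_MASK:
                stats["masked"] += 1
                continue
            bucket.append(_to_alignment(rec))
        flush()
    return pairs, stats


def annotate_snp_hits(aln: HiCAlignment, snps: dict[str, list[int]]) -> HiCAlignment:
    """Count retained SNP positions under the read's aligned reference columns.

    Only M/=/X columns count: a SNP inside a deletion or beyond a clip is not
    covered.
    """
    positions = snps.get(aln.ref)
    if not positions:
        aln.snp_hits = 0
        return aln
    hits = 0
    for s, e in aln.ref_blocks or ((aln.start, aln.end),):
        hits += bisect_left(positions, e) - bisect_right(positions, s - 1)
    aln.snp_hits = hits
    return aln


def alignment_passes(aln: HiCAlignment, q: int = DEFAULT_MAPQ,
                     e: int = DEFAULT_EDIT_DIST) -> bool:
    quality_ok = aln.mapq > q and 0 <= aln.edit_distance < e
    return quality_ok or aln.snp_hits >= 1


def filter_matepairs(pairs: list[HiCMatePair], snps: dict[str, list[int]] | None = None,
                     q: int = DEFAULT_MAPQ, e: int = DEFAULT_EDIT_DIST,
                     dedup: bool = False) -> tuple[list[HiCMatePair], dict]:
    """Keep pairs whose both mates pass the quality-or-SNP filter."""
    snps = snps or {}
    kept: list[HiCMatePair] = []
    stats = {"seen": 0, "kept": 0, "dropped": 0, "quality_only": 0,
             "snp_rescued": 0, "duplicates": 0}
    coords_seen: set[tuple] = set()
    for pair in pairs:
        stats["seen"] += 1
        a1 = annotate_snp_hits(pair.aln1, snps)
        a2 = annotate_snp_hits(pair.aln2, snps)
        pair.passed = alignment_passes(a1, q, e) and alignment_passes(a2, q, e)
        if not pair.passed:
            stats["dropped"] += 1
            continue
        if dedup:
            key = (a1.ref, a1.start, a1.end, a2.ref, a2.start, a2.end)
            if key in coords_seen:
                stats["duplicates"] += 1
                continue
            coords_seen.add(key)
        quality_both = (a1.mapq > q and 0 <= a1.edit_distance < e
                        and a2.mapq > q and 0 <= a2.edit_distance < e)
        stats["quality_only" if quality_both else "snp_rescued"] += 1
        stats["kept"] += 1
        kept.append(pair)
    return kept, stats


def write_pairs_tsv(path, pairs: list[HiCMatePair]) -> None:
    with open(path, "w") as fh:
        fh.write("#read\tref1\tstart1\tend1\tref2\tstart2\tend2\n")
        for p in pairs:
            fh.write(f"{p.read_name}\t{p.aln1.ref}\t{p.aln1.start}\t{p.aln1.end}"
                     f"\t{p.aln2.ref}\t{p.aln2.start}\t{p.aln2.end}\n")


def read_pairs_tsv(path) -> Iterator[tuple[str, str, int, int, str, int, int]]:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            name, r1, s1, e1, r2, s2, e2 = line.split()
            yield name, r1, int(s1), int(e1), r2, int(s2), int(e2)
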