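"""Minimal PAF reader/writer (12 mandatory columns + cg:Z CIGAR tag)."""

from __future__ import annotations

from .model import AlignedSegment


def parse_paf_line(line: str) -> AlignedSegment:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"malformed PAF line ({len(fields)} columns)")
    cigar = None
    for tag in fields[12:]:
        if tag.startswith("cg:Z:"):
            cigar = tag[5:]
    return AlignedSegment(
        query_name=fields[0],
        query_start=int(fields[2]),
        query_end=int(fields[3]),
        strand=fields[4],
        target_name=fields[5],
        target_start=int(fields[7]),
        target_end=int(fields[8]),
        aln_len=int(fields[10]),
        mapq=int(fields[11]),
        cigar=cigar,
    )


def read_paf(path) -> list[AlignedSegment]:
    segments = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                segments.append(parse_paf_line(line))
    return segments


def write_paf(path, records) -> None:
    """records: iterable of (segment, query_len, target_len, n_match)."""
    with open(path, "w") as fh:
        for seg, qlen, tlen, n_match in records:
            cols = [
                seg.query_name, str(qlen), str(seg.query_start), str(seg.query_end),
                seg.strand,
                seg.target_name, str(tlen), str(seg.target_start), str(seg.target_end),
                str(n_match), str(seg.aln_len), str(seg.mapq),
            ]
            if seg.cigar:
                cols.append(f"cg:Z:{seg.cigar}")
            fh.write("\t".join(cols) + "\n")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = []
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            if not n or ch not in "MIDNSHP=X":
                raise ValueError(f"bad CIGAR {cigar!r}")
            ops.append((int(n), ch))
            n = ""
    if n:
        raise ValueError(f"trailing count in CIGAR {cigar!r}")
    return ops
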