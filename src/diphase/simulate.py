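"""Synthetic diploid fixtures with full ground truth.

Generates everything the pipeline consumes -- a diploid genome, a
primary/alternate assembly with optional injected haplotype switches, SNP
VCFs with correct reciprocal alleles, an alternate-to-primary PAF with exact
CIGARs, and a name-grouped Hi-C SAM -- as a pure function of (parameters,
seed). Hi-C "alignments" are synthesized directly as SAM records against
the minced assembly; no read simulation or aligner is involved, which keeps
fixtures desk-scale. The generative assumption mirrors chromatin contact
data: cis mate-pairs (both reads from one parental haplotype) outnumber
trans pairs by the configured ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from . import placement
from .fastaio import write_fasta
from .model import AlignedSegment, revcomp
from .pafio import write_paf

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
READ_LEN = 150
# MAPQ drawn 0/5/20/60 with these weights; NM ~ Poisson(2)
NOISE_MAPQ = (np.array([0, 5, 20, 60]), np.array([0.1, 0.1, 0.2, 0.6]))
NOISE_NM_MEAN = 2.0


@dataclass
class TruthBlock:
    contig: str
    start: int
    end: int
    kind: str  # 'het' | 'collapsed'
    origin: str = ""  # haplotype carried by the primary at block start: 'A'|'B'
    switch: int | None = None  # primary coordinate where the origin flips
    alt_name: str | None = None
    strand: str = "+"

    def origin_at(self, pos: int) -> str:
        if self.kind != "het":
            raise ValueError("collapsed block has no origin")
        o = self.origin
        if self.switch is not None and pos >= self.switch:
            o = "B" if o == "A" else "A"
        return o


@dataclass
class TruthSet:
    """Ground truth behind one synthetic fixture."""

    hap_a: dict[str, str]
    hap_b: dict[str, str]
    snps: dict[str, list[tuple[int, str, str]]]  # contig -> (pos, base_a, base_b)
    blocks: list[TruthBlock] = field(default_factory=list)
    switches: list[tuple[str, int]] = field(default_factory=list)
    pair_labels: list[str] = field(default_factory=list)  # 'cis' | 'trans' per pair

    def blocks_of(self, contig: str) -> list[TruthBlock]:
        return [b for b in self.blocks if b.contig == contig]

    def to_json(self) -> dict:
        return {
            "contigs": sorted(self.hap_a),
            "snps": {c: [[p, a, b] for p, a, b in v] for c, v in self.snps.items()},
            "blocks": [vars(b) for b in self.blocks],
            "switches": [list(s) for s in self.switches],
        }

    @classmethod
    def from_json(cls, d: dict, hap_a: dict[str, str], hap_b: dict[str, str]) -> "TruthSet":
        t = cls(hap_a=hap_a, hap_b=hap_b,
                snps={c: [tuple(x) for x in v] for c, v in d["snps"].items()})
        t.blocks = [TruthBlock(**b) for b in d["blocks"]]
        t.switches = [tuple(s) for s in d["switches"]]
        return t


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def simulate_diploid(length: int, n_contigs: int, het_rate: float,
                     seed: int) -> TruthSet:
    """Two haplotypes: B is A with Bernoulli(het_rate) substitutions."""
    if length < 10_000:
        raise ValueError("length must be at least 10 kb")
    if not 0 <= het_rate <= 0.05:
        raise ValueError("het_rate out of range (0, 0.05]")
    rng = np.random.default_rng(seed)
    hap_a: dict[str, str] = {}
    hap_b: dict[str, str] = {}
    snps: dict[str, list[tuple[int, str, str]]] = {}
    clen = length // n_contigs
    for i in range(n_contigs):
        name = f"ctg{i + 1}"
        a = _random_seq(rng, clen)
        b = a.copy()
        sites = np.flatnonzero(rng.random(clen) < het_rate)
        contig_snps = []
        for p in sites:
            choices = BASES[BASES != a[p]]
            b[p] = rng.choice(choices)
            contig_snps.append((int(p), chr(a[p]), chr(b[p])))
        hap_a[name] = a.tobytes().decode()
        hap_b[name] = b.tobytes().decode()
        snps[name] = contig_snps
    return TruthSet(hap_a=hap_a, hap_b=hap_b, snps=snps)


@dataclass
class Assembly:
    primary: dict[str, str]
    alternate: dict[str, str]
    paf_records: list  # (AlignedSegment, qlen, tlen, n_match)
    primary_vcf: list[tuple[str, int, str, str]]  # contig, pos0, ref, alt
    alternate_vcf: list[tuple[str, int, str, str]]


def derive_assembly(truth: TruthSet, block_len_mean: int, switch_count: int,
                    seed: int, collapsed_frac: float = 0.3,
                    rev_frac: float = 0.25, split_frac: float = 0.3) -> Assembly:
    """Mosaic primary + opposite-origin alternates, with injected switches.

    Each contig is cut into blocks of roughly ``block_len_mean``; a block is
    collapsed with probability ``collapsed_frac`` (its heterozygous sites
    are erased from the truth -- the assembler merged the haplotypes there),
    otherwise the primary carries a random parental origin and an alternate
    contig carries the other. ``switch_count`` blocks get a mid-block origin
    flip on both sequences, recorded in the truth. A fraction of alternates
    is stored reverse-complemented; a fraction of PAF placements is split in
    two abutting segments to exercise chaining.
    """
    rng = np.random.default_rng(seed)
    # partition contigs into blocks
    for contig, seq in truth.hap_a.items():
        clen = len(seq)
        pos = 0
        while pos < clen:
            blen = int(rng.uniform(0.6, 1.4) * block_len_mean)
            end = min(pos + blen, clen)
            if clen - end < block_len_mean // 2:
                end = clen
            kind = "collapsed" if rng.random() < collapsed_frac else "het"
            tb = TruthBlock(contig, pos, end, kind)
            if kind == "het":
                tb.origin = "A" if rng.random() < 0.5 else "B"
                tb.strand = "-" if rng.random() < rev_frac else "+"
            truth.blocks.append(tb)
            pos = end
    het_blocks = [b for b in truth.blocks if b.kind == "het"]
    if not het_blocks and collapsed_frac < 1:
        truth.blocks[0].kind = "het"
        truth.blocks[0].origin = "A"
        het_blocks = [truth.blocks[0]]

    # collapsed regions are homozygous: erase their planted substitutions
    collapsed = {(b.contig, b.start, b.end) for b in truth.blocks if b.kind == "collapsed"}
    for contig in list(truth.hap_b):
        b_arr = bytearray(truth.hap_b[contig], "ascii")
        a_seq = truth.hap_a[contig]
        kept = []
        for p, a, b in truth.snps[contig]:
            in_collapsed = any(s <= p < e for (c, s, e) in collapsed if c == contig)
            if in_collapsed:
                b_arr[p] = ord(a_seq[p])
            else:
                kept.append((p, a, b))
        truth.hap_b[contig] = b_arr.decode()
        truth.snps[contig] = kept

    # inject switches into the largest het blocks, away from block edges
    eligible = sorted(het_blocks, key=lambda b: b.start - b.end)
    eligible = [b for b in eligible if b.end - b.start >= 4000]
    if switch_count > len(eligible):
        raise ValueError("switch_count exceeds feasible blocks")
    for b in eligible[:switch_count]:
        lo = b.start + (b.end - b.start) // 4
        hi = b.end - (b.end - b.start) // 4
        b.switch = int(rng.integers(lo, hi))
        truth.switches.append((b.contig, b.switch))

    primary: dict[str, str] = {}
    alternate: dict[str, str] = {}
    paf_records = []
    p_vcf: list[tuple[str, int, str, str]] = []
    a_vcf: list[tuple[str, int, str, str]] = []
    alt_idx = 0
    for contig in sorted(truth.hap_a):
        parts = []
        for b in sorted(truth.blocks_of(contig), key=lambda x: x.start):
            hap = {"A": truth.hap_a, "B": truth.hap_b}
            if b.kind == "collapsed":
                parts.append(truth.hap_a[contig][b.start:b.end])
                continue
            cut = b.switch if b.switch is not None else b.end
            o1, o2 = b.origin, ("B" if b.origin == "A" else "A")
            prim_seq = hap[o1][contig][b.start:cut] + hap[o2][contig][cut:b.end]
            alt_seq = hap[o2][contig][b.start:cut] + hap[o1][contig][cut:b.end]
            parts.append(prim_seq)
            alt_idx += 1
            alt_name = f"alt{alt_idx}"
            b.alt_name = alt_name
            stored = revcomp(alt_seq) if b.strand == "-" else alt_seq
            alternate[alt_name] = stored
            blen = b.end - b.start
            segs = []
            if rng.random() < split_frac and blen > 4000:
                m = int(rng.integers(blen // 4, 3 * blen // 4))
                tgt = [(b.start, b.start + m), (b.start + m, b.end)]
            else:
                tgt = [(b.start, b.end)]
            for ts, te in tgt:
                ln = te - ts
                if b.strand == "+":
                    qs, qe = ts - b.start, te - b.start
                else:
                    qs, qe = blen - (te - b.start), blen - (ts - b.start)
                segs.append(AlignedSegment(alt_name, qs, qe, b.strand, contig,
                                           ts, te, ln, 60, cigar=f"{ln}M"))
            for seg in segs:
                paf_records.append((seg, blen, len(truth.hap_a[contig]),
                                    seg.aln_len))
            for p, ba, bb in truth.snps[contig]:
                if not b.start <= p < b.end:
                    continue
                prim_base = ba if b.origin_at(p) == "A" else bb
                alt_base = bb if b.origin_at(p) == "A" else ba
                p_vcf.append((contig, p, prim_base, alt_base))
                if b.strand == "+":
                    ap = p - b.start
                    a_vcf.append((alt_name, ap, alt_base, prim_base))
                else:
                    ap = blen - 1 - (p - b.start)
                    a_vcf.append((alt_name, ap, revcomp(alt_base), revcomp(prim_base)))
        primary[contig] = "".join(parts)
    return Assembly(primary=primary, alternate=alternate, paf_records=paf_records,
                    primary_vcf=sorted(p_vcf), alternate_vcf=sorted(a_vcf))


def write_vcf(path, records, contig_lengths: dict[str, int]) -> None:
    """records: (contig, pos0, ref, alt); written as minimal VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(contig_lengths):
            fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for contig, pos, ref, alt in records:
            fh.write(f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t30\tPASS\t.\tGT\t0/1\n")


class _MincedMapper:
    """Maps (haplotype, contig, primary position) -> (minced ref, position)."""

    def __init__(self, truth: TruthSet, assembly: Assembly, min_block_len: int = 1000):
        placements, retained = placement.resolve_placements(
            [rec[0] for rec in assembly.paf_records])
        lengths = {c: len(s) for c, s in assembly.primary.items()}
        self.blocks, self.pairing = placement.mince(lengths, placements, min_block_len)
        self.sequences = {
            b.block_id: placement.block_sequence(b, assembly.primary, assembly.alternate)
            for b in self.blocks}
        self.truth_by_contig = {
            c: sorted(truth.blocks_of(c), key=lambda b: b.start) for c in truth.hap_a}
        self.tiling = {}
        for b in self.blocks:
            if b.role in ("hap2", "collapsed"):
                self.tiling.setdefault(b.contig, []).append(b)
        for v in self.tiling.values():
            v.sort(key=lambda b: b.start)
        self.by_id = {b.block_id: b for b in self.blocks}

    def locate(self, hap: str, contig: str, pos: int, read_len: int):
        """Returns (ref, start) or None when the read would cross a boundary."""
        for tb in self.truth_by_contig[contig]:
            if tb.start <= pos < tb.end:
                break
        else:
            return None
        if pos + read_len > tb.end:
            return None
        if tb.kind == "het" and tb.switch is not None:
            if pos < tb.switch < pos + read_len:
                return None
        for mb in self.tiling[contig]:
            if mb.start <= pos < mb.end:
                break
        else:
            return None
        if pos + read_len > mb.end:
            return None
        if tb.kind == "collapsed" or mb.role == "collapsed":
            return mb.block_id, pos - mb.start
        if hap == tb.origin_at(pos):
            return mb.block_id, pos - mb.start
        partner = self.by_id[self.pairing[mb.block_id]]
        if partner.strand == "+":
            return partner.block_id, pos - mb.start
        alt_len = partner.src_end - partner.src_start
        return partner.block_id, alt_len - (pos - mb.start) - read_len


def simulate_hic(truth: TruthSet, assembly: Assembly, out_sam, pairs_n: int,
                 cis_trans_ratio: float, seed: int,
                 insert_range: tuple[int, int | None] = (1000, None),
                 noise: bool = True, read_len: int = READ_LEN,
                 min_block_len: int = 1000,
                 inter_contig_frac: float = 0.15) -> dict:
    """Write a name-grouped Hi-C SAM against the minced assembly.

    Each mate-pair picks a contig (length-weighted) and a parental
    haplotype; with probability ratio/(ratio+1) the second mate comes from
    the same haplotype (cis), otherwise from the other (trans). Mates are
    separated by a log-uniform distance within ``insert_range`` (upper
    bound defaulting to the contig length), emulating the power-law decay
    of chromatin contact probability while keeping support across the whole
    contig; each mate maps to the minced reference the chosen haplotype
    occupies at its position. A fraction of pairs joins two contigs (the
    long-range contacts that anchor contig clustering).
    MAPQ/NM noise follows a fixed categorical/Poisson model; with
    ``noise=False`` every record gets MAPQ 60 and NM 0 and passes the
    default quality filter.
    """
    rng = np.random.default_rng(seed)
    mapper = _MincedMapper(truth, assembly, min_block_len)
    refs = sorted(mapper.sequences)
    header = {"HD": {"VN": "1.6", "SO": "unsorted", "GO": "query"},
              "SQ": [{"SN": r, "LN": len(mapper.sequences[r])} for r in refs]}
    ref_id = {r: i for i, r in enumerate(refs)}
    contigs = sorted(truth.hap_a)
    weights = np.array([len(truth.hap_a[c]) for c in contigs], dtype=float)
    weights /= weights.sum()
    p_cis = cis_trans_ratio / (cis_trans_ratio + 1.0)
    stats = {"pairs": 0, "cis": 0, "trans": 0, "discarded_draws": 0}
    truth.pair_labels = []
    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as sam:
        written = 0
        while written < pairs_n:
            contig = contigs[rng.choice(len(contigs), p=weights)]
            clen = len(truth.hap_a[contig])
            hap1 = "A" if rng.random() < 0.5 else "B"
            cis = rng.random() < p_cis
            hap2 = hap1 if cis else ("B" if hap1 == "A" else "A")
            inter = len(contigs) > 1 and rng.random() < inter_contig_frac
            placed = None
            for _ in range(30):
                p1 = int(rng.integers(0, clen - read_len))
                if inter:
                    others = [c for c in contigs if c != contig]
                    contig2 = others[int(rng.integers(0, len(others)))]
                    p2 = int(rng.integers(0, len(truth.hap_a[contig2]) - read_len))
                else:
                    contig2 = contig
                    lo = insert_range[0]
                    hi = insert_range[1] or (clen - read_len)
                    d = int(np.exp(rng.uniform(np.log(lo), np.log(max(hi, lo + 1)))))
                    p2 = p1 + d if rng.random() < 0.5 else p1 - d
                    if not 0 <= p2 <= clen - read_len:
                        continue
                loc1 = mapper.locate(hap1, contig, p1, read_len)
                loc2 = mapper.locate(hap2, contig2, p2, read_len)
                if loc1 and loc2:
                    placed = (loc1, loc2)
                    break
                stats["discarded_draws"] += 1
            if placed is None:
                continue
            written += 1
            name = f"pair{written}"
            label = "cis" if cis else "trans"
            truth.pair_labels.append(label)
            stats["cis" if cis else "trans"] += 1
            stats["pairs"] += 1
            for mate, (ref, start) in enumerate(placed, start=1):
                rec = pysam.AlignedSegment()
                rec.query_name = name
                rec.reference_id = ref_id[ref]
                rec.reference_start = start
                rec.mapping_quality = (int(rng.choice(NOISE_MAPQ[0], p=NOISE_MAPQ[1]))
                                       if noise else 60)
                rec.cigarstring = f"{read_len}M"
                rec.query_sequence = mapper.sequences[ref][start:start + read_len]
                rec.flag = 0x1 | (0x40 if mate == 1 else 0x80)
                other = placed[1] if mate == 1 else placed[0]
                rec.next_reference_id = ref_id[other[0]]
                rec.next_reference_start = other[1]
                rec.set_tag("NM", int(rng.poisson(NOISE_NM_MEAN)) if noise else 0)
                sam.write(rec)
    return stats


def simulate_switch_replicate(length: int, coverage: float, switch_pos: int | None,
                              seed: int, insert_mean: int = 15_000,
                              read_len: int = READ_LEN,
                              cis_trans_ratio: float = 4.0,
                              refs: tuple[str, str] = ("hapA", "hapB")) -> list[tuple]:
    """Same-ref physical-coverage pairs for a paired haplotig, optional switch.

    Cis pairs never span a switch of parental origin, so coverage dips there
    on both sequences of the block; trans pairs crossing the switch still
    land on one reference (both the read's haplotype and the sequence's
    origin flip together), so the dip bottoms out near the trans rate rather
    than at zero. Returns (ref, s1, e1, ref, s2, e2) rows for both refs at
    the requested mean physical coverage.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    p_cis = cis_trans_ratio / (cis_trans_ratio + 1.0)
    segments = [(0, length)] if switch_pos is None else [(0, switch_pos),
                                                         (switch_pos, length)]

    def draw(ref, s, e, n):
        for _ in range(n):
            span = int(rng.exponential(insert_mean)) + 2 * read_len
            span = min(span, e - s)
            x = int(rng.integers(s, max(s + 1, e - span + 1)))
            pairs.append((ref, x, x + read_len, ref, x + span - read_len, x + span))

    for ref in refs:
        n_pairs = int(coverage * length / (insert_mean + 2 * read_len))
        n_cis = int(n_pairs * p_cis)
        for s, e in segments:
            draw(ref, s, e, int(n_cis * (e - s) / length))
        # half the trans pairs land same-ref; they ignore the switch entirely
        draw(ref, 0, length, int(n_pairs * (1 - p_cis) / 2))
    return pairs


def write_fixture(out_dir, length: int = 2_000_000, n_contigs: int = 4,
                  het_rate: float = 0.002, block_len_mean: int = 120_000,
                  switch_count: int = 0, pairs_n: int = 50_000,
                  cis_trans_ratio: float = 4.0, noise: bool = True,
                  seed: int = 42,
                  insert_range: tuple[int, int | None] = (1000, None)) -> dict:
    """Generate a complete fixture directory; returns stage counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = simulate_diploid(length, n_contigs, het_rate, seed)
    assembly = derive_assembly(truth, block_len_mean, switch_count, seed + 1)
    write_fasta(out / "primary.fasta", sorted(assembly.primary.items()))
    write_fasta(out / "alternate.fasta", sorted(assembly.alternate.items()))
    write_paf(out / "aln.paf", assembly.paf_records)
    write_vcf(out / "primary.vcf", assembly.primary_vcf,
              {c: len(s) for c, s in assembly.primary.items()})
    write_vcf(out / "alternate.vcf", assembly.alternate_vcf,
              {c: len(s) for c, s in assembly.alternate.items()})
    hic_stats = simulate_hic(truth, assembly, out / "hic.sam", pairs_n,
                             cis_trans_ratio, seed + 2, noise=noise,
                             insert_range=insert_range)
    write_fasta(out / "truth_hap_a.fasta", sorted(truth.hap_a.items()))
    write_fasta(out / "truth_hap_b.fasta", sorted(truth.hap_b.items()))
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_json(), fh)
    n_snps = sum(len(v) for v in truth.snps.values())
    return {"contigs": n_contigs, "planted_snps": n_snps,
            "switches": len(truth.switches), **hic_stats}
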