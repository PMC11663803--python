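"""Core domain types shared across pipeline stages.

Coordinate convention: 0-based half-open everywhere. PAF already uses it;
VCF POS is converted on read; BED output is native.
"""

from __future__ import annotations

from dataclasses import dataclass, field


COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class AlignedSegment:
    """One alternate-to-primary alignment segment (a PAF line)."""

    query_name: str
    query_start: int
    query_end: int
    strand: str  # '+' or '-'
    target_name: str
    target_start: int
    target_end: int
    aln_len: int  # number of aligned bases (PAF col 11, "alignment block length")
    mapq: int
    cigar: str | None = None  # cg:Z tag, target-centric (M/I/D/=/X)

    def __post_init__(self) -> None:
        if not self.query_start < self.query_end:
            raise ValueError(f"bad query interval {self.query_start}..{self.query_end}")
        if not self.target_start < self.target_end:
            raise ValueError(f"bad target interval {self.target_start}..{self.target_end}")
        if self.aln_len <= 0:
            raise ValueError("aln_len must be positive")
        # indel slack: the aligned block can exceed the target span but not wildly
        if self.aln_len > 2 * (self.target_end - self.target_start):
            raise ValueError("aln_len inconsistent with target span")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class Chain:
    """Result of co-linear chaining over one alternate contig's segments.

    ``segment_indices`` index into the input list sorted by target_start;
    ``score`` is the chained alignment length (sum of member lengths minus
    the inter-member gaps on the primary contig).
    """

    segment_indices: list[int]
    score: int
    predecessors: list[int]  # P(i), 1-based with 0 = chain start, parallel to input


@dataclass
class Block:
    """A minced region of a primary contig.

    ``start``/``end`` are primary-contig coordinates for every role (a hap1
    block shares the primary span of its hap2 partner; its own span on the
    alternate contig lives in ``src_start``/``src_end``).
    """

    block_id: str
    contig: str
    start: int
    end: int
    role: str  # 'hap1' | 'hap2' | 'collapsed'
    partner_id: str | None
    source: str  # alternate contig id for hap1 blocks, primary contig id otherwise
    src_start: int = -1  # span on the source sequence
    src_end: int = -1
    strand: str = "+"  # placement orientation (hap1 blocks only)
    parent_id: str | None = None  # set on sub-blocks created by switch splitting

    def __post_init__(self) -> None:
        if self.role not in ("hap1", "hap2", "collapsed"):
            raise ValueError(f"bad role {self.role!r}")
        if self.src_start < 0:
            self.src_start, self.src_end = self.start, self.end

    @property
    def length(self) -> int:
        return self.src_end - self.src_start


@dataclass
class SnpPair:
    """A heterozygous site observed on both assemblies, reciprocity-checked."""

    primary_contig: str
    x_p: int
    alt_contig: str
    x_a: int
    alt_p: str  # ALT allele called on the primary at x_p
    alt_a: str  # ALT allele called on the alternate at x_a
    retained: bool


@dataclass
class HiCAlignment:
    """One Hi-C read alignment on the minced assembly."""

    read_name: str
    mate: int  # 1 or 2
    ref: str
    start: int
    end: int
    mapq: int
    edit_distance: int  # NM tag; -1 when absent
    snp_hits: int = 0
    ref_blocks: tuple = ()  # aligned reference intervals (M runs), for SNP overlap


@dataclass
class HiCMatePair:
    read_name: str
    aln1: HiCAlignment
    aln2: HiCAlignment
    passed: bool = False


@dataclass
class CoverageProfile:
    """Binned Hi-C physical coverage along one minced sequence."""

    ref: str
    bin_size: int
    counts: "object"  # numpy int array


@dataclass
class SuspiciousInterval:
    ref: str
    start: int  # bases
    end: int
    threshold: float


@dataclass
class SwitchPoint:
    ref: str
    position: int  # bases, on the minced sequence
    support: int
    confirmed: bool = False


@dataclass
class PhaseAssignment:
    """Output of the stochastic phasing optimizer."""

    theta: dict  # unit id -> +1 / -1
    objective: float
    seed: int
    rounds: int
    flagged: list = field(default_factory=list)  # zero-contact units, ties
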