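"""Phasing metrics from haplotype-specific k-mers.

Haplotype-specific k-mers are those present in exactly one of the two truth
haplotypes. Scanning an emitted haplotype yields an ordered track of
paternal/maternal labels, from which four metrics derive:

* phased-block N50 -- blocks are runs of at least two same-label k-mers;
  an isolated single opposite k-mer stays inside a block (and counts as a
  switch error) while two consecutive opposite k-mers start a new block;
* switch error -- minority-label k-mers within phased blocks, over all
  block k-mers;
* hamming error -- min(N_pat, N_mat) / (N_pat + N_mat) per emitted
  haplotype, the minority-parent fraction;
* phasing error -- the length-weighted fraction of phased assembly blocks
  whose parental assignment contradicts the best of the two global H1/H2
  labelings, ignoring within-block switches. This definition is this
  package's documented variant of a block-level misassignment rate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed forward k-mers and their start positions (k <= 32)."""
    if k > 32:
        raise ValueError("k must be <= 32")
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    packed = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        col = codes[i:i + n]
        valid &= col >= 0
        packed = (packed << np.uint64(2)) | col.astype(np.uint64)
    return packed[valid], np.flatnonzero(valid)


def specific_kmer_sets(hap_a: dict[str, str], hap_b: dict[str, str],
                       k: int = 21) -> tuple[np.ndarray, np.ndarray]:
    """(paternal-specific, maternal-specific) sorted k-mer arrays."""
    def all_kmers(seqs):
        parts = [kmer_codes(s, k)[0] for s in seqs.values()]
        return np.unique(np.concatenate(parts)) if parts else np.empty(0, np.uint64)
    ka, kb = all_kmers(hap_a), all_kmers(hap_b)
    return np.setdiff1d(ka, kb, assume_unique=True), np.setdiff1d(kb, ka, assume_unique=True)


def label_track(seq: str, pat: np.ndarray, mat: np.ndarray,
                k: int = 21) -> tuple[np.ndarray, np.ndarray]:
    """Positions and labels (0=pat, 1=mat) of specific k-mers along a sequence."""
    kmers, pos = kmer_codes(seq, k)
    is_pat = np.isin(kmers, pat)
    is_mat = np.isin(kmers, mat)
    hit = is_pat | is_mat
    return pos[hit], np.where(is_mat[hit], 1, 0)


def phased_blocks(labels: np.ndarray, positions: np.ndarray,
                  k: int = 21) -> list[dict]:
    """Decompose a label track into phased blocks.

    A block opens at a k-mer and extends while following k-mers carry the
    block label, tolerating isolated single opposite labels (counted as
    wrong); two consecutive opposite labels close the block. Runs of fewer
    than two k-mers are not blocks.
    """
    blocks = []
    n = len(labels)
    i = 0
    while i < n:
        lab = labels[i]
        j = i + 1
        while j < n:
            if labels[j] == lab:
                j += 1
            elif j + 1 >= n or labels[j + 1] == lab:
                j += 2  # isolated flip (or trailing single): stays inside
            else:
                break
        j = min(j, n)
        size = j - i
        if size >= 2:
            wrong = int(np.sum(labels[i:j] != lab))
            blocks.append({"start": int(positions[i]), "end": int(positions[j - 1]) + k,
                           "label": "pat" if lab == 0 else "mat",
                           "kmers": size, "wrong": wrong})
        i = j
    return blocks


def n50(lengths) -> int:
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    if total == 0:
        return 0
    acc = 0
    for ln in lengths:
        acc += ln
        if 2 * acc >= total:
            return ln
    return lengths[-1]


def hamming_error(n_pat: int, n_mat: int) -> float | None:
    if n_pat + n_mat == 0:
        return None
    return min(n_pat, n_mat) / (n_pat + n_mat)


def switch_error(blocks: list[dict]) -> float | None:
    total = sum(b["kmers"] for b in blocks)
    if total == 0:
        return None
    return sum(b["wrong"] for b in blocks) / total


def phasing_error(entries: list[tuple[int, str]]) -> float | None:
    """entries: (block length, parent routed to group H1) in {'pat','mat'}.

    The assembly-level misassignment rate under the better of the two global
    labelings (H1=pat or H1=mat); invariant to a global flip.
    """
    total = sum(ln for ln, _ in entries)
    if total == 0:
        return None
    pat_h1 = sum(ln for ln, par in entries if par != "pat")
    return min(pat_h1, total - pat_h1) / total


@dataclass
class MetricsReport:
    phased_block_n50: int
    switch_error: float | None
    hamming_error_h1: float | None
    hamming_error_h2: float | None
    hamming_error: float | None  # max of the two haplotypes
    phasing_error: float | None
    n_phased_blocks: int
    n_specific_kmers: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_haplotypes(hap1: dict[str, str], hap2: dict[str, str],
                        truth_a: dict[str, str], truth_b: dict[str, str],
                        k: int = 21,
                        phasing_entries: list[tuple[int, str]] | None = None
                        ) -> MetricsReport:
    """Score two emitted haplotype FASTAs against the truth haplotypes."""
    pat, mat = specific_kmer_sets(truth_a, truth_b, k)
    all_blocks: list[dict] = []
    hams: list[float | None] = []
    n_specific = 0
    for hap in (hap1, hap2):
        n_pat = n_mat = 0
        for seq in hap.values():
            pos, labels = label_track(seq, pat, mat, k)
            n_pat += int(np.sum(labels == 0))
            n_mat += int(np.sum(labels == 1))
            all_blocks.extend(phased_blocks(labels, pos, k))
        hams.append(hamming_error(n_pat, n_mat))
        n_specific += n_pat + n_mat
    finite = [h for h in hams if h is not None]
    return MetricsReport(
        phased_block_n50=n50([b["end"] - b["start"] for b in all_blocks]),
        switch_error=switch_error(all_blocks),
        hamming_error_h1=hams[0],
        hamming_error_h2=hams[1],
        hamming_error=max(finite) if finite else None,
        phasing_error=phasing_error(phasing_entries) if phasing_entries else None,
        n_phased_blocks=len(all_blocks),
        n_specific_kmers=n_specific,
    )


def phasing_entries_from_truth(truth, blocks, theta: dict[str, int],
                               groups: dict[str, str]) -> list[tuple[int, str]]:
    """Derive (length, parent-in-H1) per phased unit from the ground truth.

    The primary span of a unit with phase +1 goes to the contig's haplotype
    1, which lands in group H1 or H2 per the contig clustering; the truth
    says which parent the primary span carries (majority by length when a
    residual switch crosses the unit).
    """
    entries = []
    tblocks = {c: truth.blocks_of(c) for c in truth.hap_a}
    for b in blocks:
        if b.role != "hap2" or b.block_id not in theta:
            continue
        # majority parental origin of the primary span
        len_a = 0
        for tb in tblocks.get(b.contig, ()):
            if tb.kind != "het":
                continue
            lo, hi = max(b.start, tb.start), min(b.end, tb.end)
            if lo >= hi:
                continue
            cut = tb.switch if tb.switch is not None else hi
            cut = min(max(cut, lo), hi)
            # before the cut the primary carries tb.origin, after it the other
            len_a += (cut - lo) if tb.origin == "A" else (hi - cut)
        origin = "pat" if len_a * 2 >= (b.end - b.start) else "mat"
        in_h1 = (theta[b.block_id] == 1) == (groups.get(b.contig, "H1") == "H1")
        parent_h1 = origin if in_h1 else ("mat" if origin == "pat" else "pat")
        entries.append((b.end - b.start, parent_h1))
    return entries
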