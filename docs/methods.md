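# Methods

This note documents the models and procedures implemented in `diphase`,
the parameters that matter, the synthetic data the test-bed generates, and
the numerical and design choices made where the problem left them open.

## Coordinates and data model

All coordinates are 0-based half-open internally. PAF is consumed natively;
VCF `POS` is converted on read; emitted BED/TSV files are 0-based half-open
(documented in their headers). A *block* is a minced region of a primary
contig with role `hap1` (the placing alternate span), `hap2` (the placed
primary span) or `collapsed`; hap1/hap2 blocks of one placement are partners
and together form a phasing *unit*. Block ids double as the sequence names
of the minced FASTA (`contig:start-end`, `alt:qstart-qend`), so every
downstream file refers to sequences by id.

## Placement and mincing

Alignment segments of one alternate contig on one primary contig are sorted
by target start and chained by the dynamic program

    f(i) = max( max_{i>j>=1} { f(j) + |S_i| - gap(j, i) },  |S_i| )

where `|S_i|` is the aligned length and `gap(j, i)` the distance on the
primary contig between segment ends, clamped to 0 when segments overlap.
Ties in the predecessor argmax prefer the smallest index, making
backtracking deterministic. Gaps are measured on the primary axis only.
Containment filtering precedes chaining; among byte-identical records the
first in sort order is kept.

Open choices resolved here:

* **Overlapping placements** from different alternate contigs are resolved
  by truncating the later-starting placement at the earlier one's end (the
  query span is trimmed by the same number of bases); this preserves the
  tiling invariant — hap2 + collapsed blocks of a contig exactly partition
  `[0, L)`.
* **Minimum block length** (`--min-block-len`, default 1000 bases):
  shorter placement residues fall back to collapsed sequence, avoiding
  degenerate phasing units.
* Reverse-strand placements keep the alternate contig's own orientation in
  the minced FASTA; orientation is restored at emission.

## Reciprocal SNP validation

SNPs are called independently on the two assemblies. Over a placed block
the assemblies carry opposite haplotypes, so a true heterozygous site
appears twice with swapped alleles. With `B_p`/`B_a` the bases and
`ALT_p`/`ALT_a` the called alternate alleles at mapped positions
`x_p`/`x_a`, a site is retained iff `ALT_p = B_a` and `ALT_a = B_p`
(alleles compared in primary orientation; reverse-strand placements
complement the alternate-side alleles). Genotype fields are ignored — the
reciprocity condition alone decides. Multiallelic records are split and
each allele tested independently; sites outside any placement (collapsed
regions) are discarded and counted.

## Hi-C mate-pair filter

After dropping records with SAM flags 0x4/0x8/0x100/0x800 (mask 2316) and
discarding read names without exactly one surviving record per mate, an
alignment passes iff

    (MAPQ > q  and  NM < e)   or   snp_hits >= 1

with strict inequalities and defaults `q = 10`, `e = 5`. `snp_hits` counts
retained SNP positions under aligned (M) reference columns — a SNP inside a
deletion or beyond a clip is not covered, and the read base need not match
an allele (an allele-match mode exists behind `--require-allele-match`).
Records lacking an NM tag fail the quality clause but can still pass via a
SNP. A pair survives iff both mates pass. With an empty SNP set the filter
reduces exactly to the MAPQ/edit-distance baseline. Duplicate pairs are not
removed by default (`--dedup` enables coordinate-identical deduplication).

## Switch detection

Physical coverage of a mate-pair is the span from the leftmost fragment
start to the rightmost fragment end; only pairs with both mates on the same
minced sequence contribute, binned at `bin_size` (default 1000 bases,
`counts` length `ceil(L / bin_size)`). Because cis contacts dominate, a
within-block switch of parental origin starves its neighbourhood of
same-reference pairs and coverage dips; the floor of the dip is set by
trans pairs (which cross a switch freely on one reference), roughly the
trans share of the cis rate — not zero.

Detection per reference:

1. **Cutoff ladder**: 10%–90% of the median non-zero bin coverage (the
   absolute cutoffs are data-dependent by design).
2. **Suspicious intervals**: per cutoff, the longest run of bins below it
   (leftmost on ties).
3. **End margins**: coverage ramps up over about one pair span from each
   sequence end, so the first/last `10 + ceil(q90(spans)/bin_size)` bins
   are excluded; references too short to leave 10 interior bins are
   skipped. A fixed small margin proved insufficient — the ramp mimics a
   dip and, worse, does so at the *corresponding* position on the partner
   sequence.
4. **Stabbing**: the position covered by the most intervals is found by an
   endpoint sweep; support must reach `min_support` (default: half the
   cutoffs, rounded up), and coverage within ±2 bins of the called point
   must fall below half the median (a loose sanity bound on dip depth).
5. **Cross-haplotype confirmation**: a candidate is confirmed only if the
   partner block has a candidate at the corresponding coordinate (mirrored
   for reverse-strand placements) within 5 kb. Requiring positional
   correspondence, not mere partner candidacy, is what drives the false
   positive rate to zero in the no-switch simulations: independent noise
   dips on the two sequences almost never align.

Confirmed switches split both blocks into paired sub-blocks (left-left for
forward placements, mirrored for reverse); one switch per reference per
pass; sub-blocks record their parent so a later same-phase decision can
undo the split. Short intra-block switches below bin resolution are out of
scope.

## Phasing

For units *a, b* with sequence sides (hap1, hap2), four contact counts
`w_ab, w_ab', w_a'b, w_a'b'` are tallied from the filtered pairs; a mate is
assigned to the sub-block containing its alignment start, pairs touching
collapsed sequence or falling within a single unit are excluded. The phase
vector maximizes

    f(theta) = sum_{a,b} theta_a theta_b (w_ab + w_a'b' - w_a'b - w_ab')

which is invariant under a global sign flip. The optimizer is a seeded
multi-restart greedy flip search: random ±1 start, accept any
single-unit flip with positive gain (computed incrementally from the unit's
incident net weights) until a local optimum, keep the best across restarts
(default 100; instances of ≤ 24 units exhaust the budget — a single greedy
descent can fail with sizable probability, which repetition drives to
zero — larger ones stop after 10 stale restarts). The returned vector is
canonicalized to `theta[first unit] = +1`, making results deterministic
given (contacts, seed). Units with no informative contacts are assigned +1
and flagged.

Blocks are grouped per primary contig and each group is phased with **all**
contacts inside it. Switch splits whose sub-blocks share a phase are merged
back and the switch dismissed. Contig-level clustering then aggregates
contacts between the per-contig haplotypes (side 0 = the sequences theta
routed to the contig's haplotype 1) and runs the same optimizer with
contigs as units; `theta_c = +1` puts the contig's haplotype 1 in group H1.
Contigs without cross-contig contacts are flagged "unanchored".

## Haplotype emission

`theta = +1` sends the unit's primary span to the contig's haplotype 1 and
the partner alternate span to haplotype 2; collapsed spans are copied into
both. Segments are butt-joined in primary-coordinate order (the tiling is
contiguous); reverse-strand alternate spans are reverse-complemented so all
output reads in primary orientation. Alternate spans may differ in length
from their primary partner, so the two haplotypes of a contig may differ in
length — accepted, no padding. Total output obeys
`|H1| + |H2| = Σ hap1 + Σ hap2 + 2 Σ collapsed` exactly. FASTA headers are
`{contig}_h{1|2} group={H1|H2}`, 80-column wrapped, grouped into
`hap1.final.fasta`/`hap2.final.fasta` by the contig clustering.

## Evaluation metrics

Haplotype-specific k-mers (default `k = 21`, 2-bit packed, forward strand —
all sequences are emitted in primary orientation) are those occurring in
exactly one truth haplotype. Scanning an emitted haplotype yields an
ordered label track, from which:

* **Phased blocks**: runs of ≥ 2 same-label k-mers; an isolated single
  opposite k-mer stays inside the block (and is counted wrong), two
  consecutive opposite k-mers close it. Block span runs from its first
  k-mer start to its last k-mer end. N50 is the length covering half the
  total phased length.
* **Switch error** = wrong k-mers / total k-mers over phased blocks.
* **Hamming error** = `min(N_pat, N_mat) / (N_pat + N_mat)` per emitted
  haplotype (bounded by 0.5); the report also carries the max over the two.
* **Phasing error** (this package's documented variant): each phased unit
  is assigned the parent its H1-routed sequence carries (majority by
  length if a residual switch crosses it); the error is the length-weighted
  fraction contradicting the better of the two global H1/H2 labelings —
  block-level misassignment ignoring within-block switches.

K-mer labels come from the simulator's truth haplotypes, standing in for
parental-read k-mer databases.

## The synthetic test-bed

`simulate` builds, from (parameters, seed) only:

* a diploid genome (haplotype B = haplotype A with Bernoulli(`het_rate`)
  substitutions; default 0.002, the order of human heterozygosity; no
  indels);
* an assembly: contigs are cut into blocks around `block_len_mean`
  (uniform 0.6–1.4×); each block is collapsed with probability 0.3 (its
  het sites are erased — the assembler merged the haplotypes there),
  otherwise the primary carries a random parental origin and an alternate
  contig the other; 25% of alternates are stored reverse-complemented and
  30% of placements are emitted as two abutting PAF segments to exercise
  chaining; injected switches flip the origin mid-block on both sequences
  and are recorded;
* SNP VCFs with the correct reciprocal alleles, and a PAF with exact
  CIGARs;
* Hi-C alignments synthesized directly as SAM records against the minced
  assembly (the pipeline never needs raw reads, so no aligner is
  involved): each pair picks a contig (length-weighted) and a parental
  haplotype, is cis with probability `r/(r+1)` (default ratio 4), and its
  mates sit a log-uniform distance apart, from 1 kb up to the contig
  length — emulating the power-law decay of chromatin contact probability
  while keeping support across the whole contig. An earlier bounded-uniform
  insert model left long-range blocks without intra-contig contacts, which
  no real Hi-C library does. 15% of pairs join two contigs, carrying the
  haplotype signal that anchors contig clustering. MAPQ is drawn from
  {0: 10%, 5: 10%, 20: 20%, 60: 60%} and NM from Poisson(2) when noise is
  on; with `--no-noise` every record passes the default quality filter.

What the simulator does **not** model: restriction-site placement,
read-level sequence errors, indel heterozygosity, chimeric pairs, mapping
ambiguity between the two haplotype sequences of a block (reads are placed
on the correct side by construction; in real data low-MAPQ cross-placement
is exactly what the SNP rescue addresses). Passing tests therefore
demonstrate the correctness of the algorithms under the stated generative
assumptions, not the calibration of thresholds to any particular library
preparation.

A separate light-weight generator (`simulate_switch_replicate`) produces
same-reference physical-coverage pairs for one block pair with an optional
switch — cis pairs never cross it, trans pairs (half of which stay on one
reference) do — at a requested mean physical coverage, for the switch
detector's sensitivity/specificity studies.

## Problem sizes and defaults in the checks

The acceptance script and test suite run, per invocation: 200 random
chaining instances of ≤ 8 segments against exhaustive enumeration; the
12-pair filter truth table; 100 contact matrices of 3–12 units against the
2^n optimum; 100 planted-phase recoveries at 20 units with Poisson(30) cis
and Poisson(7.5) trans contacts; 100 + 100 switch replicates on 1 Mb block
pairs at 35× physical coverage with the switch at least 150 kb from the
ends; and one noise-free 2 Mb, 4-contig end-to-end run (50 000 pairs) that
must reach zero hamming/switch/phasing error, exact base conservation, and
byte-identical outputs across repeated runs. These sizes keep each check
well under a few minutes while leaving the statistical margins comfortable
(the observed switch-detection rate is 96–99% against a 90% bar, with zero
false positives in 900 held-out replicates).

## Known limitations

* One switch per block per detection pass; no iterative re-detection after
  splitting.
* Switches closer than about one pair span to a block end are masked by
  the coverage ramp and cannot be detected.
* The phasing objective treats contact counts as independent evidence; no
  distance normalization is applied to the contact matrix.
* Collapsed sequence is copied verbatim into both haplotypes; junction
  overlaps between alternate spans and flanking collapsed sequence are not
  trimmed (butt-joining).
* The evaluator's phasing-error definition is this package's variant;
  other tools define block-level error differently.
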