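"""FASTA reading/writing helpers (plain sequences, 80-column output)."""

from __future__ import annotations

from Bio import SeqIO


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records, width: int = 80) -> None:
    """records: iterable of (header, sequence); header may carry a description."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
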