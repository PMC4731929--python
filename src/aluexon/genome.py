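"""Random-access genome sequence with strand-aware fetches."""

from __future__ import annotations

from typing import Mapping

from Bio.Seq import reverse_complement


class GenomeSequence:
    """Chromosome name -> nucleotide string, with 0-based half-open fetch.

    Minus-strand fetches return the reverse complement, so a fetch in
    transcript sense can be expressed directly. Backed either by an
    in-memory dict or by an indexed FASTA (pyfaidx).
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = sequences

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        import pyfaidx

        return cls(pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True))

    def chromosomes(self) -> list[str]:
        return list(self._seqs.keys())

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= start <= end <= len(self._seqs[chrom])):
            raise ValueError(f"interval [{start}, {end}) out of bounds on {chrom}")
        seq = str(self._seqs[chrom][start:end]).upper()
        if strand == "-":
            return reverse_complement(seq)
        if strand != "+":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        return seq
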