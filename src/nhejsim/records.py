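"""Minimal DNA record container with circular-topology support.

Biopython's :class:`~Bio.SeqRecord.SeqRecord` is used at the I/O boundary
(FASTA/GenBank); internally sequences are plain upper-case strings over
{A,C,G,T} so that modular arithmetic on circular plasmids stays explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_matches(pattern: str, text: str) -> bool:
    """Exact-length IUPAC pattern match."""
    if len(pattern) != len(text):
        return False
    return all(t in IUPAC[p] for p, t in zip(pattern, text))


@dataclass
class DnaRecord:
    """A named DNA sequence, optionally circular.

    Coordinates are 0-based, half-open, on the top strand; circular records
    use coordinates modulo ``len(seq)``.
    """

    id: str
    seq: str
    circular: bool = False
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError("empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end); wraps across the origin when circular."""
        n = len(self.seq)
        if not self.circular:
            if start < 0 or end > n or start > end:
                raise IndexError(f"[{start}, {end}) outside linear record of length {n}")
            return self.seq[start:end]
        return fetch_circular(self.seq, start, end - start)

    def rotate(self, offset: int) -> "DnaRecord":
        """Rotate a circular record so position ``offset`` becomes position 0."""
        if not self.circular:
            raise ValueError("cannot rotate a linear record")
        off = offset % len(self.seq)
        return DnaRecord(self.id, self.seq[off:] + self.seq[:off], circular=True,
                         annotations=dict(self.annotations))

    def to_seqrecord(self) -> SeqRecord:
        rec = SeqRecord(Seq(self.seq), id=self.id, description="")
        rec.annotations["topology"] = "circular" if self.circular else "linear"
        rec.annotations["molecule_type"] = "DNA"
        return rec

    @classmethod
    def from_seqrecord(cls, rec: SeqRecord) -> "DnaRecord":
        return cls(rec.id, str(rec.seq),
                   circular=rec.annotations.get("topology") == "circular")


def fetch_circular(seq: str, start: int, length: int) -> str:
    """Return ``length`` bases starting at ``start`` with wrap-around."""
    n = len(seq)
    if length > n:
        raise IndexError("span longer than record")
    start %= n
    end = start + length
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n]


def write_fasta(records, path) -> None:
    from Bio import SeqIO

    SeqIO.write([r.to_seqrecord() for r in records], path, "fasta")


def read_fasta(path) -> list[DnaRecord]:
    from Bio import SeqIO

    return [DnaRecord.from_seqrecord(r) for r in SeqIO.parse(path, "fasta")]
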