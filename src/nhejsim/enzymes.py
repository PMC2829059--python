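"""Restriction digestion, end structures, and ligation primitives.

Conventions
-----------
Coordinates are 0-based, half-open, on the top strand.  A cut is described
by two offsets into the recognition site: ``cut_top`` (where the top strand
is severed) and ``cut_bottom`` (where the bottom strand is severed, in
top-strand coordinates).  ``cut_top < cut_bottom`` yields a 5' overhang,
``cut_top > cut_bottom`` a 3' overhang, equality a blunt cut.

A :class:`LinearFragment` stores the full top strand of the duplex,
including single-stranded overhang regions, so that the total top-strand
content of a digest always equals the parent length and ligation is plain
concatenation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

from .records import DnaRecord, IUPAC, fetch_circular, revcomp


class ZeroSitesWarning(UserWarning):
    """Digestion requested but the enzyme has no site in the record."""


class LigationError(ValueError):
    """Ends presented for ligation are not compatible."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition: str  # IUPAC, top strand
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        if not (0 <= self.cut_top <= len(self.recognition)):
            raise ValueError("cut_top outside recognition site")
        if not (0 <= self.cut_bottom <= len(self.recognition)):
            raise ValueError("cut_bottom outside recognition site")

    @property
    def overhang_length(self) -> int:
        return abs(self.cut_top - self.cut_bottom)

    @property
    def overhang_kind(self) -> str:
        if self.cut_top < self.cut_bottom:
            return "five_prime_overhang"
        if self.cut_top > self.cut_bottom:
            return "three_prime_overhang"
        return "blunt"

    @property
    def palindromic(self) -> bool:
        return revcomp(self.recognition) == self.recognition


@dataclass(frozen=True)
class EndStructure:
    """One end of a linear duplex."""

    kind: str  # blunt | five_prime_overhang | three_prime_overhang
    overhang_seq: str  # 5'->3' on the protruding strand; empty iff blunt
    flank_ref_pos: int  # top-strand cut coordinate on the parent record

    def __post_init__(self) -> None:
        if (self.kind == "blunt") != (self.overhang_seq == ""):
            raise ValueError("overhang_seq must be empty iff blunt")


BLUNT_LEFT = EndStructure("blunt", "", 0)


@dataclass
class LinearFragment:
    """A digested molecule: full top strand plus end descriptions."""

    seq: str
    left_end: EndStructure
    right_end: EndStructure
    ref_id: str = ""
    ref_interval: tuple[int, int] = (0, 0)

    def __len__(self) -> int:
        return len(self.seq)


# --- site search -----------------------------------------------------------


def _iupac_hit(seq: str, pos: int, pattern: str) -> bool:
    return all(seq[pos + i] in IUPAC[p] for i, p in enumerate(pattern))


def find_sites(record: DnaRecord, enzyme: RestrictionEnzyme) -> list[tuple[int, str]]:
    """All recognition-site matches as ``(top-strand start, strand)``.

    Circular records are scanned across the origin.  Palindromic sites are
    reported once, on the plus strand.
    """
    seq = record.seq
    n = len(seq)
    pat_fwd = enzyme.recognition
    pat_rev = revcomp(pat_fwd)
    L = len(pat_fwd)
    scan = seq + seq[: L - 1] if record.circular else seq
    limit = n if record.circular else n - L + 1
    hits: list[tuple[int, str]] = []
    for p in range(max(limit, 0)):
        if _iupac_hit(scan, p, pat_fwd):
            hits.append((p, "+"))
        if not enzyme.palindromic and _iupac_hit(scan, p, pat_rev):
            hits.append((p, "-"))
    return hits


def _cut_coords(pos: int, strand: str, enzyme: RestrictionEnzyme, n: int) -> tuple[int, int]:
    """(top, bottom) scission coordinates for a site at ``pos``/``strand``."""
    L = len(enzyme.recognition)
    if strand == "+":
        t, b = pos + enzyme.cut_top, pos + enzyme.cut_bottom
    else:
        t, b = pos + L - enzyme.cut_bottom, pos + L - enzyme.cut_top
    return t % n, b % n


def digest(record: DnaRecord, enzyme: RestrictionEnzyme):
    """Cut ``record`` at every site of ``enzyme``.

    Circular records with k sites yield k fragments; linear records yield
    k+1.  With zero sites the record is returned unchanged, with a
    :class:`ZeroSitesWarning`.
    """
    sites = find_sites(record, enzyme)
    if not sites:
        warnings.warn(f"{enzyme.name} has no site in {record.id}", ZeroSitesWarning)
        return record

    n = len(record.seq)
    cuts = sorted(_cut_coords(p, s, enzyme, n) for p, s in sites)

    def _make_fragment(c1, c2, span):
        t1, b1 = c1
        t2, b2 = c2
        top = fetch_circular(record.seq, t1, span) if record.circular else record.seq[t1:t2]
        left = _left_end(record, t1, b1)
        right = _right_end(record, t2, b2)
        return LinearFragment(top, left, right, ref_id=record.id, ref_interval=(t1, t2))

    frags = []
    if record.circular:
        for i, c1 in enumerate(cuts):
            c2 = cuts[(i + 1) % len(cuts)]
            span = (c2[0] - c1[0]) % n or n
            frags.append(_make_fragment(c1, c2, span))
    else:
        bounds = [(0, 0)] + cuts + [(n, n)]
        for c1, c2 in zip(bounds[:-1], bounds[1:]):
            frags.append(_make_fragment(c1, c2, c2[0] - c1[0]))
    return frags


def _signed_stagger(t: int, b: int, record: DnaRecord) -> int:
    """b - t, taking the nearest circular representative (staggers are short)."""
    if not record.circular:
        return b - t
    n = len(record.seq)
    return ((b - t + n // 2) % n) - n // 2


def _left_end(record: DnaRecord, t: int, b: int) -> EndStructure:
    d = _signed_stagger(t, b, record)
    if d == 0:
        return EndStructure("blunt", "", t)
    if d > 0:
        # top cut left of bottom cut: fragment top starts at t, bottom at b;
        # the top strand protrudes over [t, b) -- a 5' overhang.
        return EndStructure("five_prime_overhang", fetch_circular(record.seq, t, d), t)
    # bottom cut left of top cut: the bottom strand protrudes over [b, t)
    # terminating in its 3' end -- a 3' overhang.
    return EndStructure("three_prime_overhang", revcomp(fetch_circular(record.seq, b, -d)), t)


def _right_end(record: DnaRecord, t: int, b: int) -> EndStructure:
    d = _signed_stagger(t, b, record)
    if d == 0:
        return EndStructure("blunt", "", t)
    if d > 0:
        # bottom strand protrudes over [t, b) ending at its 5' terminus.
        return EndStructure("five_prime_overhang", revcomp(fetch_circular(record.seq, t, d)), t)
    # top strand protrudes over [b, t) ending at its 3' terminus.
    return EndStructure("three_prime_overhang", fetch_circular(record.seq, b, -d), t)


# --- compatibility & ligation ---------------------------------------------


def ends_compatible(a: EndStructure, b: EndStructure) -> bool:
    """True iff the two ends can anneal and seal without processing."""
    if a.kind == "blunt" and b.kind == "blunt":
        return True
    if a.kind != b.kind or len(a.overhang_seq) != len(b.overhang_seq):
        return False
    return a.overhang_seq == revcomp(b.overhang_seq)


def ligate(a: LinearFragment, b: LinearFragment | None = None, product_id: str = "ligation") -> DnaRecord:
    """Circularize one fragment, or join two fragments into a circle.

    Cohesive junctions write the annealed overhang once, so the product
    length is the sum of the fragments' top-strand lengths.
    """
    if b is None:
        if not ends_compatible(a.right_end, a.left_end):
            raise LigationError("fragment ends are not compatible for self-circularization")
        return DnaRecord(product_id, a.seq, circular=True)
    if not (ends_compatible(a.right_end, b.left_end) and ends_compatible(b.right_end, a.left_end)):
        raise LigationError("fragment ends are not compatible")
    return DnaRecord(product_id, a.seq + b.seq, circular=True)


# --- enzyme registry -------------------------------------------------------


def _load_registry() -> dict[str, RestrictionEnzyme]:
    table = resources.files("nhejsim.data").joinpath("enzymes.tsv").read_text()
    registry = {}
    for line in table.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, recog, ct, cb = line.split("\t")
        registry[name] = RestrictionEnzyme(name, recog, int(ct), int(cb))
    return registry


_REGISTRY: dict[str, RestrictionEnzyme] | None = None


def get_enzyme(name: str) -> RestrictionEnzyme:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return _REGISTRY[name]
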