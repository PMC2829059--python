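"""Emulation of the three readouts used to score repair.

* re-digestion: a repaired cohesive-substrate plasmid is cut with the
  linearizing enzyme; reconstruction of exactly one site at the junction
  (and an otherwise unaltered sequence) scores a perfect join.
* GFP/FACS: a product is GFP-positive when exact donor-to-acceptor
  splicing removes the internal exon and leaves the reconstituted GFP
  reading frame intact; the percent repair is the double-positive over
  red-positive cell ratio in a simulated co-transfection.
* microhomology diagnostic: PCR across the junction of the direct-repeat
  substrate followed by BstXI digestion; junctions that collapsed the
  terminal repeats to one copy carry the diagnostic site and cleave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enzymes import RestrictionEnzyme, digest, find_sites, get_enzyme, ZeroSitesWarning
from .records import DnaRecord, revcomp
from .reporter import ReporterLayout, RepeatReporterLayout

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class FacsModel:
    transfection_prob: float = 0.3  # per-cell productive co-transfection
    cells: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.transfection_prob <= 1.0:
            raise ValueError("transfection_prob must be in [0, 1]")


@dataclass
class AssayResult:
    assay: str
    per_product: list
    summary: float


# --- re-digestion perfect-join test ---------------------------------------


def redigest_perfect_join(product: DnaRecord, enzyme: RestrictionEnzyme,
                          perfect_reference: DnaRecord):
    """Score a repaired plasmid by re-digestion.

    ``perfect_reference`` is the designed perfect-religation circle.  Returns
    ``(is_perfect, fragment_sizes)``; perfect means the junction restored a
    single recognition site and the sequence is the designed one.
    """
    if not product.circular:
        raise ValueError("re-digestion test expects a circular product")
    sites = find_sites(product, enzyme)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ZeroSitesWarning)
        frags = digest(product, enzyme)
    sizes = sorted(len(f) for f in frags) if isinstance(frags, list) else []
    is_perfect = (
        len(sites) == 1
        and len(product.seq) == len(perfect_reference.seq)
        and product.seq in perfect_reference.seq + perfect_reference.seq
    )
    return is_perfect, sizes


# --- splicing / GFP prediction --------------------------------------------


def splice_predict_gfp(product: DnaRecord, reference: DnaRecord,
                       layout: ReporterLayout) -> bool:
    """Predict GFP expression of a repaired reporter plasmid.

    Positive iff both GFP exons, the splice donor and the splice acceptor are
    intact, the internal (Ad2) exon is gone from the message, and exact
    donor-to-acceptor excision leaves an uninterrupted reading frame.  The
    intron buffers junction scars: any deletion or insertion strictly between
    donor and acceptor leaves the prediction positive.
    """
    seq = product.seq
    if not product.circular:
        return False
    doubled = seq + seq
    exon1 = layout.feature_seq(reference, "gfp_exon1")
    exon2 = layout.feature_seq(reference, "gfp_exon2")
    sd = layout.feature_seq(reference, "splice_donor")
    sa = layout.feature_seq(reference, "splice_acceptor")
    ad2 = layout.feature_seq(reference, "ad2_exon")

    i1 = doubled.find(exon1 + sd)
    if i1 < 0 or i1 >= len(seq):
        return False
    i2 = doubled.find(sa + exon2, i1)
    if i2 < 0:
        return False
    if ad2 in doubled:
        return False
    message = exon1 + exon2  # exact donor->acceptor excision
    if len(message) % 3 or not message.startswith("ATG"):
        return False
    if any(message[i : i + 3] in STOP_CODONS for i in range(3, len(message) - 3, 3)):
        return False
    return message[-3:] in STOP_CODONS


# --- FACS ------------------------------------------------------------------


def facs_readout(gfp_calls: list[bool], facs_model: FacsModel) -> float:
    """Percent repair from a simulated co-transfection.

    Each cell is productively co-transfected (red) with probability
    ``transfection_prob``; a red cell receives one repair event drawn from
    the cohort and is green iff that event produced a GFP-positive circle.
    Returns 100 * double-positive / red-positive.
    """
    if not gfp_calls:
        raise ValueError("no events supplied")
    rng = np.random.default_rng(facs_model.seed)
    red = rng.random(facs_model.cells) < facs_model.transfection_prob
    n_red = int(red.sum())
    if n_red == 0:
        raise ZeroDivisionError("no productively transfected cells")
    events = rng.integers(0, len(gfp_calls), size=n_red)
    green = np.asarray(gfp_calls, dtype=bool)[events]
    return 100.0 * float(green.sum()) / n_red


def cohort_gfp_calls(cohort, reference: DnaRecord, layout: ReporterLayout) -> list[bool]:
    """One GFP call per attempted event (unrepaired events are negative)."""
    calls = [splice_predict_gfp(p.seq, reference, layout) for p in cohort.products]
    calls.extend([False] * cohort.n_unrepaired)
    return calls


# --- PCR + BstXI microhomology assay --------------------------------------


def pcr_amplify(product: DnaRecord, fragment_seq: str,
                layout: RepeatReporterLayout) -> str | None:
    """Amplicon across the repair junction of a direct-repeat product.

    Returns the top-strand amplicon between the forward-primer start and the
    reverse-primer end, or None when a primer site was destroyed by the
    junction.  Multiple matches of either primer raise ValueError.
    """
    if not product.circular:
        raise ValueError("expected a circular repaired product")
    fwd = layout.primer_fwd_seq(fragment_seq)
    rev_site = fragment_seq[layout.primer_rev[0] : layout.primer_rev[1]]
    seq = product.seq
    doubled = seq + seq[: max(len(fwd), len(rev_site)) - 1]

    def _unique(probe: str) -> int | None:
        first = doubled.find(probe)
        if first < 0 or first >= len(seq):
            return None
        if doubled.find(probe, first + 1) != -1 and doubled.find(probe, first + 1) < len(seq):
            raise ValueError(f"primer matches more than once: {probe[:8]}...")
        if revcomp(probe) in doubled[: len(seq) + len(probe) - 1]:
            raise ValueError("primer also matches the opposite strand")
        return first

    i_fwd = _unique(fwd)
    i_rev = _unique(rev_site)
    if i_fwd is None or i_rev is None:
        return None
    span = (i_rev + len(rev_site) - i_fwd) % len(seq)
    if span == 0 or span > len(seq):
        return None
    from .records import fetch_circular

    return fetch_circular(seq, i_fwd, span)


def bstxi_fraction(amplicons: list[str]):
    """Fraction of amplicons cleaved by BstXI, with fragment-size sets.

    Cleavage of the junction amplicon is the diagnostic of a
    repeat-collapse (microhomology-mediated) junction.
    """
    if not amplicons:
        raise ValueError("no amplicons supplied")
    bstx = get_enzyme("BstXI")
    cut, size_sets = 0, []
    for amp in amplicons:
        rec = DnaRecord("amplicon", amp, circular=False)
        sites = find_sites(rec, bstx)
        if sites:
            cut += 1
            cuts = sorted((p + bstx.cut_top) if s == "+" else
                          (p + len(bstx.recognition) - bstx.cut_bottom)
                          for p, s in sites)
            bounds = [0] + cuts + [len(amp)]
            size_sets.append(tuple(b - a for a, b in zip(bounds[:-1], bounds[1:])))
        else:
            size_sets.append((len(amp),))
    return cut / len(amplicons), size_sets
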