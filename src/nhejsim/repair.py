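"""Stochastic repair of a linearized substrate under a genotype profile.

Pathway choice follows the Ku end-access competition model: Ku and the
alternative-pathway machinery race for the fresh ends; Ku occupancy commits
the break to classic NHEJ (C-NHEJ), which joins with minimal processing.
Unoccupied ends are channeled to alternative NHEJ (A-NHEJ): both ends are
resected 5'->3', the exposed 3' single-strand tails anneal at a short
direct repeat (microhomology), and the intervening sequence plus one repeat
copy is lost.

A-NHEJ is modeled commit-then-anneal: each end draws a committed resection
extent from a geometric distribution (mean ``resection_mean``, resampled
above ``resection_max``), and annealing uses the best microhomology whose
copies lie within ``mh_window`` nt of the two stall points.  This makes the
junction deletion track the resection extent, which is what lets the
summarizer recover the resection scale from deletion spectra.

RNG contract: one seeded generator per cohort; per attempt the draws are
consumed in a fixed order (pathway-choice uniform(s), then the join's
draws), so identical (profile, substrate, n, seed) replays byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .enzymes import LinearFragment, ends_compatible
from .profiles import GenotypeProfile
from .records import DnaRecord, revcomp

PATHWAY_CNHEJ = "C-NHEJ"
PATHWAY_ANHEJ = "A-NHEJ"
UNREPAIRED = "unrepaired"

_BASES = ("A", "C", "G", "T")


@dataclass
class RepairTruth:
    """Ground-truth bookkeeping for one repair event."""

    pathway: str
    direct: bool = False            # untouched cohesive religation
    left_del: int = 0               # nt removed from the left break side
    right_del: int = 0              # nt removed from the right break side
    mh_len: int = 0
    mh_seq: str = ""
    insertion: str = ""
    resect_left: int = 0            # committed resection draws (A-NHEJ)
    resect_right: int = 0
    left_op: str = ""               # C-NHEJ overhang handling: fill | trim
    right_op: str = ""

    @property
    def deletion_total(self) -> int:
        return self.left_del + self.right_del

    @property
    def resect_left_used(self) -> int:
        """Resection consumed on the left: through the far edge of the left MH copy."""
        return self.left_del

    @property
    def resect_right_used(self) -> int:
        """Resection consumed on the right: through the near edge of the right MH copy."""
        return self.right_del + self.mh_len

    def check_identity(self) -> bool:
        """A-NHEJ bookkeeping: deletion = used resections minus the retained repeat."""
        if self.pathway != PATHWAY_ANHEJ:
            return True
        ok = self.deletion_total == self.resect_left_used + self.resect_right_used - self.mh_len
        return ok and self.left_del >= self.mh_len and self.mh_len >= 1


@dataclass
class RepairedProduct:
    seq: DnaRecord                  # circular repaired plasmid
    pathway_label: str
    truth: RepairTruth


@dataclass
class Cohort:
    profile: GenotypeProfile
    substrate_id: str
    n_attempted: int
    products: list[RepairedProduct] = field(default_factory=list)
    n_unrepaired: int = 0

    @property
    def repaired_fraction(self) -> float:
        return len(self.products) / self.n_attempted


def choose_pathway(profile: GenotypeProfile, rng: np.random.Generator) -> str:
    """One break's fate under the end-access competition model."""
    denom = profile.ku_affinity * profile.ku_level + profile.anhej_level
    if denom == 0:
        return UNREPAIRED
    if rng.random() < profile.capture_prob:
        if profile.cnhej_capacity:
            return PATHWAY_CNHEJ
        return PATHWAY_ANHEJ if rng.random() < profile.leak_prob else UNREPAIRED
    return PATHWAY_ANHEJ


# --- classic NHEJ ----------------------------------------------------------


def _blunt_left(fragment: LinearFragment, op: str, seq: str) -> str:
    end = fragment.left_end
    if end.kind == "blunt":
        return seq
    ov = len(end.overhang_seq)
    if end.kind == "five_prime_overhang":
        # protruding top bases are in seq: fill keeps them, trim removes them
        return seq if op == "fill" else seq[ov:]
    # 3' overhang: protruding bottom bases are not in seq; fill restores the
    # parental top strand over them, trim chews them away
    return (revcomp(end.overhang_seq) + seq) if op == "fill" else seq


def _blunt_right(fragment: LinearFragment, op: str, seq: str) -> str:
    end = fragment.right_end
    if end.kind == "blunt":
        return seq
    ov = len(end.overhang_seq)
    if end.kind == "five_prime_overhang":
        return (seq + revcomp(end.overhang_seq)) if op == "fill" else seq
    return seq if op == "fill" else seq[:-ov]


def cnhej_join(fragment: LinearFragment, profile: GenotypeProfile,
               rng: np.random.Generator, product_id: str = "cnhej") -> RepairedProduct:
    """Classic-NHEJ joining: direct religation when possible, else limited
    end processing (fill-in or trim per overhang, small trims, optional
    small insert) followed by blunt sealing."""
    cohesive = ends_compatible(fragment.right_end, fragment.left_end)
    if cohesive and rng.random() < profile.cnhej_direct_prob:
        mh = fragment.left_end.overhang_seq
        truth = RepairTruth(PATHWAY_CNHEJ, direct=True, mh_len=len(mh), mh_seq=mh)
        return RepairedProduct(DnaRecord(product_id, fragment.seq, circular=True),
                               PATHWAY_CNHEJ, truth)

    left_op = "fill" if rng.random() < 0.5 else "trim"
    right_op = "fill" if rng.random() < 0.5 else "trim"
    seq = _blunt_left(fragment, left_op, fragment.seq)
    seq = _blunt_right(fragment, right_op, seq)

    cap = profile.small_indel_max
    d_l = int(rng.integers(0, cap + 1)) if cap else 0
    d_r = int(rng.integers(0, cap + 1)) if cap else 0
    ins = ""
    if cap and rng.random() < profile.insert_prob:
        ins = "".join(rng.choice(_BASES, size=int(rng.integers(1, cap + 1))))
    if d_l:
        seq = seq[d_l:]
    if d_r:
        seq = seq[:-d_r]
    truth = RepairTruth(PATHWAY_CNHEJ, left_del=d_l, right_del=d_r,
                        insertion=ins, left_op=left_op, right_op=right_op)
    return RepairedProduct(DnaRecord(product_id, seq + ins, circular=True),
                           PATHWAY_CNHEJ, truth)


# --- alternative NHEJ ------------------------------------------------------


def _sample_resection(profile: GenotypeProfile, rng: np.random.Generator, limit: int) -> int:
    cap = min(profile.resection_max, limit)
    for _ in range(1000):
        r = int(rng.geometric(1.0 / profile.resection_mean))
        if r <= cap:
            return r
    return cap


def _find_anneal(seq: str, r_l: int, r_r: int, profile: GenotypeProfile):
    """Best microhomology pair near the two resection stall points.

    Candidates are direct repeats with the left copy ending within
    ``mh_window`` nt of r_l and the right copy starting within ``mh_window``
    nt of len(seq)-r_r.  Selection: minimal total deletion, ties broken by
    longer microhomology, then leftmost left copy.
    """
    F = len(seq)
    w = profile.mh_window
    k_min = profile.mh_min_anneal
    best = None  # (deletion, -k, a, b, k)
    lo_e1 = max(k_min, r_l - w)
    for e1 in range(lo_e1, r_l + 1):            # left copy ends at e1
        for b in range(F - r_r, min(F - r_r + w, F - k_min) + 1):
            k = _max_overlap(seq, e1, b, min(e1, F - b))
            if k >= k_min:
                a = e1 - k
                deletion = (a + k) + (F - b - k)  # left loss + right loss
                key = (deletion, -k, a)
                if best is None or key < best[:3]:
                    best = (deletion, -k, a, b, k)
    if best is None:
        return None
    _, _negk, a, b, k = best
    return a, b, k


_MH_CAP = 16  # longest repeat ever considered for annealing


def _max_overlap(seq: str, e1: int, b: int, kmax: int) -> int:
    """Longest k with seq[e1-k:e1] == seq[b:b+k] (a direct repeat across the junction)."""
    for k in range(min(kmax, _MH_CAP), 0, -1):
        if seq[e1 - k:e1] == seq[b:b + k]:
            return k
    return 0


def anhej_join(fragment: LinearFragment, profile: GenotypeProfile,
               rng: np.random.Generator, product_id: str = "anhej") -> RepairedProduct | None:
    """Alternative-NHEJ joining; returns None if no annealable microhomology
    is found within the allowed number of resection re-draws."""
    seq = fragment.seq
    F = len(seq)
    # leave the middle of the substrate untouched so deletions from the two
    # ends can never meet (and downstream junction calling keeps an anchor)
    for _ in range(profile.max_anneal_attempts):
        r_l = _sample_resection(profile, rng, F // 2 - 40)
        r_r = _sample_resection(profile, rng, F // 2 - 40)
        hit = _find_anneal(seq, r_l, r_r, profile)
        if hit is None:
            continue
        a, b, k = hit
        product_seq = seq[a + k : b + k]
        truth = RepairTruth(
            PATHWAY_ANHEJ,
            left_del=a + k,
            right_del=F - (b + k),
            mh_len=k,
            mh_seq=seq[b : b + k],
            resect_left=r_l,
            resect_right=r_r,
        )
        return RepairedProduct(DnaRecord(product_id, product_seq, circular=True),
                               PATHWAY_ANHEJ, truth)
    return None


def collapse_terminal_repeats(fragment: LinearFragment, repeat_len: int = 6,
                              product_id: str = "repeat-collapse") -> RepairedProduct:
    """The canonical microhomology-mediated join of a direct-repeat substrate:
    the two terminal repeats anneal and collapse to a single copy."""
    seq = fragment.seq
    if seq[:repeat_len] != seq[-repeat_len:]:
        raise ValueError("fragment termini do not carry the same repeat")
    truth = RepairTruth(
        PATHWAY_ANHEJ,
        left_del=repeat_len,
        right_del=0,
        mh_len=repeat_len,
        mh_seq=seq[:repeat_len],
        resect_left=repeat_len,
        resect_right=repeat_len,
    )
    return RepairedProduct(DnaRecord(product_id, seq[repeat_len:], circular=True),
                           PATHWAY_ANHEJ, truth)


# --- cohorts ---------------------------------------------------------------


def simulate_cohort(profile: GenotypeProfile, fragment: LinearFragment,
                    n: int, seed: int) -> Cohort:
    """n independent repair attempts on ``fragment`` under ``profile``."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = Cohort(profile, fragment.ref_id, n)
    for i in range(n):
        fate = choose_pathway(profile, rng)
        if fate == PATHWAY_CNHEJ:
            prod = cnhej_join(fragment, profile, rng, product_id=f"{fragment.ref_id}|{i}")
        elif fate == PATHWAY_ANHEJ:
            prod = anhej_join(fragment, profile, rng, product_id=f"{fragment.ref_id}|{i}")
        else:
            prod = None
        if prod is None:
            cohort.n_unrepaired += 1
        else:
            cohort.products.append(prod)
    assert len(cohort.products) + cohort.n_unrepaired == n
    return cohort


def write_cohort(cohort: Cohort, fasta_path, sidecar_path) -> None:
    """Products as FASTA plus a JSON sidecar with labels and truth records."""
    from .records import write_fasta

    write_fasta([p.seq for p in cohort.products], fasta_path)
    meta = {
        "profile": cohort.profile.name,
        "substrate": cohort.substrate_id,
        "n_attempted": cohort.n_attempted,
        "n_unrepaired": cohort.n_unrepaired,
        "products": [
            {"id": p.seq.id, "pathway": p.pathway_label, "truth": asdict(p.truth)}
            for p in cohort.products
        ],
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)
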