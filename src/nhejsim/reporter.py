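"""In-silico reporter substrates.

Two designed plasmids are generated from a seed:

* a split-GFP reporter: a GFP cassette whose two exon halves are separated
  by a 2.4 kb intron carrying an adenovirus-derived exon flanked by paired
  HindIII and inverted I-SceI sites.  Cutting out the internal exon and
  re-circularizing restores GFP expression after splicing.
* a blunt direct-repeat reporter biased toward microhomology-mediated
  joining: digestion with AfeI and EcoRV leaves a blunt linear molecule
  carrying the same 6-bp repeat at both termini; collapse of the repeats to
  a single copy creates a diagnostic BstXI site in the junction amplicon.

The architecture (feature order, site pairing, repeat geometry) is fixed;
all sequence not forced by the architecture is drawn pseudo-randomly at
~50% GC and rejection-sampled so that no stray HindIII/I-SceI/BstXI/primer
matches exist anywhere on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enzymes import LinearFragment, find_sites, get_enzyme, _cut_coords
from .records import DnaRecord, fetch_circular, revcomp


class ConfigurationError(ValueError):
    """Requested substrate geometry is infeasible."""


STOP_CODONS = {"TAA", "TAG", "TGA"}

_SD = "GTAAGT"  # splice donor consensus
_SA = "TTTCAG"  # polypyrimidine-tract/acceptor consensus, ends AG


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(("A", "C", "G", "T"), size=n))


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    out = []
    while len(out) < n_codons:
        c = _random_dna(rng, 3)
        if c not in STOP_CODONS:
            out.append(c)
    return "".join(out)


def _has_internal_stop(orf: str) -> bool:
    return any(orf[i : i + 3] in STOP_CODONS for i in range(0, len(orf) - 3, 3))


# --- split-GFP reporter ----------------------------------------------------


@dataclass(frozen=True)
class GfpReporterConfig:
    intron_len: int = 2400          # splice donor through splice acceptor
    ad2_len: int = 200              # internal (GFP-breaking) exon
    exon1_len: int = 300            # "G" half; must be a codon multiple
    exon2_len: int = 399            # "FP" half incl. stop; codon multiple
    promoter_len: int = 200
    polya_len: int = 120
    backbone_len: int = 800
    site_spacing: int = 20          # between paired HindIII and I-SceI sites
    inner_gap: int = 20             # between I-SceI site and internal exon


@dataclass
class ReporterLayout:
    """Feature intervals (0-based, half-open, top strand) on the plasmid."""

    promoter: tuple[int, int]
    gfp_exon1: tuple[int, int]
    splice_donor: tuple[int, int]
    intron: tuple[int, int]         # interior between donor and acceptor
    ad2_exon: tuple[int, int]
    splice_acceptor: tuple[int, int]
    gfp_exon2: tuple[int, int]
    polya: tuple[int, int]
    hindiii_sites: list[int] = field(default_factory=list)
    iscei_sites: list[tuple[int, str]] = field(default_factory=list)

    @property
    def excised_intron(self) -> tuple[int, int]:
        """Splice-donor start through splice-acceptor end (the spliced-out span)."""
        return (self.splice_donor[0], self.splice_acceptor[1])

    def feature_seq(self, record: DnaRecord, name: str) -> str:
        start, end = getattr(self, name)
        return record.fetch(start, end)

    def spliced_message(self, record: DnaRecord) -> str:
        return self.feature_seq(record, "gfp_exon1") + self.feature_seq(record, "gfp_exon2")


def _protected_mask(n: int, intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def _stray_site_positions(seq: str, enzymes, allowed: dict[str, set[int]]):
    """(enzyme, pos, strand) for every unsanctioned recognition match."""
    rec = DnaRecord("scan", seq, circular=True)
    out = []
    for enz in enzymes:
        ok = allowed.get(enz.name, set())
        for pos, strand in find_sites(rec, enz):
            if pos not in ok:
                out.append((enz, pos, strand))
    return out


def _scrub_strays(seq: str, rng, enzymes, allowed, protected, orf_check, max_rounds: int = 300) -> str:
    """Mutate single bases until no unsanctioned site remains."""
    n = len(seq)
    chars = list(seq)
    for _ in range(max_rounds):
        strays = _stray_site_positions("".join(chars), enzymes, allowed)
        if not strays:
            return "".join(chars)
        enz, pos, _strand = strays[0]
        span = [(pos + i) % n for i in range(len(enz.recognition))]
        candidates = [p for p in span if not protected[p]]
        rng.shuffle(candidates)
        fixed = False
        for p in candidates:
            old = chars[p]
            for base in rng.permutation(["A", "C", "G", "T"]):
                if base == old:
                    continue
                chars[p] = base
                if orf_check("".join(chars)):
                    fixed = True
                    break
                chars[p] = old
            if fixed:
                break
        if not fixed:
            raise ConfigurationError("cannot remove stray site without touching protected bases")
    raise ConfigurationError("stray-site scrubbing did not converge")


def build_reporter(config: GfpReporterConfig | None = None, seed: int = 0):
    """Construct the split-GFP reporter plasmid.

    Returns ``(record, layout)``; deterministic for a given seed.
    """
    cfg = config or GfpReporterConfig()
    if cfg.exon1_len % 3 or cfg.exon2_len % 3:
        raise ConfigurationError("exon lengths must be codon multiples")
    hind = get_enzyme("HindIII")
    scei = get_enzyme("I-SceI")
    bstx = get_enzyme("BstXI")
    core = (len(_SD) + 6 + cfg.site_spacing + 18 + cfg.inner_gap + cfg.ad2_len
            + cfg.inner_gap + 18 + cfg.site_spacing + 6 + len(_SA))
    if cfg.intron_len < core + 40:
        raise ConfigurationError("intron too short for the internal-exon cassette")
    arm = (cfg.intron_len - core) // 2
    arm_r = cfg.intron_len - core - arm

    rng = np.random.default_rng(seed)

    exon1 = "ATG" + _random_codons(rng, cfg.exon1_len // 3 - 1)
    exon2 = _random_codons(rng, cfg.exon2_len // 3 - 1) + "TAA"
    # internal exon starts with an in-frame stop so its retention breaks the ORF
    ad2 = "TAA" + _random_dna(rng, cfg.ad2_len - 3)

    parts = [
        ("promoter", _random_dna(rng, cfg.promoter_len)),
        ("gfp_exon1", exon1),
        ("splice_donor", _SD),
        ("left_arm", _random_dna(rng, arm)),
        ("hindiii_1", hind.recognition),
        ("spacer_1", _random_dna(rng, cfg.site_spacing)),
        ("iscei_1", scei.recognition),
        ("gap_1", _random_dna(rng, cfg.inner_gap)),
        ("ad2_exon", ad2),
        ("gap_2", _random_dna(rng, cfg.inner_gap)),
        ("iscei_2", revcomp(scei.recognition)),
        ("spacer_2", _random_dna(rng, cfg.site_spacing)),
        ("hindiii_2", hind.recognition),
        ("right_arm", _random_dna(rng, arm_r)),
        ("splice_acceptor", _SA),
        ("gfp_exon2", exon2),
        ("polya", _random_dna(rng, cfg.polya_len)),
        ("backbone", _random_dna(rng, cfg.backbone_len)),
    ]
    coords, pos = {}, 0
    for name, s in parts:
        coords[name] = (pos, pos + len(s))
        pos += len(s)
    seq = "".join(s for _, s in parts)

    allowed = {
        "HindIII": {coords["hindiii_1"][0], coords["hindiii_2"][0]},
        "I-SceI": {coords["iscei_1"][0], coords["iscei_2"][0]},
        "BstXI": set(),
    }
    protected = _protected_mask(len(seq), [
        coords["hindiii_1"], coords["hindiii_2"],
        coords["iscei_1"], coords["iscei_2"],
        coords["splice_donor"], coords["splice_acceptor"],
        (coords["gfp_exon1"][0], coords["gfp_exon1"][0] + 3),       # ATG
        (coords["gfp_exon2"][1] - 3, coords["gfp_exon2"][1]),       # stop
        (coords["ad2_exon"][0], coords["ad2_exon"][0] + 3),         # planted stop
    ])
    e1, e2 = coords["gfp_exon1"], coords["gfp_exon2"]

    def orf_ok(s: str) -> bool:
        orf = s[e1[0]:e1[1]] + s[e2[0]:e2[1]]
        return not _has_internal_stop(orf) and orf.startswith("ATG") and orf.endswith("TAA")

    seq = _scrub_strays(seq, rng, [hind, scei, bstx], allowed, protected, orf_ok)

    layout = ReporterLayout(
        promoter=coords["promoter"],
        gfp_exon1=coords["gfp_exon1"],
        splice_donor=coords["splice_donor"],
        intron=(coords["splice_donor"][1], coords["splice_acceptor"][0]),
        ad2_exon=coords["ad2_exon"],
        splice_acceptor=coords["splice_acceptor"],
        gfp_exon2=coords["gfp_exon2"],
        polya=coords["polya"],
        hindiii_sites=[coords["hindiii_1"][0], coords["hindiii_2"][0]],
        iscei_sites=[(coords["iscei_1"][0], "+"), (coords["iscei_2"][0], "-")],
    )
    record = DnaRecord(f"gfp-reporter-{seed}", seq, circular=True)
    return record, layout


# --- direct-repeat (microhomology-bias) reporter ---------------------------


@dataclass(frozen=True)
class RepeatReporterConfig:
    repeat_seq: str = "GCTGAT"      # forced by AfeI/EcoRV cut geometry
    amplicon_len: int = 180         # full PCR product across a direct junction
    diagnostic_len: int = 120       # labeled BstXI fragment of the collapsed junction
    primer_len: int = 20
    fragment_len: int = 2400        # blunt linear substrate length
    discard_len: int = 300          # stuffer between the AfeI and EcoRV sites


@dataclass
class RepeatReporterLayout:
    """Coordinates on the *digested linear fragment* (0-based, top strand)."""

    repeat_seq: str
    fragment_len: int
    left_flank: str                 # 20 nt after the left terminal repeat
    right_flank: str                # 20 nt before the right terminal repeat
    primer_fwd: tuple[int, int]     # top-strand interval of the forward primer
    primer_rev: tuple[int, int]     # top-strand interval matched by the reverse primer
    amplicon_len: int
    diagnostic_len: int
    plasmid_interval: tuple[int, int]  # fragment's span on the circular plasmid

    def primer_fwd_seq(self, fragment_seq: str) -> str:
        return fragment_seq[self.primer_fwd[0]:self.primer_fwd[1]]

    def primer_rev_seq(self, fragment_seq: str) -> str:
        return revcomp(fragment_seq[self.primer_rev[0]:self.primer_rev[1]])


def build_repeat_reporter(config: RepeatReporterConfig | None = None, seed: int = 0):
    """Construct the direct-repeat reporter plasmid.

    Returns ``(record, layout)``.  The plasmid cut with AfeI + EcoRV releases
    a blunt fragment beginning and ending with ``repeat_seq``; the canonical
    microhomology collapse of its termini recreates a single BstXI site whose
    amplicon cleaves into the configured diagnostic fragment.
    """
    cfg = config or RepeatReporterConfig()
    rep = cfg.repeat_seq.upper()
    if len(rep) != 6 or not (rep.startswith("GCT") and rep.endswith("GAT")):
        # AfeI leaves GCT... at the downstream cut; EcoRV leaves ...GAT upstream.
        raise ConfigurationError(
            "repeat must be a 6-mer of the form GCTnGAT-compatible (GCT...GAT) "
            "to sit at both blunt termini of an AfeI/EcoRV digest")
    d2 = cfg.diagnostic_len + 5     # junction-to-amplicon-end distance
    d1 = cfg.amplicon_len - d2      # primer-fwd start to fragment right end
    F = cfg.fragment_len
    if d1 < cfg.primer_len + 12 or d2 + cfg.primer_len > F // 2:
        raise ConfigurationError("amplicon geometry infeasible for fragment length")

    afe = get_enzyme("AfeI")
    ecorv = get_enzyme("EcoRV")
    bstx = get_enzyme("BstXI")
    rng = np.random.default_rng(seed)

    # fragment top strand: GCTGAT TGG ... CCA GCTGAT
    interior = _random_dna(rng, F - 6 - 3 - 3 - 6)
    fragment = rep + "TGG" + interior + "CCA" + rep
    # plasmid: ...AGC | fragment | ATC ... (AfeI and EcoRV straddle the termini)
    stuffer = _random_dna(rng, cfg.discard_len - 6)
    plasmid = fragment + "ATC" + stuffer + "AGC"

    allowed = {
        "AfeI": {len(fragment) + 3 + len(stuffer)},      # AGC^GCT across origin
        "EcoRV": {len(fragment) - 3},                    # GAT^ATC at fragment end
        "BstXI": set(),
    }
    n = len(plasmid)
    protected = _protected_mask(n, [
        (0, 9),                       # left repeat + TGG
        (len(fragment) - 9, len(fragment) + 3),  # CCA + right repeat + ATC
        (n - 3, n),                   # AGC
        (F - d1, F - d1 + cfg.primer_len),       # forward primer
        (d2 - cfg.primer_len, d2),               # reverse-primer match
    ])

    seq = _scrub_strays(plasmid, rng, [afe, ecorv, bstx], allowed, protected,
                        lambda s: True)
    # primer sites must be unique on both strands of the plasmid
    fwd = seq[F - d1 : F - d1 + cfg.primer_len]
    rev = seq[d2 - cfg.primer_len : d2]
    for probe in (fwd, rev):
        doubled = seq + seq[: len(probe) - 1]
        hits = _count_occurrences(doubled, probe, len(seq)) + _count_occurrences(doubled, revcomp(probe), len(seq))
        if hits != 1:
            # extremely unlikely for random 20-mers; regenerate with a shifted seed
            return build_repeat_reporter(cfg, seed + 104729)

    record = DnaRecord(f"repeat-reporter-{seed}", seq, circular=True)
    layout = RepeatReporterLayout(
        repeat_seq=rep,
        fragment_len=F,
        left_flank=seq[6:26],
        right_flank=seq[F - 26 : F - 6],
        primer_fwd=(F - d1, F - d1 + cfg.primer_len),
        primer_rev=(d2 - cfg.primer_len, d2),
        amplicon_len=cfg.amplicon_len,
        diagnostic_len=cfg.diagnostic_len,
        plasmid_interval=(0, F),
    )
    return record, layout


def _count_occurrences(text: str, probe: str, limit: int) -> int:
    count = start = 0
    while True:
        i = text.find(probe, start)
        if i < 0 or i >= limit:
            return count
        count += 1
        start = i + 1


# --- digestion helpers -----------------------------------------------------


def multi_digest(record: DnaRecord, enzymes) -> list[LinearFragment]:
    """Digest with several enzymes at once (used for the AfeI+EcoRV cut)."""
    from .enzymes import _left_end, _right_end

    n = len(record.seq)
    cuts = []
    for enz in enzymes:
        for pos, strand in find_sites(record, enz):
            cuts.append(_cut_coords(pos, strand, enz, n))
    if not cuts:
        raise ConfigurationError("no sites for any enzyme supplied")
    cuts.sort()
    frags = []
    for i, (t1, b1) in enumerate(cuts):
        t2, b2 = cuts[(i + 1) % len(cuts)]
        span = (t2 - t1) % n or n
        top = fetch_circular(record.seq, t1, span)
        frags.append(LinearFragment(top, _left_end(record, t1, b1),
                                    _right_end(record, t2, b2),
                                    ref_id=record.id, ref_interval=(t1, t2)))
    return frags


def _fragment_containing(frags, record: DnaRecord, anchor_pos: int) -> LinearFragment:
    anchor = fetch_circular(record.seq, anchor_pos, 24)
    for f in frags:
        if anchor in f.seq:
            return f
    raise ValueError("no fragment contains the anchor")


def hindiii_fragment(record: DnaRecord, layout: ReporterLayout) -> LinearFragment:
    """The transfected substrate: HindIII digest, internal exon removed."""
    from .enzymes import digest

    frags = digest(record, get_enzyme("HindIII"))
    return _fragment_containing(frags, record, layout.promoter[0])


def iscei_fragment(record: DnaRecord, layout: ReporterLayout) -> LinearFragment:
    from .enzymes import digest

    frags = digest(record, get_enzyme("I-SceI"))
    return _fragment_containing(frags, record, layout.promoter[0])


def repeat_fragment(record: DnaRecord, layout: RepeatReporterLayout) -> LinearFragment:
    """The blunt direct-repeat substrate (AfeI + EcoRV double digest)."""
    frags = multi_digest(record, [get_enzyme("AfeI"), get_enzyme("EcoRV")])
    for f in frags:
        if f.seq.startswith(layout.repeat_seq) and f.seq.endswith(layout.repeat_seq):
            return f
    raise ValueError("repeat-terminated fragment not found")
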