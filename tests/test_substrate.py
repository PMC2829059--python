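"""Substrate construction, digestion, and ligation primitives."""

import numpy as np
import pytest

from nhejsim import (
    DnaRecord,
    build_reporter,
    build_repeat_reporter,
    digest,
    ends_compatible,
    find_sites,
    get_enzyme,
    ligate,
)
from nhejsim.enzymes import EndStructure, ZeroSitesWarning
from nhejsim.reporter import ConfigurationError, GfpReporterConfig

# ---------------------------------------------------------------------------
# independent regex site oracle

from _oracles import regex_sites  # noqa: E402


# ---------------------------------------------------------------------------
# GFP reporter


def test_reporter_designed_sites_only(gfp_reporter):
    record, layout = gfp_reporter
    hind, scei, bstx = (get_enzyme(n) for n in ("HindIII", "I-SceI", "BstXI"))
    assert len(find_sites(record, hind)) == 2
    assert len(find_sites(record, scei)) == 2
    assert find_sites(record, bstx) == []
    # regex oracle agrees and confirms no strays anywhere
    for enz in (hind, scei, bstx):
        assert regex_sites(record.seq, enz.recognition) == sorted(find_sites(record, enz))


def test_reporter_layout_invariants(gfp_reporter):
    record, layout = gfp_reporter
    span = layout.excised_intron
    assert span[1] - span[0] == 2400
    ad2 = layout.ad2_exon
    assert span[0] < ad2[0] and ad2[1] < span[1]
    # each HindIII/I-SceI pair flanks the internal exon, I-SceI sites inverted
    h1, h2 = layout.hindiii_sites
    (s1, o1), (s2, o2) = layout.iscei_sites
    assert h1 < s1 < ad2[0] and ad2[1] < s2 < h2
    assert {o1, o2} == {"+", "-"}
    # intervals ordered and non-overlapping
    names = ["promoter", "gfp_exon1", "splice_donor", "intron", "ad2_exon",
             "splice_acceptor", "gfp_exon2", "polya"]
    ivs = [getattr(layout, n) for n in names]
    order = [ivs[0], ivs[1], ivs[2], ivs[4], ivs[5], ivs[6], ivs[7]]
    assert all(a[1] <= b[0] for a, b in zip(order, order[1:]))


def test_reporter_deterministic():
    a, _ = build_reporter(seed=7)
    b, _ = build_reporter(seed=7)
    c, _ = build_reporter(seed=8)
    assert a.seq == b.seq
    assert a.seq != c.seq


def test_reporter_orf_logic(gfp_reporter):
    record, layout = gfp_reporter
    stops = {"TAA", "TAG", "TGA"}
    msg = layout.spliced_message(record)
    assert msg.startswith("ATG") and msg[-3:] in stops and len(msg) % 3 == 0
    assert not any(msg[i:i + 3] in stops for i in range(3, len(msg) - 3, 3))
    # retaining the internal exon in the message breaks the frame / adds a stop
    broken = (layout.feature_seq(record, "gfp_exon1")
              + layout.feature_seq(record, "ad2_exon")
              + layout.feature_seq(record, "gfp_exon2"))
    has_stop = any(broken[i:i + 3] in stops for i in range(3, len(broken) - 3, 3))
    assert has_stop or len(broken) % 3 != 0


def test_reporter_infeasible_config_rejected():
    with pytest.raises(ConfigurationError):
        build_reporter(GfpReporterConfig(intron_len=300), seed=0)
    with pytest.raises(ConfigurationError):
        build_reporter(GfpReporterConfig(exon1_len=301), seed=0)


# ---------------------------------------------------------------------------
# site search


def test_find_sites_matches_biopython_on_random_sequences():
    from Bio.Restriction import BstXI as BioBstXI, EcoRV as BioEcoRV, \
        HindIII as BioHindIII
    from Bio.Seq import Seq

    rng = np.random.default_rng(0)
    pairs = [("HindIII", BioHindIII), ("EcoRV", BioEcoRV), ("BstXI", BioBstXI)]
    for trial in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        rec = DnaRecord("r", seq, circular=False)
        for name, bio_enz in pairs:
            enz = get_enzyme(name)
            ours = sorted(p for p, _ in find_sites(rec, enz))
            bio = sorted(s - 1 - enz.cut_top for s in bio_enz.search(Seq(seq), linear=True))
            assert ours == bio, name


def test_find_sites_circular_origin_spanning():
    enz = get_enzyme("HindIII")
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(20, 100))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        rec = DnaRecord("r", seq, circular=True)
        got = {p for p, _ in find_sites(rec, enz)}
        # brute force: check every rotation's prefix
        expect = {i for i in range(n) if (seq + seq)[i:i + 6] == "AAGCTT"}
        assert got == expect


def test_find_sites_absent_enzyme_empty():
    rec = DnaRecord("r", "ACGT" * 30, circular=True)
    assert find_sites(rec, get_enzyme("HindIII")) == []


# ---------------------------------------------------------------------------
# digestion


def test_hindiii_digest_overhangs_and_conservation(gfp_reporter, hind_frag):
    record, _ = gfp_reporter
    frags = digest(record, get_enzyme("HindIII"))
    assert len(frags) == 2
    assert sum(len(f) for f in frags) == len(record)
    for f in frags:
        for end in (f.left_end, f.right_end):
            assert end.kind == "five_prime_overhang"
            assert end.overhang_seq == "AGCT"
    assert ends_compatible(hind_frag.right_end, hind_frag.left_end)


def test_iscei_digest_incompatible_ends(iscei_frag):
    for end in (iscei_frag.left_end, iscei_frag.right_end):
        assert end.kind == "three_prime_overhang"
        assert len(end.overhang_seq) == 4
    assert not ends_compatible(iscei_frag.right_end, iscei_frag.left_end)


def test_single_site_circular_digest_conserves_length():
    rng = np.random.default_rng(3)
    core = "".join(rng.choice(list("ACGT"), size=200)).replace("AAGCTT", "AAGATT")
    rec = DnaRecord("r", core + "AAGCTT", circular=True)
    frags = digest(rec, get_enzyme("HindIII"))
    assert len(frags) == 1
    assert len(frags[0]) == len(rec)


def test_zero_site_digest_warns_and_returns_record():
    rec = DnaRecord("r", "ACGT" * 30, circular=True)
    with pytest.warns(ZeroSitesWarning):
        out = digest(rec, get_enzyme("HindIII"))
    assert out is rec


# ---------------------------------------------------------------------------
# compatibility & ligation


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (EndStructure("blunt", "", 0), EndStructure("blunt", "", 0), True),
        (EndStructure("five_prime_overhang", "AGCT", 0),
         EndStructure("five_prime_overhang", "AGCT", 0), True),
        (EndStructure("five_prime_overhang", "AGCT", 0),
         EndStructure("three_prime_overhang", "AGCT", 0), False),
        (EndStructure("three_prime_overhang", "ATAA", 0),
         EndStructure("three_prime_overhang", "ATAA", 0), False),
        (EndStructure("three_prime_overhang", "ATAA", 0),
         EndStructure("three_prime_overhang", "TTAT", 0), True),
        (EndStructure("five_prime_overhang", "AGCT", 0),
         EndStructure("five_prime_overhang", "AGC", 0), False),
    ],
)
def test_ends_compatible_rules(a, b, expected):
    assert ends_compatible(a, b) is expected


def test_religation_restores_single_site(hind_frag):
    circ = ligate(hind_frag)
    assert len(circ) == len(hind_frag.seq)
    doubled = circ.seq + circ.seq[:5]
    assert doubled.count("AAGCTT") == 1


def test_incompatible_ends_rejected(iscei_frag):
    from nhejsim.enzymes import LigationError

    with pytest.raises(LigationError):
        ligate(iscei_frag)


def test_digest_ligate_round_trip_random_substrates():
    """ligate(digest(x)) returns the parent circle for single-cut substrates."""
    enz = get_enzyme("HindIII")
    rng = np.random.default_rng(9)
    done = 0
    while done < 100:
        n = int(rng.integers(50, 200))
        seq = "".join(rng.choice(list("ACGT"), size=n)) + "AAGCTT"
        rec = DnaRecord("r", seq, circular=True)
        if len(find_sites(rec, enz)) != 1:
            continue
        done += 1
        frag = digest(rec, enz)[0]
        circ = ligate(frag)
        assert len(circ) == len(rec)
        assert circ.seq in rec.seq + rec.seq  # same circle, any rotation
        # and re-digestion reproduces the same end structures
        refrag = digest(circ, enz)[0]
        assert refrag.left_end.overhang_seq == frag.left_end.overhang_seq
        assert refrag.right_end.overhang_seq == frag.right_end.overhang_seq


# ---------------------------------------------------------------------------
# direct-repeat reporter


def test_repeat_reporter_termini_and_bstxi(repeat_reporter, repeat_frag):
    record, layout = repeat_reporter
    rep = layout.repeat_seq
    assert len(rep) == 6
    assert repeat_frag.seq.startswith(rep) and repeat_frag.seq.endswith(rep)
    assert repeat_frag.left_end.kind == "blunt" and repeat_frag.right_end.kind == "blunt"
    # collapse junction: one BstXI site; direct blunt junction: none
    collapsed = DnaRecord("c", repeat_frag.seq[6:], circular=True)
    direct = DnaRecord("d", repeat_frag.seq, circular=True)
    assert len(regex_sites(collapsed.seq, "CCANNNNNNTGG")) == 1
    assert regex_sites(direct.seq, "CCANNNNNNTGG") == []
    junction = collapsed.seq[-15:] + collapsed.seq[:15]
    assert "CCA" + rep + "TGG" in junction


def test_repeat_reporter_bad_repeat_rejected():
    from nhejsim.reporter import RepeatReporterConfig

    with pytest.raises(ConfigurationError):
        build_repeat_reporter(RepeatReporterConfig(repeat_seq="AAAAAA"), seed=0)


def test_repeat_reporter_deterministic():
    a, _ = build_repeat_reporter(seed=5)
    b, _ = build_repeat_reporter(seed=5)
    assert a.seq == b.seq


def test_two_fragment_ligation_reassembles_plasmid(gfp_reporter):
    record, _ = gfp_reporter
    a, b = digest(record, get_enzyme("HindIII"))
    circ = ligate(a, b)
    assert len(circ) == len(record)
    assert circ.seq in record.seq + record.seq  # the original circle, rotated
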