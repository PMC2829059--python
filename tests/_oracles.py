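"""Shared independent oracles used across test modules."""

import re

from nhejsim.records import IUPAC, revcomp


def regex_sites(seq: str, recognition: str, circular: bool = True):
    """All recognition matches on both strands via a plain regex scan."""
    def _pat(r):
        return "".join(c if c in "ACGT" else f"[{IUPAC[c]}]" for c in r)

    hits = set()
    scan = seq + seq[: len(recognition) - 1] if circular else seq
    for strand, p in (("+", _pat(recognition)), ("-", _pat(revcomp(recognition)))):
        for m in re.finditer(f"(?={p})", scan):
            if m.start() < len(seq):
                hits.add((m.start(), strand))
    if revcomp(recognition) == recognition:  # palindromes counted once
        hits = {(p, "+") for p, _ in hits}
    return sorted(hits)
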