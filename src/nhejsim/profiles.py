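"""Genotype profiles embodying the Ku end-access gatekeeper model.

A profile summarizes one cell line as: how much Ku it has (``ku_level``),
whether the downstream classic-NHEJ machinery (DNA-PKcs/XLF/LIGIV) is
functional (``cnhej_capacity``), how abundant the alternative end-joining
machinery is (``anhej_level``), and the processing parameters of each
pathway.  Pathway choice per break: Ku captures the ends with probability
kappa*ku_level / (kappa*ku_level + anhej_level); captured ends are fated to
classic NHEJ (or stall unrepaired when the downstream machinery is absent,
escaping to the alternative pathway only with ``leak_prob``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import yaml


@dataclass(frozen=True)
class GenotypeProfile:
    name: str
    ku_level: float = 1.0           # fraction of wild-type Ku abundance
    cnhej_capacity: bool = True     # downstream DNA-PKcs/XLF/LIGIV intact
    anhej_level: float = 1.0        # relative A-NHEJ machinery abundance
    ku_affinity: float = 9.0        # kappa: end-capture weight of Ku
    leak_prob: float = 0.02         # Ku-occupied end released to A-NHEJ
    cnhej_direct_prob: float = 0.25  # cohesive ends religated untouched
    small_indel_max: int = 8        # nt; C-NHEJ per-side trim / insert cap
    insert_prob: float = 0.2        # C-NHEJ junction gains a small insert
    resection_mean: float = 350.0   # nt; geometric 5'->3' resection per end
    resection_max: int = 900        # nt; processivity bound (resampled above)
    mh_min_anneal: int = 2          # nt; shortest annealable microhomology
    mh_window: int = 25             # nt; annealing search window at the stall point
    max_anneal_attempts: int = 8    # resection re-draws before giving up

    def __post_init__(self) -> None:
        for p in ("ku_level", "leak_prob", "cnhej_direct_prob", "insert_prob"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{p} must be in [0, 1], got {v}")
        if self.anhej_level < 0:
            raise ValueError("anhej_level must be >= 0")
        if self.resection_mean <= 0:
            raise ValueError("resection_mean must be > 0")
        if self.mh_min_anneal < 1:
            raise ValueError("mh_min_anneal must be >= 1")
        if self.resection_max < self.resection_mean / 10:
            raise ValueError("resection_max implausibly small")

    @property
    def capture_prob(self) -> float:
        """Closed-form probability that Ku wins the race to the ends."""
        denom = self.ku_affinity * self.ku_level + self.anhej_level
        return 0.0 if denom == 0 else self.ku_affinity * self.ku_level / denom

    def with_(self, **kw) -> "GenotypeProfile":
        return replace(self, **kw)


def load_profiles(path=None) -> dict[str, GenotypeProfile]:
    """Profiles from a YAML config; defaults to the packaged cell-line panel."""
    if path is None:
        text = resources.files("nhejsim.data").joinpath("profiles.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out = {}
    for name, params in raw.items():
        out[name] = GenotypeProfile(name=name, **(params or {}))
    return out


def default_profiles() -> dict[str, GenotypeProfile]:
    return load_profiles()
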