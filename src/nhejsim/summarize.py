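"""Cohort aggregation and parameter recovery.

Summaries mirror how transfection experiments are reported: category
fractions over classified products, deletion mean/median, and percent
repair normalized to a wild-type cohort.

``recover_parameters`` closes the analysis loop: from classified junctions
alone it estimates the fraction of events repaired by the alternative
pathway and the resection scale.  The microhomology-category fraction is
corrected for the chance rate at which classic-NHEJ junctions display
microhomology (estimated from a matched classic-only null simulation), and
the resection scale is recovered by simulated method of moments: the mean
A-NHEJ junction deletion is matched against alternative-pathway-only
simulations of the same substrate, which accounts for resection truncation
and annealing-window effects without closed-form approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .junctions import ClassifierParams, classify_cohort
from .profiles import GenotypeProfile
from .repair import anhej_join, cnhej_join

CATEGORIES = ("perfect", "imperfect", "microhomology", "insertion")


@dataclass
class CohortSummary:
    genotype: str
    n: int                           # classified products
    percent_repair: float            # FACS readout (percent, 0-100)
    percent_repair_rel_wt: float | None
    category_fractions: dict[str, float]
    deletion_mean: float
    deletion_median: float
    insertion_freq: float

    def __post_init__(self) -> None:
        total = sum(self.category_fractions.values())
        if self.n and abs(total - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")


@dataclass
class RecoveryEstimate:
    anhej_fraction_hat: float
    anhej_fraction_se: float
    resection_mean_hat: float | None
    resection_mean_se: float | None


def _median_lower(values) -> float:
    """Median with the lower-middle convention for even n."""
    v = sorted(values)
    if not v:
        return float("nan")
    return float(v[(len(v) - 1) // 2])


def cohort_summary(calls, percent_repair: float, genotype: str,
                   include_perfect_in_deletions: bool = False) -> CohortSummary:
    """Aggregate junction calls into the standard summary surface.

    Deletion statistics exclude perfect joins by default (zero-deletion
    religations are a different event class from processed junctions).
    """
    if not calls:
        raise ValueError("no calls supplied")
    n = len(calls)
    fractions = {c: sum(call.category == c for call in calls) / n for c in CATEGORIES}
    if include_perfect_in_deletions:
        dels = [c.deletion_total for c in calls]
    else:
        dels = [c.deletion_total for c in calls if c.category != "perfect"]
    ins_freq = fractions["insertion"]
    return CohortSummary(
        genotype=genotype,
        n=n,
        percent_repair=percent_repair,
        percent_repair_rel_wt=None,
        category_fractions=fractions,
        deletion_mean=float(np.mean(dels)) if dels else 0.0,
        deletion_median=_median_lower(dels) if dels else 0.0,
        insertion_freq=ins_freq,
    )


def compare_to_wildtype(summaries: dict[str, list[CohortSummary]], wt_name: str = "WT"):
    """Percent repair of each genotype relative to wild type.

    ``summaries`` maps genotype -> replicate summaries (one per seed).
    Returns a DataFrame with one row per genotype: mean relative percent
    repair and the replicate standard deviation.
    """
    import pandas as pd

    if wt_name not in summaries:
        raise ValueError(f"wild-type cohort {wt_name!r} missing")
    wt_vals = [s.percent_repair for s in summaries[wt_name]]
    wt_mean = float(np.mean(wt_vals))
    if wt_mean == 0:
        raise ZeroDivisionError("wild-type percent repair is zero")
    rows = []
    for name, reps in summaries.items():
        rel = [100.0 * s.percent_repair / wt_mean for s in reps]
        rows.append({
            "genotype": name,
            "n_replicates": len(rel),
            "percent_repair": float(np.mean([s.percent_repair for s in reps])),
            "relative_to_wt": float(np.mean(rel)),
            "relative_sd": float(np.std(rel, ddof=1)) if len(rel) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


# --- parameter recovery ----------------------------------------------------


@dataclass
class RecoveryParams:
    fragment: object                 # the transfected LinearFragment
    profile_template: GenotypeProfile
    substrate_kind: str = "cohesive"
    classifier: ClassifierParams | None = None
    n_null: int = 2000               # classic-only null simulation size
    n_sim: int = 250                 # per-evaluation A-NHEJ simulation size
    n_boot: int = 200                # bootstrap resamples (moment-level)
    seed: int = 0


class _FixedPathwayCohort:
    """Duck-typed cohort holding pre-built products (for null simulations)."""

    def __init__(self, products):
        self.products = products
        self.n_unrepaired = 0
        self.n_attempted = len(products)


def _null_cnhej_calls(params: RecoveryParams, n: int, rng):
    """Classic-NHEJ-only junction calls on the same substrate."""
    profile = params.profile_template
    products = []
    i = 0
    while len(products) < n and i < 20 * n:
        i += 1
        products.append(cnhej_join(params.fragment, profile, rng, product_id=f"null|{i}"))
    calls, _, _ = classify_cohort(params.fragment.seq, _FixedPathwayCohort(products),
                                  params.classifier, params.substrate_kind)
    return calls


def _anhej_mean_deletion(m: float, params: RecoveryParams, seed: int) -> float:
    """Mean junction deletion of A-NHEJ-only products at resection mean m."""
    profile = params.profile_template.with_(resection_mean=float(m))
    rng = np.random.default_rng(seed)
    dels = []
    for i in range(params.n_sim):
        p = anhej_join(params.fragment, profile, rng, product_id=f"sim|{i}")
        if p is not None:
            dels.append(p.truth.deletion_total)
    return float(np.mean(dels)) if dels else 0.0


def recover_parameters(calls, params: RecoveryParams) -> RecoveryEstimate:
    """Estimate the A-NHEJ fraction and resection scale from junction calls.

    Requires >= 50 classified calls.  The resection estimate is flagged
    (None) when no microhomology-category calls are present.
    """
    if len(calls) < 50:
        raise ValueError("need at least 50 classified calls")
    rng = np.random.default_rng(params.seed)

    n = len(calls)
    is_mh = np.array([c.category == "microhomology" for c in calls])
    dels = np.array([c.deletion_total for c in calls], dtype=float)
    f_obs = float(is_mh.mean())

    null_calls = _null_cnhej_calls(params, params.n_null, rng)
    null_mh = np.array([c.category == "microhomology" for c in null_calls])
    c_rate = float(null_mh.mean())
    null_del_mh = float(np.mean([c.deletion_total for c in null_calls
                                 if c.category == "microhomology"])) if null_mh.any() else 0.0

    def _a_hat(f: float) -> float:
        if c_rate >= 1.0:
            return 0.0
        return min(1.0, max(0.0, (f - c_rate) / (1.0 - c_rate)))

    a_hat = _a_hat(f_obs)

    def _mean_del_anhej(f: float, mean_mh_del: float, a: float) -> float | None:
        # among MH-category calls, subtract the classic-pathway contamination
        if f == 0 or a <= 0:
            return None
        w_c = (1.0 - a) * c_rate
        num = f * mean_mh_del - w_c * null_del_mh
        den = f - w_c
        return num / den if den > 1e-12 else None

    mean_mh_del = float(dels[is_mh].mean()) if is_mh.any() else 0.0
    target = _mean_del_anhej(f_obs, mean_mh_del, a_hat)

    m_hat = None
    slope = None
    if target is not None and is_mh.any() and a_hat > 0:
        sim_seed = int(rng.integers(0, 2**31 - 1))
        g = lambda m: _anhej_mean_deletion(m, params, sim_seed) - target
        lo, hi = 5.0, 4.0 * max(target, 50.0)
        if g(lo) > 0:
            m_hat = lo
        elif g(hi) < 0:
            m_hat = hi
        else:
            from scipy.optimize import brentq

            m_hat = float(brentq(g, lo, hi, xtol=1.0, rtol=1e-3))
        # local slope for delta-method bootstrap
        h = max(0.05 * m_hat, 5.0)
        slope = (_anhej_mean_deletion(m_hat + h, params, sim_seed)
                 - _anhej_mean_deletion(max(m_hat - h, 1.0), params, sim_seed)) / (
                     (m_hat + h) - max(m_hat - h, 1.0))

    # bootstrap at the moment level, mapped through the fitted response
    a_boot, m_boot = [], []
    for _ in range(params.n_boot):
        idx = rng.integers(0, n, size=n)
        f_b = float(is_mh[idx].mean())
        a_b = _a_hat(f_b)
        a_boot.append(a_b)
        if m_hat is not None and slope and is_mh[idx].any():
            mean_b = float(dels[idx][is_mh[idx]].mean())
            t_b = _mean_del_anhej(f_b, mean_b, a_b)
            if t_b is not None:
                m_boot.append(m_hat + (t_b - (target)) / slope)
    a_se = float(np.std(a_boot, ddof=1)) if len(a_boot) > 1 else 0.0
    m_se = float(np.std(m_boot, ddof=1)) if len(m_boot) > 1 else None

    return RecoveryEstimate(
        anhej_fraction_hat=a_hat,
        anhej_fraction_se=max(a_se, 1e-9),
        resection_mean_hat=m_hat,
        resection_mean_se=m_se,
    )
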