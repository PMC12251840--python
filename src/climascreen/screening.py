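"""Percentile-threshold tolerance screening with sensitivity analysis.

Thresholds are sample quantiles of the 35 (or however many) species-level
medians — NOT of pooled specimens: the drought threshold is the chosen
percentile of median PDQ across species, the cold threshold likewise for
median MTCM.  Classification is strict: a species is a drought candidate
iff median PDQ < threshold (boundary species are nontolerant), and
candidates are ranked strongest→weakest by ascending median.  The
sensitivity analysis repeats the classification over a ladder of
percentiles (default 5th..35th around the 25th reference); a species
tolerant in at least ``core_min`` of the scenarios is a "core" candidate.
Group separation is validated with a specimen-level Mann–Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from . import stats_core
from .niche_profile import SpeciesProfile
from .stats_core import TestResult

#: the seven percentile scenarios of the sensitivity ladder
DEFAULT_PERCENTILES: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35)
REFERENCE_PERCENTILE = 0.25
CORE_MIN = 5  # tolerant in >= 5 of the 7 scenarios -> core candidate


@dataclass(frozen=True)
class ThresholdScenario:
    percentile: float
    pdq_threshold: float  # mm
    mtcm_threshold: float  # °C


@dataclass(frozen=True)
class ScreeningResult:
    species: str
    variable: str  # "drought" | "cold"
    tolerant_at: frozenset  # percentiles at which the species is tolerant
    consistency_score: int
    core: bool
    rank: Optional[int]  # 1 = strongest, at the reference percentile; None if not tolerant there


def derive_thresholds(
    profiles: Sequence[SpeciesProfile], percentile: float = REFERENCE_PERCENTILE
) -> ThresholdScenario:
    """Quantile of the species medians, per variable, at ``percentile``."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 species profiles")
    if not 0.0 <= percentile <= 1.0:
        raise ValueError(f"percentile {percentile} outside [0, 1]")
    return ThresholdScenario(
        percentile=percentile,
        pdq_threshold=stats_core.quantile([p.median_pdq for p in profiles], percentile),
        mtcm_threshold=stats_core.quantile([p.median_mtcm for p in profiles], percentile),
    )


def classify_species(
    profiles: Sequence[SpeciesProfile], scenario: ThresholdScenario
) -> tuple[list[str], list[str]]:
    """Strict-inequality classification, ranked strongest first.

    Returns (drought candidates, cold candidates): species whose median
    PDQ (resp. MTCM) is strictly below the scenario threshold, sorted by
    ascending median with ties broken by species label.
    """
    drought = sorted(
        (p for p in profiles if p.median_pdq < scenario.pdq_threshold),
        key=lambda p: (p.median_pdq, p.species),
    )
    cold = sorted(
        (p for p in profiles if p.median_mtcm < scenario.mtcm_threshold),
        key=lambda p: (p.median_mtcm, p.species),
    )
    return [p.species for p in drought], [p.species for p in cold]


def sensitivity_analysis(
    profiles: Sequence[SpeciesProfile],
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    reference: float = REFERENCE_PERCENTILE,
    core_min: int = CORE_MIN,
) -> list[ScreeningResult]:
    """Classify at every percentile scenario and score consistency.

    By quantile monotonicity the tolerant set at a lower percentile is
    nested inside the set at any higher percentile, so the consistency
    score counts how far down the ladder a species stays tolerant.
    """
    if not percentiles:
        raise ValueError("percentile list is empty")
    if len(set(percentiles)) != len(percentiles):
        raise ValueError("duplicate percentiles in the scenario list")
    if reference not in percentiles:
        raise ValueError(f"reference percentile {reference} not among scenarios")

    scenarios = {p: derive_thresholds(profiles, p) for p in percentiles}
    classified = {p: classify_species(profiles, s) for p, s in scenarios.items()}
    ref_drought, ref_cold = classified[reference]
    ref_rank = {
        "drought": {sp: i + 1 for i, sp in enumerate(ref_drought)},
        "cold": {sp: i + 1 for i, sp in enumerate(ref_cold)},
    }

    results: list[ScreeningResult] = []
    for prof in sorted(profiles, key=lambda p: p.species):
        for variable, side in (("drought", 0), ("cold", 1)):
            tolerant_at = frozenset(
                p for p in percentiles if prof.species in classified[p][side]
            )
            score = len(tolerant_at)
            results.append(
                ScreeningResult(
                    species=prof.species,
                    variable=variable,
                    tolerant_at=tolerant_at,
                    consistency_score=score,
                    core=score >= core_min,
                    rank=ref_rank[variable].get(prof.species),
                )
            )
    return results


def validate_separation(
    specimens: Sequence, tolerant: Iterable[str], variable: str
) -> TestResult:
    """Mann–Whitney U on specimen-level values: tolerant-species specimens
    versus all others, for the variable the screening used ("drought" →
    PDQ, "cold" → MTCM)."""
    tol = set(tolerant)
    if variable == "drought":
        get = lambda s: s.pdq
    elif variable == "cold":
        get = lambda s: s.mtcm
    else:
        raise ValueError(f"unknown screening variable {variable!r}")
    x = [get(s) for s in specimens if s.species in tol]
    y = [get(s) for s in specimens if s.species not in tol]
    if not x or not y:
        raise ValueError("both tolerant and nontolerant groups must be non-empty")
    return stats_core.mann_whitney_u(x, y)
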