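"""Cohort selection funnel for longitudinal visual-field analyses.

The funnel mirrors the selection flow of a multicenter perimetry study:

1. drop each eye's first tests (perimetric learning effect),
2. keep only reliable tests (fixation-loss / false-negative / false-positive
   thresholds, boundary-inclusive),
3. enforce visit spacing (greedy forward scan over a closed day interval),
4. longitudinal eligibility (minimum test count, minimum follow-up span),
5. one eye per patient (seeded uniform choice when both eyes qualify).

The order is fixed: learning exclusion -> reliability -> spacing ->
eligibility.  All thresholds default to the conventional clinical values but
are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .vf_core import EyeSeries, VisualFieldTest

logger = logging.getLogger("vfdecomp")

__all__ = [
    "ReliabilityCriteria",
    "LongitudinalCriteria",
    "CohortSummary",
    "filter_reliable",
    "drop_learning_tests",
    "enforce_visit_spacing",
    "build_md_change_cohort",
    "build_progression_cohort",
    "summarize_cohort",
]


@dataclass(frozen=True)
class ReliabilityCriteria:
    """Inclusive upper bounds on the three reliability indices (fractions)."""

    max_fixation_loss: float = 0.33
    max_false_negative: float = 0.20
    max_false_positive: float = 0.20

    def __post_init__(self) -> None:
        for name in ("max_fixation_loss", "max_false_negative", "max_false_positive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def is_reliable(self, t: VisualFieldTest) -> bool:
        return (
            t.fixation_loss_rate <= self.max_fixation_loss
            and t.false_negative_rate <= self.max_false_negative
            and t.false_positive_rate <= self.max_false_positive
        )


@dataclass(frozen=True)
class LongitudinalCriteria:
    """Eligibility thresholds for the progression cohort."""

    min_reliable_tests: int = 5
    min_followup_years: float = 3.0
    visit_interval_days: tuple[int, int] = (150, 210)
    learning_exclusion_count: int = 2

    def __post_init__(self) -> None:
        if self.min_reliable_tests < 2:
            raise ValueError("min_reliable_tests must be >= 2")
        lo, hi = self.visit_interval_days
        if lo > hi:
            raise ValueError("visit interval lower bound exceeds upper bound")


@dataclass(frozen=True)
class CohortSummary:
    n_tests: int
    n_eyes: int
    n_patients: int
    age_mean: float
    age_sd: float
    md_mean: float
    md_sd: float
    psd_mean: float
    psd_sd: float
    vfi_mean: float
    vfi_sd: float
    tests_per_eye_mean: float
    tests_per_eye_sd: float
    followup_months_mean: float
    followup_months_sd: float


def _reseries(series: EyeSeries, visits: Sequence[VisualFieldTest]) -> EyeSeries:
    return EyeSeries(patient_id=series.patient_id, eye=series.eye, visits=tuple(visits))


def filter_reliable(
    tests: Iterable[VisualFieldTest], criteria: ReliabilityCriteria | None = None
) -> list[VisualFieldTest]:
    """Keep exactly the tests whose three reliability rates are all within bounds."""
    criteria = criteria or ReliabilityCriteria()
    return [t for t in tests if criteria.is_reliable(t)]


def filter_reliable_series(series: EyeSeries, criteria: ReliabilityCriteria) -> EyeSeries:
    return _reseries(series, filter_reliable(series.visits, criteria))


def drop_learning_tests(series: EyeSeries, n: int = 2) -> EyeSeries:
    """Remove the first ``n`` visits of an eye; times rebased to the new baseline."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return _reseries(series, series.visits[n:])


def enforce_visit_spacing(
    series: EyeSeries,
    interval_days: tuple[int, int] = (150, 210),
    *,
    long_gap_policy: str = "skip",
) -> EyeSeries:
    """Greedy forward scan keeping visits spaced within a closed day interval.

    The first visit is always kept; each later visit is kept iff its gap from
    the last *kept* visit lies within ``[lo, hi]``.  Visits with shorter gaps
    are skipped.  A gap exceeding ``hi``:

    - ``"skip"`` (default): the visit is dropped and scanning continues;
    - ``"terminate"``: accumulation stops, discarding all later visits.
    """
    if long_gap_policy not in ("skip", "terminate"):
        raise ValueError("long_gap_policy must be 'skip' or 'terminate'")
    lo, hi = interval_days
    if not series.visits:
        return series
    kept = [series.visits[0]]
    for v in series.visits[1:]:
        gap = (v.exam_date - kept[-1].exam_date).days
        if lo <= gap <= hi:
            kept.append(v)
        elif gap > hi and long_gap_policy == "terminate":
            break
    return _reseries(series, kept)


def _apply_funnel(
    series: EyeSeries,
    reliability: ReliabilityCriteria,
    *,
    learning_n: int,
    interval_days: tuple[int, int],
    long_gap_policy: str = "skip",
) -> EyeSeries:
    s = drop_learning_tests(series, learning_n)
    s = filter_reliable_series(s, reliability)
    return enforce_visit_spacing(s, interval_days, long_gap_policy=long_gap_policy)


def _one_eye_per_patient(
    eligible: list[EyeSeries], rng: np.random.Generator
) -> list[EyeSeries]:
    """Uniform random selection among a patient's eligible eyes, in sorted
    patient order so the draw sequence is reproducible for a given seed."""
    by_patient: dict[str, list[EyeSeries]] = {}
    for s in eligible:
        by_patient.setdefault(s.patient_id, []).append(s)
    chosen = []
    for pid in sorted(by_patient):
        eyes = sorted(by_patient[pid], key=lambda s: s.eye)
        if len(eyes) == 1:
            chosen.append(eyes[0])
        else:
            chosen.append(eyes[int(rng.integers(len(eyes)))])
    return chosen


def build_md_change_cohort(
    all_series: Iterable[EyeSeries],
    reliability: ReliabilityCriteria | None = None,
    seed: int | None = None,
    *,
    learning_n: int = 2,
    interval_days: tuple[int, int] = (150, 210),
    min_tests: int = 2,
) -> list[EyeSeries]:
    """Eyes with >= 2 surviving reliable tests, one eye per patient.

    Applies the full funnel (learning exclusion, reliability, spacing) and
    then selects one eye uniformly at random (seeded) for patients with two
    eligible eyes.
    """
    reliability = reliability or ReliabilityCriteria()
    rng = np.random.default_rng(seed)
    eligible = []
    n_in = 0
    for s in all_series:
        n_in += 1
        surv = _apply_funnel(
            s, reliability, learning_n=learning_n, interval_days=interval_days
        )
        if len(surv) >= min_tests:
            eligible.append(surv)
    chosen = _one_eye_per_patient(eligible, rng)
    logger.info(
        "md-change cohort: %d eyes in, %d eligible, %d after one-eye selection",
        n_in, len(eligible), len(chosen),
    )
    return chosen


def build_progression_cohort(
    all_series: Iterable[EyeSeries],
    reliability: ReliabilityCriteria | None = None,
    longitudinal: LongitudinalCriteria | None = None,
    seed: int | None = None,
) -> list[EyeSeries]:
    """Eyes meeting the progression-analysis eligibility, one per patient.

    Same funnel as :func:`build_md_change_cohort`, then requires at least
    ``min_reliable_tests`` surviving tests AND a first-to-last follow-up span
    of at least ``min_followup_years``.
    """
    reliability = reliability or ReliabilityCriteria()
    longitudinal = longitudinal or LongitudinalCriteria()
    rng = np.random.default_rng(seed)
    eligible = []
    n_in = 0
    for s in all_series:
        n_in += 1
        surv = _apply_funnel(
            s,
            reliability,
            learning_n=longitudinal.learning_exclusion_count,
            interval_days=longitudinal.visit_interval_days,
        )
        if (
            len(surv) >= longitudinal.min_reliable_tests
            and surv.followup_years >= longitudinal.min_followup_years
        ):
            eligible.append(surv)
    chosen = _one_eye_per_patient(eligible, rng)
    logger.info(
        "progression cohort: %d eyes in, %d eligible, %d after one-eye selection",
        n_in, len(eligible), len(chosen),
    )
    return chosen


def _mean_sd(values) -> tuple[float, float]:
    a = np.asarray(values, dtype=float)
    if a.size == 1:
        return float(a[0]), 0.0
    return float(a.mean()), float(a.std(ddof=1))


def summarize_cohort(series_list: Sequence[EyeSeries]) -> CohortSummary:
    """Counts plus mean +/- SD of baseline metrics (first included visit per eye)."""
    if not series_list:
        raise ValueError("cannot summarize an empty cohort")
    base = [s.visits[0] for s in series_list]
    age = _mean_sd([b.age_years for b in base])
    md = _mean_sd([b.md_db for b in base])
    psd = _mean_sd([b.psd_db for b in base])
    vfi = _mean_sd([b.vfi_pct for b in base])
    tpe = _mean_sd([len(s) for s in series_list])
    fu = _mean_sd([s.followup_years * 12.0 for s in series_list])
    return CohortSummary(
        n_tests=sum(len(s) for s in series_list),
        n_eyes=len(series_list),
        n_patients=len({s.patient_id for s in series_list}),
        age_mean=age[0], age_sd=age[1],
        md_mean=md[0], md_sd=md[1],
        psd_mean=psd[0], psd_sd=psd[1],
        vfi_mean=vfi[0], vfi_sd=vfi[1],
        tests_per_eye_mean=tpe[0], tests_per_eye_sd=tpe[1],
        followup_months_mean=fu[0], followup_months_sd=fu[1],
    )
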