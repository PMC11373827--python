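"""Synthetic visual-field cohorts with known archetype structure.

Real multicenter perimetry cohorts are not public, so every pipeline stage
is exercised against generated data with full ground truth: a bank of 16
named archetypal TDV patterns built from coordinate masks on the canonical
grid, cross-sectional convex mixtures with Gaussian test-retest noise, and
longitudinal series with clinically spaced visits, a progressing
subpopulation drifting toward an assigned defect pattern, reliability
indices that exercise the cohort filters, and prepended extra-noisy
"learning" tests.

Proxies: the generator's MD is the unweighted mean of the 52 TDVs and its
VFI is an affine map of MD clipped to [0, 100].  The instrument definitions
are proprietary and weighted; the proxies preserve the monotone
relationships the pipeline relies on and are labelled as proxies throughout.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vf_core import (
    EyeSeries,
    VisualFieldTest,
    canonical_grid,
    write_vf_table,
)

__all__ = [
    "ArchetypeBank",
    "SimulationConfig",
    "GroundTruth",
    "canonical_bank",
    "simulate_cross_section",
    "simulate_longitudinal",
    "export_fixture",
]

_COORDS = canonical_grid().active_coords()  # (52, 2) of (x, y)
_START_DATE = _dt.date(2012, 1, 3)

#: fraction of the nominal defect depth used for the shallow "depression" pattern
_MILD_SCALE = 0.4
#: uniform physiologic depression of the "normal" pattern, dB
_NORMAL_LEVEL_DB = -1.0


@dataclass(frozen=True)
class ArchetypeBank:
    """16 named archetypal TDV patterns (k, 52), right-eye convention."""

    patterns: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        P = np.asarray(self.patterns, dtype=float)
        object.__setattr__(self, "patterns", P)
        if P.shape[0] != len(self.labels):
            raise ValueError("one label per pattern required")

    @property
    def k(self) -> int:
        return self.patterns.shape[0]


def _masks() -> dict[str, np.ndarray]:
    x, y = _COORDS[:, 0], _COORDS[:, 1]
    r = np.hypot(x, y)
    annulus = (r > 9.0) & (r <= 22.0)          # Bjerrum-type ring region
    arcuate_sup = annulus & (y > 0) & (x < 15)  # arcs spare the temporal edge
    arcuate_inf = annulus & (y < 0) & (x < 15)
    central = (np.abs(x) <= 9) & (np.abs(y) <= 9)
    return {
        "sup_arcuate": arcuate_sup,
        "sup_nasal_step": (y > 0) & (y <= 9) & (x <= -9),
        "sup_hemifield_sparing": (y > 0) & ~central,
        "sup_altitudinal": y > 0,
        "inf_arcuate": arcuate_inf,
        "inf_nasal": (y < 0) & (x <= -9),
        "inf_hemifield_sparing": (y < 0) & ~central,
        "inf_altitudinal": y < 0,
        "double_arcuate": arcuate_sup | arcuate_inf,
        "inf_nasal_periphery": (x <= -15) & (y < 0),
        "temporal_wedge": x >= 15,
        "ring_scotoma": annulus,
        "total": np.ones(52, dtype=bool),
        "central_scotoma": central,
        "temporal_hemianopsia": x > 0,
        "sup_depression": y >= 9,
    }


def canonical_bank(defect_depth_db: float = -25.0) -> ArchetypeBank:
    """Deterministic 16-pattern bank built from coordinate-mask regions.

    AT1 is the normal field (uniform mild physiologic depression of -1 dB so
    the pattern has a defined direction); AT2-AT5 are superior-hemifield
    defects (AT5 superior altitudinal), AT6-AT9 their inferior counterparts,
    AT10 double arcuate, AT11 temporal wedge, AT12 ring scotoma, AT13 total
    loss, AT14 central scotoma, AT15 temporal hemianopsia, and AT16 a
    shallow superior depression.
    """
    if not defect_depth_db < 0:
        raise ValueError("defect_depth_db must be negative")
    m = _masks()
    # per-pattern depth factor: typical defect depth varies by clinical
    # picture, and mutually non-commensurate depths keep the bank affinely
    # independent (no pattern is an exact vector combination of the others),
    # so noise-free mixtures are uniquely decomposable
    pattern_defs: list[tuple[str, np.ndarray, float]] = [
        ("AT1 normal", np.zeros(52, dtype=bool), 0.0),
        ("AT2 superior arcuate", m["sup_arcuate"], 1.00),
        ("AT3 superior nasal step", m["sup_nasal_step"], 0.85),
        ("AT4 central-sparing superior hemifield", m["sup_hemifield_sparing"], 0.92),
        ("AT5 superior altitudinal", m["sup_altitudinal"], 1.06),
        ("AT6 inferior arcuate", m["inf_arcuate"], 0.96),
        ("AT7 inferonasal", m["inf_nasal"], 0.82),
        ("AT8 central-sparing inferior hemifield", m["inf_hemifield_sparing"], 0.90),
        ("AT9 inferior altitudinal", m["inf_altitudinal"], 1.02),
        ("AT10 double arcuate", m["double_arcuate"], 1.00),
        ("AT11 temporal wedge", m["temporal_wedge"], 0.78),
        ("AT12 ring scotoma", m["ring_scotoma"], 0.94),
        ("AT13 total loss", m["total"], 1.00),
        ("AT14 central scotoma", m["central_scotoma"], 1.08),
        ("AT15 temporal hemianopsia", m["temporal_hemianopsia"], 0.88),
        ("AT16 superior depression", m["sup_depression"], _MILD_SCALE),
    ]
    patterns = np.full((16, 52), 0.0)
    for i, (_, mask, factor) in enumerate(pattern_defs[1:], start=1):
        patterns[i, mask] = factor * defect_depth_db
    x, y = _COORDS[:, 0], _COORDS[:, 1]
    r = np.hypot(x, y)
    # shape shading (same independence point as the depth factors): the
    # normal field dips mildly with eccentricity, altitudinal loss deepens
    # away from the horizontal midline, a central scotoma is deepest at
    # fixation, and the double arcuate breaks through nasally
    patterns[0, :] = _NORMAL_LEVEL_DB * (0.5 + 0.03 * r)
    patterns[4, :] *= np.where(y > 0, 0.85 + 0.3 * y / 21.0, 1.0)
    patterns[8, :] *= np.where(y < 0, 0.85 - 0.3 * y / 21.0, 1.0)
    patterns[13, :] *= np.where(m["central_scotoma"], 1.0 - 0.03 * (r - 4.0), 1.0)
    patterns[9, m["inf_nasal_periphery"]] = _MILD_SCALE * defect_depth_db
    patterns[12, m["central_scotoma"]] = 1.12 * defect_depth_db
    return ArchetypeBank(patterns=patterns, labels=tuple(name for name, _, _ in pattern_defs))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the generated cohorts.

    Defaults emulate the clinical setting the pipeline targets: roughly
    half-yearly visits (uniform 150-210 day gaps), ~1 dB per-location
    test-retest noise, sparse Dirichlet mixing so most fields are dominated
    by few patterns, a progressing subpopulation drifting toward one defect
    pattern, ~10% unreliable tests, and two learning tests per eye.
    """

    n_patients: int = 150
    visits_per_eye: int = 7
    interval_days: tuple[int, int] = (150, 210)
    noise_sd_db: float = 1.0
    dirichlet_alpha: float = 0.3
    pure_fraction: float = 0.15
    progression_fraction: float = 0.3
    progression_rate: float = 0.1        # weight shift per year toward the defect AT
    progression_target_at: int | None = None  # 0-based index; None = random defect AT
    reliability_fail_fraction: float = 0.1
    learning_tests: int = 2
    defect_depth_db: float = -25.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("pure_fraction", "progression_fraction", "reliability_fail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.noise_sd_db < 0 or self.progression_rate < 0:
            raise ValueError("noise_sd_db and progression_rate must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Generator bookkeeping aligned with the returned tests/series order."""

    weights: np.ndarray                       # baseline mixing weights, (n, 16)
    progressing: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    defect_at: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))  # -1 = stable
    drift_per_year: np.ndarray = field(default_factory=lambda: np.empty(0))
    eye_ids: tuple[tuple[str, str], ...] = ()


def _reliability_rates(rng: np.random.Generator, fail: bool) -> tuple[float, float, float]:
    fl = float(rng.uniform(0.0, 0.30))
    fn = float(rng.uniform(0.0, 0.18))
    fp = float(rng.uniform(0.0, 0.18))
    if fail:
        which = int(rng.integers(3))
        if which == 0:
            fl = float(rng.uniform(0.35, 0.80))
        elif which == 1:
            fn = float(rng.uniform(0.22, 0.60))
        else:
            fp = float(rng.uniform(0.22, 0.60))
    return fl, fn, fp


def _render_test(
    *,
    patient_id: str,
    eye: str,
    exam_date: _dt.date,
    age: float,
    w: np.ndarray,
    bank: ArchetypeBank,
    noise_sd: float,
    fail: bool,
    rng: np.random.Generator,
) -> VisualFieldTest:
    tdv = w @ bank.patterns + rng.normal(0.0, noise_sd, size=52)
    tdv = np.clip(tdv, -50.0, 20.0)
    md = float(tdv.mean())                      # MD proxy: unweighted mean TDV
    vfi = float(np.clip(100.0 + 1.5 * md, 0.0, 100.0))  # VFI proxy: affine in MD
    psd = float(tdv.std(ddof=0))
    fl, fn, fp = _reliability_rates(rng, fail)
    return VisualFieldTest(
        patient_id=patient_id,
        eye=eye,
        exam_date=exam_date,
        age_years=age,
        fixation_loss_rate=fl,
        false_negative_rate=fn,
        false_positive_rate=fp,
        md_db=md,
        psd_db=psd,
        vfi_pct=vfi,
        tdv=tdv,
    )


def _draw_weights(rng: np.random.Generator, k: int, config: SimulationConfig) -> np.ndarray:
    if rng.uniform() < config.pure_fraction:
        w = np.zeros(k)
        w[int(rng.integers(k))] = 1.0
        return w
    return rng.dirichlet(np.full(k, config.dirichlet_alpha))


def simulate_cross_section(
    bank: ArchetypeBank,
    n: int,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[list[VisualFieldTest], GroundTruth]:
    """n independent single-visit tests: noisy convex mixtures of the bank.

    A ``pure_fraction`` share of rows sits exactly at a hull corner (a single
    archetype) so the corners are represented in the sample.
    """
    config = config or SimulationConfig()
    master = seed if seed is not None else config.seed
    k = bank.k
    tests: list[VisualFieldTest] = []
    weights = np.empty((n, k))
    for i in range(n):
        rng = np.random.default_rng([0, i] if master is None else [master, 0, i])
        w = _draw_weights(rng, k, config)
        weights[i] = w
        fail = rng.uniform() < config.reliability_fail_fraction
        tests.append(
            _render_test(
                patient_id=f"X{i:05d}",
                eye="R",
                exam_date=_START_DATE,
                age=float(np.clip(rng.normal(55.5, 17.0), 20.0, 95.0)),
                w=w,
                bank=bank,
                noise_sd=config.noise_sd_db,
                fail=fail,
                rng=rng,
            )
        )
    return tests, GroundTruth(weights=weights)


def _drifted_weights(w0: np.ndarray, target: int, rate: float, t_years: float) -> np.ndarray:
    """Shift weight toward ``target`` linearly in time, then renormalize."""
    shift = rate * t_years
    w = w0.copy()
    w[target] += shift
    return w / w.sum()


def simulate_longitudinal(
    bank: ArchetypeBank,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[list[EyeSeries], GroundTruth]:
    """Two-eye longitudinal cohort with a progressing subpopulation.

    Each patient contributes both eyes with independent mixing weights and
    progression status, so downstream one-eye-per-patient selection is
    exercised.  Progressing eyes shift weight toward their assigned defect
    archetype at ``progression_rate`` per year (renormalized), which induces
    an MD decline through the defect pattern's depth.  ``learning_tests``
    extra-noisy visits are prepended before the analysis visits.
    """
    config = config or SimulationConfig()
    master = seed if seed is not None else config.seed
    k = bank.k
    defect_choices = np.arange(1, k)  # any non-normal pattern
    n_eyes = 2 * config.n_patients
    n_prog = int(np.ceil(config.progression_fraction * n_eyes))
    master_rng = np.random.default_rng([2] if master is None else [master, 2])
    prog_set = set(master_rng.choice(n_eyes, size=n_prog, replace=False).tolist())
    series: list[EyeSeries] = []
    weights, progressing, defect_at, drift, eye_ids = [], [], [], [], []
    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        for e, eye in enumerate(("L", "R")):
            rng = np.random.default_rng([1, p, e] if master is None else [master, 1, p, e])
            w0 = _draw_weights(rng, k, config)
            prog = (2 * p + e) in prog_set
            target = -1
            if prog:
                target = (
                    int(rng.choice(defect_choices))
                    if config.progression_target_at is None
                    else int(config.progression_target_at)
                )
            age0 = float(np.clip(rng.normal(55.5, 17.0), 20.0, 95.0))
            n_total = config.learning_tests + config.visits_per_eye
            gaps = rng.integers(
                config.interval_days[0], config.interval_days[1] + 1, size=n_total - 1
            )
            offsets = np.concatenate([[0], np.cumsum(gaps)])
            start = _START_DATE + _dt.timedelta(days=int(rng.integers(0, 365)))
            visits = []
            for v in range(n_total):
                is_learning = v < config.learning_tests
                # analysis-visit clock starts at the first post-learning visit
                t_years = max(0.0, (offsets[v] - offsets[config.learning_tests]) / 365.25)
                w = (
                    _drifted_weights(w0, target, config.progression_rate, t_years)
                    if prog and not is_learning
                    else w0
                )
                fail = rng.uniform() < config.reliability_fail_fraction
                visits.append(
                    _render_test(
                        patient_id=pid,
                        eye=eye,
                        exam_date=start + _dt.timedelta(days=int(offsets[v])),
                        age=age0 + offsets[v] / 365.25,
                        w=w,
                        bank=bank,
                        noise_sd=config.noise_sd_db * (2.0 if is_learning else 1.0),
                        fail=fail,
                        rng=rng,
                    )
                )
            series.append(EyeSeries(patient_id=pid, eye=eye, visits=tuple(visits)))
            weights.append(w0)
            progressing.append(prog)
            defect_at.append(target)
            drift.append(config.progression_rate if prog else 0.0)
            eye_ids.append((pid, eye))
    truth = GroundTruth(
        weights=np.vstack(weights),
        progressing=np.array(progressing, dtype=bool),
        defect_at=np.array(defect_at, dtype=int),
        drift_per_year=np.array(drift),
        eye_ids=tuple(eye_ids),
    )
    return series, truth


def export_fixture(series: list[EyeSeries], truth: GroundTruth, out_dir) -> None:
    """Write a cohort CSV (vf.csv) plus a ground-truth CSV (truth.csv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tests = [v for s in series for v in s.visits]
    write_vf_table(tests, out / "vf.csv")
    rows = []
    for i, (pid, eye) in enumerate(truth.eye_ids):
        row = {
            "patient_id": pid,
            "eye": eye,
            "progressing": int(truth.progressing[i]),
            "defect_at": int(truth.defect_at[i]),
            "drift_per_year": float(truth.drift_per_year[i]),
        }
        for j, w in enumerate(truth.weights[i]):
            row[f"w{j + 1:02d}"] = round(float(w), 8)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "truth.csv", index=False)
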