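"""Per-eye slope estimation and visual-field progression criteria.

For an eye followed over time, ordinary least squares gives the rate of
change (per year) of any per-visit quantity: mean deviation (MD), Visual
Field Index (VFI), each of the 52 pointwise TDVs, and each of the k
decomposition coefficients (slope_AA / slope_FCM).

Three standard trend-based progression criteria are implemented:

- MD slope:  progressing iff the slope is negative with p < 0.05;
- VFI slope: same rule on the VFI (%/year);
- PLR (pointwise linear regression): progressing iff at least 3 locations
  have TDV slope <= -1.0 dB/year with p < 0.01 (boundary inclusive on the
  slope, strict on p).

p-value conventions for degenerate fits: an exactly-determined 2-visit line
has no residual degrees of freedom and reports p = 1 (it can never satisfy a
p-threshold); a perfect fit with n > 2 visits reports p = 0 (the continuous
limit of an unbounded t statistic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .archetypal import ArchetypeSet, aa_decompose_matrix
from .fuzzy import FcmConfig, hybrid_decompose_matrix
from .vf_core import EyeSeries

__all__ = [
    "SlopeFit",
    "ProgressionAssessment",
    "ols_slope",
    "ols_slopes_columns",
    "aa_decomposer",
    "fcm_decomposer",
    "coefficient_slopes",
    "md_progression",
    "vfi_progression",
    "plr_progression",
    "assess_progression",
    "baseline_deltas",
    "slope_md_relation",
]

#: callable mapping an (n, 52) TDV matrix to an (n, k) coefficient matrix
Decomposer = Callable[[np.ndarray], np.ndarray]

MD_VFI_P_THRESHOLD = 0.05
PLR_SLOPE_THRESHOLD = -1.0   # dB/year, inclusive
#: absolute slack on the PLR slope comparison so a decay of exactly
#: -1.0 dB/year counts regardless of last-ulp rounding in the OLS arithmetic
PLR_SLOPE_EPS = 1e-9
PLR_P_THRESHOLD = 0.01
PLR_MIN_POINTS = 3


def _plr_point_progresses(fit: "SlopeFit") -> bool:
    return (
        fit.slope <= PLR_SLOPE_THRESHOLD + PLR_SLOPE_EPS
        and fit.p_value < PLR_P_THRESHOLD
    )


@dataclass(frozen=True)
class SlopeFit:
    """An OLS line: slope (units/year), intercept, two-sided p on the slope, n."""

    slope: float
    intercept: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ProgressionAssessment:
    """The three progression criteria plus per-archetype slope features for one eye."""

    md_criterion: bool
    vfi_criterion: bool
    plr_criterion: bool
    plr_progressing_points: int
    md_fit: SlopeFit
    vfi_fit: SlopeFit
    slope_features_aa: tuple[SlopeFit, ...]
    slope_features_fcm: tuple[SlopeFit, ...]

    def __post_init__(self) -> None:
        if self.plr_criterion != (self.plr_progressing_points >= PLR_MIN_POINTS):
            raise ValueError("plr_criterion inconsistent with progressing-point count")


def _ols_columns(t: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form OLS of each column of Y on t: (slopes, intercepts, p_values)."""
    n = len(t)
    tb = t - t.mean()
    stt = float(tb @ tb)
    if n < 2 or stt <= 0.0:
        raise ValueError("need >= 2 distinct time points")
    ybar = Y.mean(axis=0)
    slopes = (tb @ (Y - ybar)) / stt  # centered: exactly 0 for constant y
    intercepts = ybar - slopes * t.mean()
    resid = Y - (np.outer(t, slopes) + intercepts)
    sse = np.einsum("ij,ij->j", resid, resid)
    if n == 2:
        p = np.ones_like(slopes)
    else:
        scale = np.maximum(np.einsum("ij,ij->j", Y, Y), 1.0)
        perfect = sse <= 1e-12 * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sse / ((n - 2) * stt))
            tstat = np.where(se > 0, slopes / np.where(se > 0, se, 1.0), np.inf)
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        p = np.where(perfect, 0.0, p)
    return slopes, intercepts, p


def ols_slope(t_years: Sequence[float], y: Sequence[float]) -> SlopeFit:
    """OLS line of ``y`` on ``t_years`` with a two-sided t-test on the slope."""
    t = np.asarray(t_years, dtype=float)
    y = np.asarray(y, dtype=float)
    s, b, p = _ols_columns(t, y[:, None])
    return SlopeFit(slope=float(s[0]), intercept=float(b[0]), p_value=float(p[0]), n=len(t))


def ols_slopes_columns(t_years: np.ndarray, Y: np.ndarray) -> list[SlopeFit]:
    """Column-wise :func:`ols_slope` for an (n_visits, m) matrix."""
    t = np.asarray(t_years, dtype=float)
    Y = np.asarray(Y, dtype=float)
    s, b, p = _ols_columns(t, Y)
    n = len(t)
    return [SlopeFit(float(si), float(bi), float(pi), n) for si, bi, pi in zip(s, b, p)]


def aa_decomposer(archetypes: ArchetypeSet) -> Decomposer:
    """Decomposer computing AA simplex-projection coefficients per visit."""
    def decompose(X: np.ndarray) -> np.ndarray:
        W, _ = aa_decompose_matrix(X, archetypes)
        return W
    decompose.method = "AA"  # type: ignore[attr-defined]
    return decompose


def fcm_decomposer(archetypes: ArchetypeSet, config: FcmConfig | None = None) -> Decomposer:
    """Decomposer computing FCM membership coefficients per visit."""
    cfg = config or FcmConfig()
    def decompose(X: np.ndarray) -> np.ndarray:
        return hybrid_decompose_matrix(X, archetypes, cfg)
    decompose.method = "FCM"  # type: ignore[attr-defined]
    return decompose


def coefficient_slopes(series: EyeSeries, decomposer: Decomposer) -> list[SlopeFit]:
    """OLS slope of each decomposition coefficient over the eye's visit times."""
    W = decomposer(series.tdv_matrix())
    return ols_slopes_columns(series.t_years, W)


def md_progression(series: EyeSeries) -> tuple[bool, SlopeFit]:
    """Progressing iff the MD slope is negative with p < 0.05 (strict)."""
    fit = ols_slope(series.t_years, series.md_values())
    return fit.slope < 0.0 and fit.p_value < MD_VFI_P_THRESHOLD, fit


def vfi_progression(series: EyeSeries) -> tuple[bool, SlopeFit]:
    """Progressing iff the VFI slope is negative with p < 0.05 (strict)."""
    fit = ols_slope(series.t_years, series.vfi_values())
    return fit.slope < 0.0 and fit.p_value < MD_VFI_P_THRESHOLD, fit


def plr_progression(series: EyeSeries) -> tuple[bool, list[SlopeFit]]:
    """Pointwise linear regression over the 52 locations.

    Progressing iff >= 3 locations have slope <= -1.0 dB/year (inclusive)
    with p < 0.01 (strict).
    """
    fits = ols_slopes_columns(series.t_years, series.tdv_matrix())
    n_prog = sum(1 for f in fits if _plr_point_progresses(f))
    return n_prog >= PLR_MIN_POINTS, fits


def assess_progression(
    series: EyeSeries,
    archetypes: ArchetypeSet,
    fcm_config: FcmConfig | None = None,
) -> ProgressionAssessment:
    """All three criteria plus both methods' coefficient-slope features."""
    md_flag, md_fit = md_progression(series)
    vfi_flag, vfi_fit = vfi_progression(series)
    plr_flag, plr_fits = plr_progression(series)
    n_prog = sum(1 for f in plr_fits if _plr_point_progresses(f))
    return ProgressionAssessment(
        md_criterion=md_flag,
        vfi_criterion=vfi_flag,
        plr_criterion=plr_flag,
        plr_progressing_points=n_prog,
        md_fit=md_fit,
        vfi_fit=vfi_fit,
        slope_features_aa=tuple(coefficient_slopes(series, aa_decomposer(archetypes))),
        slope_features_fcm=tuple(
            coefficient_slopes(series, fcm_decomposer(archetypes, fcm_config))
        ),
    )


def baseline_deltas(
    series: EyeSeries, decomposer: Decomposer
) -> tuple[np.ndarray, np.ndarray]:
    """Per-visit deltas from baseline: (n_visits-1, k) coefficient differences
    and (n_visits-1,) MD differences, one row per non-baseline visit."""
    if len(series) < 2:
        return np.empty((0, 0)), np.empty(0)
    W = decomposer(series.tdv_matrix())
    md = series.md_values()
    return W[1:] - W[0], md[1:] - md[0]


@dataclass(frozen=True)
class SlopeMdRelation:
    """Spearman correlation and OLS line of MD slope on a coefficient slope."""

    rho: float
    p_value: float
    line_slope: float
    line_intercept: float
    n: int


def slope_md_relation(
    at_slopes: Sequence[float], md_slopes: Sequence[float]
) -> SlopeMdRelation:
    """Relate one archetype's coefficient slopes to MD slopes across eyes.

    Diffuse-loss archetypes give steep fitted lines (their coefficient drift
    moves the global MD); focal-loss archetypes give near-horizontal lines.
    """
    x = np.asarray(at_slopes, dtype=float)
    y = np.asarray(md_slopes, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired slope observations")
    rho, p = stats.spearmanr(x, y)
    fit = ols_slope(x, y)  # OLS of MD slope on AT slope
    return SlopeMdRelation(
        rho=float(rho), p_value=float(p),
        line_slope=fit.slope, line_intercept=fit.intercept, n=len(x),
    )
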