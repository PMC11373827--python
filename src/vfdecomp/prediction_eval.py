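"""MD-change prediction and diagnostic evaluation of slope features.

Two evaluation protocols:

1. *Prediction*: MD change from baseline is regressed on the 16
   decomposition-coefficient deltas (AA and FCM arms share identical
   train/test splits within each repeat), scored by mean squared error and
   Pearson correlation over repeated random splits, with paired two-sided
   t-tests across repeats comparing the two arms.

2. *Diagnosis*: per-archetype coefficient slopes are used as scores against
   the three progression-criterion labels; AUCs come from the Mann-Whitney
   pair-count estimator with DeLong variance for confidence intervals, and
   paired curves on the same cases are compared with the DeLong test.  The
   default score orientation treats a coefficient *increase* as progressive
   (a progressing eye gains weight on its defect pattern); the orientation
   is configurable because the normal pattern's coefficient moves the
   opposite way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .archetypal import ArchetypeSet
from .fuzzy import FcmConfig
from .longitudinal import (
    Decomposer,
    aa_decomposer,
    baseline_deltas,
    coefficient_slopes,
    fcm_decomposer,
    md_progression,
    plr_progression,
    vfi_progression,
)
from .vf_core import EyeSeries

__all__ = [
    "PredictionEval",
    "RocResult",
    "mse",
    "pcc",
    "build_instances",
    "repeated_eval",
    "roc_auc",
    "delong_compare",
    "progression_auc_table",
]

_MODELS = ("knn", "random_forest", "gradient_boosting")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def mse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean squared error: mean of (y_i - x_i)^2."""
    y = np.asarray(actual, dtype=float)
    x = np.asarray(predicted, dtype=float)
    if y.shape != x.shape or y.size == 0:
        raise ValueError("actual and predicted must have equal nonzero length")
    return float(np.mean((y - x) ** 2))


def pcc(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Pearson correlation coefficient by the direct sum formula."""
    y = np.asarray(actual, dtype=float)
    x = np.asarray(predicted, dtype=float)
    if y.shape != x.shape or y.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0.0:
        raise ValueError("correlation undefined: zero variance")
    return float((xc @ yc) / den)


# ---------------------------------------------------------------------------
# Instance construction and repeated evaluation
# ---------------------------------------------------------------------------

def build_instances(
    cohort: Sequence[EyeSeries], decomposer: Decomposer
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-eye baseline deltas into a feature table.

    Returns (features, labels, eye_index): one row per non-baseline visit,
    features = the k coefficient deltas, label = the MD delta, eye_index =
    the position of the source eye in ``cohort``.  AA and FCM tables built
    from the same cohort share row identity (same visits, same labels).
    """
    if not cohort:
        raise ValueError("empty cohort")
    feats, labels, idx = [], [], []
    for i, s in enumerate(cohort):
        dw, dmd = baseline_deltas(s, decomposer)
        if dw.size:
            feats.append(dw)
            labels.append(dmd)
            idx.append(np.full(len(dmd), i))
    if not feats:
        raise ValueError("no eye in the cohort has >= 2 visits")
    return np.vstack(feats), np.concatenate(labels), np.concatenate(idx)


@dataclass(frozen=True)
class PredictionEval:
    """Repeated-split performance of one model on one decomposition method."""

    model: str
    method: str  # "AA" | "FCM"
    mse_values: np.ndarray
    pcc_values: np.ndarray

    @property
    def mse_mean(self) -> float:
        return float(np.mean(self.mse_values))

    @property
    def mse_sd(self) -> float:
        return float(np.std(self.mse_values, ddof=1)) if len(self.mse_values) > 1 else 0.0

    @property
    def pcc_mean(self) -> float:
        return float(np.mean(self.pcc_values))

    @property
    def pcc_sd(self) -> float:
        return float(np.std(self.pcc_values, ddof=1)) if len(self.pcc_values) > 1 else 0.0


def _make_model(name: str, seed: int):
    if name == "knn":
        from sklearn.neighbors import KNeighborsRegressor

        return KNeighborsRegressor(n_neighbors=5)
    if name == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(n_estimators=500, random_state=seed, n_jobs=1)
    if name == "gradient_boosting":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(
            n_estimators=100, learning_rate=0.1, random_state=seed, verbose=-1
        )
    raise ValueError(f"unknown model {name!r}; choose from {_MODELS}")


def repeated_eval(
    instances_aa: tuple[np.ndarray, np.ndarray],
    instances_fcm: tuple[np.ndarray, np.ndarray],
    model: str = "gradient_boosting",
    *,
    repeats: int = 30,
    train_fraction: float = 0.70,
    seed: int | None = None,
) -> tuple[PredictionEval, PredictionEval, dict[str, float]]:
    """Repeated shared-split evaluation of AA vs FCM features.

    Each repeat draws one random train/test split applied identically to
    both feature tables (required for the paired comparison), fits the named
    regressor per arm, and records test MSE and PCC.  Returns the two
    evaluations plus paired two-sided t-test p-values across repeats
    (``{"mse": p, "pcc": p}``).
    """
    Xa, ya = (np.asarray(a, dtype=float) for a in instances_aa)
    Xf, yf = (np.asarray(a, dtype=float) for a in instances_fcm)
    if len(ya) != len(yf) or not np.allclose(ya, yf):
        raise ValueError("AA and FCM instance tables must share row identity")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if repeats < 2:
        raise ValueError("need >= 2 repeats for the paired t-test")
    n = len(ya)
    n_train = max(1, int(round(train_fraction * n)))
    rng = np.random.default_rng(seed)
    rec = {"AA": ([], []), "FCM": ([], [])}
    for r in range(repeats):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        mseed = int(rng.integers(2**31 - 1))
        for method, X in (("AA", Xa), ("FCM", Xf)):
            est = _make_model(model, mseed)
            est.fit(X[tr], ya[tr])
            pred = est.predict(X[te])
            rec[method][0].append(mse(ya[te], pred))
            rec[method][1].append(pcc(ya[te], pred))
    out = {
        m: PredictionEval(
            model=model, method=m,
            mse_values=np.array(rec[m][0]), pcc_values=np.array(rec[m][1]),
        )
        for m in ("AA", "FCM")
    }
    pvals = {}
    for metric in ("mse", "pcc"):
        a = getattr(out["AA"], f"{metric}_values")
        f = getattr(out["FCM"], f"{metric}_values")
        d = a - f
        if np.allclose(d, 0.0):
            pvals[metric] = 1.0
        else:
            pvals[metric] = float(stats.ttest_rel(a, f).pvalue)
    return out["AA"], out["FCM"], pvals


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    """AUC with its DeLong 95% confidence interval and class counts."""

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties averaged) used by the fast DeLong algorithm."""
    return stats.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    """AUC plus the per-case placement values V10 (positives), V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_s = np.concatenate([pos, neg])
    r_all = _midrank(all_s)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return float(auc), v10, v01


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """AUC by the Mann-Whitney pair-count estimator (ties count 1/2).

    Orientation: higher score = more progression.  The 95% CI uses the
    DeLong variance, clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    auc, v10, v01 = _delong_placements(s, y)
    m, n = (y == 1).sum(), (y == 0).sum()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return RocResult(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=int(m),
        n_neg=int(n),
    )


def delong_compare(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> float:
    """DeLong paired test for two correlated ROC curves; two-sided p.

    Both score vectors must be computed on the same cases.  Identical score
    vectors (zero AUC difference, zero variance) give p = 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("score vectors and labels must share length")
    auc_a, v10a, v01a = _delong_placements(sa, y)
    auc_b, v10b, v01b = _delong_placements(sb, y)
    m, n = (y == 1).sum(), (y == 0).sum()
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2.0 * S[0, 1]
    diff = auc_a - auc_b
    if var <= 1e-16:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Table 5-shaped progression evaluation
# ---------------------------------------------------------------------------

def progression_auc_table(
    cohort: Sequence[EyeSeries],
    archetypes: ArchetypeSet,
    fcm_config: FcmConfig | None = None,
    *,
    orientation: str = "increase",
) -> pd.DataFrame:
    """Per-archetype, per-criterion AUCs of slope_AA vs slope_FCM.

    Scores are the coefficient slopes; with the default
    ``orientation="increase"`` a rising coefficient scores as more
    progressive (defect patterns gain weight as an eye progresses), while
    ``"decrease"`` negates the scores (appropriate when reading the normal
    pattern's coefficient).  For each of the k archetypes and each criterion
    (MD slope, VFI slope, PLR) the table holds both methods' AUCs with
    DeLong 95% CIs and the paired DeLong p; criteria with a single label
    class yield NaN cells rather than an error.
    """
    if orientation not in ("increase", "decrease"):
        raise ValueError("orientation must be 'increase' or 'decrease'")
    sign = 1.0 if orientation == "increase" else -1.0
    k = archetypes.k
    dec_aa = aa_decomposer(archetypes)
    dec_fcm = fcm_decomposer(archetypes, fcm_config)
    slopes_aa = np.empty((len(cohort), k))
    slopes_fcm = np.empty((len(cohort), k))
    labels = {"md_slope": [], "vfi_slope": [], "plr": []}
    for i, s in enumerate(cohort):
        slopes_aa[i] = [f.slope for f in coefficient_slopes(s, dec_aa)]
        slopes_fcm[i] = [f.slope for f in coefficient_slopes(s, dec_fcm)]
        labels["md_slope"].append(int(md_progression(s)[0]))
        labels["vfi_slope"].append(int(vfi_progression(s)[0]))
        labels["plr"].append(int(plr_progression(s)[0]))
    rows = []
    for j in range(k):
        for crit, lab in labels.items():
            y = np.asarray(lab)
            row: dict[str, object] = {"archetype": j + 1, "criterion": crit}
            if y.min() == y.max():  # single class: undefined cells
                row.update({c: float("nan") for c in (
                    "auc_aa", "ci_aa_low", "ci_aa_high",
                    "auc_fcm", "ci_fcm_low", "ci_fcm_high", "p_delong",
                )})
            else:
                sa = sign * slopes_aa[:, j]
                sf = sign * slopes_fcm[:, j]
                ra = roc_auc(sa, y)
                rf = roc_auc(sf, y)
                row.update(
                    auc_aa=ra.auc, ci_aa_low=ra.ci_low, ci_aa_high=ra.ci_high,
                    auc_fcm=rf.auc, ci_fcm_low=rf.ci_low, ci_fcm_high=rf.ci_high,
                    p_delong=delong_compare(sa, sf, y),
                )
            rows.append(row)
    return pd.DataFrame(rows)
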