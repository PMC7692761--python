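"""One-class SIMCA authenticity modeling.

Implements the alternative-SIMCA reduced-distance rule (accept iff
sqrt((Q/Q_lim)^2 + (T2/T2_lim)^2) <= sqrt(2)), cross-validated complexity
selection under several criteria, data-driven SIMCA (scaled chi-square
distances with moment-estimated degrees of freedom) and ROC-driven joint
selection of complexity and significance level.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .spectra import SpectraMatrix

__all__ = [
    "PCAClassModel",
    "DistancePair",
    "ClassMetrics",
    "CVResult",
    "DDSIMCAModel",
    "ROCResult",
    "fit_class_model",
    "t2_limit",
    "q_limit",
    "distances",
    "classify",
    "cv_class_model",
    "select_components",
    "class_metrics",
    "ddsimca_fit",
    "ddsimca_classify",
    "estimate_dof",
    "roc_auc",
    "roc_simca",
    "save_model",
    "load_model",
]

SQRT2 = math.sqrt(2.0)
_BOUNDARY_TOL = 1e-12  # boundary points (d_red == sqrt(2)) are accepted
_Q_LIM_FLOOR = 1e-30  # degenerate perfect-fit models get a tiny positive Q_lim


@dataclass
class PCAClassModel:
    """Disjoint PCA model of the target class with its acceptance limits."""

    mean: np.ndarray
    loadings: np.ndarray  # p x A, orthonormal columns
    score_scale: np.ndarray  # per-component calibration score variance
    a: int
    n_cal: int
    alpha: float
    t2_lim: float
    q_lim: float
    q_moments: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.t2_lim <= 0 or self.q_lim <= 0:
            raise ValueError("limits must be positive")


@dataclass(frozen=True)
class DistancePair:
    """Score and orthogonal distances of one sample, raw and reduced."""

    q: float
    t2: float
    q_red: float
    t2_red: float
    d_red: float


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    n_target: int
    tn: int
    n_nontarget: int
    sensitivity: float
    specificity: float
    efficiency: float
    sensitivity_pct: int
    specificity_pct: int
    efficiency_pct: int


@dataclass
class CVResult:
    """Per-complexity cross-validation summary."""

    a_values: list[int]
    sensitivity_cv: dict[int, float]
    rmsecv: dict[int, float]
    specificity_cv: dict[int, float] | None = None
    efficiency_cv: dict[int, float] | None = None
    fold_plan: str = "venetian blinds, 10 splits"


@dataclass
class DDSIMCAModel:
    """Data-driven SIMCA model: chi-square combined-distance rule."""

    base: PCAClassModel
    h0: float
    v0: float
    nh: int
    nv: int
    c_crit: float
    calibration_sensitivity: float


@dataclass
class ROCResult:
    auc: dict[int, float]
    chosen_a: int
    chosen_alpha: float
    operating_threshold: float


def t2_limit(a: int, n: int, alpha: float) -> float:
    """Hotelling T2 control limit: a(n-1)/(n-a) * F_{1-alpha}(a, n-a)."""
    if not (n > a >= 1):
        raise ValueError(f"need n > a >= 1, got a={a}, n={n}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(
        a * (n - 1) / (n - a) * stats.f.ppf(1.0 - alpha, a, n - a)
    )


def q_limit(q_moments: tuple[float, float], alpha: float) -> float:
    """Moment-matched scaled chi-square limit for the residual statistic.

    g = var / (2 mean), h = 2 mean^2 / var; limit = g * chi2_{1-alpha}(h).
    """
    mean, var = q_moments
    if mean <= 0:
        raise ValueError("Q mean must be positive")
    if var <= 0:
        raise ValueError(
            "Q variance is zero (all residuals identical); limit undefined"
        )
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    g = var / (2.0 * mean)
    h = 2.0 * mean**2 / var
    return float(g * stats.chi2.ppf(1.0 - alpha, h))


def _pca(x: np.ndarray, a: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered PCA via SVD: (mean, loadings p x a, calibration scores)."""
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(x.shape) * np.finfo(float).eps))
    if a > rank:
        raise ValueError(f"requested {a} components but data rank is {rank}")
    loadings = vt[:a].T
    scores = xc @ loadings
    return mean, loadings, scores


def fit_class_model(
    x_target: SpectraMatrix | np.ndarray, a: int, alpha: float = 0.05
) -> PCAClassModel:
    """Fit the one-class PCA model with T2 and Q acceptance limits."""
    x = x_target.values if isinstance(x_target, SpectraMatrix) else np.asarray(
        x_target, dtype=float
    )
    n = x.shape[0]
    if a < 1:
        raise ValueError("number of components must be >= 1")
    if n <= a + 1:
        raise ValueError(f"need more than a+1={a + 1} calibration spectra")
    mean, loadings, scores = _pca(x, a)
    score_scale = scores.var(axis=0, ddof=1)
    if np.any(score_scale <= 0):
        raise ValueError("degenerate component with zero score variance")
    resid = (x - mean) - scores @ loadings.T
    q = np.sum(resid**2, axis=1)
    q_mean = float(q.mean())
    q_var = float(q.var(ddof=1))
    t2l = t2_limit(a, n, alpha)
    # perfect-subspace calibration: residuals are numerically zero and the
    # chi-square limit is undefined; floor Q_lim above the numerical noise
    # of the projection so in-subspace points keep q_red ~ 0
    floor = max(_Q_LIM_FLOOR, 1e-16 * x.shape[1] * float(np.mean((x - mean) ** 2)))
    try:
        ql = q_limit((q_mean, q_var), alpha)
    except ValueError:
        ql = floor
    ql = max(ql, floor)
    return PCAClassModel(
        mean=mean,
        loadings=loadings,
        score_scale=score_scale,
        a=a,
        n_cal=n,
        alpha=alpha,
        t2_lim=t2l,
        q_lim=ql,
        q_moments=(q_mean, q_var),
    )


def _distance_arrays(
    model: PCAClassModel, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.mean.size:
        raise ValueError(
            f"sample has {x.shape[1]} variables, model expects "
            f"{model.mean.size}"
        )
    xc = x - model.mean
    scores = xc @ model.loadings
    t2 = np.sum(scores**2 / model.score_scale, axis=1)
    resid = xc - scores @ model.loadings.T
    q = np.sum(resid**2, axis=1)
    return q, t2


def distances(model: PCAClassModel, x: np.ndarray) -> DistancePair:
    """Score/orthogonal distances of one sample and the reduced forms."""
    q, t2 = _distance_arrays(model, np.atleast_2d(x))
    q_red = float(q[0] / model.q_lim)
    t2_red = float(t2[0] / model.t2_lim)
    return DistancePair(
        q=float(q[0]),
        t2=float(t2[0]),
        q_red=q_red,
        t2_red=t2_red,
        d_red=math.hypot(q_red, t2_red),
    )


def classify(model: PCAClassModel, x: np.ndarray) -> tuple[bool, DistancePair]:
    """Accept iff the reduced combined distance is <= sqrt(2)."""
    d = distances(model, x)
    return d.d_red <= SQRT2 + _BOUNDARY_TOL, d


def d_red_matrix(model: PCAClassModel, x: np.ndarray) -> np.ndarray:
    """Vectorized reduced combined distance for many samples."""
    q, t2 = _distance_arrays(model, x)
    return np.hypot(q / model.q_lim, t2 / model.t2_lim)


def accept_mask(model: PCAClassModel, x: np.ndarray) -> np.ndarray:
    return d_red_matrix(model, x) <= SQRT2 + _BOUNDARY_TOL


def _venetian_folds(
    n: int, n_folds: int, groups: list | np.ndarray | None = None
) -> np.ndarray:
    """Fold index per row; grouped rows share the fold of their group."""
    if groups is None:
        return np.arange(n) % n_folds
    groups = list(groups)
    if len(groups) != n:
        raise ValueError("one group label per row required")
    order: dict = {}
    for g in groups:
        if g not in order:
            order[g] = len(order)
    return np.array([order[g] % n_folds for g in groups])


def cv_class_model(
    x_target: SpectraMatrix | np.ndarray,
    a_range: list[int] | range,
    alpha: float = 0.05,
    x_nontarget: SpectraMatrix | np.ndarray | None = None,
    groups: list | None = None,
    n_folds: int = 10,
) -> CVResult:
    """Venetian-blind cross-validation of the one-class model.

    Per complexity A: held-out target acceptance rate (Sensitivity_CV),
    RMSECV = sqrt(sum of held-out Q / (n p)), and, when non-target spectra
    are supplied, the mean per-fold rejection rate (Specificity_CV) and
    the geometric-mean Efficiency_CV.
    """
    x = x_target.values if isinstance(x_target, SpectraMatrix) else np.asarray(
        x_target, dtype=float
    )
    xn = None
    if x_nontarget is not None:
        xn = (
            x_nontarget.values
            if isinstance(x_nontarget, SpectraMatrix)
            else np.asarray(x_nontarget, dtype=float)
        )
    n, p = x.shape
    a_values = sorted(int(a) for a in a_range)
    folds = _venetian_folds(n, n_folds, groups)
    fold_ids = np.unique(folds)
    a_max = max(a_values)
    for f in fold_ids:
        if int(np.sum(folds != f)) < a_max + 2:
            raise ValueError(
                f"fold {f}: fewer than A+2 training spectra for A={a_max}"
            )

    sens = {a: 0.0 for a in a_values}
    q_sum = {a: 0.0 for a in a_values}
    spec = {a: [] for a in a_values} if xn is not None else None
    for f in fold_ids:
        train = folds != f
        test = ~train
        for a in a_values:
            model = fit_class_model(x[train], a, alpha)
            d = d_red_matrix(model, x[test])
            sens[a] += float(np.sum(d <= SQRT2 + _BOUNDARY_TOL))
            q, _ = _distance_arrays(model, x[test])
            q_sum[a] += float(q.sum())
            if spec is not None:
                dn = d_red_matrix(model, xn)
                spec[a].append(float(np.mean(dn > SQRT2 + _BOUNDARY_TOL)))

    sensitivity_cv = {a: sens[a] / n for a in a_values}
    rmsecv = {a: math.sqrt(q_sum[a] / (n * p)) for a in a_values}
    specificity_cv = None
    efficiency_cv = None
    if spec is not None:
        specificity_cv = {a: float(np.mean(spec[a])) for a in a_values}
        efficiency_cv = {
            a: math.sqrt(sensitivity_cv[a] * specificity_cv[a])
            for a in a_values
        }
    return CVResult(
        a_values=a_values,
        sensitivity_cv=sensitivity_cv,
        rmsecv=rmsecv,
        specificity_cv=specificity_cv,
        efficiency_cv=efficiency_cv,
        fold_plan=f"venetian blinds, {n_folds} splits",
    )


def first_rmsecv_minimum(
    a_values: list[int], rmsecv: list[float], rel_tol: float = 0.01
) -> int:
    """Smallest A at a local RMSECV minimum or where the curve flattens
    (relative decrease vs the previous A below ``rel_tol``)."""
    for i in range(1, len(a_values)):
        prev, cur = rmsecv[i - 1], rmsecv[i]
        if cur >= prev:
            return a_values[i - 1]
        if prev > 0 and (prev - cur) / prev < rel_tol:
            return a_values[i]
    return a_values[-1]


def select_components(cv: CVResult, criterion: str) -> int:
    """Pick the model complexity; ties break toward the smallest A."""
    a_values = cv.a_values
    if criterion == "max_sensitivity_cv":
        curve = [cv.sensitivity_cv[a] for a in a_values]
        return a_values[int(np.argmax(curve))]
    if criterion == "min_rmsecv":
        return first_rmsecv_minimum(
            a_values, [cv.rmsecv[a] for a in a_values]
        )
    if criterion == "max_efficiency_cv":
        if cv.efficiency_cv is None:
            raise ValueError(
                "efficiency criterion requires non-target spectra in CV"
            )
        curve = [cv.efficiency_cv[a] for a in a_values]
        return a_values[int(np.argmax(curve))]
    raise ValueError(f"unknown criterion {criterion!r}")


def _pct(fraction: float) -> int:
    return int(math.floor(100.0 * fraction + 0.5))


def class_metrics(
    tp: int, n_target: int, tn: int, n_nontarget: int
) -> ClassMetrics:
    """Sensitivity, specificity, their geometric-mean efficiency, and the
    integer-rounded percent forms."""
    if not 0 <= tp <= n_target or not 0 <= tn <= n_nontarget:
        raise ValueError("counts out of range")
    if n_target == 0 or n_nontarget == 0:
        raise ValueError("zero denominator: metric undefined")
    sens = tp / n_target
    spec = tn / n_nontarget
    eff = math.sqrt(sens * spec)
    return ClassMetrics(
        tp=tp,
        n_target=n_target,
        tn=tn,
        n_nontarget=n_nontarget,
        sensitivity=sens,
        specificity=spec,
        efficiency=eff,
        sensitivity_pct=_pct(sens),
        specificity_pct=_pct(spec),
        efficiency_pct=_pct(eff),
    )


def estimate_dof(values: np.ndarray) -> int:
    """Moment-matched chi-square degrees of freedom: round(2 mean^2/var)."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    var = values.var(ddof=1)
    if mean <= 0 or var <= 0:
        raise ValueError("degenerate moments: cannot estimate dof")
    return max(1, int(round(2.0 * mean**2 / var)))


def ddsimca_fit(
    x_target: SpectraMatrix | np.ndarray,
    alpha: float = 0.05,
    a_range: list[int] | range = range(1, 6),
) -> DDSIMCAModel:
    """Data-driven SIMCA: combined chi-square statistic with estimated dof.

    For each complexity the score distances h and orthogonal distances v
    get moment-matched degrees of freedom; the acceptance rule is
    Nh h/h0 + Nv v/v0 <= chi2_{1-alpha}(Nh+Nv).  The smallest A whose
    calibration sensitivity is closest to 1-alpha is returned.
    """
    x = x_target.values if isinstance(x_target, SpectraMatrix) else np.asarray(
        x_target, dtype=float
    )
    best: DDSIMCAModel | None = None
    best_gap = np.inf
    for a in sorted(int(a) for a in a_range):
        base = fit_class_model(x, a, alpha)
        q, t2 = _distance_arrays(base, x)
        h0 = float(t2.mean())
        v0 = float(q.mean())
        if h0 <= 0 or v0 <= 0:
            raise ValueError("degenerate moments in DDSIMCA fit")
        nh = estimate_dof(t2)
        nv = estimate_dof(q)
        c = nh * t2 / h0 + nv * q / v0
        c_crit = float(stats.chi2.ppf(1.0 - alpha, nh + nv))
        sens = float(np.mean(c <= c_crit))
        gap = abs(sens - (1.0 - alpha))
        if gap < best_gap - 1e-12:
            best_gap = gap
            best = DDSIMCAModel(
                base=base, h0=h0, v0=v0, nh=nh, nv=nv, c_crit=c_crit,
                calibration_sensitivity=sens,
            )
    assert best is not None
    return best


def ddsimca_classify(model: DDSIMCAModel, x: np.ndarray) -> np.ndarray:
    """Boolean acceptance of rows of ``x`` under the DDSIMCA rule."""
    q, t2 = _distance_arrays(model.base, np.atleast_2d(x))
    c = model.nh * t2 / model.h0 + model.nv * q / model.v0
    return c <= model.c_crit


def roc_auc(d_target: np.ndarray, d_nontarget: np.ndarray) -> float:
    """AUC by sweeping the distance threshold (trapezoid rule).

    Target samples are positives and are accepted when their distance is
    at or below the threshold.
    """
    thresholds = np.unique(np.concatenate([d_target, d_nontarget]))
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(float(np.mean(d_target <= t)))
        fpr.append(float(np.mean(d_nontarget <= t)))
    tpr.append(1.0)
    fpr.append(1.0)
    return float(np.trapezoid(tpr, fpr))


def roc_simca(
    x_target: SpectraMatrix | np.ndarray,
    x_nontarget: SpectraMatrix | np.ndarray,
    a_range: list[int] | range = range(1, 6),
    alpha_grid: tuple[float, ...] = (0.10, 0.05, 0.025, 0.01),
    groups: list | None = None,
    n_folds: int = 10,
) -> ROCResult:
    """Joint complexity / significance-level selection via CV ROC area.

    Distances for target spectra come from held-out folds; non-target
    distances are averaged over the per-fold models.  The complexity with
    the largest AUC wins (smallest on ties); the significance level is the
    grid value whose sqrt(2) acceptance boundary maximizes Youden's J on
    the cross-validated distances.
    """
    x = x_target.values if isinstance(x_target, SpectraMatrix) else np.asarray(
        x_target, dtype=float
    )
    xn = (
        x_nontarget.values
        if isinstance(x_nontarget, SpectraMatrix)
        else np.asarray(x_nontarget, dtype=float)
    )
    if xn.shape[0] < 2:
        raise ValueError("need at least 2 non-target spectra")
    n = x.shape[0]
    a_values = sorted(int(a) for a in a_range)
    folds = _venetian_folds(n, n_folds, groups)
    fold_ids = np.unique(folds)

    auc: dict[int, float] = {}
    for a in a_values:
        d_t = np.empty(n)
        d_n_acc = np.zeros(xn.shape[0])
        for f in fold_ids:
            train = folds != f
            model = fit_class_model(x[train], a, alpha=0.05)
            d_t[~train] = d_red_matrix(model, x[~train])
            d_n_acc += d_red_matrix(model, xn)
        d_n = d_n_acc / fold_ids.size
        if np.allclose(
            np.concatenate([d_t, d_n]), np.concatenate([d_t, d_n])[0]
        ):
            raise ValueError("all distances identical: AUC undefined")
        auc[a] = roc_auc(d_t, d_n)

    best_a = a_values[int(np.argmax([auc[a] for a in a_values]))]

    # alpha whose sqrt(2) boundary maximizes Youden's J, evaluated on
    # cross-validated decisions with the limits refit at each alpha
    best_alpha = alpha_grid[0]
    best_j = -np.inf
    for al in alpha_grid:
        acc_t = np.zeros(n, dtype=bool)
        rej_n = np.zeros(fold_ids.size)
        for i, f in enumerate(fold_ids):
            train = folds != f
            model = fit_class_model(x[train], best_a, alpha=al)
            acc_t[~train] = accept_mask(model, x[~train])
            rej_n[i] = float(np.mean(~accept_mask(model, xn)))
        j = float(np.mean(acc_t)) + float(np.mean(rej_n)) - 1.0
        if j > best_j + 1e-12:
            best_j = j
            best_alpha = al
    return ROCResult(
        auc=auc,
        chosen_a=best_a,
        chosen_alpha=best_alpha,
        operating_threshold=SQRT2,
    )


def save_model(model: PCAClassModel, path: str | Path,
               provenance: str = "") -> None:
    """Serialize a class model to a structured JSON text file."""
    payload = {
        "mean": model.mean.tolist(),
        "loadings": model.loadings.tolist(),
        "score_scale": model.score_scale.tolist(),
        "a": model.a,
        "n_cal": model.n_cal,
        "alpha": model.alpha,
        "t2_lim": model.t2_lim,
        "q_lim": model.q_lim,
        "q_moments": list(model.q_moments),
        "provenance": provenance,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> PCAClassModel:
    payload = json.loads(Path(path).read_text())
    return PCAClassModel(
        mean=np.array(payload["mean"]),
        loadings=np.array(payload["loadings"]),
        score_scale=np.array(payload["score_scale"]),
        a=int(payload["a"]),
        n_cal=int(payload["n_cal"]),
        alpha=float(payload["alpha"]),
        t2_lim=float(payload["t2_lim"]),
        q_lim=float(payload["q_lim"]),
        q_moments=tuple(payload["q_moments"]),
    )
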