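"""PLS regression of rind content with VIP ranking, RMSECV latent-variable
selection, duplex-based calibration updating and 18 % w/w compliance
classification."""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selection import duplex_split, pc_scores
from .spectra import SpectraMatrix

__all__ = [
    "PLSModel",
    "VIPVector",
    "fit_pls",
    "select_lv_rmsecv",
    "first_local_minimum",
    "predict_rind",
    "rmse",
    "vip_scores",
    "update_calibration",
]

COMPLIANCE_THRESHOLD = 18.0  # % w/w


@dataclass
class PLSModel:
    """PLS1 model (NIPALS deflation) on mean-centered spectra."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x L (unit columns, deflated-X weights)
    x_loadings: np.ndarray  # p x L
    y_loadings: np.ndarray  # L
    scores: np.ndarray  # n_cal x L
    coefficients: np.ndarray  # p, acts on centered spectra
    n_lv: int
    fitted: np.ndarray  # calibration predictions

    def predict(self, x: np.ndarray | SpectraMatrix) -> np.ndarray:
        if isinstance(x, SpectraMatrix):
            x = x.values
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.x_mean.size:
            raise ValueError(
                f"axis mismatch: {x.shape[1]} variables vs model "
                f"{self.x_mean.size}"
            )
        return (x - self.x_mean) @ self.coefficients + self.y_mean


@dataclass(frozen=True)
class VIPVector:
    scores: np.ndarray
    mask: np.ndarray  # VIP > 1

    def __post_init__(self) -> None:
        assert self.scores.shape == self.mask.shape


def fit_pls(
    x: SpectraMatrix | np.ndarray, y: np.ndarray, n_lv: int
) -> PLSModel:
    """Fit PLS1 by sequential covariance maximization (NIPALS)."""
    x = x.values if isinstance(x, SpectraMatrix) else np.asarray(
        x, dtype=float
    )
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if y.shape != (n,):
        raise ValueError("y must be a vector matching the rows of x")
    if not 1 <= n_lv < min(n, p):
        raise ValueError(f"n_lv must be in [1, min(n, p)), got {n_lv}")
    if np.ptp(y) == 0:
        raise ValueError("constant response: nothing to regress")

    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    e = x - x_mean
    f = y - y_mean

    ws = np.empty((p, n_lv))
    ps = np.empty((p, n_lv))
    qs = np.empty(n_lv)
    ts = np.empty((n, n_lv))
    for l in range(n_lv):
        w = e.T @ f
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(
                f"response fully explained before LV {l + 1}; lower n_lv"
            )
        w /= norm
        t = e @ w
        tt = float(t @ t)
        pl = e.T @ t / tt
        ql = float(f @ t / tt)
        e = e - np.outer(t, pl)
        f = f - ql * t
        ws[:, l] = w
        ps[:, l] = pl
        qs[l] = ql
        ts[:, l] = t

    coeffs = ws @ np.linalg.solve(ps.T @ ws, qs)
    fitted = (x - x_mean) @ coeffs + y_mean
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=ws,
        x_loadings=ps,
        y_loadings=qs,
        scores=ts,
        coefficients=coeffs,
        n_lv=n_lv,
        fitted=fitted,
    )


def first_local_minimum(curve: np.ndarray, rel_tol: float = 0.01) -> int:
    """Index of the first local minimum of ``curve``; a plateau (relative
    improvement below ``rel_tol``) counts as a minimum."""
    curve = np.asarray(curve, dtype=float)
    for i in range(len(curve) - 1):
        if curve[i + 1] >= curve[i]:
            return i
        if curve[i] > 0 and (curve[i] - curve[i + 1]) / curve[i] < rel_tol:
            return i + 1
    return len(curve) - 1


def select_lv_rmsecv(
    x: SpectraMatrix | np.ndarray,
    y: np.ndarray,
    max_lv: int = 10,
    splits: int = 8,
    iterations: int = 20,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Latent-variable count at the first RMSECV minimum.

    Repeated random ``splits``-fold partitions (``iterations`` rounds);
    RMSECV(L) pools the held-out squared errors across every round.
    """
    x = x.values if isinstance(x, SpectraMatrix) else np.asarray(
        x, dtype=float
    )
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 2 * splits:
        raise ValueError("too few samples for the requested split count")
    max_lv = min(max_lv, min(n - math.ceil(n / splits), x.shape[1]) - 1)
    rng = np.random.default_rng(seed)
    sq_err = np.zeros(max_lv)
    count = 0
    for _ in range(iterations):
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[perm] = np.arange(n) % splits
        for fidx in range(splits):
            train = folds != fidx
            test = ~train
            for l in range(1, max_lv + 1):
                model = fit_pls(x[train], y[train], l)
                err = model.predict(x[test]) - y[test]
                sq_err[l - 1] += float(err @ err)
            count += int(test.sum())
    curve = np.sqrt(sq_err / count)
    n_lv = 1 + first_local_minimum(curve)
    return n_lv, curve


def rmse(pred: np.ndarray, truth: np.ndarray, kind: str = "p") -> float:
    """Root-mean-square error, labeled c / cv / p by data role."""
    if kind not in ("c", "cv", "p"):
        raise ValueError(f"unknown rmse kind {kind!r}")
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if pred.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def predict_rind(
    model: PLSModel,
    x: SpectraMatrix | np.ndarray,
    threshold: float = COMPLIANCE_THRESHOLD,
    y_true: np.ndarray | None = None,
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """Predict rind % and classify compliance at the threshold.

    Confusion cells (when the true rind content is known): TC (true
    compliant), TN (true non-compliant), wrongly_accepted (predicted
    compliant, truly above threshold), wrongly_rejected.
    """
    if isinstance(x, SpectraMatrix) and ids is None:
        ids = x.ids
    pred = model.predict(x)
    if ids is None:
        ids = [f"s{i:04d}" for i in range(pred.size)]
    out = pd.DataFrame({"sample_id": ids, "predicted_rind": pred})
    out["compliant_pred"] = out["predicted_rind"] <= threshold
    if y_true is not None:
        y_true = np.asarray(y_true, dtype=float)
        out["true_rind"] = y_true
        out["compliant_true"] = y_true <= threshold
        cells = []
        for ct, cp in zip(out["compliant_true"], out["compliant_pred"]):
            if ct and cp:
                cells.append("TC")
            elif not ct and not cp:
                cells.append("TN")
            elif cp:
                cells.append("wrongly_accepted")
            else:
                cells.append("wrongly_rejected")
        out["confusion_cell"] = cells
    return out


def vip_scores(model: PLSModel) -> VIPVector:
    """Variable importance in projection.

    VIP_j = sqrt(p * sum_L SSY_L (w_jL/||w_L||)^2 / sum_L SSY_L) with
    SSY_L the y-variance captured by latent variable L; mean(VIP^2) = 1.
    """
    w = model.weights
    p = w.shape[0]
    ssy = model.y_loadings**2 * np.sum(model.scores**2, axis=0)
    total = float(ssy.sum())
    if total <= 0:
        raise ValueError("model explains no response variance")
    wn2 = (w / np.linalg.norm(w, axis=0)) ** 2
    vip = np.sqrt(p * (wn2 @ ssy) / total)
    return VIPVector(scores=vip, mask=vip > 1.0)


@dataclass
class UpdateResult:
    model: PLSModel
    selected_packages: list = field(default_factory=list)
    selected_rows: np.ndarray | None = None
    rmsep_remaining: float | None = None


def update_calibration(
    base_x: SpectraMatrix | np.ndarray,
    base_y: np.ndarray,
    pool_x: SpectraMatrix | np.ndarray,
    pool_y: np.ndarray,
    k: int = 6,
    n_lv: int | None = None,
    base_model: PLSModel | None = None,
    pool_groups: list | None = None,
    n_pc: int = 5,
) -> UpdateResult:
    """Augment the calibration with k duplex-selected pool packages.

    Selection runs on the first ``n_pc`` PC scores of package-mean
    spectra; every replicate row of a selected package joins the refit.
    ``k = 0`` returns the base model unchanged; the remaining pool rows
    provide the reported RMSEP.
    """
    bx = base_x.values if isinstance(base_x, SpectraMatrix) else np.asarray(
        base_x, dtype=float
    )
    px = pool_x.values if isinstance(pool_x, SpectraMatrix) else np.asarray(
        pool_x, dtype=float
    )
    base_y = np.asarray(base_y, dtype=float)
    pool_y = np.asarray(pool_y, dtype=float)
    if n_lv is None:
        if base_model is None:
            base_model = fit_pls(bx, base_y, 3)
        n_lv = base_model.n_lv
    if base_model is None:
        base_model = fit_pls(bx, base_y, n_lv)
    if k == 0:
        pred = base_model.predict(px)
        return UpdateResult(
            model=base_model,
            selected_packages=[],
            selected_rows=np.zeros(px.shape[0], dtype=bool),
            rmsep_remaining=rmse(pred, pool_y, "p"),
        )

    if pool_groups is None:
        pool_groups = list(range(px.shape[0]))
    groups: list = []
    for g in pool_groups:
        if g not in groups:
            groups.append(g)
    if k > len(groups):
        raise ValueError(
            f"cannot select {k} packages from a pool of {len(groups)}"
        )
    garr = np.asarray(pool_groups, dtype=object)
    if k == len(groups):  # whole pool: equivalent to fitting on the union
        selected = list(groups)
        sel_rows = np.ones(px.shape[0], dtype=bool)
    else:
        pkg_means = np.vstack([px[garr == g].mean(axis=0) for g in groups])
        feats = pc_scores(pkg_means, n_pc=min(n_pc, *pkg_means.shape))
        split = duplex_split(feats, k)
        selected = [groups[i] for i in split.set_a]
        sel_rows = np.isin(garr, np.array(selected, dtype=object))

    new_x = np.vstack([bx, px[sel_rows]])
    new_y = np.concatenate([base_y, pool_y[sel_rows]])
    model = fit_pls(new_x, new_y, n_lv)
    rest = ~sel_rows
    rmsep = (
        rmse(model.predict(px[rest]), pool_y[rest], "p")
        if rest.any() else None
    )
    return UpdateResult(
        model=model,
        selected_packages=selected,
        selected_rows=sel_rows,
        rmsep_remaining=rmsep,
    )
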