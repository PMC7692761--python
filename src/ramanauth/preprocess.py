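"""Spectral preprocessing chain.

Fixed stage order (flags may skip a stage, never reorder):
replicate-point averaging -> Savitzky-Golay smoothing -> correlation
optimized warping -> weighted-least-squares baseline removal ->
normalization (unit area or probabilistic quotient).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectraMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "average_point_spectra",
    "sg_smooth",
    "cow_align",
    "wls_baseline",
    "normalize_unit_area",
    "median_quotient",
    "pqn_normalize",
    "run_preprocess",
]


@dataclass
class PreprocessConfig:
    sg_window: int = 21
    sg_order: int = 2
    cow_segment: int = 50
    cow_slack: int = 10
    cow_reference: str = "mean_of_calibration"  # or "designated_spectrum"
    wls_order: int = 4
    wls_max_iter: int = 50
    wls_tol: float = 1e-6
    normalization: str = "unit_area"  # "unit_area" | "pqn" | "none"
    pqn_reference: str = "median_of_calibration"
    smooth: bool = True
    align: bool = True
    baseline: bool = True

    def __post_init__(self) -> None:
        if self.smooth:
            if self.sg_window % 2 != 1:
                raise ValueError("sg_window must be odd")
            if self.sg_order >= self.sg_window:
                raise ValueError("sg_order must be < sg_window")
        if self.align and self.cow_slack >= self.cow_segment:
            raise ValueError("cow_slack must be < cow_segment")
        if self.normalization not in ("unit_area", "pqn", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def average_point_spectra(points: list[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of spectra sharing one axis."""
    if not points:
        raise ValueError("need at least one spectrum")
    axis = points[0].wavenumbers
    for s in points[1:]:
        if s.wavenumbers.shape != axis.shape or not np.allclose(
            s.wavenumbers, axis
        ):
            raise ValueError("point spectra must share the wavenumber axis")
    return Spectrum(axis, np.mean([s.intensities for s in points], axis=0))


def sg_smooth(s: Spectrum, window: int = 21, order: int = 2) -> Spectrum:
    """Savitzky-Golay local polynomial smoothing."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be < window")
    if window > len(s):
        raise ValueError("window longer than the spectrum")
    return s.with_intensities(savgol_filter(s.intensities, window, order))


def _segment_bounds(p: int, segment: int) -> list[int]:
    """Nominal segment boundary indices 0, segment, 2*segment, ..., p-1."""
    bounds = list(range(0, p - 1, segment))
    if p - 1 - bounds[-1] < 2:  # last segment needs >= 2 points
        bounds.pop()
    bounds.append(p - 1)
    return bounds


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; zero-variance segments count as 0."""
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt(a @ a)
    nb = np.sqrt(b @ b)
    if na <= 0 or nb <= 0:
        return 0.0
    return float((a @ b) / (na * nb))


def cow_align(
    s: Spectrum, reference: Spectrum, segment: int = 50, slack: int = 10
) -> Spectrum:
    """Correlation optimized warping onto the reference axis.

    Piecewise-linear warp: segment boundaries of ``s`` may be displaced by
    up to ``slack`` points from their nominal positions (endpoints fixed);
    dynamic programming picks the displacement path maximizing the sum of
    per-segment Pearson correlations with the reference.  Displacement ties
    resolve toward the identity warp.
    """
    if s.wavenumbers.shape != reference.wavenumbers.shape or not np.allclose(
        s.wavenumbers, reference.wavenumbers
    ):
        raise ValueError("spectrum and reference must share the axis")
    if segment < 2 * slack:
        raise ValueError("segment must be >= 2 * slack")
    p = len(reference)
    bounds = _segment_bounds(p, segment)
    nseg = len(bounds) - 1
    if slack == 0 or nseg == 0:
        return s.with_intensities(s.intensities.copy())

    y = s.intensities
    ref = reference.intensities
    # candidate displacements ordered by |u| so DP ties prefer identity
    cand = sorted(range(-slack, slack + 1), key=abs)
    u_of = np.array(cand)
    n_u = len(cand)

    NEG = -np.inf

    def seg_corr_matrix(k: int) -> np.ndarray:
        """corr[i_prev, i_cur] of warped sample segment vs reference."""
        b0, b1 = bounds[k], bounds[k + 1]
        tgt_len = b1 - b0 + 1
        refseg = ref[b0 : b1 + 1].astype(float)
        refc = refseg - refseg.mean()
        refn = np.sqrt(refc @ refc)
        out = np.full((n_u, n_u), NEG)
        for du in range(-2 * slack, 2 * slack + 1):
            src_len = tgt_len + du
            if src_len < 2:
                continue
            prev_idx = [
                i for i in range(n_u)
                if abs(u_of[i] + du) <= slack
                and b0 + u_of[i] >= 0
                and b1 + u_of[i] + du <= p - 1
            ]
            if not prev_idx:
                continue
            los = np.array([b0 + u_of[i] for i in prev_idx], dtype=float)
            g = np.linspace(0.0, src_len - 1.0, tgt_len)
            pos = los[:, None] + g[None, :]
            base = np.floor(pos).astype(int)
            np.clip(base, 0, p - 2, out=base)
            frac = pos - base
            vals = y[base] * (1.0 - frac) + y[base + 1] * frac
            valsc = vals - vals.mean(axis=1, keepdims=True)
            norms = np.sqrt(np.sum(valsc**2, axis=1))
            num = valsc @ refc
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.where(
                    (norms > 0) & (refn > 0), num / (norms * refn), 0.0
                )
            cur_u = u_of[prev_idx] + du
            cur_pos = {int(u): i for i, u in enumerate(u_of)}
            for row, i_prev in enumerate(prev_idx):
                out[i_prev, cur_pos[int(cur_u[row])]] = c[row]
        return out

    score = np.full((nseg + 1, n_u), NEG)
    back = np.zeros((nseg + 1, n_u), dtype=int)
    score[0, 0] = 0.0  # cand[0] == 0: identity start
    for k in range(nseg):
        cm = seg_corr_matrix(k)
        total = score[k][:, None] + cm
        if k == nseg - 1:
            total[:, [j for j in range(n_u) if u_of[j] != 0]] = NEG
        best_prev = np.argmax(total, axis=0)
        score[k + 1] = total[best_prev, np.arange(n_u)]
        back[k + 1] = best_prev

    # backtrack boundary displacements
    u_idx = [0] * (nseg + 1)
    u_idx[nseg] = int(np.flatnonzero(u_of == 0)[0])
    for k in range(nseg, 0, -1):
        u_idx[k - 1] = int(back[k, u_idx[k]])
    disp = [int(u_of[i]) for i in u_idx]

    out = np.empty(p)
    for k in range(nseg):
        lo = bounds[k] + disp[k]
        hi = bounds[k + 1] + disp[k + 1]
        tgt_len = bounds[k + 1] - bounds[k] + 1
        src = y[lo : hi + 1]
        out[bounds[k] : bounds[k + 1] + 1] = np.interp(
            np.linspace(0.0, src.size - 1.0, tgt_len),
            np.arange(src.size, dtype=float),
            src,
        )
    return s.with_intensities(out)


def wls_baseline(
    s: Spectrum,
    order: int = 4,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[Spectrum, Spectrum]:
    """Asymmetric iteratively reweighted polynomial baseline.

    Points above the current fit (peaks) are down-weighted with
    ``exp(-residual/scale)``; points at or below keep weight 1.  Returns
    ``(corrected, baseline)`` with ``corrected + baseline == input``
    exactly.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    x = s.wavenumbers
    y = s.intensities
    scale = float(np.max(np.abs(y)))
    if scale == 0.0:
        zero = s.with_intensities(np.zeros_like(y))
        return zero, zero
    w = np.ones_like(y)
    baseline = np.zeros_like(y)
    converged = False
    for _ in range(max_iter):
        fit = np.polynomial.Polynomial.fit(x, y, order, w=np.sqrt(w))
        new_baseline = fit(x)
        if np.max(np.abs(new_baseline - baseline)) < tol * scale:
            baseline = new_baseline
            converged = True
            break
        baseline = new_baseline
        r = y - baseline
        pos = r > 0
        sigma = float(np.std(r[pos])) if np.any(pos) else 1.0
        sigma = sigma if sigma > 0 else 1.0
        w = np.ones_like(y)
        w[pos] = np.exp(-r[pos] / sigma)
    if not converged:
        logger.warning(
            "wls_baseline did not converge in %d iterations", max_iter
        )
    return s.with_intensities(y - baseline), s.with_intensities(baseline)


def normalize_unit_area(s: Spectrum) -> Spectrum:
    """Scale so the absolute area (sum |I| x grid step) equals 1."""
    area = float(np.sum(np.abs(s.intensities)) * s.step)
    if area <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return s.with_intensities(s.intensities / area)


def median_quotient(
    s: Spectrum, reference: Spectrum, min_points: int = 10
) -> float:
    """Median of pointwise quotients s/reference over the support where
    the reference exceeds 1 % of its maximum (the PQN dilution factor)."""
    if s.wavenumbers.shape != reference.wavenumbers.shape or not np.allclose(
        s.wavenumbers, reference.wavenumbers
    ):
        raise ValueError("spectrum and reference must share the axis")
    ref = reference.intensities
    mask = ref > 0.01 * np.max(ref)
    if int(mask.sum()) < min_points:
        raise ValueError(
            f"fewer than {min_points} valid quotient points in the reference"
        )
    return float(np.median(s.intensities[mask] / ref[mask]))


def pqn_normalize(
    s: Spectrum, reference: Spectrum, min_points: int = 10
) -> Spectrum:
    """Probabilistic quotient normalization against a reference spectrum.

    The spectrum is first scaled to unit area, then divided by the median
    quotient to the reference (see :func:`median_quotient`).
    """
    normed = normalize_unit_area(s)
    factor = median_quotient(normed, reference, min_points)
    if factor == 0.0:
        raise ValueError("median quotient is zero")
    return s.with_intensities(normed.intensities / factor)


def _average_acquisitions(
    m: SpectraMatrix, meta: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Average point spectra per acquisition (replicate_group)."""
    if list(meta["spectrum_id"]) != list(m.ids):
        raise ValueError("metadata rows must match spectra rows in order")
    groups = meta["replicate_group"].tolist()
    order: list[str] = []
    seen: set[str] = set()
    for g in groups:
        if g not in seen:
            seen.add(g)
            order.append(g)
    idx = {g: [] for g in order}
    for i, g in enumerate(groups):
        idx[g].append(i)
    rows = np.vstack([m.values[idx[g]].mean(axis=0) for g in order])
    first = meta.drop_duplicates("replicate_group").set_index(
        "replicate_group"
    )
    cols = [c for c in ("package_id", "class", "rind_pct", "session", "role")
            if c in first.columns]
    acq_meta = first.loc[order, cols].reset_index()
    return rows, acq_meta


def run_preprocess(
    m: SpectraMatrix,
    meta: pd.DataFrame,
    cfg: PreprocessConfig,
    cal_mask: np.ndarray | None = None,
    reference: Spectrum | None = None,
) -> tuple[SpectraMatrix, pd.DataFrame]:
    """Run the full chain on a point-spectrum matrix.

    Returns one row per acquisition (package averages; replicate
    acquisitions stay distinct rows) plus the acquisition-level metadata.
    ``cal_mask`` flags acquisition rows belonging to the calibration pool
    used for the warping reference and the PQN reference; defaults to the
    target-class rows of the lowest session (warping) / all target rows
    (PQN), falling back to every row.
    """
    values, acq_meta = _average_acquisitions(m, meta)
    logger.info("averaged %d point spectra into %d acquisitions",
                m.n, values.shape[0])

    if cfg.smooth:
        values = savgol_filter(values, cfg.sg_window, cfg.sg_order, axis=1)
        logger.info("savitzky-golay window=%d order=%d",
                    cfg.sg_window, cfg.sg_order)

    if cal_mask is None:
        if "class" in acq_meta.columns and (acq_meta["class"] == "PR").any():
            cal_mask = (acq_meta["class"] == "PR").to_numpy()
            if "role" in acq_meta.columns and acq_meta["role"].notna().all():
                in_cal = acq_meta["role"].isin(["PR1st", "PR2nd"]).to_numpy()
                if in_cal.any():
                    cal_mask = cal_mask & in_cal
        else:
            cal_mask = np.ones(values.shape[0], dtype=bool)
    cal_mask = np.asarray(cal_mask, dtype=bool)

    if cfg.align:
        if reference is not None and cfg.cow_reference == "designated_spectrum":
            ref = reference
        else:
            ref_mask = cal_mask.copy()
            if "session" in acq_meta.columns:
                s0 = acq_meta.loc[cal_mask, "session"].min()
                ref_mask = cal_mask & (acq_meta["session"] == s0).to_numpy()
            if not ref_mask.any():
                ref_mask = cal_mask
            ref = Spectrum(m.axis, values[ref_mask].mean(axis=0))
        values = np.vstack(
            [
                cow_align(Spectrum(m.axis, row), ref, cfg.cow_segment,
                          cfg.cow_slack).intensities
                for row in values
            ]
        )
        logger.info("cow segment=%d slack=%d", cfg.cow_segment, cfg.cow_slack)

    if cfg.baseline:
        corrected = np.empty_like(values)
        for i, row in enumerate(values):
            corrected[i] = wls_baseline(
                Spectrum(m.axis, row), cfg.wls_order, cfg.wls_max_iter,
                cfg.wls_tol
            )[0].intensities
        values = corrected
        logger.info("wls baseline order=%d", cfg.wls_order)

    if cfg.normalization == "unit_area":
        values = np.vstack(
            [normalize_unit_area(Spectrum(m.axis, row)).intensities
             for row in values]
        )
    elif cfg.normalization == "pqn":
        ref_rows = values[cal_mask] if cal_mask.any() else values
        pqn_ref = Spectrum(m.axis, np.median(ref_rows, axis=0))
        values = np.vstack(
            [pqn_normalize(Spectrum(m.axis, row), pqn_ref).intensities
             for row in values]
        )
    logger.info("normalization=%s", cfg.normalization)

    out = SpectraMatrix(m.axis, values, acq_meta["replicate_group"].tolist())
    return out, acq_meta
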