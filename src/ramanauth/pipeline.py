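"""End-to-end workflows: authenticity class modeling and rind calibration.

Both run from a single config mapping (YAML on disk) whose sections are
``synthetic`` (generator overrides), ``paths`` (spectra/metadata CSVs —
exactly one of the two data sources may be present), ``preprocess``,
``simca`` and ``pls``.  All randomness flows from one seed.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .io import ConfigError, DataError
from .preprocess import PreprocessConfig, run_preprocess
from .selection import duplex_split, pc_scores
from .simca import (
    accept_mask,
    class_metrics,
    cv_class_model,
    d_red_matrix,
    ddsimca_classify,
    ddsimca_fit,
    distances,
    fit_class_model,
    roc_simca,
    save_model,
    select_components,
)
from .spectra import SpectraMatrix
from .synthetic import GeneratorConfig, generate_dataset
from . import pls as rpls

logger = logging.getLogger(__name__)

__all__ = [
    "load_run_inputs",
    "run_authenticity_workflow",
    "run_rind_workflow",
    "run_simulate",
]


def _generator_config(cfg: dict, seed: int | None) -> GeneratorConfig:
    section = dict(cfg.get("synthetic") or {})
    if seed is not None:
        section["seed"] = int(seed)
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown synthetic config keys: {sorted(unknown)}")
    for key in ("rind_fraction_range", "compliant_range", "session_shifts",
                "session_gains", "rind_gain_by_session"):
        if key in section and isinstance(section[key], list):
            section[key] = tuple(section[key])
    try:
        return GeneratorConfig(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid synthetic config: {exc}") from exc


def _preprocess_config(cfg: dict, normalization: str) -> PreprocessConfig:
    section = dict(cfg.get("preprocess") or {})
    section.setdefault("normalization", normalization)
    try:
        return PreprocessConfig(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid preprocess config: {exc}") from exc


def load_run_inputs(
    cfg: dict, seed: int | None
) -> tuple[SpectraMatrix, pd.DataFrame]:
    """Resolve the single data source: files or the synthetic generator."""
    paths = cfg.get("paths") or {}
    has_files = bool(paths.get("spectra"))
    has_synth = "synthetic" in cfg
    if has_files and has_synth:
        raise ConfigError("exactly one data source: paths or synthetic")
    if has_files:
        if not paths.get("metadata"):
            raise ConfigError("paths.metadata required with paths.spectra")
        spectra = rio.read_spectra_csv(paths["spectra"])
        meta = rio.read_meta_csv(paths["metadata"])
        if len(meta) != spectra.n:
            raise DataError("metadata row count differs from spectra rows")
        return spectra, meta
    gen_cfg = _generator_config(cfg, seed)
    ds = generate_dataset(gen_cfg)
    return ds.spectra, ds.meta


def run_simulate(cfg: dict, outdir: str | Path, seed: int | None) -> dict:
    """Generate a synthetic campaign and persist it as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen_cfg = _generator_config(cfg, seed)
    ds = generate_dataset(gen_cfg)
    rio.write_spectra_csv(ds.spectra, outdir / "spectra.csv")
    rio.write_meta_csv(ds.meta, outdir / "metadata.csv")
    ds.truth.to_csv(outdir / "truth.csv", index=False)
    rio.dump_config({"synthetic": gen_cfg.to_dict()}, outdir / "config.yaml")
    return {"n_point_spectra": ds.spectra.n, "n_packages": len(ds.truth)}


def _split_roles(acq_meta: pd.DataFrame) -> dict[str, np.ndarray]:
    if "role" not in acq_meta.columns:
        raise DataError("acquisition metadata lacks a 'role' column")
    role = acq_meta["role"]
    return {
        "cal": role.isin(["PR1st", "PR2nd"]).to_numpy(),
        "pr1": (role == "PR1st").to_numpy(),
        "pr2": (role == "PR2nd").to_numpy(),
        "unknown": (role == "PR-unknown").to_numpy(),
        "nontarget": (role == "notPR").to_numpy(),
    }


def _package_vote(
    accepted: np.ndarray, packages: pd.Series
) -> tuple[int, int]:
    """Majority vote per package; returns (n_accepted, n_packages)."""
    df = pd.DataFrame({"pkg": packages.to_numpy(), "acc": accepted})
    votes = df.groupby("pkg")["acc"].mean() >= 0.5
    return int(votes.sum()), int(votes.size)


def run_authenticity_workflow(
    cfg: dict, outdir: str | Path, seed: int | None = None
) -> pd.DataFrame:
    """One-class authenticity workflow; writes the report and returns it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spectra, meta = load_run_inputs(cfg, seed)
    pp_cfg = _preprocess_config(cfg, normalization="unit_area")
    x, acq_meta = run_preprocess(spectra, meta, pp_cfg)
    roles = _split_roles(acq_meta)
    if not roles["cal"].any():
        raise DataError("no calibration (PR1st/PR2nd) acquisitions found")

    simca_cfg = cfg.get("simca") or {}
    alpha = float(simca_cfg.get("alpha", 0.05))
    a_max = int(simca_cfg.get("a_max", 6))
    a_range = list(range(1, a_max + 1))
    criteria = list(
        simca_cfg.get("criteria", ["max_sensitivity_cv", "min_rmsecv",
                                   "max_efficiency_cv"])
    )
    variants = list(simca_cfg.get("variants", ["ddsimca", "roc_simca"]))
    n_spec_cv = int(simca_cfg.get("n_nontarget_cv", 5))

    x_cal = x.values[roles["cal"]]
    cal_groups = acq_meta.loc[roles["cal"], "package_id"].tolist()
    x_unknown = x.values[roles["unknown"]]
    x_non = x.values[roles["nontarget"]]
    non_meta = acq_meta.loc[roles["nontarget"]]

    # duplex-select packages of the non-target pool for CV specificity
    spec_rows = np.zeros(x_non.shape[0], dtype=bool)
    if x_non.shape[0] >= 2 and n_spec_cv >= 1:
        pkgs: list = []
        for g in non_meta["package_id"]:
            if g not in pkgs:
                pkgs.append(g)
        n_sel = min(n_spec_cv, (len(pkgs) + 1) // 2)
        pkg_means = np.vstack(
            [x_non[(non_meta["package_id"] == g).to_numpy()].mean(axis=0)
             for g in pkgs]
        )
        feats = pc_scores(pkg_means, n_pc=min(5, *pkg_means.shape))
        sel = duplex_split(feats, n_sel)
        chosen = {pkgs[i] for i in sel.set_a}
        spec_rows = non_meta["package_id"].isin(chosen).to_numpy()

    cv_plain = cv_class_model(x_cal, a_range, alpha, groups=cal_groups)
    cv_eff = (
        cv_class_model(x_cal, a_range, alpha, x_nontarget=x_non[spec_rows],
                       groups=cal_groups)
        if spec_rows.any() else None
    )

    rows = []
    model_for_plot = None

    def evaluate(label: str, criterion: str, a: int, accept_cal, accept_test,
                 accept_non, non_mask: np.ndarray, sens_cv: float | None):
        sens_fit = class_metrics(
            int(accept_cal.sum()), accept_cal.size, 1, 1
        ).sensitivity
        n_tp = int(accept_test.sum())
        n_tn = int((~accept_non).sum())
        pkg_tp, pkg_nt = _package_vote(
            accept_test, acq_meta.loc[roles["unknown"], "package_id"]
        )
        pkg_tn_acc, pkg_nn = _package_vote(
            accept_non, acq_meta.loc[non_mask, "package_id"]
        )
        rows.append(
            {
                "variant": label,
                "criterion": criterion,
                "n_pc": a,
                "sensitivity_fit_pct": class_metrics(
                    int(accept_cal.sum()), accept_cal.size, 1, 1
                ).sensitivity_pct,
                "sensitivity_cv_pct": (
                    int(round(100 * sens_cv)) if sens_cv is not None else ""
                ),
                "sensitivity_test_pct": class_metrics(
                    n_tp, accept_test.size, 1, 1
                ).sensitivity_pct,
                "specificity_test_pct": class_metrics(
                    1, 1, n_tn, accept_non.size
                ).specificity_pct,
                "tp_test": n_tp,
                "n_test_target": int(accept_test.size),
                "tn_test": n_tn,
                "n_test_nontarget": int(accept_non.size),
                "tp_test_packages": pkg_tp,
                "n_test_target_packages": pkg_nt,
                "tn_test_packages": pkg_nn - pkg_tn_acc,
                "n_test_nontarget_packages": pkg_nn,
                "sensitivity_fit": sens_fit,
            }
        )

    for criterion in criteria:
        if criterion == "max_efficiency_cv":
            if cv_eff is None:
                continue
            a = select_components(cv_eff, criterion)
            sens_cv = cv_eff.sensitivity_cv[a]
            non_mask_eval = roles["nontarget"].copy()
            non_mask_eval[np.flatnonzero(roles["nontarget"])[spec_rows]] = False
        else:
            a = select_components(cv_plain, criterion)
            sens_cv = cv_plain.sensitivity_cv[a]
            non_mask_eval = roles["nontarget"]
        model = fit_class_model(x_cal, a, alpha)
        acc_cal = accept_mask(model, x_cal)
        acc_test = accept_mask(model, x_unknown)
        acc_non = accept_mask(model, x.values[non_mask_eval])
        evaluate("alternative_simca", criterion, a, acc_cal, acc_test,
                 acc_non, non_mask_eval, sens_cv)
        if model_for_plot is None or criterion == "max_efficiency_cv":
            model_for_plot = model

    if "ddsimca" in variants:
        dd = ddsimca_fit(x_cal, alpha, a_range)
        acc_cal = ddsimca_classify(dd, x_cal)
        acc_test = ddsimca_classify(dd, x_unknown)
        acc_non = ddsimca_classify(dd, x_non)
        evaluate("ddsimca", "calibration_sensitivity_matches_alpha",
                 dd.base.a, acc_cal, acc_test, acc_non, roles["nontarget"],
                 None)

    if "roc_simca" in variants and spec_rows.any():
        roc = roc_simca(x_cal, x_non[spec_rows], a_range, groups=cal_groups)
        model = fit_class_model(x_cal, roc.chosen_a, roc.chosen_alpha)
        acc_cal = accept_mask(model, x_cal)
        acc_test = accept_mask(model, x_unknown)
        non_mask_eval = roles["nontarget"].copy()
        non_mask_eval[np.flatnonzero(roles["nontarget"])[spec_rows]] = False
        acc_non = accept_mask(model, x.values[non_mask_eval])
        evaluate("roc_simca", f"max_cv_auc (alpha={roc.chosen_alpha})",
                 roc.chosen_a, acc_cal, acc_test, acc_non, non_mask_eval,
                 None)

    report = pd.DataFrame(rows)
    report.to_csv(outdir / "authenticity_report.csv", index=False)

    # acceptance-plot data + per-spectrum classification for the last model
    if model_for_plot is not None:
        d = d_red_matrix(model_for_plot, x.values)
        pairs = [distances(model_for_plot, row) for row in x.values]
        plot = pd.DataFrame(
            {
                "spectrum_id": x.ids,
                "role": acq_meta["role"],
                "q": [dp.q for dp in pairs],
                "t2": [dp.t2 for dp in pairs],
                "q_red": [dp.q_red for dp in pairs],
                "t2_red": [dp.t2_red for dp in pairs],
                "d_red": d,
                "accepted": accept_mask(model_for_plot, x.values),
            }
        )
        plot.to_csv(outdir / "acceptance_plot.csv", index=False)
        save_model(model_for_plot, outdir / "class_model.json",
                   provenance=f"n_cal={x_cal.shape[0]}")

    summary = outdir / "summary.txt"
    with open(summary, "w") as fh:
        fh.write("authenticity workflow\n")
        fh.write(f"calibration spectra: {int(roles['cal'].sum())}\n")
        fh.write(f"test target spectra: {int(roles['unknown'].sum())}\n")
        fh.write(f"test non-target spectra: {int(roles['nontarget'].sum())}\n")
        fh.write(report.to_string(index=False))
        fh.write("\n")
    return report


def run_rind_workflow(
    cfg: dict, outdir: str | Path, seed: int | None = None
) -> pd.DataFrame:
    """PLS rind-content workflow with duplex calibration update."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spectra, meta = load_run_inputs(cfg, seed)
    pp_cfg = _preprocess_config(cfg, normalization="pqn")
    x, acq_meta = run_preprocess(spectra, meta, pp_cfg)
    roles = _split_roles(acq_meta)
    if not roles["pr1"].any() or not roles["pr2"].any():
        raise DataError("rind workflow needs both PR1st and PR2nd sessions")

    pls_cfg = cfg.get("pls") or {}
    max_lv = int(pls_cfg.get("max_lv", 10))
    threshold = float(pls_cfg.get("threshold", rpls.COMPLIANCE_THRESHOLD))
    update_k = int(pls_cfg.get("update_k", 6))
    cv_splits = int(pls_cfg.get("cv_splits", 8))
    cv_iter = int(pls_cfg.get("cv_iterations", 20))
    lv_seed = seed if seed is not None else 0

    y = acq_meta["rind_pct"].to_numpy(dtype=float)
    x1, y1 = x.values[roles["pr1"]], y[roles["pr1"]]
    x2, y2 = x.values[roles["pr2"]], y[roles["pr2"]]
    xu, yu = x.values[roles["unknown"]], y[roles["unknown"]]

    n_lv, curve = rpls.select_lv_rmsecv(
        x1, y1, max_lv=max_lv, splits=cv_splits, iterations=cv_iter,
        seed=lv_seed,
    )
    base = rpls.fit_pls(x1, y1, n_lv)
    rmsec_base = rpls.rmse(base.fitted, y1, "c")
    rmsecv_base = float(curve[n_lv - 1])
    rmsep_base_pr2 = rpls.rmse(base.predict(x2), y2, "p")

    pr2_groups = acq_meta.loc[roles["pr2"], "package_id"].tolist()
    upd = rpls.update_calibration(
        x1, y1, x2, y2, k=update_k, base_model=base,
        pool_groups=pr2_groups,
    )
    aug_x = np.vstack([x1, x2[upd.selected_rows]])
    aug_y = np.concatenate([y1, y2[upd.selected_rows]])
    n_lv_upd, curve_upd = rpls.select_lv_rmsecv(
        aug_x, aug_y, max_lv=max_lv, splits=cv_splits, iterations=cv_iter,
        seed=lv_seed,
    )
    updated = rpls.fit_pls(aug_x, aug_y, n_lv_upd)
    rmsec_upd = rpls.rmse(updated.fitted, aug_y, "c")
    rmsecv_upd = float(curve_upd[n_lv_upd - 1])
    rest = ~upd.selected_rows
    rmsep_upd_pr2 = rpls.rmse(updated.predict(x2[rest]), y2[rest], "p")
    rmsep_upd_unknown = (
        rpls.rmse(updated.predict(xu), yu, "p") if xu.size else float("nan")
    )

    report = pd.DataFrame(
        [
            {
                "calibration": "PR1st",
                "n_cal_spectra": x1.shape[0],
                "n_lv": n_lv,
                "rmsec": rmsec_base,
                "rmsecv": rmsecv_base,
                "validation": "PR2nd",
                "n_val_spectra": x2.shape[0],
                "rmsep": rmsep_base_pr2,
            },
            {
                "calibration": "PR1st + duplex PR2nd",
                "n_cal_spectra": aug_x.shape[0],
                "n_lv": n_lv_upd,
                "rmsec": rmsec_upd,
                "rmsecv": rmsecv_upd,
                "validation": "PR2nd (not in update)",
                "n_val_spectra": int(rest.sum()),
                "rmsep": rmsep_upd_pr2,
            },
            {
                "calibration": "PR1st + duplex PR2nd",
                "n_cal_spectra": aug_x.shape[0],
                "n_lv": n_lv_upd,
                "rmsec": rmsec_upd,
                "rmsecv": rmsecv_upd,
                "validation": "unknown-PR",
                "n_val_spectra": xu.shape[0],
                "rmsep": rmsep_upd_unknown,
            },
        ]
    )
    report.to_csv(outdir / "rind_report.csv", index=False)

    pred_mask = roles["pr2"] | roles["unknown"]
    preds = rpls.predict_rind(
        updated,
        x.values[pred_mask],
        threshold=threshold,
        y_true=y[pred_mask],
        ids=[x.ids[i] for i in np.flatnonzero(pred_mask)],
    )
    preds.insert(1, "role", acq_meta.loc[pred_mask, "role"].to_numpy())
    preds.to_csv(outdir / "rind_predictions.csv", index=False)

    vip = rpls.vip_scores(updated)
    pd.DataFrame(
        {
            "wavenumber": x.axis,
            "coefficient": updated.coefficients,
            "vip": vip.scores,
            "selected": vip.mask,
        }
    ).to_csv(outdir / "vip_coefficients.csv", index=False)

    confusion = (
        preds["confusion_cell"].value_counts().to_dict()
        if "confusion_cell" in preds else {}
    )
    with open(outdir / "summary.txt", "w") as fh:
        fh.write("rind calibration workflow\n")
        fh.write(f"selected LV (base/updated): {n_lv}/{n_lv_upd}\n")
        fh.write(f"duplex-selected packages: {upd.selected_packages}\n")
        fh.write(report.to_string(index=False))
        fh.write(f"\ncompliance threshold: {threshold}% w/w\n")
        fh.write(f"confusion: {confusion}\n")
    return report
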