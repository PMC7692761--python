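import math

import numpy as np
import pytest
from scipy import stats

from ramanauth.simca import (
    CVResult,
    DDSIMCAModel,
    PCAClassModel,
    SQRT2,
    accept_mask,
    class_metrics,
    classify,
    cv_class_model,
    d_red_matrix,
    ddsimca_classify,
    ddsimca_fit,
    distances,
    estimate_dof,
    first_rmsecv_minimum,
    fit_class_model,
    load_model,
    q_limit,
    roc_auc,
    roc_simca,
    save_model,
    select_components,
    t2_limit,
)

from conftest import gaussian_class_data


class TestT2Limit:
    @pytest.mark.parametrize(
        "a,expected", [(2, 6.3), (4, 10.3), (5, 12.2)]
    )
    def test_reference_values_n90(self, a, expected):
        assert round(t2_limit(a, 90, 0.05), 1) == expected

    def test_invalid_dof(self):
        with pytest.raises(ValueError):
            t2_limit(5, 5, 0.05)
        with pytest.raises(ValueError):
            t2_limit(0, 90, 0.05)


class TestQLimit:
    def test_closed_form(self):
        # mean=2, var=4 -> g=1, h=2 -> chi2_0.95(2)
        assert q_limit((2.0, 4.0), 0.05) == pytest.approx(5.9915, abs=1e-3)

    def test_monotone_in_alpha(self):
        limits = [q_limit((2.0, 4.0), a) for a in (0.01, 0.05, 0.2, 0.9)]
        assert all(x > y for x, y in zip(limits, limits[1:]))

    def test_monte_carlo_scaled_chi2(self):
        rng = np.random.default_rng(0)
        q = 3.0 * rng.chisquare(4, size=100_000)
        est = q_limit((q.mean(), q.var(ddof=1)), 0.05)
        truth = 3.0 * stats.chi2.ppf(0.95, 4)
        assert abs(est - truth) / truth < 0.03

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            q_limit((2.0, 0.0), 0.05)


def brute_force_distances(x_cal, a, sample):
    """Independent dense-algebra oracle via eigendecomposition of the
    covariance matrix and explicit projection matrices."""
    mean = x_cal.mean(axis=0)
    cov = np.cov(x_cal, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    lam = evals[order][:a]
    loadings = evecs[:, order][:, :a]
    z = loadings.T @ (sample - mean)
    t2 = float(np.sum(z**2 / lam))
    proj = loadings @ loadings.T
    resid = (np.eye(len(mean)) - proj) @ (sample - mean)
    return float(resid @ resid), t2


class TestFitAndDistances:
    def test_exact_subspace_zero_q(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, 8))
        x = rng.standard_normal((20, 2)) @ basis + 5.0
        model = fit_class_model(x, 2)
        q = np.array([distances(model, row).q for row in x])
        assert np.max(q) < 1e-18 * np.max(np.abs(x)) ** 2

    def test_a_zero_rejected(self):
        x = np.random.default_rng(1).standard_normal((10, 4))
        with pytest.raises(ValueError):
            fit_class_model(x, 0)

    def test_rank_exceeded_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((12, 2)) @ rng.standard_normal((2, 6))
        with pytest.raises(ValueError, match="rank"):
            fit_class_model(x, 4)

    def test_calibration_acceptance_band(self):
        x = gaussian_class_data(5, 20, 200, seed=3)
        model = fit_class_model(x, 5, 0.05)
        frac = accept_mask(model, x).mean()
        assert 0.90 <= frac <= 1.00

    def test_class_mean_is_origin(self):
        x = gaussian_class_data(3, 10, 50, seed=4)
        model = fit_class_model(x, 3)
        d = distances(model, x.mean(axis=0))
        assert d.t2 == pytest.approx(0.0, abs=1e-20)
        assert d.q == pytest.approx(0.0, abs=1e-20)
        assert d.d_red == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.standard_normal((5, 8)) * rng.uniform(0.5, 2.0, 8)
            sample = rng.standard_normal(8)
            model = fit_class_model(x, 2)
            d = distances(model, sample)
            q_bf, t2_bf = brute_force_distances(x, 2, sample)
            assert d.q == pytest.approx(q_bf, rel=1e-10, abs=1e-12)
            assert d.t2 == pytest.approx(t2_bf, rel=1e-10, abs=1e-12)

    def test_length_mismatch_rejected(self):
        x = gaussian_class_data(2, 6, 30, seed=6)
        model = fit_class_model(x, 2)
        with pytest.raises(ValueError):
            distances(model, np.zeros(7))

    def test_loadings_orthonormal(self):
        x = gaussian_class_data(4, 12, 60, seed=7)
        model = fit_class_model(x, 4)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-10)

    def test_serialization_roundtrip(self, tmp_path):
        x = gaussian_class_data(3, 10, 50, seed=8)
        model = fit_class_model(x, 3)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        sample = x[0]
        d0 = distances(model, sample)
        d1 = distances(loaded, sample)
        assert d1.q == pytest.approx(d0.q, rel=1e-12)
        assert d1.t2 == pytest.approx(d0.t2, rel=1e-12)
        assert d1.d_red == pytest.approx(d0.d_red, rel=1e-12)
        assert loaded.a == model.a and loaded.alpha == model.alpha


def synthetic_model(p=4, t2_lim=6.0, q_lim=2.0):
    return PCAClassModel(
        mean=np.zeros(p),
        loadings=np.eye(p)[:, :1],
        score_scale=np.ones(1),
        a=1,
        n_cal=50,
        alpha=0.05,
        t2_lim=t2_lim,
        q_lim=q_lim,
        q_moments=(1.0, 1.0),
    )


class TestClassify:
    def test_accept_class_mean(self):
        x = gaussian_class_data(2, 8, 40, seed=9)
        model = fit_class_model(x, 2)
        ok, d = classify(model, x.mean(axis=0))
        assert ok and d.d_red == 0.0

    def test_reject_far_point(self):
        x = gaussian_class_data(2, 8, 40, seed=10)
        model = fit_class_model(x, 2)
        far = x.mean(axis=0) + 10.0 * np.max(
            np.abs(x - x.mean(axis=0))
        ) * np.ones(8)
        ok, d = classify(model, far)
        assert not ok and d.d_red > SQRT2

    def test_boundary_point_accepted(self):
        model = synthetic_model()
        x = np.zeros(4)
        x[0] = math.sqrt(model.t2_lim * model.score_scale[0])
        x[1] = math.sqrt(model.q_lim)
        ok, d = classify(model, x)
        assert d.d_red == pytest.approx(SQRT2, rel=1e-12)
        assert ok

    def test_quarter_disc_geometry(self):
        # acceptance region in (t2_red, q_red) space is the sqrt(2) disc
        model = synthetic_model()
        for t2_red in np.linspace(0, 1.6, 9):
            for q_red in np.linspace(0, 1.6, 9):
                x = np.zeros(4)
                x[0] = math.sqrt(
                    t2_red * model.t2_lim * model.score_scale[0]
                )
                x[1] = math.sqrt(q_red * model.q_lim)
                ok, _ = classify(model, x)
                inside = math.hypot(t2_red, q_red) <= SQRT2 + 1e-9
                assert ok == inside


class TestCrossValidation:
    def test_exact_rank2_perfect(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((30, 2)) @ rng.standard_normal((2, 8))
        cv = cv_class_model(x, [1, 2], 0.05)
        assert cv.rmsecv[2] < 1e-10
        assert cv.sensitivity_cv[2] == 1.0

    def test_rmsecv_non_increasing(self):
        x = gaussian_class_data(3, 10, 40, seed=12)
        cv = cv_class_model(x, range(1, 6), 0.05)
        curve = [cv.rmsecv[a] for a in cv.a_values]
        assert all(
            curve[i + 1] <= curve[i] + 1e-10 for i in range(len(curve) - 1)
        )

    def test_paper_like_sensitivity_band(self):
        x = gaussian_class_data(3, 30, 90, seed=13)
        cv = cv_class_model(x, range(1, 6), 0.05)
        a = select_components(cv, "max_sensitivity_cv")
        assert 0.85 <= cv.sensitivity_cv[a] <= 1.0

    def test_small_fold_rejected(self):
        x = gaussian_class_data(2, 6, 12, seed=14)
        with pytest.raises(ValueError, match="training spectra"):
            cv_class_model(x, [9], 0.05)

    def test_specificity_and_efficiency(self):
        x = gaussian_class_data(2, 10, 50, seed=15)
        far = gaussian_class_data(2, 10, 20, seed=16) + 30.0
        cv = cv_class_model(x, [1, 2], 0.05, x_nontarget=far)
        assert cv.specificity_cv[2] == 1.0
        assert cv.efficiency_cv[2] == pytest.approx(
            math.sqrt(cv.sensitivity_cv[2]), rel=1e-12
        )

    def test_groups_share_folds(self):
        x = gaussian_class_data(2, 8, 40, seed=17)
        groups = [i // 2 for i in range(40)]  # replicate pairs
        cv = cv_class_model(x, [2], 0.05, groups=groups)
        assert cv.rmsecv[2] > 0  # runs without leakage errors


class TestSelectComponents:
    def cv_stub(self, sens=None, rmsecv=None, eff=None):
        a_values = list(range(1, 1 + len(sens or rmsecv or eff)))
        return CVResult(
            a_values=a_values,
            sensitivity_cv=dict(zip(a_values, sens or [0] * len(a_values))),
            rmsecv=dict(zip(a_values, rmsecv or [0] * len(a_values))),
            specificity_cv=None if eff is None else {},
            efficiency_cv=None if eff is None else dict(
                zip(a_values, eff)
            ),
        )

    def test_sensitivity_parsimony_tiebreak(self):
        cv = self.cv_stub(sens=[0.99, 0.99, 0.95])
        assert select_components(cv, "max_sensitivity_cv") == 1

    def test_convex_rmsecv_minimum(self):
        cv = self.cv_stub(rmsecv=[5.0, 3.0, 1.5, 1.0, 1.4])
        assert select_components(cv, "min_rmsecv") == 4

    def test_rmsecv_plateau_rule(self):
        # decrease below 1% relative at A=5: monotone-flattening point
        cv = self.cv_stub(rmsecv=[5.0, 3.0, 2.0, 1.5, 1.499, 1.498])
        assert select_components(cv, "min_rmsecv") == 5

    def test_efficiency_peak(self):
        eff = [0.5, 0.7, 0.9, 0.85, 0.6]
        cv = self.cv_stub(sens=[1] * 5, eff=eff)
        a = select_components(cv, "max_efficiency_cv")
        assert a == 1 + int(np.argmax(eff))

    def test_efficiency_requires_nontarget(self):
        cv = self.cv_stub(sens=[0.9, 0.95])
        with pytest.raises(ValueError):
            select_components(cv, "max_efficiency_cv")

    def test_first_rmsecv_minimum_monotone_curve(self):
        assert first_rmsecv_minimum([1, 2, 3], [3.0, 2.0, 1.0]) == 3


class TestClassMetrics:
    def test_table_sensitivity(self):
        m = class_metrics(89, 90, 1, 1)
        assert m.sensitivity_pct == 99

    def test_table_specificity(self):
        m = class_metrics(1, 1, 9, 11)
        assert m.specificity_pct == 82

    def test_perfect_efficiency(self):
        m = class_metrics(10, 10, 5, 5)
        assert m.efficiency == 1.0 and m.efficiency_pct == 100

    def test_geometric_mean(self):
        m = class_metrics(8, 10, 9, 10)
        assert m.efficiency == pytest.approx(math.sqrt(0.8 * 0.9))

    def test_zero_denominator_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            class_metrics(0, 0, 1, 1)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            class_metrics(11, 10, 0, 5)


class TestDDSIMCA:
    def test_dof_recovery_from_scaled_chi2(self):
        rng = np.random.default_rng(18)
        h = 2.5 * rng.chisquare(3, size=100_000)
        v = 0.7 * rng.chisquare(12, size=100_000)
        assert estimate_dof(h) == 3
        assert estimate_dof(v) == 12

    def test_calibration_sensitivity_near_nominal(self):
        x = gaussian_class_data(3, 20, 200, seed=19)
        model = ddsimca_fit(x, 0.05, range(1, 6))
        assert 0.93 <= model.calibration_sensitivity <= 0.99

    def test_alpha_monotonicity(self):
        x = gaussian_class_data(3, 20, 200, seed=20)
        test = gaussian_class_data(3, 20, 300, seed=21)
        strict = ddsimca_fit(x, 0.05, [3])
        loose = ddsimca_fit(x, 0.01, [3])
        acc_strict = ddsimca_classify(strict, test)
        acc_loose = ddsimca_classify(loose, test)
        assert acc_loose.sum() >= acc_strict.sum()
        assert np.all(acc_loose[acc_strict])  # nested acceptance regions

    def test_degenerate_agreement_with_alternative(self):
        # data in an exact 2-D subspace: q == 0, both rules reduce to a
        # threshold on t2 -- matched thresholds give identical decisions
        rng = np.random.default_rng(22)
        basis = rng.standard_normal((2, 6))
        x = rng.standard_normal((40, 2)) @ basis
        base = fit_class_model(x, 2, 0.05)
        c_crit = 5.0
        h0 = SQRT2 * base.t2_lim / c_crit
        dd = DDSIMCAModel(base=base, h0=h0, v0=1.0, nh=1, nv=1,
                          c_crit=c_crit, calibration_sensitivity=1.0)
        probe = rng.standard_normal((200, 2)) @ basis * 3.0
        alt = accept_mask(base, probe)
        ddm = ddsimca_classify(dd, probe)
        np.testing.assert_array_equal(alt, ddm)


class TestROC:
    def test_auc_pair_count_identity(self):
        rng = np.random.default_rng(23)
        d_t = rng.uniform(0, 2, 12)
        d_n = rng.uniform(0, 2, 8)
        # Mann-Whitney: fraction of (target, nontarget) pairs ordered
        wins = sum(
            1.0 if t < n else 0.5 if t == n else 0.0
            for t in d_t for n in d_n
        )
        assert roc_auc(d_t, d_n) == pytest.approx(
            wins / (len(d_t) * len(d_n)), abs=1e-10
        )

    def test_perfect_separation(self):
        x = gaussian_class_data(2, 10, 40, seed=24)
        far = gaussian_class_data(2, 10, 10, seed=25) + 50.0
        res = roc_simca(x, far, range(1, 4))
        assert all(v == pytest.approx(1.0) for v in res.auc.values())

    def test_permutation_auc_near_half(self):
        x = gaussian_class_data(2, 10, 60, seed=26)
        same = gaussian_class_data(2, 10, 40, seed=27)
        res = roc_simca(x, same, [2])
        assert abs(res.auc[2] - 0.5) <= 0.1

    def test_needs_two_nontarget(self):
        x = gaussian_class_data(2, 10, 40, seed=28)
        with pytest.raises(ValueError):
            roc_simca(x, x[:1], [2])

    def test_alpha_from_grid(self):
        x = gaussian_class_data(2, 10, 60, seed=29)
        far = gaussian_class_data(2, 10, 10, seed=30) + 20.0
        res = roc_simca(x, far, [1, 2])
        assert res.chosen_alpha in (0.10, 0.05, 0.025, 0.01)
        assert res.operating_threshold == pytest.approx(SQRT2)


class TestAcceptanceCalibrationProperty:
    def test_ddsimca_test_set_calibration(self):
        cal = gaussian_class_data(3, 50, 5000, seed=31)
        test = gaussian_class_data(3, 50, 1000, seed=32)
        model = ddsimca_fit(cal, 0.05, [3])
        frac = ddsimca_classify(model, test).mean()
        half = 1.96 * math.sqrt(0.95 * 0.05 / 1000)
        assert 0.95 - half <= frac <= 0.95 + half

    def test_alternative_rule_within_spec_band(self):
        cal = gaussian_class_data(3, 50, 1000, seed=33)
        test = gaussian_class_data(3, 50, 1000, seed=34)
        model = fit_class_model(cal, 3, 0.05)
        frac = accept_mask(model, test).mean()
        assert 0.90 <= frac <= 1.00
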