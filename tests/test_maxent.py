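import numpy as np
import pytest

from maxenm.maxent import (
    FeatureConfig,
    FeatureExpander,
    FeatureMatrix,
    MaxentModel,
    beta_class,
    build_feature_matrix,
    default_regularization,
    fit_maxent,
    kkt_residual,
    training_gain,
)
from maxenm.rasters import GridSpec, RasterStack


def _expander(n_vars=1, classes=("L",), **kw):
    names = [f"v{i}" for i in range(n_vars)]
    return FeatureExpander(
        variable_names=names,
        scaling={n: (0.0, 1.0) for n in names},
        config=FeatureConfig(classes=classes, **kw),
    )


class TestFeatureExpansion:
    def test_lqp_column_count_four_vars(self):
        # 4 linear + 4 quadratic + C(4,2)=6 products
        exp = _expander(4, ("L", "Q", "P"))
        X = np.random.default_rng(0).uniform(0, 1, (7, 4))
        assert exp.transform(X).shape[1] == 14
        assert len(exp.feature_meta()) == 14

    def test_single_linear_feature_is_minmax_scaled(self):
        cfg = FeatureConfig(classes=("L",))
        X = np.array([[2.0], [4.0], [10.0]])
        exp = FeatureExpander(["v0"], {"v0": (2.0, 10.0)}, cfg)
        out = exp.transform(X)
        assert np.allclose(out[:, 0], [0.0, 0.25, 1.0])

    def test_threshold_indicator_definition(self):
        exp = _expander(1, ("T",), n_threshold_knots=10)
        knots = [m["knot"] for m in exp.feature_meta()]
        k = knots[3]
        eps = 1e-9
        out = exp.transform(np.array([[k - eps], [k + eps]]))
        assert out[0, 3] == 0.0 and out[1, 3] == 1.0

    def test_hinge_features_in_unit_interval(self):
        exp = _expander(2, ("H",), n_hinge_knots=20)
        X = np.random.default_rng(1).uniform(0, 1, (50, 2))
        out = exp.transform(X)
        assert out.shape[1] == 2 * 2 * 20
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_constant_variable_flagged_not_error(self):
        cfg = FeatureConfig(classes=("L",))
        vals = np.array([[1.0, 3.0], [1.0, 4.0]])
        exp = FeatureExpander.from_calibration(vals, ["a", "b"], cfg)
        assert exp.constant_vars == ["a"]
        assert np.allclose(exp.transform(vals)[:, 0], 0.0)


class TestRegularization:
    def _meta_and_features(self):
        rng = np.random.default_rng(2)
        pres = rng.uniform(0, 1, (25, 3))
        meta = [{"class": c, "vars": ("v",), "knot": None} for c in ("L", "Q", "H")]
        return meta, pres

    def test_rm_doubling_doubles_lambda(self):
        meta, pres = self._meta_and_features()
        l1 = default_regularization(meta, pres, 25, 1.0)
        l2 = default_regularization(meta, pres, 25, 2.0)
        assert np.allclose(l2, 2.0 * l1)

    def test_constant_feature_hits_floor(self):
        meta = [{"class": "L", "vars": ("v",), "knot": None}]
        pres = np.full((16, 1), 0.3)
        lam = default_regularization(meta, pres, 16, 1.5)
        assert lam[0] == pytest.approx(1.5 * beta_class("L", 16) / 16)

    def test_hinge_base_is_half_at_any_sample_size(self):
        for m in (5, 17, 80, 1000):
            assert beta_class("H", m) == 0.5


def _two_cell_fixture():
    """One binary feature; presences 2/3 at the f=1 cell."""
    exp = _expander(1, ("L",))
    fm = FeatureMatrix(
        presence=np.array([[1.0], [1.0], [0.0]]),
        background=np.array([[0.0], [1.0]]),
        expander=exp,
    )
    return fm


class TestFitting:
    def test_fully_penalized_fit_is_uniform(self, calibration_data):
        d = calibration_data
        fm = build_feature_matrix(d["pres"], d["bg"], d["names"], FeatureConfig(classes=("L", "Q")))
        model = fit_maxent(fm, np.full(fm.presence.shape[1], 1e3))
        assert np.all(model.beta == 0.0)
        raw = model.raw_values(d["bg"])
        assert np.allclose(raw, 1.0 / d["bg"].shape[0])

    def test_two_cell_closed_form_gibbs_matching(self):
        fm = _two_cell_fixture()
        model = fit_maxent(fm, np.zeros(1), kkt_tol=1e-8)
        # stationarity: presence mean 2/3 = e^b/(1+e^b)  =>  b = ln 2
        assert model.beta[0] == pytest.approx(np.log(2.0), abs=1e-4)

    def test_two_cell_matches_brute_force_objective_scan(self):
        fm = _two_cell_fixture()
        model = fit_maxent(fm, np.zeros(1), kkt_tol=1e-8)
        betas = np.linspace(-3, 3, 20001)
        # scalar objective: -(1/3)(2b) + log(1 + e^b) - log 2
        obj = -(2.0 / 3.0) * betas + np.logaddexp(0.0, betas) - np.log(2.0)
        assert model.beta[0] == pytest.approx(betas[np.argmin(obj)], abs=1e-3)

    def test_kkt_stationarity_on_converged_fit(self, fitted_lqp):
        model, fm, lam = fitted_lqp
        assert kkt_residual(model.beta, fm.presence, fm.background, lam) <= 1e-4

    def test_raw_sums_to_one_over_background(self, fitted_lqp, calibration_data):
        model, fm, _ = fitted_lqp
        assert model.raw_values(calibration_data["bg"]).sum() == pytest.approx(1.0, abs=1e-6)

    def test_affine_rescaling_invariance(self, calibration_data):
        d = calibration_data
        pres, bg = d["pres"][:, :2], d["bg"][:, :2]
        names = d["names"][:2]
        cfg = FeatureConfig(classes=("L", "Q"))
        fm1 = build_feature_matrix(pres, bg, names, cfg)
        fm2 = build_feature_matrix(3.0 * pres + 7.0, 3.0 * bg + 7.0, names, cfg)
        lam1 = default_regularization(fm1.meta, fm1.presence, pres.shape[0], 1.0)
        lam2 = default_regularization(fm2.meta, fm2.presence, pres.shape[0], 1.0)
        m1 = fit_maxent(fm1, lam1)
        m2 = fit_maxent(fm2, lam2)
        p1 = m1.logistic_values(bg)
        p2 = m2.logistic_values(3.0 * bg + 7.0)
        assert np.allclose(p1, p2, atol=1e-6)


class TestPrediction:
    def _tiny_model(self):
        exp = _expander(1, ("L",))
        bgv = np.array([[0.1], [0.5], [0.9]])
        beta = np.array([0.7])
        eta = bgv[:, 0] * 0.7
        z = np.exp(eta).sum()
        q = np.exp(eta) / z
        H = float(-(q * np.log(q)).sum())
        return (
            MaxentModel(
                beta=beta,
                log_z=float(np.log(z)),
                entropy=H,
                rm=1.0,
                lambdas=np.zeros(1),
                clamp_bounds={"v0": (0.0, 1.0)},
                feature_config=exp.config,
                variable_set=["v0"],
                expander=exp,
            ),
            bgv,
            q,
            H,
        )

    def test_three_cell_logistic_hand_computation(self):
        model, bgv, q, H = self._tiny_model()
        raw = model.raw_values(bgv)
        assert np.allclose(raw, q, atol=1e-12)
        expected = np.exp(H) * q / (1.0 + np.exp(H) * q)
        assert np.allclose(model.logistic_values(bgv), expected, atol=1e-10)

    def test_raw_equal_exp_neg_entropy_gives_half(self):
        model, *_ , H = self._tiny_model()
        # invert: find value whose raw equals e^-H  ->  eta = log Z - H
        x = (model.log_z - H) / 0.7
        val = model.logistic_values(np.array([[x]]), clamp=False)
        assert val[0] == pytest.approx(0.5, abs=1e-12)

    def test_clamping_truncates_to_bound(self):
        model, bgv, _, _ = self._tiny_model()
        beyond = np.array([[1.7]])
        at_bound = np.array([[1.0]])
        assert model.raw_values(beyond, clamp=True)[0] == pytest.approx(
            model.raw_values(at_bound, clamp=False)[0]
        )
        assert model.raw_values(beyond, clamp=False)[0] > model.raw_values(at_bound, clamp=False)[0]

    def test_missing_variable_raises(self):
        model, *_ = self._tiny_model()
        grid = GridSpec(nrows=10, ncols=10, xllcorner=0, yllcorner=0, cellsize=0.1)
        stack = RasterStack(grid, {"other": np.zeros((10, 10))})
        with pytest.raises(KeyError):
            model.predict_logistic(stack)

    def test_json_round_trip_preserves_predictions(self, fitted_lqp, calibration_data):
        model, _, _ = fitted_lqp
        back = MaxentModel.from_json(model.to_json())
        bg = calibration_data["bg"]
        assert np.array_equal(model.logistic_values(bg), back.logistic_values(bg))


class TestRegularizationPath:
    def test_sparsity_and_gain_monotone_in_rm(self, calibration_data):
        from maxenm.selection import enumerate_rm_values

        d = calibration_data
        pres, bg = d["pres"][:, :3], d["bg"][:, :3]
        fm = build_feature_matrix(pres, bg, d["names"][:3], FeatureConfig(classes=("L", "Q", "P")))
        ks, gains = [], []
        for rm in enumerate_rm_values():
            lam = default_regularization(fm.meta, fm.presence, pres.shape[0], rm)
            model = fit_maxent(fm, lam)
            ks.append(model.n_parameters)
            gains.append(training_gain(model, fm, regularized=False))
        assert all(a >= b for a, b in zip(ks, ks[1:]))
        assert all(a >= b - 1e-6 for a, b in zip(gains, gains[1:]))
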