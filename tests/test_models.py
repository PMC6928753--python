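import numpy as np
import pytest

from npk3d import (
    EmptyCloudError,
    MultispectralPointCloud,
    evaluate_model,
    extract_canopy_reflectance,
    fit_bpann,
    fit_gpr,
    fit_svmr,
    nitrogen_mass_fraction,
    phosphorus_mass_fraction,
    potassium_mass_fraction,
    run_model_matrix,
    split_calibration_prediction,
)
from npk3d.synthetic import make_linear_calibration_dataset


@pytest.fixture(scope="module")
def linear_data():
    X, y = make_linear_calibration_dataset(n=60, seed=1)
    ic, ip = split_calibration_prediction(60, n_calib=42, seed=1)
    return X, y, ic, ip


class TestExtractCanopyReflectance:
    def _cloud(self, refl, valid=None, wl=(500.0, 600.0)):
        refl = np.atleast_2d(refl)
        return MultispectralPointCloud(
            coords=np.zeros((len(refl), 3)),
            reflectance=refl,
            refl_valid=valid,
            wavelengths_nm=np.asarray(wl)[: refl.shape[1]],
        )

    def test_uniform_reflectance(self):
        cloud = self._cloud(np.full((10, 2), 0.5))
        assert np.allclose(extract_canopy_reflectance(cloud, [500.0, 600.0]), 0.5)

    def test_invalid_points_excluded_from_mean(self):
        refl = np.array([[0.2], [0.6], [9.9]])
        valid = np.array([[True], [True], [False]])
        cloud = self._cloud(refl, valid, wl=(550.0,))
        assert extract_canopy_reflectance(cloud, [550.0])[0] == pytest.approx(0.4)

    def test_absent_wavelength_raises(self):
        with pytest.raises(KeyError):
            extract_canopy_reflectance(self._cloud(np.full((4, 2), 0.1)), [999.0])

    def test_cloud_without_reflectance_raises(self):
        cloud = MultispectralPointCloud(coords=np.zeros((3, 3)))
        with pytest.raises(EmptyCloudError):
            extract_canopy_reflectance(cloud, [500.0])


class TestLearners:
    def test_bpann_recovers_linear_map(self, linear_data):
        X, y, ic, ip = linear_data
        model = fit_bpann(X[ic], y[ic], seed=0)
        ev = evaluate_model(model, (X[ic], y[ic]), (X[ip], y[ip]))
        assert ev.Rp2 >= 0.99

    def test_bpann_constant_target(self):
        X = np.random.default_rng(0).random((10, 3))
        model = fit_bpann(X, np.full(10, 5.0), seed=0)
        assert np.allclose(model.predict(X), 5.0, atol=1e-2)

    def test_bpann_deterministic_given_seed(self, linear_data):
        X, y, ic, _ = linear_data
        p1 = fit_bpann(X[ic], y[ic], seed=7).predict(X)
        p2 = fit_bpann(X[ic], y[ic], seed=7).predict(X)
        assert np.array_equal(p1, p2)

    def test_svmr_recovers_linear_map(self, linear_data):
        X, y, ic, ip = linear_data
        ev = evaluate_model(fit_svmr(X[ic], y[ic]), (X[ic], y[ic]), (X[ip], y[ip]))
        assert ev.Rp2 >= 0.95

    def test_svmr_duplicate_rows_identical_predictions(self, linear_data):
        X, y, ic, _ = linear_data
        Xd = np.vstack([X[ic], X[ic][:5]])
        yd = np.concatenate([y[ic], y[ic][:5]])
        pred = fit_svmr(Xd, yd).predict(np.vstack([X[ic][:5], X[ic][:5]]))
        assert np.array_equal(pred[:5], pred[5:])

    def test_svmr_invariant_to_feature_rescaling(self, linear_data):
        """Internal standardization makes predictions invariant to per-feature
        affine rescaling of the inputs."""
        X, y, ic, ip = linear_data
        scale = np.array([10.0, 0.2, 3.0, 1.0, 100.0])
        offset = np.array([1.0, -5.0, 0.0, 2.0, 0.3])
        p_raw = fit_svmr(X[ic], y[ic]).predict(X[ip])
        p_scaled = fit_svmr(X[ic] * scale + offset, y[ic]).predict(X[ip] * scale + offset)
        assert np.allclose(p_raw, p_scaled, atol=1e-8)

    def test_gpr_interpolates_training_points(self, linear_data):
        X, y, ic, _ = linear_data
        model = fit_gpr(X[ic], y[ic], seed=0)
        assert np.allclose(model.predict(X[ic]), y[ic], atol=1e-3)

    def test_gpr_smooth_function_one_feature(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 1, 60))[:, None]
        y = np.sin(2 * np.pi * x[:, 0]) * 3 + 10
        ic, ip = split_calibration_prediction(60, 42, seed=2)
        model = fit_gpr(x[ic], y[ic], seed=2)
        ev = evaluate_model(model, (x[ic], y[ic]), (x[ip], y[ip]))
        assert ev.Rp2 >= 0.99

    def test_nan_input_rejected(self):
        X = np.zeros((5, 2))
        y = np.array([1.0, np.nan, 2.0, 3.0, 4.0])
        for fitter in (fit_bpann, fit_svmr, fit_gpr):
            with pytest.raises(ValueError):
                fitter(X, y)


class TestEvaluateModel:
    class _Fixed:
        def __init__(self, mapping):
            self.mapping = mapping

        def predict(self, X):
            return np.array([self.mapping[float(x[0])] for x in np.atleast_2d(X)])

    def test_perfect_predictions(self):
        model = self._Fixed({0.0: 1.0, 1.0: 2.0, 2.0: 3.0})
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([1.0, 2.0, 3.0])
        ev = evaluate_model(model, (X, y), (X, y))
        assert ev.Rc2 == ev.Rp2 == 1.0
        assert ev.RMSEC == ev.RMSEP == ev.RE == 0.0

    def test_two_point_worked_example(self):
        """Measured (10, 20) vs predicted (11, 19): RMSEP = 1, RE = 7.5 %."""
        model = self._Fixed({0.0: 11.0, 1.0: 19.0, 5.0: 1.0, 6.0: 2.0})
        calib = (np.array([[5.0], [6.0]]), np.array([1.0, 2.0]))
        pred = (np.array([[0.0], [1.0]]), np.array([10.0, 20.0]))
        ev = evaluate_model(model, calib, pred)
        assert ev.RMSEP == pytest.approx(1.0, abs=1e-12)
        assert ev.RE == pytest.approx(7.5, abs=1e-12)

    def test_constant_predictions_flag_undefined_r2(self):
        model = self._Fixed({0.0: 5.0, 1.0: 5.0, 2.0: 5.0})
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([1.0, 2.0, 3.0])
        ev = evaluate_model(model, (X, y), (X, y))
        assert np.isnan(ev.Rp2)

    def test_zero_target_rejected_for_re(self):
        model = self._Fixed({0.0: 1.0, 1.0: 1.0})
        X = np.array([[0.0], [1.0]])
        with pytest.raises(ValueError):
            evaluate_model(model, (X, np.array([1.0, 2.0])), (X, np.array([0.0, 2.0])))

    def test_re_invariant_to_sample_order(self):
        model = self._Fixed({0.0: 11.0, 1.0: 19.0})
        X = np.array([[0.0], [1.0]])
        y = np.array([10.0, 20.0])
        a = evaluate_model(model, (X, y), (X, y))
        b = evaluate_model(model, (X[::-1], y[::-1]), (X[::-1], y[::-1]))
        assert a.RE == b.RE and a.RMSEP == b.RMSEP


class TestChemistryFormulas:
    def test_nitrogen_worked_example(self):
        w1 = nitrogen_mass_fraction(V2=20, V0=0.5, c=0.05, V1=50, V=250, m=0.5)
        assert w1 == pytest.approx(13.65, abs=1e-12)

    def test_nitrogen_blank_equals_sample_gives_zero(self):
        assert nitrogen_mass_fraction(V2=5, V0=5, c=0.05, V1=50, V=250, m=0.5) == 0.0

    def test_nitrogen_mass_proportionality(self):
        w = nitrogen_mass_fraction(20, 0.5, 0.05, 50, 250, 0.5)
        assert nitrogen_mass_fraction(20, 0.5, 0.05, 50, 250, 1.0) == pytest.approx(w / 2)

    def test_phosphorus_worked_example(self):
        assert phosphorus_mass_fraction(rho=2, V=100, V1=10, V2=50, m=0.5) == pytest.approx(
            0.2, abs=1e-12
        )

    def test_phosphorus_zero_and_linearity(self):
        assert phosphorus_mass_fraction(0, 100, 10, 50, 0.5) == 0.0
        assert phosphorus_mass_fraction(4, 100, 10, 50, 0.5) == pytest.approx(0.4)

    def test_potassium_worked_example(self):
        w3 = potassium_mass_fraction(rho=5, rho0=0.2, V=100, V1=10, V2=50, m=0.5)
        assert w3 == pytest.approx(0.48, abs=1e-12)

    def test_potassium_blank_cancellation_and_antisymmetry(self):
        assert potassium_mass_fraction(0.7, 0.7, 100, 10, 50, 0.5) == 0.0
        a = potassium_mass_fraction(5, 0.2, 100, 10, 50, 0.5)
        b = potassium_mass_fraction(0.2, 5, 100, 10, 50, 0.5)
        assert a == pytest.approx(-b)

    def test_invalid_denominators_rejected(self):
        with pytest.raises(ValueError):
            nitrogen_mass_fraction(20, 0.5, 0.05, 50, 250, 0.0)
        with pytest.raises(ValueError):
            phosphorus_mass_fraction(2, 100, 0.0, 50, 0.5)
        with pytest.raises(ValueError):
            potassium_mass_fraction(5, 0.2, 100, 0.0, 50, 0.5)


class TestModelMatrix:
    def test_full_grid_has_45_rows(self):
        rng = np.random.default_rng(0)
        X, y = make_linear_calibration_dataset(n=60, seed=0)
        features = {src: X + 0.001 * rng.standard_normal(X.shape)
                    for src in ("AOV1", "AOV2", "AOV3", "AOV4", "3DROI")}
        targets = {"N": y, "P": y * 0.2 + 1, "K": y * 0.8 + 2}
        table = run_model_matrix(features, targets, seed=0)
        assert len(table) == 45
        assert set(table["Model"]) == {"BPANN", "SVMR", "GPR"}
        assert set(table["Input"]) == set(features)

    def test_single_source_single_method_three_rows(self):
        X, y = make_linear_calibration_dataset(n=60, seed=3)
        table = run_model_matrix({"3DROI": X}, {"N": y, "P": y, "K": y},
                                 methods=("GPR",), seed=3)
        assert len(table) == 3
        assert np.all(table["Rp2"] >= 0.95)

    def test_view_occlusion_stability_mechanism(self):
        """Each single view sees a biased subset of canopy points, so its mean
        reflectance varies across views; the fused-cloud mean is one number."""
        rng = np.random.default_rng(5)
        refl = np.clip(rng.normal(0.4, 0.1, (2000, 3)), 0, 1)
        height = rng.uniform(0, 1, 2000)
        cloud = MultispectralPointCloud(
            coords=np.column_stack([rng.normal(size=2000), height, rng.normal(size=2000)]),
            reflectance=refl,
            wavelengths_nm=[500.0, 600.0, 700.0],
        )
        full = extract_canopy_reflectance(cloud, [500.0, 600.0, 700.0])
        view_means = []
        for k in range(4):  # biased visibility per view
            visible = (height > 0.25 * k) & (height < 0.25 * k + 0.4)
            view_means.append(
                extract_canopy_reflectance(cloud.select(visible), [500.0, 600.0, 700.0])
            )
        view_means = np.array(view_means)
        assert np.ptp(view_means, axis=0).max() > 0  # single views disagree
        # the 3DROI feature is unique: recomputing it is exactly reproducible
        assert np.array_equal(full, extract_canopy_reflectance(cloud, [500.0, 600.0, 700.0]))
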