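"""Nutrient regression models and wet-chemistry reference formulas.

Mean reflectance at the characteristic wavelengths — either over the fused 3D
canopy cloud ("3DROI") or over one single-view cloud — is mapped to the measured
N/P/K mass content (mg/g) by three learners: a three-layer back-propagation
neural network (tanh hidden layer, linear output, quasi-Newton training), an
epsilon-SVR with a Gaussian kernel, and Gaussian-process regression with a
rational-quadratic kernel.  Model quality is summarized by Rc²/Rp² (squared
Pearson correlation between measured and predicted values on the calibration /
prediction set), RMSEC/RMSEP, and the mean relative prediction error RE (%).

The wet-chemistry formulas convert titration/spectrophotometry readings into
mass fractions (g/100 g): Kjeldahl for N, molybdenum-antimony colorimetry for P,
flame atomic absorption for K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, RationalQuadratic, WhiteKernel
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .cloud import MultispectralPointCloud
from .errors import EmptyCloudError

__all__ = [
    "ModelEvaluation",
    "extract_canopy_reflectance",
    "fit_bpann",
    "fit_svmr",
    "fit_gpr",
    "evaluate_model",
    "nitrogen_mass_fraction",
    "phosphorus_mass_fraction",
    "potassium_mass_fraction",
    "split_calibration_prediction",
    "run_model_matrix",
    "MODEL_FITTERS",
]


def extract_canopy_reflectance(
    cloud: MultispectralPointCloud, wavelengths_nm, tol: float = 1e-6
) -> np.ndarray:
    """Mean reflectance per requested wavelength over spectrally valid points."""
    if cloud.reflectance is None or cloud.wavelengths_nm is None:
        raise EmptyCloudError("cloud carries no reflectance")
    out = []
    for w in np.atleast_1d(wavelengths_nm):
        idx = np.where(np.isclose(cloud.wavelengths_nm, w, atol=tol))[0]
        if idx.size == 0:
            raise KeyError(f"wavelength {w} nm not present in the cloud")
        b = idx[0]
        valid = cloud.refl_valid[:, b]
        if not valid.any():
            raise EmptyCloudError(f"no valid reflectance at {w} nm")
        out.append(float(cloud.reflectance[valid, b].mean()))
    return np.array(out)


def _check_xy(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN in training data")
    if len(X) != len(y) or len(y) < 2:
        raise ValueError("need >= 2 matched samples")
    return X, y


class _StandardizedTarget:
    """Wrap a pipeline with target standardization (all three learners use it)."""

    def __init__(self, pipeline: Pipeline):
        self.pipeline = pipeline
        self._mu = 0.0
        self._sd = 1.0

    def fit(self, X, y):
        self._mu = float(np.mean(y))
        self._sd = float(np.std(y))
        ys = (y - self._mu) / self._sd if self._sd > 0 else y - self._mu
        self.pipeline.fit(X, ys)
        return self

    def predict(self, X):
        return self.pipeline.predict(np.atleast_2d(np.asarray(X, float))) * (
            self._sd if self._sd > 0 else 1.0
        ) + self._mu


def fit_bpann(
    X,
    y,
    hidden_nodes: int = 15,
    max_iter: int = 500,
    goal: float = 1e-4,
    seed: int = 0,
) -> _StandardizedTarget:
    """Three-layer feedforward net: tanh hidden layer (15 nodes), linear output,
    quasi-Newton (L-BFGS) training to the iteration/goal limits; standardized
    inputs and target; seeded weight initialization."""
    X, y = _check_xy(X, y)
    net = MLPRegressor(
        hidden_layer_sizes=(hidden_nodes,),
        activation="tanh",
        solver="lbfgs",
        max_iter=max_iter,
        tol=goal,
        alpha=1e-6,
        random_state=seed,
    )
    model = _StandardizedTarget(Pipeline([("scale", StandardScaler()), ("net", net)]))
    return model.fit(X, y)


def _auto_box_constraint(y: np.ndarray) -> float:
    """IQR-based rule for the SVR box constraint on the standardized target."""
    sd = np.std(y)
    if sd == 0:
        return 1.0
    iqr = np.subtract(*np.percentile(y, [75, 25])) / sd
    return max(iqr / 1.349, 1e-3)


def fit_svmr(
    X,
    y,
    kernel_scale: float = 0.56,
    box_constraint: float | None = None,
    epsilon: float | None = None,
) -> _StandardizedTarget:
    """Epsilon-SVR, Gaussian kernel with kernel scale s (gamma = 1/s²) on
    standardized features; 'automatic' box constraint resolved as iqr(y)/1.349
    on the standardized target and epsilon as box/10."""
    X, y = _check_xy(X, y)
    C = box_constraint if box_constraint is not None else _auto_box_constraint(y)
    eps = epsilon if epsilon is not None else C / 10.0
    svr = SVR(kernel="rbf", gamma=1.0 / kernel_scale**2, C=C, epsilon=eps)
    model = _StandardizedTarget(Pipeline([("scale", StandardScaler()), ("svr", svr)]))
    return model.fit(X, y)


def fit_gpr(
    X,
    y,
    n_restarts: int = 3,
    seed: int = 0,
) -> _StandardizedTarget:
    """GP regression: constant mean, isotropic rational-quadratic kernel plus a
    white-noise term, hyperparameters optimized by marginal likelihood with
    seeded restarts; standardized features and target."""
    X, y = _check_xy(X, y)
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RationalQuadratic(
        length_scale=1.0, alpha=1.0, length_scale_bounds=(1e-2, 1e3)
    ) + WhiteKernel(1e-5, (1e-10, 1e1))
    gp = GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=False,
        n_restarts_optimizer=n_restarts,
        random_state=seed,
        alpha=1e-10,
    )
    model = _StandardizedTarget(Pipeline([("scale", StandardScaler()), ("gp", gp)]))
    return model.fit(X, y)


MODEL_FITTERS = {"BPANN": fit_bpann, "SVMR": fit_svmr, "GPR": fit_gpr}


@dataclass(frozen=True)
class ModelEvaluation:
    """Calibration/prediction figures of merit (Rc², Rp², RMSEC, RMSEP, RE%)."""

    Rc2: float
    Rp2: float
    RMSEC: float
    RMSEP: float
    RE: float

    def as_dict(self) -> dict:
        return {"Rc2": self.Rc2, "Rp2": self.Rp2, "RMSEC": self.RMSEC,
                "RMSEP": self.RMSEP, "RE_pct": self.RE}


def _r2_pearson(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.std(y) == 0 or np.std(yhat) == 0:
        return float("nan")  # undefined for constant series
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def _r2_sse(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return float("nan")
    return 1.0 - float(((y - yhat) ** 2).sum()) / sst


def evaluate_model(
    model,
    calib: tuple[np.ndarray, np.ndarray],
    pred: tuple[np.ndarray, np.ndarray],
    r2_convention: str = "pearson",
) -> ModelEvaluation:
    """Rc²/Rp², RMSEC/RMSEP and RE of a fitted model.

    R² defaults to the squared Pearson correlation between measured and
    predicted values (``r2_convention='sse'`` gives 1 − SSE/SST instead);
    RE = mean(|ŷ−y| / y) × 100 over the prediction set, which therefore must
    not contain zero targets.
    """
    Xc, yc = _check_xy(*calib)
    Xp, yp = _check_xy(*pred)
    if np.any(yp == 0):
        raise ValueError("RE undefined: prediction target contains zero")
    r2 = {"pearson": _r2_pearson, "sse": _r2_sse}[r2_convention]
    yhat_c = model.predict(Xc)
    yhat_p = model.predict(Xp)
    return ModelEvaluation(
        Rc2=r2(yc, yhat_c),
        Rp2=r2(yp, yhat_p),
        RMSEC=float(np.sqrt(np.mean((yhat_c - yc) ** 2))),
        RMSEP=float(np.sqrt(np.mean((yhat_p - yp) ** 2))),
        RE=float(np.mean(np.abs(yhat_p - yp) / yp) * 100.0),
    )


def split_calibration_prediction(
    n: int, n_calib: int = 42, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle split into calibration / prediction index sets (42/18 default)."""
    if not 0 < n_calib < n:
        raise ValueError("need 0 < n_calib < n")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return np.sort(order[:n_calib]), np.sort(order[n_calib:])


def nitrogen_mass_fraction(V2, V0, c, V1, V, m) -> float:
    """Kjeldahl N mass fraction w1 (g/100 g):
    w1 = (V2 − V0) · c · 0.0140 / (m · (V1/V)) · 100."""
    if m <= 0 or V1 <= 0 or V <= 0:
        raise ValueError("m, V1 and V must be positive")
    return (V2 - V0) * c * 0.0140 / (m * (V1 / V)) * 100.0


def phosphorus_mass_fraction(rho, V, V1, V2, m) -> float:
    """Colorimetric P mass fraction w2 (g/100 g): w2 = ρ·V/m · V2/V1 · 1e−4."""
    if m <= 0 or V1 <= 0:
        raise ValueError("m and V1 must be positive")
    return rho * V / m * V2 / V1 * 1e-4


def potassium_mass_fraction(rho, rho0, V, V1, V2, m) -> float:
    """Flame-AAS K mass fraction w3 (g/100 g): w3 = (ρ−ρ0)·V/m · V2/V1 · 1e−4."""
    if m <= 0 or V1 <= 0:
        raise ValueError("m and V1 must be positive")
    return (rho - rho0) * V / m * V2 / V1 * 1e-4


def run_model_matrix(
    features: dict[str, np.ndarray],
    targets: dict[str, np.ndarray],
    methods: tuple[str, ...] = ("BPANN", "SVMR", "GPR"),
    n_calib: int = 42,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit and evaluate the full nutrient × method × input-source grid.

    ``features`` maps an input source (AOV1..AOV4, 3DROI) to its samples ×
    wavelengths matrix; ``targets`` maps a nutrient to its measured values.
    Sample order must be consistent across sources.  Returns one row per
    (nutrient, method, source) with the five figures of merit.
    """
    rows = []
    for nutrient, y in targets.items():
        for source, X in features.items():
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if len(X) != len(y):
                raise ValueError(f"{source}: {len(X)} samples but {len(y)} targets")
            ic, ip = split_calibration_prediction(len(y), n_calib=n_calib, seed=seed)
            y = np.asarray(y, dtype=float)
            for method in methods:
                fitter = MODEL_FITTERS[method]
                kwargs = {"seed": seed} if method in ("BPANN", "GPR") else {}
                model = fitter(X[ic], y[ic], **kwargs)
                ev = evaluate_model(model, (X[ic], y[ic]), (X[ip], y[ip]))
                rows.append(
                    {"Nutrient": nutrient, "Model": method, "Input": source, **ev.as_dict()}
                )
    return pd.DataFrame(rows)
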