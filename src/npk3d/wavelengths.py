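"""Characteristic-wavelength selection for canopy nutrient spectra (PCA-CC-RF).

The pipeline mirrors standard chemometric practice for pushbroom canopy spectra:

1. Gaussian smoothing of each reflectance curve.
2. Removal of sensor-interference bands (the near-infrared bands polluted by the
   depth camera's active illumination).
3. PCA of the mean-centered spectra; local extrema of the aggregated component
   loadings mark spectrally resolved regions.
4. Per-wavelength Pearson correlation of reflectance with the nutrient value.
5. Random frog: an iterative stochastic subset search scored by cross-validated
   PLS regression, yielding a per-wavelength selection probability.
6. Combination: local peaks of the selection probability within spectrally
   coherent (high neighbor-autocorrelation) regions are kept, screened by the
   PCA/correlation evidence, and optionally supplemented with PCA-CC wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold

from .errors import DegenerateInputError, DimensionError

__all__ = [
    "SpectraMatrix",
    "DEFAULT_INTERFERENCE_BANDS_NM",
    "SelectionRules",
    "SelectionResult",
    "RandomFrogParams",
    "smooth_spectra",
    "remove_interference_bands",
    "pca_weights",
    "nutrient_correlations",
    "autocorrelation",
    "random_frog",
    "select_wavelengths",
]

#: Near-infrared bands corrupted by the depth sensor's active illumination (nm).
DEFAULT_INTERFERENCE_BANDS_NM = (841.42, 846.85, 852.30, 857.74, 863.19, 868.65)


@dataclass
class SpectraMatrix:
    """Samples × wavelengths reflectance with sample ids."""

    reflectance: np.ndarray
    wavelengths_nm: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self):
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.reflectance.shape[1] != self.wavelengths_nm.size:
            raise DimensionError(
                f"{self.reflectance.shape[1]} columns but {self.wavelengths_nm.size} wavelengths"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.sample_ids is None:
            self.sample_ids = [f"s{k}" for k in range(self.reflectance.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths_nm.size

    def column(self, wavelength_nm: float, tol: float = 1e-6) -> np.ndarray:
        idx = np.where(np.isclose(self.wavelengths_nm, wavelength_nm, atol=tol))[0]
        if idx.size == 0:
            raise KeyError(f"wavelength {wavelength_nm} nm not in matrix")
        return self.reflectance[:, idx[0]]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.reflectance, index=self.sample_ids, columns=self.wavelengths_nm
        )
        df.index.name = "sample_id"
        df.to_csv(path)

    @staticmethod
    def from_csv(path) -> "SpectraMatrix":
        df = pd.read_csv(path, index_col=0)
        return SpectraMatrix(
            reflectance=df.to_numpy(float),
            wavelengths_nm=df.columns.to_numpy(float),
            sample_ids=[str(s) for s in df.index],
        )


def smooth_spectra(spectra: SpectraMatrix, window: int = 6) -> SpectraMatrix:
    """Per-curve Gaussian smoothing (sigma = window/3, reflective boundary)."""
    if window < 3:
        raise ValueError("window must be >= 3")
    if window > spectra.n_wavelengths:
        raise ValueError("smoothing window larger than the number of bands")
    smoothed = gaussian_filter1d(
        spectra.reflectance, sigma=window / 3.0, axis=1, mode="reflect"
    )
    return SpectraMatrix(smoothed, spectra.wavelengths_nm.copy(), list(spectra.sample_ids))


def remove_interference_bands(
    spectra: SpectraMatrix,
    bands_nm: tuple[float, ...] = DEFAULT_INTERFERENCE_BANDS_NM,
    tol: float = 1e-6,
) -> SpectraMatrix:
    """Drop the listed wavelength columns (default: the six NIR interference bands)."""
    drop = np.zeros(spectra.n_wavelengths, dtype=bool)
    for w in bands_nm:
        idx = np.where(np.isclose(spectra.wavelengths_nm, w, atol=tol))[0]
        if idx.size == 0:
            raise KeyError(f"interference band {w} nm not present in the wavelength list")
        drop[idx[0]] = True
    keep = ~drop
    return SpectraMatrix(
        spectra.reflectance[:, keep],
        spectra.wavelengths_nm[keep],
        list(spectra.sample_ids),
    )


@dataclass
class PcaWeights:
    loadings: np.ndarray  # wavelengths × components
    contributions_pct: np.ndarray  # per-component explained variance, %
    peak_wavelengths_nm: np.ndarray  # local extrema of the aggregated |loading|
    aggregate_weight: np.ndarray  # contribution-weighted |loading| profile


def _local_extrema(profile: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima."""
    p = np.asarray(profile, dtype=float)
    idx = np.where((p[1:-1] > p[:-2]) & (p[1:-1] > p[2:]))[0] + 1
    return idx


def pca_weights(spectra: SpectraMatrix, n_components: int = 8) -> PcaWeights:
    """PCA of mean-centered (not variance-scaled) reflectance.

    Returns per-component loading vectors, explained-variance percentages, and
    candidate wavelengths at the local extrema of the contribution-weighted
    aggregate |loading| profile.
    """
    X = spectra.reflectance
    if spectra.n_samples < n_components:
        raise ValueError("need at least as many samples as components")
    if np.allclose(X.var(axis=0), 0):
        raise DegenerateInputError("zero-variance spectra matrix")
    pca = PCA(n_components=n_components)
    pca.fit(X)
    loadings = pca.components_.T  # wavelengths × components
    contrib = 100.0 * pca.explained_variance_ratio_
    weights = np.abs(loadings) @ (contrib / contrib.sum())
    peaks = spectra.wavelengths_nm[_local_extrema(weights)]
    return PcaWeights(
        loadings=loadings,
        contributions_pct=contrib,
        peak_wavelengths_nm=peaks,
        aggregate_weight=weights,
    )


def nutrient_correlations(
    spectra: SpectraMatrix, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between each wavelength column and the nutrient values.

    Zero-variance columns get r = 0 with a flag (second return) instead of NaN.
    """
    y = np.asarray(y, dtype=float)
    if y.size != spectra.n_samples or y.size < 3:
        raise ValueError("y must match the sample count and have >= 3 samples")
    X = spectra.reflectance
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    tol = 1e-12 * max(float(np.abs(X).max()), 1.0)
    flagged = (sx <= tol) | (sy <= tol)
    denom = np.where(flagged, 1.0, sx * sy)
    r = (Xc.T @ yc) / denom
    r[flagged] = 0.0
    return r, flagged


def autocorrelation(spectra: SpectraMatrix) -> np.ndarray:
    """Wavelength × wavelength Pearson correlation matrix (unit diagonal)."""
    X = spectra.reflectance
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    C[~np.isfinite(C)] = 0.0
    bad = sd == 0
    C[bad, :] = 0.0
    C[:, bad] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


@dataclass(frozen=True)
class RandomFrogParams:
    """Random-frog hyperparameters (PLS inner model)."""

    n_iter: int = 1000
    q0: int = 8  # initial subset size
    variance_factor: float = 0.3  # sd of the proposed subset size, relative
    candidate_pool_factor: int = 3  # extra variables sampled when growing
    accept_factor: float = 0.1  # acceptance scale for worse candidates
    max_components: int = 5
    cv_folds: int = 4
    min_iter: int = 100
    seed: int = 0


def _pls_rmsecv(X: np.ndarray, y: np.ndarray, cols: np.ndarray, params: RandomFrogParams) -> float:
    ncomp = int(min(params.max_components, cols.size, X.shape[0] - 2))
    ncomp = max(1, ncomp)
    kf = KFold(n_splits=params.cv_folds, shuffle=False)
    sse, n = 0.0, 0
    Xs = X[:, cols]
    for tr, te in kf.split(Xs):
        pls = PLSRegression(n_components=min(ncomp, len(tr) - 1), scale=False)
        pls.fit(Xs[tr], y[tr])
        pred = pls.predict(Xs[te]).ravel()
        sse += float(((pred - y[te]) ** 2).sum())
        n += len(te)
    return np.sqrt(sse / n)


def _pls_rank(X: np.ndarray, y: np.ndarray, cols: np.ndarray, params: RandomFrogParams) -> np.ndarray:
    """Columns ordered by decreasing |PLS regression coefficient|."""
    ncomp = max(1, int(min(params.max_components, cols.size, X.shape[0] - 2)))
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(X[:, cols], y)
    order = np.argsort(-np.abs(pls.coef_.ravel()))
    return cols[order]


def random_frog(
    spectra: SpectraMatrix,
    y: np.ndarray,
    params: RandomFrogParams | None = None,
) -> np.ndarray:
    """Selection probability per wavelength from a reversible-jump subset search.

    Each iteration proposes a new subset size from a normal around the current
    size; the subset shrinks by keeping the top |PLS coefficient| variables or
    grows by sampling extra variables and re-ranking.  A candidate replaces the
    current subset when its cross-validated PLS RMSE is lower, or with
    probability ``accept_factor * RMSE/RMSE*`` otherwise.  The probability of a
    wavelength is the fraction of iterations whose accepted subset contains it.
    Deterministic under a fixed seed.
    """
    params = params or RandomFrogParams()
    if params.n_iter < params.min_iter:
        raise ValueError(f"n_iter must be >= {params.min_iter}")
    rng = np.random.default_rng(params.seed)
    X = spectra.reflectance - spectra.reflectance.mean(axis=0)
    yv = np.asarray(y, dtype=float)
    yv = yv - yv.mean()
    p = spectra.n_wavelengths
    q0 = int(np.clip(params.q0, 1, p))
    current = rng.choice(p, size=q0, replace=False)
    current_rmse = _pls_rmsecv(X, yv, current, params)
    counts = np.zeros(p)
    for _ in range(params.n_iter):
        q = current.size
        q_star = int(np.clip(round(rng.normal(q, params.variance_factor * q)), 1, p))
        if q_star == q:
            candidate = current
        elif q_star < q:
            candidate = _pls_rank(X, yv, current, params)[:q_star]
        else:
            pool = np.setdiff1d(np.arange(p), current, assume_unique=False)
            n_extra = min(params.candidate_pool_factor * (q_star - q), pool.size)
            extra = rng.choice(pool, size=n_extra, replace=False)
            union = np.concatenate([current, extra])
            candidate = _pls_rank(X, yv, union, params)[:q_star]
        if candidate is current:
            cand_rmse = current_rmse
        else:
            cand_rmse = _pls_rmsecv(X, yv, candidate, params)
        accept = cand_rmse <= current_rmse or rng.random() < params.accept_factor * (
            current_rmse / cand_rmse
        )
        if accept:
            current, current_rmse = candidate, cand_rmse
        counts[current] += 1.0
    return counts / params.n_iter


@dataclass
class SelectionRules:
    """Combination rule for PCA-CC-RF wavelength selection."""

    adjacency_r_threshold: float = 0.9  # "highly significant" neighbor correlation
    min_abs_corr: float = 0.2  # screen: |r| with the nutrient must exceed this ...
    pca_peak_tol_nm: float = 12.0  # ... unless a PCA loading peak lies this close
    supplement_nm: tuple[float, ...] = ()  # PCA-CC additions
    max_selected: int | None = None


@dataclass
class SelectionResult:
    """Selected characteristic wavelengths with per-wavelength provenance."""

    nutrient: str
    wavelengths_nm: list[float]
    provenance: dict[float, str] = field(default_factory=dict)
    removed_nm: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "nutrient": self.nutrient,
            "method": "PCA-CC-RF",
            "number": len(self.wavelengths_nm),
            "wavelengths_nm": self.wavelengths_nm,
            "provenance": {f"{w:g}": tag for w, tag in self.provenance.items()},
            "removed_nm": self.removed_nm,
        }


def select_wavelengths(
    pca: PcaWeights,
    correlations: np.ndarray,
    rf_probs: np.ndarray,
    autocorr: np.ndarray,
    wavelengths_nm: np.ndarray,
    rules: SelectionRules | None = None,
    nutrient: str = "N",
) -> SelectionResult:
    """Combine the three evidence sources into the final wavelength set.

    Local peaks of the random-frog probability are candidate wavelengths when
    the spectral neighborhood is coherent (adjacent-band autocorrelation above
    ``adjacency_r_threshold``).  Candidates lacking both correlation evidence
    (|r| ≥ ``min_abs_corr``) and PCA-peak support nearby are removed.  Rules may
    supplement wavelengths selected by PCA-CC alone; provenance records how
    every wavelength entered the set.
    """
    rules = rules or SelectionRules()
    wl = np.asarray(wavelengths_nm, dtype=float)
    probs = np.asarray(rf_probs, dtype=float)
    r = np.asarray(correlations, dtype=float)
    if not (wl.size == probs.size == r.size == autocorr.shape[0]):
        raise DimensionError("all inputs must share the wavelength grid")

    peak_idx = _local_extrema(probs)
    coherent = []
    for i in peak_idx:
        neigh = []
        if i > 0:
            neigh.append(abs(autocorr[i, i - 1]))
        if i < wl.size - 1:
            neigh.append(abs(autocorr[i, i + 1]))
        if neigh and min(neigh) >= rules.adjacency_r_threshold:
            coherent.append(i)

    selected: dict[float, str] = {}
    removed: list[float] = []
    for i in coherent:
        near_pca = (
            pca.peak_wavelengths_nm.size > 0
            and np.min(np.abs(pca.peak_wavelengths_nm - wl[i])) <= rules.pca_peak_tol_nm
        )
        if abs(r[i]) >= rules.min_abs_corr or near_pca:
            selected[float(wl[i])] = "RF-peak"
        else:
            removed.append(float(wl[i]))

    if rules.max_selected is not None and len(selected) > rules.max_selected:
        keep = sorted(selected, key=lambda w: -probs[np.argmin(np.abs(wl - w))])
        for w in keep[rules.max_selected :]:
            removed.append(w)
            del selected[w]

    for w in rules.supplement_nm:
        idx = np.argmin(np.abs(wl - w))
        if not np.isclose(wl[idx], w, atol=1e-6):
            raise KeyError(f"supplement wavelength {w} nm not on the grid")
        if float(w) not in selected:
            selected[float(w)] = "PCA-CC-supplement"

    if not selected:
        raise DegenerateInputError("no candidate wavelengths survived the screens")
    ordered = sorted(selected)
    return SelectionResult(
        nutrient=nutrient,
        wavelengths_nm=ordered,
        provenance={w: selected[w] for w in ordered},
        removed_nm=sorted(removed),
    )
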