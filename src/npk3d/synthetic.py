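"""Synthetic turntable scenes and nutrient datasets with retrievable ground truth.

Emulates the acquisition geometry of a greenhouse phenotyping rig: a rigid
parametric plant (cylindrical stem, ellipsoidal leaf patches, a cultivation pot)
on a motorized turntable, viewed by a fixed pinhole depth camera from four
angles 90° apart, with a spectral imager whose frames are displaced/rotated/
scaled by a known similarity transform relative to the depth frame.  Depth maps
are rendered by z-buffer splatting with a local-plane fit: each occupied pixel
stores the depth of the visible surface along the pixel-center ray (fitted from
the nearby projected points within a small depth band), so back-projected
points lie on the true surface up to depth quantization.  Attributes (gray,
reflectance) take the nearest projecting point.  Deliberately not
photorealistic, but every ground-truth parameter (cloud, axis, transforms,
planted wavelengths) is retrievable for testing.

The nutrient generator emulates a five-dose fertilization design (25/75/100/
150/200 % of the standard formula, equal group sizes): N/P/K respond to dose
monotonically with saturation plus per-plant jitter, and band reflectance is a
leaf-like baseline plus nutrient-linked Gaussian signatures at planted
wavelengths plus smooth correlated noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation

from .calibration import AxisCalibration
from .cloud import MultispectralPointCloud
from .errors import EmptyCloudError
from .reconstruction import CameraIntrinsics, ViewPose
from .registration import RegistrationTransform, SpectralCube, invert_transform, apply_transform
from .wavelengths import DEFAULT_INTERFERENCE_BANDS_NM, SpectraMatrix

__all__ = [
    "SceneSpec",
    "RenderedView",
    "soc710_like_wavelengths",
    "make_plant_cloud",
    "render_views",
    "make_sticker_frames",
    "make_npk_dataset",
    "make_linear_calibration_dataset",
    "NpkDatasetSpec",
]

#: Characteristic-band grid used for synthetic cubes (nm).
DEFAULT_BAND_WAVELENGTHS = (451.6, 497.7, 544.1, 585.7, 617.1, 675.1, 696.3, 739.0, 787.3)

#: Fertilizer dose levels as fractions of the standard formula.
DOSE_LEVELS = (0.25, 0.75, 1.0, 1.5, 2.0)


def soc710_like_wavelengths(n_total: int = 128) -> np.ndarray:
    """A 128-value wavelength grid over 400–1100 nm containing the six
    depth-sensor interference bands at their exact nominal positions."""
    base = np.linspace(400.0, 1100.0, n_total - len(DEFAULT_INTERFERENCE_BANDS_NM))
    grid = np.union1d(np.round(base, 2), np.asarray(DEFAULT_INTERFERENCE_BANDS_NM))
    return grid


@dataclass
class SceneSpec:
    """Full parameterization of a synthetic turntable scene; all randomness
    flows from ``seed``."""

    # plant (meters)
    stem_height: float = 0.30
    stem_radius: float = 0.012
    leaf_count: int = 6
    leaf_major: float = 0.065
    leaf_minor: float = 0.035
    # pot
    pot_radius: float = 0.07
    pot_height: float = 0.10
    # turntable geometry (camera frame: x right, y up, z forward)
    axis_center: tuple[float, float, float] = (0.02, -0.25, 1.2)
    axis_dir: tuple[float, float, float] = (0.02, 1.0, 0.015)
    disc_radius: float = 0.12
    sticker_offset: float = 0.08
    sticker_radius: float = 0.015
    # acquisition
    view_angles_deg: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    intrinsics: CameraIntrinsics = field(default_factory=CameraIntrinsics)
    image_shape: tuple[int, int] = (424, 512)  # rows, cols
    depth_noise_mm: float = 2.0
    depth_quant_mm: float = 1.0
    # spectral imager misalignment (moving → fixed ground truth)
    spectral_transform: RegistrationTransform = field(
        default_factory=lambda: RegistrationTransform(x0=6.0, y0=-4.0, theta0=5.0, sigma=1.05)
    )
    band_wavelengths_nm: tuple[float, ...] = DEFAULT_BAND_WAVELENGTHS
    #: surface sampling density (points per m²); the default ~0.7 mm point
    #: spacing emulates a dense handheld-scanner reference model
    point_density: float = 2.0e6
    seed: int = 0

    @property
    def axis_unit(self) -> np.ndarray:
        d = np.asarray(self.axis_dir, dtype=float)
        return d / np.linalg.norm(d)

    @property
    def calibration(self) -> AxisCalibration:
        """Ground-truth axis calibration."""
        return AxisCalibration(
            axis_center=np.asarray(self.axis_center, float), axis_dir=self.axis_unit
        )


def _axis_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to u (and each other)."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _leaf_reflectance(wavelengths: np.ndarray) -> np.ndarray:
    """Vegetation-like reflectance: green bump, chlorophyll absorption, red edge."""
    w = np.asarray(wavelengths, dtype=float)
    green = 0.12 * np.exp(-0.5 * ((w - 550.0) / 35.0) ** 2)
    red_edge = 0.45 / (1.0 + np.exp(-(w - 715.0) / 16.0))
    return 0.04 + green + red_edge


def make_plant_cloud(spec: SceneSpec) -> MultispectralPointCloud:
    """Ground-truth rigid plant + pot cloud with per-point band reflectance.

    Leaf and stem points carry leaf-class reflectance; pot points carry none
    (their reflectance entries are invalid), emulating a spectral imager whose
    footprint excludes the cultivation pot.
    """
    if spec.leaf_count == 0 and spec.stem_height <= 0:
        raise EmptyCloudError("scene has neither stem nor leaves")
    rng = np.random.default_rng(spec.seed)
    M = np.asarray(spec.axis_center, float)
    u = spec.axis_unit
    e1, e2 = _axis_basis(u)

    def _embed(radial, height, radial2):
        return M + np.outer(radial, e1) + np.outer(height, u) + np.outer(radial2, e2)

    parts, labels = [], []

    def _cylinder(radius, h0, h1, density):
        area = 2 * np.pi * radius * (h1 - h0)
        n = max(int(area * density), 1)
        phi = rng.uniform(0, 2 * np.pi, n)
        h = rng.uniform(h0, h1, n)
        return _embed(radius * np.cos(phi), h, radius * np.sin(phi))

    if spec.stem_height > 0:
        pts = _cylinder(spec.stem_radius, spec.pot_height, spec.pot_height + spec.stem_height,
                        spec.point_density)
        parts.append(pts)
        labels.append(np.full(len(pts), "stem"))

    for k in range(spec.leaf_count):
        phi_k = 2 * np.pi * k / max(spec.leaf_count, 1) + rng.uniform(-0.2, 0.2)
        h_k = spec.pot_height + spec.stem_height * (0.35 + 0.6 * k / max(spec.leaf_count, 1))
        tilt = np.deg2rad(rng.uniform(15, 40))
        area = np.pi * spec.leaf_major * spec.leaf_minor
        n = max(int(area * spec.point_density), 1)
        r = np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * np.pi, n)
        a_loc = spec.leaf_major * r * np.cos(th) + spec.leaf_major + spec.stem_radius
        b_loc = spec.leaf_minor * r * np.sin(th)
        lift = a_loc * np.sin(tilt) + 0.004 * np.sin(8 * th) * r
        radial = a_loc * np.cos(tilt)
        c, s = np.cos(phi_k), np.sin(phi_k)
        pts = _embed(radial * c - b_loc * s, h_k + lift, radial * s + b_loc * c)
        parts.append(pts)
        labels.append(np.full(len(pts), "leaf"))

    if spec.pot_height > 0:
        pts = _cylinder(spec.pot_radius, 0.0, spec.pot_height, spec.point_density)
        parts.append(pts)
        labels.append(np.full(len(pts), "pot"))

    coords = np.vstack(parts)
    labels = np.concatenate(labels)
    n = len(coords)

    wl = np.asarray(spec.band_wavelengths_nm, float)
    base = _leaf_reflectance(wl)
    reflectance = np.tile(base, (n, 1)) * (1.0 + 0.05 * rng.standard_normal((n, 1)))
    reflectance = np.clip(reflectance, 0.0, 1.0)
    refl_valid = np.ones((n, wl.size), dtype=bool)
    refl_valid[labels == "pot"] = False
    reflectance[labels == "pot"] = 0.0

    rgb = np.empty((n, 3))
    rgb[labels == "leaf"] = (45, 130, 55)
    rgb[labels == "stem"] = (80, 110, 60)
    rgb[labels == "pot"] = (160, 95, 60)
    rgb += rng.normal(0, 6, rgb.shape)
    rgb = np.clip(rgb, 0, 255)

    return MultispectralPointCloud(
        coords=coords, rgb=rgb, reflectance=reflectance, refl_valid=refl_valid,
        wavelengths_nm=wl, labels=labels,
    )


@dataclass
class RenderedView:
    """One turntable view: depth map (mm), grayscale render, the aligned
    ground-truth cube, the misaligned ("as acquired") cube and its grayscale."""

    depth_mm: np.ndarray
    gray: np.ndarray
    cube: SpectralCube
    acquired_cube: SpectralCube
    acquired_gray: np.ndarray
    pose: ViewPose


def _rotate_about_axis(coords: np.ndarray, spec: SceneSpec, gamma_deg: float) -> np.ndarray:
    R = Rotation.from_rotvec(np.deg2rad(gamma_deg) * spec.axis_unit).as_matrix()
    M = np.asarray(spec.axis_center, float)
    return (coords - M) @ R.T + M


def _project(cloud_coords, values, spec: SceneSpec, band_m: float = 0.008,
             radius_px: float = 1.5, knn: int = 12):
    """Pinhole z-buffer render; returns (depth_m, value images stack list).

    Depth at each occupied pixel is the visible-surface depth along the
    pixel-center ray, obtained from a least-squares plane fit to the projected
    points within ``radius_px`` of the pixel center and within ``band_m`` of
    the front (z-buffer) depth, clamped to that band.  Attribute channels take
    the nearest projecting point.
    """
    from scipy.spatial import cKDTree

    intr = spec.intrinsics
    rows, cols = spec.image_shape
    z = cloud_coords[:, 2]
    if np.any(z <= 0.05):
        raise ValueError("camera inside or behind the object; cannot render")
    u = cloud_coords[:, 0] * intr.fx / z + intr.cx
    v = intr.cy - cloud_coords[:, 1] * intr.fy / z
    i = np.round(u).astype(int)
    j = np.round(v).astype(int)
    ok = (i >= 0) & (i < cols) & (j >= 0) & (j < rows)
    u, v, i, j, z = u[ok], v[ok], i[ok], j[ok], z[ok]

    order = np.argsort(z)[::-1]  # far first, near last wins
    io, jo = i[order], j[order]
    depth_front = np.full((rows, cols), np.inf)
    np.minimum.at(depth_front, (j, i), z)
    images = []
    for val in values:
        val = val[ok][order]
        img = np.zeros((rows, cols) + val.shape[1:])
        img[jo, io] = val
        images.append(img)

    occupied = np.argwhere(np.isfinite(depth_front))
    pc = occupied[:, ::-1].astype(float)  # pixel centers as (u, v)
    tree = cKDTree(np.column_stack([u, v]))
    dist, idx = tree.query(pc, k=knn, distance_upper_bound=radius_px)
    zmin = depth_front[occupied[:, 0], occupied[:, 1]]
    valid = np.isfinite(dist)
    safe = np.where(valid, idx, 0)
    zi = z[safe]
    band = valid & (zi < zmin[:, None] + band_m)  # exclude occluded back surfaces
    du = np.where(band, u[safe] - pc[:, 0:1], 0.0)
    dv = np.where(band, v[safe] - pc[:, 1:2], 0.0)
    w = band.astype(float)
    A = np.stack([du, dv, np.ones_like(du)], axis=-1)
    Aw = A * w[..., None]
    zb = np.where(band, zi, 0.0)
    normal = np.einsum("nki,nkj->nij", Aw, A) + 1e-9 * np.eye(3)
    rhs = np.einsum("nki,nk->ni", Aw, zb)
    zfit = np.linalg.solve(normal, rhs[..., None])[:, 2, 0]
    zfit = np.where(band.sum(axis=1) >= 4, zfit, zmin)
    zfit = np.clip(zfit, zmin - 0.002, zmin + band_m)
    depth = np.zeros((rows, cols))
    depth[occupied[:, 0], occupied[:, 1]] = zfit
    return depth, images


def render_views(
    cloud: MultispectralPointCloud, spec: SceneSpec
) -> list[RenderedView]:
    """Render every configured turntable angle of the (rigid) cloud.

    Depth is quantized to ``depth_quant_mm`` after adding Gaussian noise of
    ``depth_noise_mm``; the spectral cube is corrupted by the inverse of the
    scene's ground-truth registration transform, so registering the acquired
    cube back onto the grayscale render should recover ``spec.spectral_transform``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    gray_pts = (cloud.rgb @ np.array([0.299, 0.587, 0.114])) if cloud.rgb is not None else None
    views = []
    for gamma in spec.view_angles_deg:
        rotated = _rotate_about_axis(cloud.coords, spec, gamma)
        values = []
        if gray_pts is not None:
            values.append(gray_pts)
        if cloud.reflectance is not None:
            values.append(np.where(cloud.refl_valid, cloud.reflectance, 0.0))
            values.append(cloud.refl_valid.astype(float))
        depth_m, images = _project(rotated, values, spec)
        gray = images[0] if gray_pts is not None else np.zeros(spec.image_shape)
        depth_mm = depth_m * 1000.0
        filled = depth_mm > 0
        if spec.depth_noise_mm > 0:
            depth_mm[filled] += rng.normal(0, spec.depth_noise_mm, filled.sum())
        if spec.depth_quant_mm > 0:
            depth_mm = np.round(depth_mm / spec.depth_quant_mm) * spec.depth_quant_mm
        depth_mm[~filled] = 0.0

        wl = cloud.wavelengths_nm
        if cloud.reflectance is not None:
            bands = np.moveaxis(images[1], -1, 0)
            valid = np.all(images[2] > 0.5, axis=-1) & filled
            cube = SpectralCube(bands=bands, wavelengths_nm=wl, mask=valid)
        else:
            cube = SpectralCube(
                bands=np.zeros((0, *spec.image_shape)), wavelengths_nm=np.empty(0),
                mask=filled,
            )
        t_inv = invert_transform(spec.spectral_transform, spec.image_shape)
        acquired = apply_transform(cube, t_inv, spec.image_shape)
        acq_gray = _warp_gray(gray, t_inv, spec.image_shape)
        views.append(
            RenderedView(
                depth_mm=depth_mm, gray=gray, cube=cube, acquired_cube=acquired,
                acquired_gray=acq_gray, pose=ViewPose(gamma=gamma),
            )
        )
    return views


def _warp_gray(gray, t, shape):
    cube = SpectralCube(bands=gray[None], wavelengths_nm=[550.0])
    return apply_transform(cube, t, shape).bands[0]


def make_sticker_frames(
    spec: SceneSpec, noise_m: float = 0.0, seed: int | None = None
) -> tuple[MultispectralPointCloud, MultispectralPointCloud]:
    """The two colored calibration clouds: turntable disc with yellow and red
    stickers at 0° and after an exact 180° rotation about the scene axis."""
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    M = np.asarray(spec.axis_center, float)
    u = spec.axis_unit
    e1, e2 = _axis_basis(u)

    def _disc(center_radial, center_phi, radius, n, color):
        r = radius * np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * np.pi, n)
        cx = center_radial * np.cos(center_phi) + r * np.cos(th)
        cz = center_radial * np.sin(center_phi) + r * np.sin(th)
        pts = M + np.outer(cx, e1) + np.outer(cz, e2)
        cols = np.tile(np.asarray(color, float), (n, 1))
        return pts, cols

    disc_pts, disc_col = _disc(0.0, 0.0, spec.disc_radius, 3000, (120, 120, 120))
    y_pts, y_col = _disc(spec.sticker_offset, 0.0, spec.sticker_radius, 400, (230, 210, 30))
    r_pts, r_col = _disc(spec.sticker_offset * 1.1, np.deg2rad(120), spec.sticker_radius,
                         400, (220, 40, 40))
    pts0 = np.vstack([disc_pts, y_pts, r_pts])
    cols = np.vstack([disc_col, y_col, r_col])
    pts180 = _rotate_about_axis(pts0, spec, 180.0)
    if noise_m > 0:
        pts0 = pts0 + rng.normal(0, noise_m, pts0.shape)
        pts180 = pts180 + rng.normal(0, noise_m, pts180.shape)
    return (
        MultispectralPointCloud(coords=pts0, rgb=cols),
        MultispectralPointCloud(coords=pts180, rgb=cols.copy()),
    )


def make_planted_signal_dataset(
    n: int = 200,
    snr: float = 10.0,
    n_informative: int = 5,
    seed: int = 0,
) -> tuple[SpectraMatrix, np.ndarray, np.ndarray]:
    """Planted-signal fixture for wavelength-selection recovery tests.

    Spectra are a leaf-like baseline with per-sample scale jitter plus weakly
    correlated band noise; the response is a linear combination of
    ``n_informative`` well-separated wavelength columns plus observation noise
    at the requested signal-to-noise ratio.  Returns (spectra, y, planted nm).
    """
    rng = np.random.default_rng(seed)
    wl = soc710_like_wavelengths()
    base = _leaf_reflectance(wl)
    scale = 1.0 + 0.03 * rng.standard_normal(n)
    noise = rng.standard_normal((n, wl.size))
    noise = gaussian_filter1d(noise, sigma=1.0, axis=1)
    noise /= noise.std()
    X = np.outer(scale, base) + 0.03 * noise
    cols = np.linspace(8, wl.size - 9, n_informative).round().astype(int)
    w = rng.uniform(0.5, 1.5, n_informative) * np.sign(rng.normal(size=n_informative))
    signal = X[:, cols] @ w
    y = signal + (signal.std() / snr) * rng.standard_normal(n)
    spectra = SpectraMatrix(np.clip(X, 0, None), wl, [f"s{k}" for k in range(n)])
    return spectra, y, wl[cols]


def make_linear_calibration_dataset(
    n: int = 60, n_bands: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced calibration-gradient fixture for learner validation.

    One nutrient gradient drives all bands linearly (a noiseless rank-1
    calibration series, the standard design for checking that a regression
    implementation recovers a clean linear response): X is n × n_bands
    reflectance, y the nutrient value (mg/g), exactly linear in every band.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n)
    gains = rng.uniform(0.5, 1.5, n_bands) * np.sign(rng.normal(size=n_bands))
    X = 0.3 + np.outer(t, gains) * 0.05
    y = 18.0 + 24.0 * t
    return X, y


@dataclass
class NpkDatasetSpec:
    """Nutrient-dataset generator parameters (doses, signatures, noise)."""

    n_samples: int = 60
    wavelengths_nm: np.ndarray = field(default_factory=soc710_like_wavelengths)
    planted_nm: dict = field(default_factory=dict)  # nutrient -> tuple of nm
    signature_width_nm: float = 9.0
    signature_amplitude: float = 0.03
    snr: float = 10.0  # signature amplitude over noise sd; np.inf = noiseless
    dose_jitter: float = 0.04
    baseline_jitter: float = 0.03  # per-sample multiplicative baseline variation
    seed: int = 0

    #: saturating dose response per nutrient: value = vmax * d / (d + half)
    dose_response: dict = field(
        default_factory=lambda: {
            "N": (52.0, 0.55),  # mg/g dry mass, (vmax, half-saturation dose)
            "P": (8.5, 0.65),
            "K": (46.0, 0.70),
        }
    )


def _default_planted(wl: np.ndarray) -> dict[str, np.ndarray]:
    targets = {
        "N": (451.6, 544.1, 585.7, 696.3, 739.0),
        "P": (446.5, 585.7, 675.1, 728.3, 787.3),
        "K": (497.7, 585.7, 617.1, 675.1, 739.0),
    }
    return {
        nut: np.array([wl[np.argmin(np.abs(wl - t))] for t in ts])
        for nut, ts in targets.items()
    }


def make_npk_dataset(
    spec: NpkDatasetSpec | None = None,
) -> tuple[SpectraMatrix, pd.DataFrame, dict[str, np.ndarray]]:
    """Synthetic nutrient dataset with planted spectral signatures.

    Samples are split equally over the five dose levels; each nutrient follows
    a saturating dose response with per-plant jitter.  Reflectance is a leaf
    baseline (with per-sample scale jitter) plus, per nutrient, a Gaussian-bump
    signature at the planted wavelengths scaled by the standardized nutrient
    value, plus smooth correlated noise with sd = signature_amplitude / snr.
    Returns the spectra, the N/P/K table (mg/g) and the planted wavelengths.
    """
    spec = spec or NpkDatasetSpec()
    if spec.n_samples < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(spec.seed)
    wl = np.asarray(spec.wavelengths_nm, float)
    n = spec.n_samples
    doses = np.repeat(DOSE_LEVELS, int(np.ceil(n / len(DOSE_LEVELS))))[:n]

    npk = {}
    for nut, (vmax, half) in spec.dose_response.items():
        jitter = 1.0 + spec.dose_jitter * rng.standard_normal(n)
        npk[nut] = vmax * doses / (doses + half) * jitter
    npk_df = pd.DataFrame(npk)
    npk_df["dose"] = doses

    planted = spec.planted_nm or _default_planted(wl)
    base = _leaf_reflectance(wl)
    scale = 1.0 + spec.baseline_jitter * rng.standard_normal(n)
    X = np.outer(scale, base)
    for nut, centers in planted.items():
        z = (npk_df[nut] - npk_df[nut].mean()) / npk_df[nut].std()
        sig = np.zeros_like(wl)
        for c in np.atleast_1d(centers):
            sig += np.exp(-0.5 * ((wl - c) / spec.signature_width_nm) ** 2)
        X += spec.signature_amplitude * np.outer(z, sig)
    if np.isfinite(spec.snr) and spec.snr > 0:
        noise = rng.standard_normal((n, wl.size))
        noise = gaussian_filter1d(noise, sigma=2.0, axis=1)
        noise /= noise.std()
        X += (spec.signature_amplitude / spec.snr) * noise
    X = np.clip(X, 0.0, None)
    spectra = SpectraMatrix(X, wl, [f"plant{k:03d}" for k in range(n)])
    planted = {k: np.asarray(v, float) for k, v in planted.items()}
    return spectra, npk_df, planted
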