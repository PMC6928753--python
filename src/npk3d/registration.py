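"""Frequency-domain registration of multispectral images onto the depth-sensor frame.

A depth camera and a pushbroom spectral imager view the same scene from nearby but
distinct optics, so their images differ by an (approximately) similarity transform:
translation, in-plane rotation and isotropic scale.  Translation is recovered from
the peak of the inverse FFT of the normalized cross-power spectrum; rotation and
scale are recovered by the Fourier-Mellin route — phase correlation of the
log-polar resampled FFT magnitude spectra, which are invariant to translation.
One shared transform is then applied to every wavelength band of the cube so that
the per-band reflectance stays mutually consistent.

Pixel convention: ``x``/``x0`` are column offsets, ``y``/``y0`` row offsets,
``theta0`` in degrees, ``sigma`` the moving→fixed scale factor.  The transform
scales/rotates about the image center first and translates second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.filters import window as _fft_window
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, warp, warp_polar

from .errors import DegenerateInputError, DimensionError

__all__ = [
    "RegistrationTransform",
    "SpectralCube",
    "ChannelStack",
    "phase_correlation",
    "fourier_mellin",
    "register_image",
    "apply_transform",
    "invert_transform",
    "stack_registered",
    "to_gray",
]

#: ITU-R BT.601 luma weights used for every RGB "graying" step in the pipeline.
BT601_LUMA = np.array([0.299, 0.587, 0.114])


def to_gray(rgb: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) RGB image to grayscale with BT.601 luma weights."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim == 2:
        return rgb
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise DimensionError(f"expected (H, W, 3) RGB image, got {rgb.shape}")
    return rgb @ BT601_LUMA


@dataclass(frozen=True)
class RegistrationTransform:
    """Similarity transform mapping moving-image pixels into fixed-image pixels.

    The map is ``p_fixed = T(x0, y0) · R(theta0) · S(sigma) · (p_moving - c) + c``
    with ``c`` the image center; i.e. scale/rotate about the center, then shift.
    """

    x0: float = 0.0
    y0: float = 0.0
    theta0: float = 0.0
    sigma: float = 1.0

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        # normalize angle into (-180, 180]
        t = (self.theta0 + 180.0) % 360.0 - 180.0
        if t == -180.0:
            t = 180.0
        object.__setattr__(self, "theta0", float(t))

    def matrix(self, out_shape: tuple[int, int], in_shape: tuple[int, int] | None = None) -> np.ndarray:
        """3x3 homogeneous matrix in (x=col, y=row) coordinates, moving → fixed."""
        if in_shape is None:
            in_shape = out_shape
        cy_out, cx_out = (out_shape[0] - 1) / 2.0, (out_shape[1] - 1) / 2.0
        cy_in, cx_in = (in_shape[0] - 1) / 2.0, (in_shape[1] - 1) / 2.0
        pre = AffineTransform(translation=(-cx_in, -cy_in))
        sim = AffineTransform(scale=self.sigma, rotation=np.deg2rad(self.theta0))
        post = AffineTransform(translation=(cx_out + self.x0, cy_out + self.y0))
        return post.params @ sim.params @ pre.params


@dataclass
class SpectralCube:
    """Reflectance cube: ``bands[b]`` is the 2-D image at ``wavelengths_nm[b]``.

    ``mask`` is the per-pixel validity image (True = reflectance is meaningful);
    pixels that fall outside the source during warping become invalid, never
    silently zero.
    """

    bands: np.ndarray  # (B, H, W)
    wavelengths_nm: np.ndarray  # (B,)
    mask: np.ndarray | None = None  # (H, W) bool

    def __post_init__(self):
        self.bands = np.asarray(self.bands, dtype=float)
        if self.bands.ndim != 3:
            raise DimensionError(f"bands must be (B, H, W), got {self.bands.shape}")
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.wavelengths_nm.shape != (self.bands.shape[0],):
            raise DimensionError(
                f"{self.bands.shape[0]} bands but {self.wavelengths_nm.size} wavelengths"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if self.mask is None:
            self.mask = np.ones(self.bands.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.bands.shape[1:]:
                raise DimensionError("mask shape must match band shape")

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]


@dataclass
class ChannelStack:
    """Aligned multi-channel array (RGB + depth + per-wavelength reflectance)."""

    data: np.ndarray  # (H, W, C)
    channel_names: list[str] = field(default_factory=list)
    wavelengths_nm: np.ndarray | None = None
    spectral_mask: np.ndarray | None = None  # (H, W) bool

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]


def _as_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise DimensionError(f"expected 2-D image with m, n >= 2, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def _check_pair(fixed: np.ndarray, moving: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fixed, moving = _as_image(fixed), _as_image(moving)
    if fixed.shape != moving.shape:
        raise DimensionError(f"shape mismatch: {fixed.shape} vs {moving.shape}")
    if fixed.std() == 0 or moving.std() == 0:
        raise DegenerateInputError("constant image has no registrable structure")
    return fixed, moving


def _wrap_signed(idx: np.ndarray, n: int) -> np.ndarray:
    return np.where(idx > n // 2, idx - n, idx)


def phase_correlation(
    fixed: np.ndarray, moving: np.ndarray, subpixel: bool = False
) -> tuple[float, float, float]:
    """Translation (x0 cols, y0 rows) aligning ``moving`` to ``fixed``.

    Returns the shift maximizing the inverse FFT of the normalized cross-power
    spectrum, i.e. ``fixed ≈ roll(moving, (y0, x0))``; exact for circular integer
    shifts.  ``peak`` is the correlation value in [0, 1] (1 for identical images).
    With ``subpixel=True`` the integer peak is refined by a parabolic fit.
    """
    fixed, moving = _check_pair(fixed, moving)
    F = np.fft.fft2(fixed)
    M = np.fft.fft2(moving)
    R = F * np.conj(M)
    mag = np.abs(R)
    mag[mag == 0] = 1.0
    corr = np.real(np.fft.ifft2(R / mag))
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    peak = float(np.clip(corr[iy, ix], 0.0, 1.0))
    m, n = corr.shape

    def _parabolic(c, i, size):
        num = c[(i - 1) % size] - c[(i + 1) % size]
        den = c[(i - 1) % size] - 2 * c[i] + c[(i + 1) % size]
        return 0.5 * num / den if den != 0 else 0.0

    dy, dx = float(iy), float(ix)
    if subpixel:
        dy += _parabolic(corr[:, ix], iy, m)
        dx += _parabolic(corr[iy, :], ix, n)
    dy = float(_wrap_signed(np.array(dy), m))
    dx = float(_wrap_signed(np.array(dx), n))
    return dx, dy, peak


def _translation_candidates(
    fixed: np.ndarray, moving: np.ndarray, k: int = 3, min_sep: int = 5
) -> list[tuple[float, float]]:
    """Top-k distinct (x0, y0) peaks of the normalized cross-power surface.

    The de-rotated/de-scaled moving image carries border zeros that violate the
    circular-shift model, so the global peak is occasionally spurious; callers
    re-rank these candidates by actual spatial correlation.
    """
    F = np.fft.fft2(fixed)
    M = np.fft.fft2(moving)
    R = F * np.conj(M)
    mag = np.abs(R)
    mag[mag == 0] = 1.0
    corr = np.real(np.fft.ifft2(R / mag))
    m, n = corr.shape
    flat = np.argsort(corr.ravel())[::-1]
    out: list[tuple[float, float]] = []
    taken: list[tuple[int, int]] = []
    for idx in flat[: 50 * k]:
        iy, ix = divmod(int(idx), n)
        if any(min(abs(iy - ty), m - abs(iy - ty)) < min_sep
               and min(abs(ix - tx), n - abs(ix - tx)) < min_sep for ty, tx in taken):
            continue
        taken.append((iy, ix))
        out.append((float(_wrap_signed(np.array(ix), n)), float(_wrap_signed(np.array(iy), m))))
        if len(out) == k:
            break
    return out


def _best_similarity_alignment(
    fixed: np.ndarray, moving: np.ndarray, theta_candidates, sigma: float
) -> RegistrationTransform:
    """Resolve the 180° rotation ambiguity and spurious translation peaks by
    scoring every (rotation branch, candidate shift) with the masked Pearson
    correlation of the fully warped moving image against the fixed image."""
    best = None
    for cand in theta_candidates:
        t_rs = RegistrationTransform(theta0=cand, sigma=sigma)
        warped = _warp_band(moving, t_rs, fixed.shape, moving.shape)[0]
        if warped.std() == 0:
            continue
        for x0, y0 in _translation_candidates(fixed, warped):
            t_full = RegistrationTransform(x0=x0, y0=y0, theta0=cand, sigma=sigma)
            aligned, mask = _warp_band(moving, t_full, fixed.shape, moving.shape)
            if mask.sum() < 16 or aligned[mask].std() == 0 or fixed[mask].std() == 0:
                continue
            score = float(np.corrcoef(aligned[mask], fixed[mask])[0, 1])
            if best is None or score > best[1]:
                best = (t_full, score)
    if best is None:
        raise DegenerateInputError("no rotation/translation candidate produced a valid overlap")
    return best[0]


def _logpolar_magnitude(
    img: np.ndarray, radius: float, output_shape: tuple[int, int]
) -> np.ndarray:
    win = _fft_window("hann", img.shape)
    spec = np.abs(np.fft.fftshift(np.fft.fft2(img * win)))
    # log compression keeps the DC-dominated spectrum from swamping the texture
    return warp_polar(
        np.log1p(spec), radius=radius, output_shape=output_shape, scaling="log", order=1
    )


def fourier_mellin(
    fixed: np.ndarray,
    moving: np.ndarray,
    angular_bins: int = 720,
    radial_bins: int = 400,
) -> tuple[float, float]:
    """Rotation (deg) and scale aligning ``moving`` to ``fixed``.

    The FFT magnitude spectrum is translation invariant; resampled to log-polar
    coordinates, rotation and scale of the scene become a circular shift which is
    recovered by (subpixel) phase correlation.  The inherent 180° ambiguity of the
    magnitude spectrum is resolved by testing both candidate rotations and keeping
    the one with the stronger final translation-correlation peak.

    Defaults give 0.5° angular bins and logarithmic radial bins over
    [1, min(m, n)/2], matching a 1° / 2% target accuracy.
    """
    fixed, moving = _check_pair(fixed, moving)
    radius = min(fixed.shape) // 2
    shape = (angular_bins, radial_bins)
    wf = _logpolar_magnitude(fixed, radius, shape)
    wm = _logpolar_magnitude(moving, radius, shape)
    if wf.std() == 0 or wm.std() == 0:
        raise DegenerateInputError("spectrum magnitude is rotationally featureless")

    shift, _, _ = phase_cross_correlation(wf, wm, upsample_factor=20)
    dtheta = shift[0] * 360.0 / angular_bins
    klog = radial_bins / np.log(radius)
    sigma = float(np.exp(-shift[1] / klog))

    best = _best_similarity_alignment(fixed, moving, (dtheta, dtheta + 180.0), sigma)
    return best.theta0, best.sigma


def register_image(
    fixed: np.ndarray, moving: np.ndarray, subpixel: bool = False
) -> RegistrationTransform:
    """Full similarity registration: Fourier-Mellin rotation/scale first, then
    phase correlation of the de-rotated/de-scaled moving image for translation.

    Both 180° rotation branches and the leading translation-peak candidates
    are scored by spatial correlation of the fully warped image, which guards
    against spurious cross-power peaks caused by the non-periodic borders."""
    fixed, moving = _check_pair(fixed, moving)
    theta, sigma = fourier_mellin(fixed, moving)
    t = _best_similarity_alignment(fixed, moving, (theta,), sigma)
    if subpixel:
        t_rs = RegistrationTransform(theta0=t.theta0, sigma=t.sigma)
        derotated = _warp_band(moving, t_rs, fixed.shape, moving.shape)[0]
        x0, y0, _ = phase_correlation(fixed, derotated, subpixel=True)
        if (round(x0), round(y0)) == (round(t.x0), round(t.y0)):
            t = RegistrationTransform(x0=x0, y0=y0, theta0=t.theta0, sigma=t.sigma)
    return t


def _warp_band(
    band: np.ndarray,
    t: RegistrationTransform,
    out_shape: tuple[int, int],
    in_shape: tuple[int, int],
    valid_in: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Warp one band into the fixed frame; returns (values, validity mask)."""
    M = t.matrix(out_shape, in_shape)
    inv = AffineTransform(matrix=np.linalg.inv(M))
    out = warp(np.asarray(band, float), inv, output_shape=out_shape, order=1, cval=0.0)
    vin = np.ones(in_shape) if valid_in is None else valid_in.astype(float)
    vout = warp(vin, inv, output_shape=out_shape, order=1, cval=0.0)
    return out, vout > 0.999


def apply_transform(
    cube: SpectralCube, t: RegistrationTransform, out_shape: tuple[int, int]
) -> SpectralCube:
    """Resample every band of the cube with the identical transform.

    Output pixels whose source falls outside the moving image (or on invalid
    input pixels) are marked invalid in the mask rather than zero-filled.
    """
    if not t.sigma > 0:
        raise ValueError("sigma must be positive")
    bands_out = np.empty((cube.n_bands, *out_shape))
    mask_out = None
    for b in range(cube.n_bands):
        bands_out[b], mask_out = _warp_band(
            cube.bands[b], t, out_shape, cube.shape, valid_in=cube.mask
        )
    if mask_out is None:  # zero-band cube
        mask_out = np.zeros(out_shape, dtype=bool)
    bands_out[:, ~mask_out] = 0.0
    return SpectralCube(bands=bands_out, wavelengths_nm=cube.wavelengths_nm, mask=mask_out)


def invert_transform(
    t: RegistrationTransform, shape: tuple[int, int]
) -> RegistrationTransform:
    """Inverse similarity transform (center convention of ``shape``)."""
    Minv = np.linalg.inv(t.matrix(shape, shape))
    theta = -t.theta0
    sigma = 1.0 / t.sigma
    base = RegistrationTransform(theta0=theta, sigma=sigma).matrix(shape, shape)
    dx = Minv[0, 2] - base[0, 2]
    dy = Minv[1, 2] - base[1, 2]
    return RegistrationTransform(x0=dx, y0=dy, theta0=theta, sigma=sigma)


def stack_registered(
    rgb: np.ndarray, depth_mm: np.ndarray, cube: SpectralCube
) -> ChannelStack:
    """Stack color, depth and registered reflectance into one aligned array.

    All inputs must already live in the depth sensor's pixel frame and share its
    shape; channel metadata records the wavelength of every spectral channel.
    """
    rgb = np.asarray(rgb, dtype=float)
    depth_mm = np.asarray(depth_mm, dtype=float)
    if rgb.ndim == 2:
        color = rgb[..., None]
        names = ["gray"]
    elif rgb.ndim == 3 and rgb.shape[2] == 3:
        color = rgb
        names = ["R", "G", "B"]
    else:
        raise DimensionError(f"rgb must be (H, W) or (H, W, 3), got {rgb.shape}")
    shape = color.shape[:2]
    if depth_mm.shape != shape or cube.shape != shape:
        raise DimensionError(
            f"aligned inputs required: color {shape}, depth {depth_mm.shape}, cube {cube.shape}"
        )
    spectral = np.moveaxis(cube.bands, 0, -1)
    data = np.concatenate([color, depth_mm[..., None], spectral], axis=-1)
    names = names + ["depth_mm"] + [f"refl_{w:g}" for w in cube.wavelengths_nm]
    return ChannelStack(
        data=data.astype(np.float32),
        channel_names=names,
        wavelengths_nm=cube.wavelengths_nm.copy(),
        spectral_mask=cube.mask.copy(),
    )
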