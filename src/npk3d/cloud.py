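"""Point-cloud container carrying per-point color and multispectral reflectance."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError

__all__ = ["MultispectralPointCloud"]


@dataclass
class MultispectralPointCloud:
    """N points with optional RGB, per-band reflectance and view provenance.

    coords are meters in the depth-camera (or unified) frame.  ``reflectance``
    is (N, B) with ``refl_valid`` marking which entries are meaningful — points
    back-projected from pixels outside the spectral imager's footprint (e.g. the
    cultivation pot) carry no reflectance.
    """

    coords: np.ndarray  # (N, 3) float, meters
    rgb: np.ndarray | None = None  # (N, 3), 0..255
    reflectance: np.ndarray | None = None  # (N, B)
    refl_valid: np.ndarray | None = None  # (N, B) bool
    wavelengths_nm: np.ndarray | None = None  # (B,)
    view_id: np.ndarray | None = None  # (N,) int
    labels: np.ndarray | None = field(default=None, repr=False)  # synthetic part labels

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DimensionError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        n = len(self.coords)
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb, dtype=float).reshape(n, 3)
        if self.reflectance is not None:
            self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
            if self.reflectance.shape[0] != n:
                raise DimensionError("reflectance rows must match point count")
            if self.refl_valid is None:
                self.refl_valid = np.isfinite(self.reflectance)
            else:
                self.refl_valid = np.asarray(self.refl_valid, dtype=bool)
                if self.refl_valid.shape != self.reflectance.shape:
                    raise DimensionError("refl_valid shape must match reflectance")
            if self.wavelengths_nm is not None:
                self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
                if self.wavelengths_nm.size != self.reflectance.shape[1]:
                    raise DimensionError("wavelength count must match reflectance bands")
        if self.view_id is not None:
            self.view_id = np.asarray(self.view_id, dtype=int).reshape(n)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_bands(self) -> int:
        return 0 if self.reflectance is None else self.reflectance.shape[1]

    def select(self, idx: np.ndarray) -> "MultispectralPointCloud":
        """Subset of points (boolean mask or integer indices); attributes follow."""
        return MultispectralPointCloud(
            coords=self.coords[idx],
            rgb=None if self.rgb is None else self.rgb[idx],
            reflectance=None if self.reflectance is None else self.reflectance[idx],
            refl_valid=None if self.refl_valid is None else self.refl_valid[idx],
            wavelengths_nm=None if self.wavelengths_nm is None else self.wavelengths_nm.copy(),
            view_id=None if self.view_id is None else self.view_id[idx],
            labels=None if self.labels is None else self.labels[idx],
        )

    def transformed(self, R: np.ndarray, t: np.ndarray | None = None) -> "MultispectralPointCloud":
        """Rigidly transformed copy: coords' = coords @ R.T + t."""
        R = np.asarray(R, dtype=float)
        if R.shape == (4, 4):
            t = R[:3, 3]
            R = R[:3, :3]
        t = np.zeros(3) if t is None else np.asarray(t, dtype=float)
        out = self.select(slice(None))
        out.coords = self.coords @ R.T + t
        return out

    @staticmethod
    def concatenate(clouds: list["MultispectralPointCloud"]) -> "MultispectralPointCloud":
        """Stack clouds; spectral attributes are kept when all inputs carry them."""
        if not clouds:
            return MultispectralPointCloud(coords=np.empty((0, 3)))
        coords = np.vstack([c.coords for c in clouds])

        def _cat(attr):
            vals = [getattr(c, attr) for c in clouds]
            return np.concatenate(vals, axis=0) if all(v is not None for v in vals) else None

        wl = clouds[0].wavelengths_nm
        return MultispectralPointCloud(
            coords=coords,
            rgb=_cat("rgb"),
            reflectance=_cat("reflectance"),
            refl_valid=_cat("refl_valid"),
            wavelengths_nm=None if wl is None else wl.copy(),
            view_id=_cat("view_id"),
            labels=_cat("labels"),
        )
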