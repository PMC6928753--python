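"""Turntable rotation-axis self-calibration from two RGB-D frames 180° apart.

Two colored calibration stickers (yellow and red) sit on the turntable disc.
A 180° rotation maps each sticker centroid to its antipode across the axis, so
the midpoint of each before/after pair lies on the axis line, and the chords
(Y1−Y2) and (R1−R2) are both perpendicular to it — their cross product gives the
axis direction.  The calibration (axis center ``M`` and unit direction ``P``)
is cached to JSON and reused while the camera/turntable geometry is unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cloud import MultispectralPointCloud
from .errors import AmbiguousAngleError, CalibrationError, IllConditionedAxisError

__all__ = [
    "AxisCalibration",
    "StickerObservation",
    "DEFAULT_COLOR_THRESHOLDS",
    "sticker_centroids",
    "estimate_axis",
    "axis_angles",
    "axis_alignment_rotation",
    "save_calibration",
    "load_calibration",
]

#: RGB gates (0..255) for the two calibration stickers: yellow = R,G high / B low,
#: red = R high / G,B low.  Override per setup if sticker colors differ.
DEFAULT_COLOR_THRESHOLDS = {
    "yellow": {"min": (150, 150, 0), "max": (255, 255, 100)},
    "red": {"min": (150, 0, 0), "max": (255, 100, 100)},
}


@dataclass(frozen=True)
class StickerObservation:
    """Sticker centroids (meters, camera frame) in one turntable frame."""

    yellow_center: np.ndarray
    red_center: np.ndarray
    n_yellow: int
    n_red: int


@dataclass(frozen=True)
class AxisCalibration:
    """Rotation-axis center (m) and unit direction in the depth-camera frame."""

    axis_center: np.ndarray
    axis_dir: np.ndarray
    midpoint_residual_m: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "axis_center", np.asarray(self.axis_center, dtype=float))
        d = np.asarray(self.axis_dir, dtype=float)
        norm = np.linalg.norm(d)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("axis_dir must be a nonzero finite vector")
        object.__setattr__(self, "axis_dir", d / norm)


def sticker_centroids(
    cloud: MultispectralPointCloud,
    thresholds: dict | None = None,
    min_points: int = 3,
) -> StickerObservation:
    """Centroids of the yellow and red sticker points selected by RGB gating."""
    if cloud.rgb is None:
        raise CalibrationError("calibration cloud has no per-point RGB")
    thresholds = thresholds or DEFAULT_COLOR_THRESHOLDS
    centers, counts = {}, {}
    for name in ("yellow", "red"):
        lo = np.asarray(thresholds[name]["min"], dtype=float)
        hi = np.asarray(thresholds[name]["max"], dtype=float)
        sel = np.all((cloud.rgb >= lo) & (cloud.rgb <= hi), axis=1)
        counts[name] = int(sel.sum())
        if counts[name] < min_points:
            raise CalibrationError(
                f"only {counts[name]} points pass the {name} color gate (need >= {min_points})"
            )
        centers[name] = cloud.coords[sel].mean(axis=0)
    return StickerObservation(
        yellow_center=centers["yellow"],
        red_center=centers["red"],
        n_yellow=counts["yellow"],
        n_red=counts["red"],
    )


def estimate_axis(
    obs0: StickerObservation,
    obs180: StickerObservation,
    max_midpoint_gap_m: float = 5e-3,
    min_chord_angle_deg: float = 5.0,
) -> AxisCalibration:
    """Axis from sticker pairs observed at 0° and 180°.

    The two before/after midpoints must agree within ``max_midpoint_gap_m``
    (they coincide when both stickers lie on the disc plane); their mean is the
    axis center.  Direction is the normalized cross product of the chords, with
    the sign fixed so the camera-up (+y) component is positive.
    """
    y1, y2 = obs0.yellow_center, obs180.yellow_center
    r1, r2 = obs0.red_center, obs180.red_center
    chord_y, chord_r = y1 - y2, r1 - r2
    ny, nr = np.linalg.norm(chord_y), np.linalg.norm(chord_r)
    if ny < 1e-9 or nr < 1e-9:
        raise IllConditionedAxisError("zero-length sticker chord: did the turntable rotate?")
    cosang = np.clip(abs(chord_y @ chord_r) / (ny * nr), 0.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    if angle < min_chord_angle_deg:
        raise IllConditionedAxisError(
            f"sticker chords nearly parallel ({angle:.2f}° < {min_chord_angle_deg}°)"
        )
    mid_y, mid_r = (y1 + y2) / 2.0, (r1 + r2) / 2.0
    gap = float(np.linalg.norm(mid_y - mid_r))
    if gap > max_midpoint_gap_m:
        raise CalibrationError(
            f"sticker midpoints disagree by {gap * 1e3:.2f} mm (> {max_midpoint_gap_m * 1e3:g} mm)"
        )
    direction = np.cross(chord_y, chord_r)
    direction = direction / np.linalg.norm(direction)
    if direction[1] < 0 or (direction[1] == 0 and direction[2] < 0):
        direction = -direction
    return AxisCalibration(
        axis_center=(mid_y + mid_r) / 2.0, axis_dir=direction, midpoint_residual_m=gap
    )


def axis_angles(axis_dir: np.ndarray, eps: float = 1e-12) -> tuple[float, float]:
    """Sequential tilt angles (alpha, beta) in degrees aligning the axis to +Y.

    beta rotates about Z to null the x-component; alpha then rotates about X to
    null the z-component: ``beta = atan2(a, b)``, ``alpha = atan2(c, sqrt(a²+b²))``.
    ``axis_alignment_rotation(alpha, beta)`` maps ``axis_dir`` exactly onto +Y.
    """
    a, b, c = np.asarray(axis_dir, dtype=float) / np.linalg.norm(axis_dir)
    if np.hypot(a, b) < eps and abs(c) < eps:
        raise AmbiguousAngleError("axis direction has no Y-alignable projection")
    if np.hypot(a, b) < eps:
        raise AmbiguousAngleError("axis orthogonal to Y: beta undefined")
    beta = np.degrees(np.arctan2(a, b))
    alpha = np.degrees(np.arctan2(c, np.hypot(a, b)))
    return float(alpha), float(beta)


def _rot_x(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rot_y(deg: float) -> np.ndarray:
    """Right-handed rotation about +Y."""
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def axis_alignment_rotation(alpha_deg: float, beta_deg: float) -> np.ndarray:
    """Rotation Rx(−alpha)·Rz(beta) mapping the calibrated axis direction to +Y."""
    return _rot_x(-alpha_deg) @ _rot_z(beta_deg)


def save_calibration(calib: AxisCalibration, path: str | Path) -> None:
    payload = {
        "axis_center_m": calib.axis_center.tolist(),
        "axis_dir": calib.axis_dir.tolist(),
        "midpoint_residual_m": calib.midpoint_residual_m,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_calibration(path: str | Path) -> AxisCalibration:
    payload = json.loads(Path(path).read_text())
    return AxisCalibration(
        axis_center=payload["axis_center_m"],
        axis_dir=payload["axis_dir"],
        midpoint_residual_m=payload.get("midpoint_residual_m", 0.0),
    )
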