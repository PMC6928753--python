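"""Multiview RGB-D reconstruction: back-projection, rough axis-based registration, ICP.

Each turntable view is converted to a point cloud through the pinhole model
(x = (i−cx)·z/fx, y = −(j−cy)·z/fy, z = depth/1000, with i the column and j the
row index), cropped to the plant ROI, and brought into a unified frame by the
analytic axis transform: translate the calibrated rotation-axis center to the
origin, tilt the axis onto +Y, then undo the turntable angle about Y.  Residual
misalignment (plants are not perfectly rigid) is removed by sequential
point-to-point ICP in acquisition order.  Spectral attributes ride along with
their points, so the fused cloud is a multispectral 3D model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .calibration import AxisCalibration, axis_alignment_rotation, axis_angles, rot_y
from .cloud import MultispectralPointCloud
from .errors import EmptyCloudError, RegistrationFailureError
from .registration import ChannelStack

__all__ = [
    "CameraIntrinsics",
    "ViewPose",
    "IcpParams",
    "depth_to_cloud",
    "roi_filter",
    "rough_register",
    "icp_refine",
    "reconstruct",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics in pixels (Kinect-v2-like defaults)."""

    cx: float = 256.0
    cy: float = 212.0
    fx: float = 365.0
    fy: float = 365.0

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")


@dataclass(frozen=True)
class ViewPose:
    """Turntable angle of a view relative to the reference view, degrees."""

    gamma: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "gamma", float(self.gamma) % 360.0)


@dataclass(frozen=True)
class IcpParams:
    max_iter: int = 50
    tol: float = 1e-6
    max_corr_dist: float = 0.01  # meters
    #: fraction of closest correspondences used for the update (trimmed ICP);
    #: guards the alignment against pull from partially overlapping views
    trim_ratio: float = 0.8
    voxel_size: float | None = None  # optional downsampling before ICP


def depth_to_cloud(
    depth_mm: np.ndarray,
    intr: CameraIntrinsics,
    attrs: ChannelStack | None = None,
) -> MultispectralPointCloud:
    """Back-project a 16-bit depth image (mm; 0 = missing) to a point cloud.

    Per-pixel attributes from an aligned channel stack (RGB, reflectance) are
    copied onto the points; spectrally invalid pixels yield reflectance-invalid
    points rather than zeros.
    """
    depth_mm = np.asarray(depth_mm, dtype=float)
    valid = depth_mm > 0
    if not valid.any():
        raise EmptyCloudError("depth image has no valid pixels")
    j, i = np.nonzero(valid)  # j = row, i = column
    z = depth_mm[valid] / 1000.0
    x = (i - intr.cx) * z / intr.fx
    y = -(j - intr.cy) * z / intr.fy
    coords = np.column_stack([x, y, z])

    rgb = reflectance = refl_valid = wavelengths = None
    if attrs is not None:
        if attrs.data.shape[:2] != depth_mm.shape:
            raise EmptyCloudError(
                f"attribute stack shape {attrs.data.shape[:2]} != depth shape {depth_mm.shape}"
            )
        names = attrs.channel_names
        color_idx = [k for k, n in enumerate(names) if n in ("R", "G", "B")]
        if len(color_idx) == 3:
            rgb = attrs.data[j, i][:, color_idx]
        refl_idx = [k for k, n in enumerate(names) if n.startswith("refl_")]
        if refl_idx:
            reflectance = attrs.data[j, i][:, refl_idx].astype(float)
            wavelengths = attrs.wavelengths_nm
            if attrs.spectral_mask is not None:
                pix_ok = attrs.spectral_mask[j, i]
                refl_valid = np.repeat(pix_ok[:, None], len(refl_idx), axis=1)
    return MultispectralPointCloud(
        coords=coords,
        rgb=rgb,
        reflectance=reflectance,
        refl_valid=refl_valid,
        wavelengths_nm=wavelengths,
    )


def roi_filter(
    cloud: MultispectralPointCloud, bounds: np.ndarray
) -> MultispectralPointCloud:
    """Keep points inside the closed axis-aligned box ``bounds = [[min], [max]]`` (m)."""
    bounds = np.asarray(bounds, dtype=float).reshape(2, 3)
    if np.any(bounds[0] >= bounds[1]):
        raise ValueError("ROI box must have min < max on every axis")
    inside = np.all((cloud.coords >= bounds[0]) & (cloud.coords <= bounds[1]), axis=1)
    return cloud.select(inside)


def rough_register(
    cloud: MultispectralPointCloud,
    calib: AxisCalibration,
    pose: ViewPose,
) -> MultispectralPointCloud:
    """Analytic transform into the unified (axis-aligned, reference-view) frame.

    coords' = Ry(−gamma) · A · (coords − axis_center) with A the tilt rotation
    taking the calibrated axis direction onto +Y; the reference view (gamma = 0)
    receives only the axis alignment.
    """
    alpha, beta = axis_angles(calib.axis_dir)
    A = axis_alignment_rotation(alpha, beta)
    R = rot_y(-pose.gamma) @ A
    t = -R @ calib.axis_center
    return cloud.transformed(R, t)


def _voxel_downsample(coords: np.ndarray, voxel: float) -> np.ndarray:
    keys = np.floor(coords / voxel).astype(np.int64)
    _, idx = np.unique(keys, axis=0, return_index=True)
    return coords[np.sort(idx)]


def icp_refine(
    source: MultispectralPointCloud,
    target: MultispectralPointCloud,
    params: IcpParams | None = None,
) -> tuple[np.ndarray, float, float]:
    """Point-to-point ICP aligning ``source`` onto ``target``.

    Returns the 4x4 rigid transform (to apply to source), the inlier fitness
    (fraction of source points with a correspondence within ``max_corr_dist``)
    and the inlier RMSE (m).  Iteration stops at ``max_iter`` or when the RMSE
    improvement drops below ``tol``.
    """
    params = params or IcpParams()
    if len(source) == 0 or len(target) == 0:
        raise EmptyCloudError("ICP requires two non-empty clouds")
    src = source.coords.copy()
    tgt = target.coords
    if params.voxel_size:
        src = _voxel_downsample(src, params.voxel_size)
        tgt = _voxel_downsample(tgt, params.voxel_size)
    tree = cKDTree(tgt)
    T = np.eye(4)
    prev_rmse = np.inf
    fitness = 0.0
    rmse = np.inf
    for _ in range(params.max_iter):
        dist, idx = tree.query(src)
        inlier = dist <= params.max_corr_dist
        if not inlier.any():
            raise RegistrationFailureError(
                f"no correspondences within {params.max_corr_dist} m"
            )
        fitness = float(inlier.mean())
        rmse = float(np.sqrt(np.mean(dist[inlier] ** 2)))
        if prev_rmse - rmse < params.tol:
            break
        prev_rmse = rmse
        if 0 < params.trim_ratio < 1:
            thr = np.quantile(dist[inlier], params.trim_ratio)
            inlier = inlier & (dist <= thr)
        R, t = _kabsch(src[inlier], tgt[idx[inlier]])
        src = src @ R.T + t
        step = np.eye(4)
        step[:3, :3] = R
        step[:3, 3] = t
        T = step @ T
    return T, fitness, rmse


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with R@P.T + t ≈ Q (row convention)."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


@dataclass
class ReconstructionReport:
    per_view_counts: list[int] = field(default_factory=list)
    icp_fitness: list[float] = field(default_factory=list)
    icp_rmse: list[float] = field(default_factory=list)


def reconstruct(
    views: list[tuple[np.ndarray, ChannelStack | None, ViewPose]],
    calib: AxisCalibration,
    intr: CameraIntrinsics,
    roi: np.ndarray | None = None,
    icp_params: IcpParams | None = None,
) -> tuple[MultispectralPointCloud, ReconstructionReport]:
    """Full multiview fusion: per-view back-projection, ROI crop, rough axis
    registration, then sequential ICP chaining in acquisition order.

    The first view is the reference; each later view is ICP-refined against the
    running fused cloud before being concatenated (with per-point provenance).
    """
    if len(views) < 2:
        raise ValueError("reconstruction needs at least 2 views")
    report = ReconstructionReport()
    registered = []
    for vid, (depth, stack, pose) in enumerate(views):
        cloud = depth_to_cloud(depth, intr, stack)
        if roi is not None:
            cloud = roi_filter(cloud, roi)
        if len(cloud) == 0:
            raise EmptyCloudError(f"view {vid}: ROI removed every point")
        cloud = rough_register(cloud, calib, pose)
        cloud.view_id = np.full(len(cloud), vid, dtype=int)
        report.per_view_counts.append(len(cloud))
        registered.append(cloud)

    merged = registered[0]
    for cloud in registered[1:]:
        T, fit, rmse = icp_refine(cloud, merged, icp_params)
        report.icp_fitness.append(fit)
        report.icp_rmse.append(rmse)
        merged = MultispectralPointCloud.concatenate([merged, cloud.transformed(T)])
    return merged, report
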