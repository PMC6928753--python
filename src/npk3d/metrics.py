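"""Reconstruction and registration quality measures.

Three measures: the normalized grayscale similarity D = 1 − Σ|M−F| / (m·n·255)
between the registered spectral grayscale image and the depth-sensor grayscale
image; the degree of spectral overlap C = |F2 ∧ M2| / |F2| · 100 between the two
binary ROI masks; and the directed Hausdorff distance set — for every point of
the reconstructed cloud, the Euclidean distance to its nearest neighbor in the
reference (scanned) cloud — summarized by its mean, population standard
deviation, maximum, and the proportion falling in fixed centimeter bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import MultispectralPointCloud
from .errors import AlignmentError, DimensionError, EmptyCloudError, OverlapUndefinedError
from .reconstruction import _kabsch

__all__ = [
    "HDStats",
    "HD_BIN_EDGES_CM",
    "grayscale_similarity",
    "spectral_overlap",
    "hausdorff_set",
    "hd_stats",
    "evaluate_reconstruction",
]

#: Segment edges for the HD distribution report, in cm:
#: (0, 0.1], (0.1, 0.3], (0.3, 0.6], (0.6, 1.0], (1.0, inf).
HD_BIN_EDGES_CM = (0.1, 0.3, 0.6, 1.0)


def grayscale_similarity(F: np.ndarray, M: np.ndarray) -> float:
    """Normalized grayscale similarity D in [0, 1] on the 8-bit intensity scale.

    Both images must cover the same registered region (crop identically before
    calling); D = 1 iff the images are identical.
    """
    F = np.asarray(F, dtype=float)
    M = np.asarray(M, dtype=float)
    if F.shape != M.shape or F.ndim != 2:
        raise DimensionError(f"shape mismatch: {F.shape} vs {M.shape}")
    return float(1.0 - np.abs(M - F).sum() / (F.size * 255.0))


def spectral_overlap(F2: np.ndarray, M2: np.ndarray) -> float:
    """Overlap C in percent: coverage of the reference mask F2 by the spectral mask M2."""
    F2 = np.asarray(F2).astype(bool)
    M2 = np.asarray(M2).astype(bool)
    if F2.shape != M2.shape:
        raise DimensionError(f"shape mismatch: {F2.shape} vs {M2.shape}")
    denom = F2.sum()
    if denom == 0:
        raise OverlapUndefinedError("reference mask is empty; overlap undefined")
    return float(100.0 * (F2 & M2).sum() / denom)


def hausdorff_set(RP: np.ndarray, MP: np.ndarray) -> np.ndarray:
    """Directed nearest-neighbor distance set RP→MP (same units as the coords).

    One distance per point of RP; its maximum is the classical directed
    Hausdorff distance.  Not symmetric in its arguments.
    """
    RP = np.atleast_2d(np.asarray(RP, dtype=float))
    MP = np.atleast_2d(np.asarray(MP, dtype=float))
    if RP.size == 0 or MP.size == 0:
        raise EmptyCloudError("hausdorff_set requires two non-empty clouds")
    dist, _ = cKDTree(MP).query(RP)
    return dist


@dataclass(frozen=True)
class HDStats:
    """Distribution summary of a directed distance set, reported in cm."""

    distances_cm: np.ndarray
    hd_avg: float
    hd_std: float
    hd_max: float
    segment_props: tuple[float, ...]  # %, bins per HD_BIN_EDGES_CM

    def as_dict(self) -> dict:
        return {
            "hd_avg_cm": self.hd_avg,
            "hd_std_cm": self.hd_std,
            "hd_max_cm": self.hd_max,
            "segment_props_pct": list(self.segment_props),
        }


def hd_stats(distances_cm: np.ndarray) -> HDStats:
    """Summarize a distance set (cm): average, population std, max and the
    percentage of distances in each segment of ``HD_BIN_EDGES_CM``.

    Zero distances count in the first segment; proportions sum to 100%.
    """
    d = np.asarray(distances_cm, dtype=float).ravel()
    if d.size == 0:
        raise EmptyCloudError("empty distance set")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    edges = np.array([-np.inf, *HD_BIN_EDGES_CM, np.inf])
    counts = np.histogram(d, bins=edges)[0]
    props = tuple(100.0 * counts / d.size)
    return HDStats(
        distances_cm=d,
        hd_avg=float(d.mean()),
        hd_std=float(d.std()),  # population (divide-by-N) convention
        hd_max=float(d.max()),
        segment_props=props,
    )


def align_landmarks(pairs_recon: np.ndarray, pairs_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares (Kabsch) rigid transform taking reference-frame landmarks
    onto reconstruction-frame landmarks; needs ≥ 3 non-collinear pairs."""
    P = np.atleast_2d(np.asarray(pairs_ref, dtype=float))
    Q = np.atleast_2d(np.asarray(pairs_recon, dtype=float))
    if P.shape != Q.shape or P.shape[0] < 3 or P.shape[1] != 3:
        raise AlignmentError("need >= 3 matched 3-D landmark pairs")
    centered = P - P.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise AlignmentError("landmarks are collinear; rotation under-determined")
    return _kabsch(P, Q)


def evaluate_reconstruction(
    recon: MultispectralPointCloud | np.ndarray,
    reference: MultispectralPointCloud | np.ndarray,
    prealign_pairs: tuple[np.ndarray, np.ndarray] | None = None,
) -> HDStats:
    """HD statistics of a reconstruction against a reference scan.

    When the two clouds live in different frames, manually selected landmark
    pairs ``(points_in_recon, points_in_reference)`` are used to rigidly align
    the reference first.  Coordinates are meters; statistics are reported in cm.
    """
    rp = recon.coords if isinstance(recon, MultispectralPointCloud) else np.asarray(recon)
    mp = (
        reference.coords
        if isinstance(reference, MultispectralPointCloud)
        else np.asarray(reference)
    )
    if prealign_pairs is not None:
        R, t = align_landmarks(*prealign_pairs)
        mp = mp @ R.T + t
    distances_m = hausdorff_set(rp, mp)
    return hd_stats(distances_m * 100.0)
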