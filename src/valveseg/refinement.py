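"""Spatiotemporal refinement of the binary segmentation.

Two steps: (1) locate the valve by an iterative Gaussian-attenuated centroid
of the temporally accumulated sparse component, and (2) keep only the
spatiotemporally connected component of the binary mask whose closest voxel
(in the spatial plane) is nearest that centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import RefinementFailure, ValidationError
from .segmentation import BinaryMask


@dataclass
class AccumulationMap:
    S_map: np.ndarray

    def __post_init__(self) -> None:
        self.S_map = np.asarray(self.S_map, dtype=np.float64)
        if self.S_map.ndim != 2:
            raise ValidationError("accumulation map must be 2-D")
        if np.min(self.S_map) < 0:
            raise ValidationError("accumulation map must be nonnegative")


@dataclass
class Centroid:
    cx: float  # row coordinate
    cy: float  # column coordinate


@dataclass
class ClusterSet:
    labels: np.ndarray
    n_clusters: int
    voxel_lists: list[np.ndarray] = field(default_factory=list)


def temporal_projection(S3D: np.ndarray) -> AccumulationMap:
    """Sum the frames of a nonnegative ``(sx, sy, t)`` tensor into a 2-D map."""
    S3D = np.asarray(S3D, dtype=np.float64)
    if S3D.ndim != 3:
        raise ValidationError("expected a 3-D (sx, sy, t) tensor")
    if np.min(S3D) < 0:
        raise ValidationError("input must be nonnegative")
    return AccumulationMap(S_map=S3D.sum(axis=2))


def default_sigma_schedule(sx: int, sy: int, n_iters: int = 11) -> np.ndarray:
    """Geometric decay from max(sx, sy)/4 down to max(sx, sy)/16."""
    s0 = max(sx, sy) / 4.0
    s_end = max(sx, sy) / 16.0
    if n_iters == 1:
        return np.array([s0])
    return s0 * (s_end / s0) ** (np.arange(n_iters) / (n_iters - 1))


def iterative_centroid(
    S_map: AccumulationMap | np.ndarray,
    n_iters: int = 11,
    sigma_schedule: np.ndarray | None = None,
) -> Centroid:
    """Mass centroid refined by repeated Gaussian attenuation.

    Each iteration computes the mass-weighted centroid of the current map and
    multiplies the map by an isotropic 2-D Gaussian centered there, with a
    standard deviation that decreases between iterations, pulling the
    centroid toward the densest structure and away from outliers.
    """
    m = S_map.S_map if isinstance(S_map, AccumulationMap) else np.asarray(S_map, float)
    m = m.copy()
    sx, sy = m.shape
    if sigma_schedule is None:
        sigma_schedule = default_sigma_schedule(sx, sy, n_iters)
    sigma_schedule = np.asarray(sigma_schedule, dtype=np.float64)
    if len(sigma_schedule) < n_iters:
        raise ValidationError("sigma_schedule shorter than n_iters")

    rows = np.arange(sx, dtype=np.float64)[:, None]
    cols = np.arange(sy, dtype=np.float64)[None, :]
    cx = cy = 0.0
    for i in range(n_iters):
        total = m.sum()
        if total <= 0:
            raise RefinementFailure("zero-mass accumulation map", stage="centroid")
        cx = float(np.sum(m * rows) / total)
        cy = float(np.sum(m * cols) / total)
        sig = sigma_schedule[i]
        # normalization constant kept for fidelity; centroids are scale-invariant
        g = (
            1.0
            / (2.0 * np.pi * sig**2)
            * np.exp(-((rows - cx) ** 2 + (cols - cy) ** 2) / (2.0 * sig**2))
        )
        m *= g
    return Centroid(cx=cx, cy=cy)


_STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)


def connected_components_3d(mask: BinaryMask | np.ndarray) -> ClusterSet:
    """Label 6-connected foreground clusters of a binary (sx, sy, t) mask.

    Two voxels are connected iff they differ by 1 in exactly one of
    (row, col, frame).  Labels follow first-encounter order under a
    row-major, frame-minor scan.
    """
    vol = mask.tensor if isinstance(mask, BinaryMask) else np.asarray(mask)
    if vol.ndim != 3:
        raise ValidationError("expected a 3-D binary tensor")
    vol = vol.astype(bool)
    raw, n = ndimage.label(vol, structure=_STRUCTURE_6)
    if n == 0:
        return ClusterSet(labels=raw.astype(np.int32), n_clusters=0, voxel_lists=[])
    # relabel in first-encounter order of the C-order scan (row, col, frame)
    flat = raw.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so the earliest occurrence wins
    first_idx[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first_idx[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order + 1] = np.arange(1, n + 1)
    labels = remap[raw]
    voxel_lists = [np.argwhere(labels == k) for k in range(1, n + 1)]
    return ClusterSet(labels=labels, n_clusters=n, voxel_lists=voxel_lists)


def select_cluster(clusters: ClusterSet, c: Centroid) -> BinaryMask:
    """Keep only the cluster spatially nearest the centroid.

    The distance of a cluster is the minimum over its voxels of the Euclidean
    distance between the voxel's (row, col) coordinates and the centroid; the
    frame coordinate is ignored.  Ties go to the smallest cluster id.
    """
    if clusters.n_clusters < 1:
        raise RefinementFailure("empty cluster set", stage="clustering")
    dists = np.empty(clusters.n_clusters)
    for k, voxels in enumerate(clusters.voxel_lists):
        d = np.hypot(voxels[:, 0] - c.cx, voxels[:, 1] - c.cy)
        dists[k] = d.min()
    best = int(np.argmin(dists))  # argmin returns the first (smallest id) on ties
    keep = clusters.labels == best + 1
    sx, sy, _t = keep.shape
    return BinaryMask(B_tilde=keep.reshape(sx * sy, -1).astype(np.uint8), sx=sx, sy=sy)


def cluster_table(clusters: ClusterSet, c: Centroid) -> str:
    """Per-cluster diagnostics: id, size, min spatial distance to centroid."""
    lines = ["id\tsize\tmin_dist"]
    for k, voxels in enumerate(clusters.voxel_lists):
        d = float(np.hypot(voxels[:, 0] - c.cx, voxels[:, 1] - c.cy).min())
        lines.append(f"{k + 1}\t{len(voxels)}\t{d:.3f}")
    return "\n".join(lines) + "\n"
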