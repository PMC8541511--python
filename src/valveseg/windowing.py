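"""Window-based valve localization.

Scans a fixed-size spatial rectangle over the video and scores each position
by the squared Frobenius norm of the sparse component restricted to the
window (summed over all frames).  The scan uses a summed-area table over the
per-pixel temporal sum of ``S**2`` so its cost is linear in image size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    row0: int
    col0: int
    height_w: int
    width_w: int
    score: float = 0.0

    def serialize(self) -> str:
        return f"{self.row0} {self.col0} {self.height_w} {self.width_w} {self.score:.6g}\n"

    @classmethod
    def deserialize(cls, line: str) -> "WindowSpec":
        r, c, h, w, s = line.split()
        return cls(int(r), int(c), int(h), int(w), float(s))


def _window_scores(energy2d: np.ndarray, hw: int, ww: int, stride: int):
    """Scores of all stride-spaced window positions via an integral image."""
    sat = np.zeros((energy2d.shape[0] + 1, energy2d.shape[1] + 1))
    np.cumsum(np.cumsum(energy2d, axis=0), axis=1, out=sat[1:, 1:])
    r0 = np.arange(0, energy2d.shape[0] - hw + 1, stride)
    c0 = np.arange(0, energy2d.shape[1] - ww + 1, stride)
    R0, C0 = np.meshgrid(r0, c0, indexing="ij")
    return (
        sat[R0 + hw, C0 + ww]
        - sat[R0, C0 + ww]
        - sat[R0 + hw, C0]
        + sat[R0, C0],
        r0,
        c0,
    )


def detect_window(
    S_hat3D: np.ndarray, height_w: int, width_w: int, stride: int = 1
) -> WindowSpec:
    """Best-scoring window over the sparse component.

    Ties are broken lexicographically by (row0, col0).  A zero-energy input
    yields the window at (0, 0) with score 0 and a logged warning.
    """
    S = np.asarray(S_hat3D, dtype=np.float64)
    if S.ndim != 3:
        raise ValidationError("expected a 3-D (sx, sy, t) tensor")
    sxd, syd, _t = S.shape
    if height_w > sxd or width_w > syd:
        raise ValidationError("window larger than the frame")
    if height_w < 1 or width_w < 1 or stride < 1:
        raise ValidationError("window size and stride must be >= 1")

    energy2d = np.sum(S**2, axis=2)
    scores, r0, c0 = _window_scores(energy2d, height_w, width_w, stride)
    flat = int(np.argmax(scores))  # first max in row-major = lexicographic tie-break
    i, j = np.unravel_index(flat, scores.shape)
    best = float(scores[i, j])
    if best <= 0:
        logger.warning("window detection saw zero energy; defaulting to (0, 0)")
    return WindowSpec(
        row0=int(r0[i]), col0=int(c0[j]), height_w=height_w, width_w=width_w, score=best
    )


def restrict_to_window(mask_or_video: np.ndarray, w: WindowSpec) -> np.ndarray:
    """Zero out everything outside the window's spatial rectangle, all frames."""
    arr = np.asarray(mask_or_video)
    if arr.ndim != 3:
        raise ValidationError("expected a 3-D (sx, sy, t) tensor")
    out = np.zeros_like(arr)
    r1 = w.row0 + w.height_w
    c1 = w.col0 + w.width_w
    out[w.row0 : r1, w.col0 : c1, :] = arr[w.row0 : r1, w.col0 : c1, :]
    return out


def window_recall(w: WindowSpec, truth_mask: np.ndarray) -> float:
    """Fraction of foreground truth voxels spatially covered by the window."""
    truth = np.asarray(truth_mask).astype(bool)
    if truth.ndim != 3:
        raise ValidationError("expected a 3-D binary tensor")
    total = truth.sum()
    if total == 0:
        raise ValidationError("truth mask has no foreground voxels")
    covered = truth[
        w.row0 : w.row0 + w.height_w, w.col0 : w.col0 + w.width_w, :
    ].sum()
    return float(covered / total)
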