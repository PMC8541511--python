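"""Container for grayscale echo-like video tensors.

A video is stored as a nonnegative ``(sx, sy, t)`` tensor.  All matrix-based
stages of the pipeline operate on the ``(sx*sy, t)`` view obtained by
row-major vectorization of the two spatial dimensions, with one column per
frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass
class EchoVideo:
    """Grayscale video as a nonnegative ``(sx, sy, t)`` float tensor."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(
                f"video tensor must be 3-D (sx, sy, t); got shape {self.data.shape}"
            )
        if self.data.size == 0:
            raise ValidationError("video tensor must be non-empty")
        if np.min(self.data) < 0:
            raise ValidationError("video tensor must be nonnegative")

    @property
    def sx(self) -> int:
        return self.data.shape[0]

    @property
    def sy(self) -> int:
        return self.data.shape[1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.sx * self.sy

    @property
    def matrix(self) -> np.ndarray:
        """Pixels-by-frames matrix view (row-major spatial vectorization)."""
        return self.data.reshape(self.n_pixels, self.n_frames)


def matrix_to_tensor(X: np.ndarray, sx: int, sy: int) -> np.ndarray:
    """Undo the row-major spatial vectorization of a pixels-by-frames matrix."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] != sx * sy:
        raise ValidationError(
            f"matrix of shape {X.shape} does not match spatial dims ({sx}, {sy})"
        )
    return X.reshape(sx, sy, X.shape[1])
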