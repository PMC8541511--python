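"""Convex variational segmentation of the sparse video component.

Minimizes, over relaxed masks ``B`` with entries in [0, 1],

    0.5 * <Theta - S, B> + lam1 * TV(B) + lam2 * <1, B> + lam3 * <WH, B>

where ``S`` is the sparse component and ``WH`` the low-rank background from
the factorization stage.  Absorbing the background-exclusion term into a
per-pixel threshold map ``Theta2 = Theta + 2 * lam3 * WH`` gives the
equivalent form ``0.5 * <Theta2 - S, B> + lam1 * TV(B) + lam2 * <1, B>``,
which is solved by a primal–dual hybrid gradient (PDHG) iteration.  TV is
isotropic with forward differences and is applied within each frame
independently.  The relaxed minimizer is binarized at 0.5; because the
energy is linear in ``B`` apart from TV, thresholding a relaxed minimizer
yields a binary minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: Upper bound on the squared operator norm of the forward-difference gradient.
GRAD_NORM_SQ = 8.0


@dataclass
class SegmentationConfig:
    theta: float = 0.01
    lam1: float = 0.04
    lam2: float = 0.075
    lam3: float = 1.0
    n_iters: int = 500
    tau: float = 1.0 / np.sqrt(8.0)
    sigma_dual: float = 1.0 / np.sqrt(8.0)

    def validate(self) -> None:
        if self.theta <= 0:
            raise ValidationError("theta must be > 0")
        if min(self.lam1, self.lam2, self.lam3) < 0:
            raise ValidationError("lam1, lam2, lam3 must be >= 0")
        if self.n_iters < 1:
            raise ValidationError("n_iters must be >= 1")
        if self.tau * self.sigma_dual * GRAD_NORM_SQ > 1.0 + 1e-12:
            raise ValidationError(
                "step sizes violate tau * sigma * ||D||^2 <= 1"
            )


@dataclass
class SoftMask:
    """Relaxed segmentation with entries in [0, 1]."""

    B: np.ndarray
    sx: int
    sy: int

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=np.float64)
        if np.min(self.B) < -1e-12 or np.max(self.B) > 1 + 1e-12:
            raise ValidationError("soft mask entries must lie in [0, 1]")

    @property
    def tensor(self) -> np.ndarray:
        return self.B.reshape(self.sx, self.sy, -1)


@dataclass
class BinaryMask:
    """Hard segmentation with entries in {0, 1}."""

    B_tilde: np.ndarray
    sx: int
    sy: int

    def __post_init__(self) -> None:
        self.B_tilde = np.asarray(self.B_tilde)
        vals = np.unique(self.B_tilde)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("binary mask entries must be 0 or 1")
        self.B_tilde = self.B_tilde.astype(np.uint8)

    @property
    def tensor(self) -> np.ndarray:
        return self.B_tilde.reshape(self.sx, self.sy, -1)


@dataclass
class ThresholdMap:
    Theta2: np.ndarray


def build_threshold_map(theta: float, lam3: float, WH: np.ndarray) -> ThresholdMap:
    """Per-pixel threshold ``Theta2 = theta + 2 * lam3 * WH``."""
    if theta <= 0:
        raise ValidationError("theta must be > 0")
    if lam3 < 0:
        raise ValidationError("lam3 must be >= 0")
    WH = np.asarray(WH, dtype=np.float64)
    if np.min(WH) < 0:
        raise ValidationError("WH must be nonnegative")
    return ThresholdMap(Theta2=theta + 2.0 * lam3 * WH)


def _grad(b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences along the two spatial axes, Neumann boundary."""
    gx = np.zeros_like(b)
    gy = np.zeros_like(b)
    gx[:-1, ...] = b[1:, ...] - b[:-1, ...]
    gy[:, :-1, ...] = b[:, 1:, ...] - b[:, :-1, ...]
    return gx, gy


def _grad_adjoint(px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Adjoint D^T of the forward-difference gradient (negative divergence)."""
    out = np.zeros_like(px)
    out[0, ...] = -px[0, ...]
    out[1:-1, ...] = px[:-2, ...] - px[1:-1, ...]
    out[-1, ...] = px[-2, ...]
    out[:, 0, ...] += -py[:, 0, ...]
    out[:, 1:-1, ...] += py[:, :-2, ...] - py[:, 1:-1, ...]
    out[:, -1, ...] += py[:, -2, ...]
    return out


def tv_isotropic(b: np.ndarray) -> float:
    """Isotropic total variation of a 2-D image (or of each frame, summed)."""
    b = np.asarray(b, dtype=np.float64)
    gx, gy = _grad(b)
    return float(np.sum(np.hypot(gx, gy)))


def energy(
    B: SoftMask | np.ndarray,
    S_hat: np.ndarray,
    WH: np.ndarray,
    cfg: SegmentationConfig,
    sx: int | None = None,
    sy: int | None = None,
) -> float:
    """Segmentation energy of a (soft or binary) mask.

    Evaluates ``0.5 <Theta - S, B> + lam1 TV(B) + lam2 <1, B> + lam3 <WH, B>``
    with TV summed over frames.
    """
    if isinstance(B, SoftMask):
        arr = B.tensor
    else:
        arr = np.asarray(B, dtype=np.float64)
        if arr.ndim == 2 and sx is not None and sy is not None:
            arr = arr.reshape(sx, sy, -1)
        if arr.ndim == 2:
            arr = arr[:, :, None]
    S3 = np.asarray(S_hat, dtype=np.float64).reshape(arr.shape)
    WH3 = np.asarray(WH, dtype=np.float64).reshape(arr.shape)
    data = 0.5 * np.sum((cfg.theta - S3) * arr)
    tv = tv_isotropic(arr)
    return float(
        data
        + cfg.lam1 * tv
        + cfg.lam2 * np.sum(arr)
        + cfg.lam3 * np.sum(WH3 * arr)
    )


def pdhg_segment(
    S_hat: np.ndarray,
    WH: np.ndarray,
    cfg: SegmentationConfig,
    sx: int,
    sy: int,
    return_trace: bool = False,
    iter_hook=None,
):
    """Minimize the relaxed segmentation energy by PDHG.

    ``S_hat`` and ``WH`` are pixels-by-frames matrices (or ``(sx, sy, t)``
    tensors).  Returns a :class:`SoftMask`; with ``return_trace=True`` also
    returns the per-iteration energy trace.
    """
    cfg.validate()
    S3 = np.asarray(S_hat, dtype=np.float64).reshape(sx, sy, -1)
    WH3 = np.asarray(WH, dtype=np.float64).reshape(sx, sy, -1)
    if S3.shape != WH3.shape:
        raise ValidationError("S and WH shapes disagree")

    theta2 = build_threshold_map(cfg.theta, cfg.lam3, WH3).Theta2
    # gradient of the linear term G(b): 0.5*(Theta2 - S) + lam2
    lin = 0.5 * (theta2 - S3) + cfg.lam2

    b = np.zeros_like(S3)
    b_bar = b.copy()
    px = np.zeros_like(S3)
    py = np.zeros_like(S3)
    tau, sig, lam1 = cfg.tau, cfg.sigma_dual, cfg.lam1
    trace: list[float] = []

    for _ in range(cfg.n_iters):
        gx, gy = _grad(b_bar)
        px += sig * gx
        py += sig * gy
        norm = np.hypot(px, py)
        scale = np.where(norm > lam1, lam1 / np.maximum(norm, 1e-300), 1.0)
        px *= scale
        py *= scale
        b_new = np.clip(b - tau * (_grad_adjoint(px, py) + lin), 0.0, 1.0)
        b_bar = 2.0 * b_new - b
        b = b_new
        if iter_hook is not None:
            iter_hook(b, px, py)
        if return_trace:
            trace.append(
                float(
                    0.5 * np.sum((theta2 - S3) * b)
                    + cfg.lam1 * tv_isotropic(b)
                    + cfg.lam2 * np.sum(b)
                )
            )

    mask = SoftMask(B=b.reshape(sx * sy, -1), sx=sx, sy=sy)
    if return_trace:
        return mask, trace
    return mask


def binarize(B: SoftMask) -> BinaryMask:
    """Threshold a soft mask at 0.5 (strictly greater; ties map to 0)."""
    return BinaryMask(B_tilde=(B.B > 0.5).astype(np.uint8), sx=B.sx, sy=B.sy)
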