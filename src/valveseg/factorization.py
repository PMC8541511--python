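"""Robust nonnegative matrix factorization with Bregman debiasing.

Separates a pixels-by-frames video matrix ``X`` into a nonnegative low-rank
product ``W @ H`` (static / rigidly moving background) and a nonnegative
sparse component ``S`` (fast, thin structures), ``X ≈ W H + S + noise``.

Two variants are provided:

* :func:`bregman_rnmf` — the l1-regularized model solved by alternating a
  soft-threshold update of ``S``, a running-subgradient (Bregman) update of
  ``p`` that removes the amplitude shrinkage of the soft threshold, and one
  multiplicative update each for ``W`` and ``H``.
* :func:`exclusion_rnmf` — the same alternation with an extra penalty on the
  overlap between ``W H`` and ``S``, used for window localization.  With
  ``mu2 = 0`` it reduces line-by-line to the first variant.

Wherever an entry of ``S`` is strictly positive, the subgradient ``p`` equals
1 there after the corresponding update, so positive values of ``S`` are no
longer penalized — this is the debiasing mechanism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalError, ValidationError


@dataclass
class VideoMatrix:
    """Nonnegative pixels-by-frames matrix plus its spatial dimensions."""

    X: np.ndarray
    sx: int
    sy: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValidationError("X must be a 2-D matrix")
        if self.X.shape[0] != self.sx * self.sy:
            raise ValidationError(
                f"X has {self.X.shape[0]} rows but sx*sy = {self.sx * self.sy}"
            )
        if np.min(self.X) < 0:
            raise ValidationError("X must be entrywise nonnegative")

    @property
    def s(self) -> int:
        return self.X.shape[0]

    @property
    def t(self) -> int:
        return self.X.shape[1]


@dataclass
class FactorizationConfig:
    rank: int = 2
    lam: float = 0.1
    mu1: float = 1.0
    mu2: float = 0.4
    n_outer_iters: int = 100
    n_init_nmf_iters: int = 200
    eps: float = 1e-12
    seed: int = 0

    def validate(self) -> None:
        if self.rank < 1:
            raise ValidationError("rank must be >= 1")
        if self.lam < 0 or self.mu1 < 0 or self.mu2 < 0:
            raise ValidationError("lam, mu1 and mu2 must be >= 0")
        if self.n_outer_iters < 1:
            raise ValidationError("n_outer_iters must be >= 1")
        if self.n_init_nmf_iters < 0:
            raise ValidationError("n_init_nmf_iters must be >= 0")
        if self.eps <= 0:
            raise ValidationError("eps must be > 0")


@dataclass
class FactorizationResult:
    W: np.ndarray
    H: np.ndarray
    S: np.ndarray
    p: np.ndarray
    r: int
    objective_trace: list[float] = field(default_factory=list)

    @property
    def WH(self) -> np.ndarray:
        return self.W @ self.H

    def save(self, path, config: "FactorizationConfig | None" = None) -> None:
        """Serialize factors to a compressed archive, config echoed as text."""
        import dataclasses as _dc
        import json as _json

        meta = _json.dumps(_dc.asdict(config)) if config is not None else ""
        np.savez_compressed(
            path,
            W=self.W,
            H=self.H,
            S=self.S,
            p=self.p,
            r=np.int64(self.r),
            objective_trace=np.asarray(self.objective_trace),
            config_json=np.str_(meta),
        )

    @classmethod
    def load(cls, path) -> "FactorizationResult":
        with np.load(path, allow_pickle=False) as d:
            return cls(
                W=d["W"],
                H=d["H"],
                S=d["S"],
                p=d["p"],
                r=int(d["r"]),
                objective_trace=list(d["objective_trace"]),
            )


def soft_threshold_nonneg(u, lam: float):
    """One-sided soft threshold: ``u - lam`` where ``u > lam``, else 0.

    Applied entrywise when ``u`` is an array; enforces nonnegativity because
    the lower branch returns 0 for every ``u <= lam``.
    """
    if lam < 0:
        raise ValidationError("threshold lam must be >= 0")
    u = np.asarray(u, dtype=np.float64)
    out = np.where(u > lam, u - lam, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def _check_rank(rank: int, s: int, t: int) -> None:
    if rank >= min(s, t):
        raise ValidationError(
            f"rank {rank} must be < min(s, t) = {min(s, t)}"
        )


def nmf_multiplicative(
    X: VideoMatrix | np.ndarray,
    rank: int,
    n_iters: int,
    seed: int = 0,
    eps: float = 1e-12,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Plain NMF by multiplicative updates, uniform (0, 1] initialization."""
    A = X.X if isinstance(X, VideoMatrix) else np.asarray(X, dtype=np.float64)
    s, t = A.shape
    _check_rank(rank, s, t)
    if init is not None:
        W = np.array(init[0], dtype=np.float64)
        H = np.array(init[1], dtype=np.float64)
    else:
        rng = np.random.default_rng(seed)
        W = 1.0 - rng.random((s, rank))
        H = 1.0 - rng.random((rank, t))
    for _ in range(n_iters):
        H *= (W.T @ A) / (W.T @ W @ H + eps)
        W *= (A @ H.T) / (W @ H @ H.T + eps)
    return W, H


def _mult_step_W(W, H, S, X, half_mu2, eps):
    # numerator |A| - A with A = (S - X + 0.5*mu2*S) H^T equals twice the
    # positive part of -A, which keeps W nonnegative
    A = (S - X + half_mu2 * S) @ H.T
    W *= (np.abs(A) - A) / (2.0 * (W @ (H @ H.T)) + eps)


def _mult_step_H(W, H, S, X, half_mu2, eps):
    B = W.T @ (S - X + half_mu2 * S)
    H *= (np.abs(B) - B) / (2.0 * ((W.T @ W) @ H) + eps)


def _normalize_columns(W: np.ndarray, H: np.ndarray) -> None:
    """Unit-norm columns of W, compensated in rows of H; WH is unchanged."""
    norms = np.linalg.norm(W, axis=0)
    nz = norms > 0
    W[:, nz] /= norms[nz]
    H[nz, :] *= norms[nz, None]


def _rnmf_loop(
    X: VideoMatrix,
    cfg: FactorizationConfig,
    lam: float,
    mu2: float,
    freeze_p: bool = False,
    iter_hook=None,
) -> FactorizationResult:
    cfg.validate()
    A = X.X
    s, t = A.shape
    _check_rank(cfg.rank, s, t)
    if lam == 0 and cfg.n_outer_iters > 0:
        warnings.warn(
            "lam = 0: sparse component S is unconstrained (no shrinkage)",
            stacklevel=3,
        )
    eps = cfg.eps
    half_mu2 = 0.5 * mu2

    # S = 0 initially, so the first W/H updates solve a plain NMF problem
    W, H = nmf_multiplicative(A, cfg.rank, cfg.n_init_nmf_iters, seed=cfg.seed, eps=eps)
    S = np.zeros_like(A)
    p = np.zeros_like(A)
    trace: list[float] = []

    for k in range(cfg.n_outer_iters):
        WH = W @ H
        S = soft_threshold_nonneg(A - WH + lam * p - mu2 * WH, lam)
        if lam > 0 and not freeze_p:
            p = p + (A - WH - S - mu2 * WH) / lam
        _mult_step_W(W, H, S, A, half_mu2, eps)
        _mult_step_H(W, H, S, A, half_mu2, eps)
        _normalize_columns(W, H)
        for M in (W, H, S, p):
            if not np.all(np.isfinite(M)):
                raise NumericalError("non-finite value in factorization", iteration=k)
        trace.append(float(np.sum((A - W @ H - S) ** 2)))
        if iter_hook is not None:
            iter_hook(k, W, H, S, p)

    return FactorizationResult(W=W, H=H, S=S, p=p, r=cfg.rank, objective_trace=trace)


def bregman_rnmf(
    X: VideoMatrix,
    cfg: FactorizationConfig,
    freeze_p: bool = False,
    iter_hook=None,
) -> FactorizationResult:
    """Muscle/valve separation with Bregman-debiased sparsity.

    With ``freeze_p=True`` the subgradient stays at 0, which reproduces the
    classical (biased) robust NMF whose soft threshold shrinks every
    recovered amplitude by ``lam``.
    """
    return _rnmf_loop(X, cfg, lam=cfg.lam, mu2=0.0, freeze_p=freeze_p, iter_hook=iter_hook)


def exclusion_rnmf(
    X: VideoMatrix,
    cfg: FactorizationConfig,
    iter_hook=None,
) -> FactorizationResult:
    """Windowing factorization with an extra ``<WH, S>`` exclusion penalty.

    Uses ``cfg.mu1`` as the sparsity weight and ``cfg.mu2`` as the exclusion
    weight; ``mu2 = 0`` reduces every update line to :func:`bregman_rnmf`
    with ``lam = mu1``.
    """
    if cfg.mu1 <= 0:
        raise ValidationError("exclusion_rnmf requires mu1 > 0")
    return _rnmf_loop(X, cfg, lam=cfg.mu1, mu2=cfg.mu2, iter_hook=iter_hook)
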