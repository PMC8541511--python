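"""End-to-end orchestration of the two segmentation modes.

``automatic``: factorize -> segment -> refine.
``windowed``:  exclusion-factorize -> detect window -> factorize ->
               segment within the window -> refine.

Default hyperparameters: sparsity weight 0.1 and factorization rank 2 for
muscle detection; TV weight 0.04, area weight 0.075 (automatic) or 0.05
(windowed), muscle-exclusion weight 1.0, base threshold 0.01 for the
segmentation; sparsity 1.0, exclusion 0.4 and rank 5 for the windowing
factorization.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import RefinementFailure, ValidationError
from .factorization import (
    FactorizationConfig,
    VideoMatrix,
    bregman_rnmf,
    exclusion_rnmf,
)
from .refinement import (
    connected_components_3d,
    iterative_centroid,
    select_cluster,
    temporal_projection,
)
from .segmentation import BinaryMask, SegmentationConfig, binarize, pdhg_segment
from .video import EchoVideo, matrix_to_tensor
from .windowing import WindowSpec, detect_window, restrict_to_window

logger = logging.getLogger(__name__)

#: Area weight when segmenting inside a window (slightly lower so more of
#: the valve is captured once the spatial extent is already restricted).
LAM2_WINDOWED = 0.05
LAM2_AUTOMATIC = 0.075


@dataclass
class RefinementConfig:
    n_iters: int = 11
    sigma_schedule: np.ndarray | None = None


@dataclass
class PipelineConfig:
    mode: str = "automatic"
    factorization: FactorizationConfig = field(default_factory=FactorizationConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    window_factorization: FactorizationConfig = field(
        default_factory=lambda: FactorizationConfig(rank=5, mu1=1.0, mu2=0.4)
    )
    refinement: RefinementConfig = field(default_factory=RefinementConfig)
    window_size: tuple[int, int] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("automatic", "windowed"):
            raise ValidationError(f"unknown mode: {self.mode!r}")
        if self.mode == "windowed" and self.window_size is None:
            raise ValidationError("windowed mode requires window_size")
        self.factorization.validate()
        self.segmentation.validate()

    @classmethod
    def default(cls, mode: str = "automatic", window_size=None, seed: int = 0):
        lam2 = LAM2_AUTOMATIC if mode == "automatic" else LAM2_WINDOWED
        cfg = cls(
            mode=mode,
            segmentation=SegmentationConfig(lam2=lam2),
            window_size=window_size,
            seed=seed,
        )
        cfg.factorization.seed = seed
        cfg.window_factorization.seed = seed
        return cfg


@dataclass
class EvalReport:
    per_video: list[tuple[str, float, float, float]]
    averages: tuple[float, float, float]


def _refine(S3D: np.ndarray, mask: BinaryMask, cfg: PipelineConfig) -> BinaryMask:
    amap = temporal_projection(S3D)
    centroid = iterative_centroid(
        amap, n_iters=cfg.refinement.n_iters, sigma_schedule=cfg.refinement.sigma_schedule
    )
    clusters = connected_components_3d(mask)
    if clusters.n_clusters == 0:
        raise RefinementFailure("binary mask is empty", stage="clustering")
    return select_cluster(clusters, centroid)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - self.t0)

    return _Timer()


def run_automatic(
    video: EchoVideo, cfg: PipelineConfig, freeze_subgradient: bool = False
) -> BinaryMask:
    """Fully automatic mode: factorize, segment, refine.

    ``freeze_subgradient=True`` replaces the debiased factorization by the
    classical (shrinkage-biased) one; used for ablation studies only.
    """
    cfg.validate()
    X = VideoMatrix(X=video.matrix, sx=video.sx, sy=video.sy)
    with _stage("factorization"):
        fact = bregman_rnmf(X, cfg.factorization, freeze_p=freeze_subgradient)
    WH = fact.WH
    with _stage("segmentation"):
        soft = pdhg_segment(fact.S, WH, cfg.segmentation, video.sx, video.sy)
        mask = binarize(soft)
    with _stage("refinement"):
        S3D = matrix_to_tensor(fact.S, video.sx, video.sy)
        return _refine(S3D, mask, cfg)


def run_windowed(video: EchoVideo, cfg: PipelineConfig) -> tuple[BinaryMask, WindowSpec]:
    """Windowed mode: localize the valve first, then segment inside the window."""
    cfg.validate()
    if cfg.window_size is None:
        raise ValidationError("windowed mode requires window_size")
    hw, ww = cfg.window_size
    if hw > video.sx or ww > video.sy:
        raise ValidationError("window larger than the frame")
    X = VideoMatrix(X=video.matrix, sx=video.sx, sy=video.sy)
    with _stage("window-factorization"):
        excl = exclusion_rnmf(X, cfg.window_factorization)
    with _stage("window-detection"):
        S3D_excl = matrix_to_tensor(excl.S, video.sx, video.sy)
        window = detect_window(S3D_excl, hw, ww)
    with _stage("factorization"):
        fact = bregman_rnmf(X, cfg.factorization)
    S3D = restrict_to_window(matrix_to_tensor(fact.S, video.sx, video.sy), window)
    WH3D = restrict_to_window(matrix_to_tensor(fact.WH, video.sx, video.sy), window)
    with _stage("segmentation"):
        soft = pdhg_segment(S3D, WH3D, cfg.segmentation, video.sx, video.sy)
        mask = binarize(soft)
    with _stage("refinement"):
        refined = _refine(S3D, mask, cfg)
    return refined, window


def evaluate(pred: BinaryMask | np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """Pixelwise (recall, precision, f1) over the whole video.

    Each metric is 0 whenever its denominator is 0.
    """
    p = (pred.tensor if isinstance(pred, BinaryMask) else np.asarray(pred)).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = float(np.sum(p & t))
    fp = float(np.sum(p & ~t))
    fn = float(np.sum(~p & t))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return recall, precision, f1


def evaluate_many(results: list[tuple[str, np.ndarray, np.ndarray]]) -> EvalReport:
    """Per-video metrics plus unweighted averages across videos."""
    rows = []
    for name, pred, truth in results:
        r, p, f = evaluate(pred, truth)
        rows.append((name, r, p, f))
    if rows:
        avg = tuple(float(np.mean([row[i] for row in rows])) for i in (1, 2, 3))
    else:
        avg = (0.0, 0.0, 0.0)
    return EvalReport(per_video=rows, averages=avg)


# ---------------------------------------------------------------------------
# flat YAML-style config loading


_FLAT_KEYS = {
    "mode": ("mode",),
    "seed": ("seed",),
    "rank": ("factorization", "rank"),
    "lam": ("factorization", "lam"),
    "n_outer_iters": ("factorization", "n_outer_iters"),
    "n_init_nmf_iters": ("factorization", "n_init_nmf_iters"),
    "mu1": ("window_factorization", "mu1"),
    "mu2": ("window_factorization", "mu2"),
    "window_rank": ("window_factorization", "rank"),
    "theta": ("segmentation", "theta"),
    "lam1": ("segmentation", "lam1"),
    "lam2": ("segmentation", "lam2"),
    "lam3": ("segmentation", "lam3"),
    "segmentation_iters": ("segmentation", "n_iters"),
    "refinement_iters": ("refinement", "n_iters"),
}


def config_from_dict(d: dict, window_size=None) -> PipelineConfig:
    """Build a PipelineConfig from a flat key/value mapping.

    Omitted keys keep the documented defaults; the windowed mode's lower
    area weight is applied only when ``lam2`` is not given explicitly.
    """
    mode = d.get("mode", "automatic")
    cfg = PipelineConfig.default(mode=mode, window_size=window_size, seed=int(d.get("seed", 0)))
    for key, value in d.items():
        if key == "window_size":
            cfg.window_size = tuple(int(v) for v in value)
            continue
        if key not in _FLAT_KEYS:
            raise ValidationError(f"unknown config key: {key!r}")
        path = _FLAT_KEYS[key]
        target = cfg
        for attr in path[:-1]:
            target = getattr(target, attr)
        current = getattr(target, path[-1])
        setattr(target, path[-1], type(current)(value) if current is not None else value)
    cfg.factorization.seed = cfg.seed
    cfg.window_factorization.seed = cfg.seed
    return cfg


def load_config(path: str | Path, window_size=None) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError("config file must contain a flat key/value mapping")
    return config_from_dict(data, window_size=window_size)
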