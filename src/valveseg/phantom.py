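"""Synthetic echo-like video phantoms with voxel-level ground truth.

Each phantom is the clipped sum of three (optionally four) components:

* a background of exact matrix rank ``<= bg_rank`` built from smooth,
  nonnegative spatial patterns modulated by slow nonnegative temporal
  profiles (rigid / periodic muscle motion),
* a thin, fast valve: two line-segment leaflets hinged at a fixed point
  whose opening angle oscillates, touching when closed,
* optional bright "distractor" blobs with independent periodic motion,
  mimicking a second valve elsewhere in the field of view,
* clipped zero-mean Gaussian noise.

The valve brightness tapers linearly from the hinge to the leaflet tip, so
amplitude fidelity of the sparse component directly affects how much of the
leaflet clears the downstream segmentation threshold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .video import EchoVideo

#: Maximum half-opening angle of a leaflet, radians.
THETA_MAX = 0.9

#: Brightness at the leaflet tip as a fraction of ``valve_amplitude``.
TIP_FRACTION = 0.4


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic echo video."""

    height: int = 96
    width: int = 96
    n_frames: int = 40
    bg_rank: int = 2
    bg_amplitude: float = 0.5
    valve_amplitude: float = 0.8
    valve_length: int = 28
    valve_thickness: int = 3
    hinge_position: tuple[int, int] = (20, 48)
    swing_period: int = 20
    noise_sigma: float = 0.01
    distractor_count: int = 0
    seed: int = 0

    def validate(self) -> None:
        if min(self.height, self.width, self.n_frames) < 1:
            raise ValidationError("height, width and n_frames must all be >= 1")
        if self.bg_rank < 1:
            raise ValidationError("bg_rank must be >= 1")
        if self.bg_rank > min(self.height * self.width, self.n_frames):
            raise ValidationError("bg_rank exceeds the matrix dimensions")
        if not 0.0 <= self.bg_amplitude <= 1.0:
            raise ValidationError("bg_amplitude must lie in [0, 1]")
        if self.valve_amplitude < 0:
            raise ValidationError("valve_amplitude must be >= 0")
        if self.valve_length >= min(self.height, self.width):
            raise ValidationError("valve_length must be < min(height, width)")
        if self.valve_thickness < 1:
            raise ValidationError("valve_thickness must be >= 1")
        r, c = self.hinge_position
        if not (0 <= r < self.height and 0 <= c < self.width):
            raise ValidationError("hinge_position must lie inside the frame")
        if self.swing_period < 2:
            raise ValidationError("swing_period must be >= 2 frames")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.distractor_count < 0:
            raise ValidationError("distractor_count must be >= 0")


@dataclass
class PhantomOutput:
    """A generated phantom and its voxel-level ground truth."""

    video: EchoVideo
    truth_background: np.ndarray
    truth_valve_mask: np.ndarray
    truth_valve_values: np.ndarray
    truth_distractor_mask: np.ndarray

    @property
    def spec_shape(self) -> tuple[int, int, int]:
        return self.video.data.shape


def _segment_values(
    shape: tuple[int, int],
    hinge: tuple[int, int],
    direction: tuple[float, float],
    length: float,
    thickness: float,
    amplitude: float,
) -> np.ndarray:
    """Rasterize one thick leaflet with a linear hinge-to-tip brightness taper."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    pr = rows - hinge[0]
    pc = cols - hinge[1]
    proj = np.clip(pr * direction[0] + pc * direction[1], 0.0, length)
    dr = pr - proj * direction[0]
    dc = pc - proj * direction[1]
    dist = np.hypot(dr, dc)
    inside = dist <= thickness / 2.0
    taper = 1.0 - (1.0 - TIP_FRACTION) * (proj / max(length, 1e-12))
    return np.where(inside, amplitude * taper, 0.0)


def _valve_frame(
    spec: PhantomSpec, theta: float, hinge: tuple[float, float]
) -> np.ndarray:
    """Brightness image of the two leaflets at opening half-angle ``theta``."""
    frame = np.zeros((spec.height, spec.width))
    for sign in (+1.0, -1.0):
        d = (np.cos(theta), sign * np.sin(theta))
        vals = _segment_values(
            (spec.height, spec.width),
            hinge,
            d,
            float(spec.valve_length),
            float(spec.valve_thickness),
            spec.valve_amplitude,
        )
        frame = np.maximum(frame, vals)
    return frame


def _background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Exact rank <= bg_rank background, zero inside the valve swing region."""
    h, w, T = spec.height, spec.width, spec.n_frames
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    hr, hc = spec.hinge_position
    # keep the background clear of the region swept by the leaflets so the
    # sparse component can recover the full valve amplitude
    # margin covers leaflet length, thickness and the slow hinge drift
    protect = np.hypot(rows - hr, cols - hc) <= spec.valve_length + spec.valve_thickness + 5

    patterns = []
    # component 0: a smooth sector-like ring, emulating the myocardial wall
    cy, cxm = h / 2.0, w / 2.0
    radius = 0.38 * min(h, w)
    ring = np.exp(-((np.hypot(rows - cy, cols - cxm) - radius) ** 2) / (2.0 * 3.0**2))
    patterns.append(ring)
    # remaining components: smooth Gaussian blobs at random positions
    for _ in range(spec.bg_rank - 1):
        br = rng.uniform(0.1 * h, 0.9 * h)
        bc = rng.uniform(0.1 * w, 0.9 * w)
        width_b = rng.uniform(0.08, 0.2) * min(h, w)
        blob = np.exp(
            -((rows - br) ** 2 + (cols - bc) ** 2) / (2.0 * width_b**2)
        )
        patterns.append(blob)

    t = np.arange(T, dtype=np.float64)
    bg = np.zeros((h, w, T))
    scale = spec.bg_amplitude / spec.bg_rank
    for k, pattern in enumerate(patterns):
        pattern = pattern.copy()
        pattern[protect] = 0.0
        peak = pattern.max()
        if peak > 0:
            pattern /= peak
        if k == 0:
            profile = np.ones(T)
        else:
            period = T / rng.integers(1, 3)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            profile = 0.75 + 0.25 * np.sin(2.0 * np.pi * t / period + phase)
        bg += scale * pattern[:, :, None] * profile[None, None, :]
    return bg


def _distractors(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Bright blobs orbiting on small circles far from the hinge."""
    h, w, T = spec.height, spec.width, spec.n_frames
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    hr, hc = spec.hinge_position
    out = np.zeros((h, w, T))
    min_sep = spec.valve_length + 12.0
    for _ in range(spec.distractor_count):
        for _attempt in range(100):
            cr = rng.uniform(4, h - 5)
            cc = rng.uniform(4, w - 5)
            if np.hypot(cr - hr, cc - hc) > min_sep:
                break
        orbit = rng.uniform(4.0, 7.0)
        period = max(3, int(round(spec.swing_period * rng.uniform(0.5, 0.9))))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        radius = rng.uniform(1.5, 2.0)
        amp = 0.5 * max(spec.valve_amplitude, spec.bg_amplitude)
        for t in range(T):
            ang = 2.0 * np.pi * t / period + phase
            pr = cr + orbit * np.sin(ang)
            pc = cc + orbit * np.cos(ang)
            disk = np.hypot(rows - pr, cols - pc) <= radius
            out[:, :, t] = np.maximum(out[:, :, t], amp * disk)
    return out


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate a seeded phantom video with ground truth.

    The same spec (including seed) always yields bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    background = _background(spec, rng)
    # per-frame angle jitter keeps the swinging valve from being exactly
    # periodic (and hence from being low-rank across frames)
    jitter = rng.uniform(-0.12, 0.12, size=spec.n_frames)
    thetas = np.clip(
        THETA_MAX * np.abs(np.sin(2.0 * np.pi * np.arange(spec.n_frames) / spec.swing_period))
        + jitter,
        0.02,
        THETA_MAX + 0.12,
    )
    # the annulus drifts slowly with the heartbeat, so the hinge region is
    # never exactly static (a static hinge would be absorbed by the low-rank
    # background term during factorization)
    drift_phase = rng.uniform(0.0, 2.0 * np.pi)
    tt = 2.0 * np.pi * np.arange(spec.n_frames) / (2.0 * spec.swing_period)
    hinge_rows = spec.hinge_position[0] + 2.5 * np.sin(tt + drift_phase)
    hinge_cols = spec.hinge_position[1] + 1.5 * np.cos(tt + drift_phase)
    valve = np.stack(
        [
            _valve_frame(spec, thetas[t], (hinge_rows[t], hinge_cols[t]))
            for t in range(spec.n_frames)
        ],
        axis=2,
    )
    distract = _distractors(spec, rng)

    clean = background + valve + distract
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=clean.shape)
    else:
        noise = 0.0
    video = np.clip(clean + noise, 0.0, 1.0)

    return PhantomOutput(
        video=EchoVideo(video),
        truth_background=background,
        truth_valve_mask=(valve > 0),
        truth_valve_values=valve,
        truth_distractor_mask=(distract > 0),
    )


def phantom_fixture_suite() -> list[tuple[str, PhantomSpec]]:
    """Named phantom presets covering easy, noisy and distractor regimes."""
    easy = PhantomSpec()
    noisy = dataclasses.replace(easy, valve_amplitude=0.7, noise_sigma=0.10, seed=1)
    distractor = dataclasses.replace(easy, distractor_count=1, noise_sigma=0.02, seed=2)
    return [("easy", easy), ("noisy", noisy), ("distractor", distractor)]


def write_phantom(output: PhantomOutput, out_dir: str | Path, spec: PhantomSpec | None = None) -> None:
    """Write video + ground-truth masks as multi-frame TIFF with a JSON sidecar."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # frames-first layout for multi-page TIFF
    vid = np.moveaxis(output.video.data, 2, 0).astype(np.float32)
    tifffile.imwrite(out_dir / "video.tif", vid, photometric="minisblack")
    mask = np.moveaxis(output.truth_valve_mask, 2, 0).astype(np.uint8) * 255
    tifffile.imwrite(out_dir / "truth_valve_mask.tif", mask, photometric="minisblack")
    dmask = np.moveaxis(output.truth_distractor_mask, 2, 0).astype(np.uint8) * 255
    tifffile.imwrite(out_dir / "truth_distractor_mask.tif", dmask, photometric="minisblack")
    if spec is not None:
        (out_dir / "phantom_spec.json").write_text(
            json.dumps(dataclasses.asdict(spec), indent=2) + "\n"
        )
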