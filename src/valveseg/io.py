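"""Reading and writing videos, masks and overlays.

Supported video containers: multi-frame TIFF, a directory of per-frame
PNG/JPEG images (sorted lexicographically), and serialized numpy tensors
(``.npy``/``.npz``).  Videos are returned as floats rescaled to [0, 1].
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import VideoIOError
from .segmentation import BinaryMask
from .video import EchoVideo
from .windowing import WindowSpec

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp"}


def _rescale(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / info.max
    arr = arr.astype(np.float64)
    peak = arr.max() if arr.size else 0.0
    if peak > 1.0:
        arr = arr / peak
    return np.clip(arr, 0.0, 1.0)


def _frames_to_tensor(frames: np.ndarray) -> np.ndarray:
    # frames-first (t, sx, sy) -> (sx, sy, t)
    if frames.ndim == 2:
        frames = frames[None, ...]
    if frames.ndim != 3:
        raise VideoIOError(f"expected grayscale frames; got shape {frames.shape}")
    return np.moveaxis(frames, 0, 2)


def read_video(path: str | Path) -> EchoVideo:
    """Read a video from TIFF, an image directory, or a numpy tensor file."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            f for f in path.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise VideoIOError(f"no image frames found in {path}")
        frames = []
        shape = None
        for f in files:
            try:
                img = iio.imread(f)
            except Exception as exc:  # noqa: BLE001
                raise VideoIOError(f"unreadable frame {f}: {exc}") from exc
            if img.ndim == 3:
                img = img.mean(axis=2)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise VideoIOError(
                    f"frame {f} has size {img.shape}, expected {shape}"
                )
            frames.append(img)
        return EchoVideo(_rescale(_frames_to_tensor(np.stack(frames))))
    if not path.exists():
        raise VideoIOError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path)
        return EchoVideo(_rescale(_frames_to_tensor(np.asarray(frames))))
    if suffix == ".npy":
        arr = np.load(path)
        if arr.ndim != 3:
            raise VideoIOError(f"tensor in {path} must be 3-D (sx, sy, t)")
        return EchoVideo(_rescale(arr))
    if suffix == ".npz":
        with np.load(path) as data:
            key = "video" if "video" in data else list(data.keys())[0]
            arr = data[key]
        if arr.ndim != 3:
            raise VideoIOError(f"tensor in {path} must be 3-D (sx, sy, t)")
        return EchoVideo(_rescale(arr))
    raise VideoIOError(f"unsupported video container: {path}")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask tensor written by :func:`write_mask`."""
    vid = read_video(path)
    return (vid.data > 0.5).astype(np.uint8)


def write_mask(mask: BinaryMask | np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a 0/255 8-bit multi-frame TIFF."""
    vol = mask.tensor if isinstance(mask, BinaryMask) else np.asarray(mask)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        (np.moveaxis(vol, 2, 0) > 0).astype(np.uint8) * 255,
        photometric="minisblack",
    )


def write_soft_mask(B3D: np.ndarray, path: str | Path) -> None:
    """Write a relaxed mask as a 32-bit float multi-frame TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.moveaxis(B3D, 2, 0).astype(np.float32), photometric="minisblack")


def _contour(mask2d: np.ndarray) -> np.ndarray:
    from skimage.segmentation import find_boundaries

    return find_boundaries(mask2d.astype(bool), mode="inner")


def write_overlay(
    video: EchoVideo,
    mask: BinaryMask | np.ndarray,
    out_dir: str | Path,
    truth: np.ndarray | None = None,
    window: WindowSpec | None = None,
) -> None:
    """Write per-frame PNG overlays: prediction contours red, truth green."""
    vol = mask.tensor if isinstance(mask, BinaryMask) else np.asarray(mask)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gray = (np.clip(video.data, 0, 1) * 255).astype(np.uint8)
    for t in range(video.n_frames):
        rgb = np.stack([gray[:, :, t]] * 3, axis=2)
        pred_c = _contour(vol[:, :, t])
        rgb[pred_c] = (255, 0, 0)
        if truth is not None:
            truth_c = _contour(truth[:, :, t])
            rgb[truth_c] = (0, 255, 0)
        if window is not None:
            r0, c0 = window.row0, window.col0
            r1 = r0 + window.height_w - 1
            c1 = c0 + window.width_w - 1
            rgb[r0, c0 : c1 + 1] = (255, 255, 0)
            rgb[r1, c0 : c1 + 1] = (255, 255, 0)
            rgb[r0 : r1 + 1, c0] = (255, 255, 0)
            rgb[r0 : r1 + 1, c1] = (255, 255, 0)
        iio.imwrite(out_dir / f"frame_{t:04d}.png", rgb)
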