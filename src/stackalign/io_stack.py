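"""Reading, writing and normalising time-lapse stacks.

A :class:`FrameStack` is the package's canonical in-memory container: a
``T x H x W`` float array of intensities normalised to ``[0, 1]``, plus
optional acquisition metadata (minutes per frame, microns per pixel).
Normalisation always divides by the *theoretical* maximum of the source
dtype (255 for 8-bit, 65535 for 16-bit), never the observed maximum, so
that genuine brightness drift between frames survives loading — flow
estimation is brightness sensitive and silently equalising frames would
bias it.
"""

from __future__ import annotations

import glob as _glob
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import ValidationError

__all__ = ["FrameStack", "load_stack", "save_stack", "export_trajectory", "load_trajectory"]

# Rec.601 luma weights; the conventional choice for camera greyscale export.
_LUMA = np.array([0.299, 0.587, 0.114])

_VIDEO_SUFFIXES = {".mp4", ".avi", ".mov", ".mkv", ".webm", ".wmv"}
_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass
class FrameStack:
    """Ordered sequence of equally shaped grayscale frames.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of intensities in ``[0, 1]``; stored as float32.
    frame_interval
        Minutes between consecutive frames, if known.
    pixel_size
        Microns per pixel, if known. Carried as metadata only.
    source
        Free-form provenance string.
    """

    frames: np.ndarray
    frame_interval: float | None = None
    pixel_size: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float32)
        if frames.ndim != 3:
            raise ValidationError(f"frames must be (T, H, W), got shape {frames.shape}")
        if frames.shape[0] < 2:
            raise ValidationError(f"a stack needs at least 2 frames, got {frames.shape[0]}")
        if not np.all(np.isfinite(frames)):
            raise ValidationError("frames contain non-finite values")
        if frames.min() < -1e-6 or frames.max() > 1 + 1e-6:
            raise ValidationError(
                f"intensities must lie in [0, 1]; observed range "
                f"[{frames.min():.4g}, {frames.max():.4g}]"
            )
        self.frames = np.clip(frames, 0.0, 1.0)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, t: int) -> np.ndarray:
        return self.frames[t]


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse a trailing colour axis with Rec.601 luma weights."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        return arr[..., :3].astype(np.float64) @ _LUMA
    raise ValidationError(f"cannot interpret frame of shape {arr.shape} as grayscale or RGB")


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1] by the dtype's full theoretical range."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    arr = arr.astype(np.float64)
    if arr.size and (arr.min() < -1e-6 or arr.max() > 1 + 1e-6):
        raise ValidationError(
            "float input must already be normalised to [0, 1]; "
            f"observed range [{arr.min():.4g}, {arr.max():.4g}]"
        )
    return arr


def _read_one(path: str) -> np.ndarray:
    try:
        if Path(path).suffix.lower() in {".tif", ".tiff"}:
            return tifffile.imread(path)
        return iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"could not read image file {path!r}: {exc}") from exc


def _frames_from_arrays(arrays: Sequence[np.ndarray]) -> np.ndarray:
    grays = []
    raw_norm = []
    for a in arrays:
        raw_norm.append(_normalize(np.asarray(a)))
    for a in raw_norm:
        grays.append(_to_gray(a))
    shapes = [g.shape for g in grays]
    ref_shape = shapes[0]
    bad = [i for i, s in enumerate(shapes) if s != ref_shape]
    if bad:
        raise ValidationError(
            f"frames {bad} have shape differing from frame 0 shape {ref_shape}"
        )
    return np.stack(grays)


def load_stack(
    path_or_glob: str | os.PathLike,
    frame_interval: float | None = None,
    pixel_size: float | None = None,
) -> FrameStack:
    """Load a time-lapse stack from a multi-page TIFF, an image-sequence
    glob pattern, or a video file.

    Frames are ordered by TIFF page, by lexicographic sort of the matched
    file names, or by decode order respectively. RGB input is converted to
    grayscale with Rec.601 weights; integer intensities are divided by the
    dtype's full range.
    """
    path = str(path_or_glob)
    if any(ch in path for ch in "*?["):
        files = sorted(_glob.glob(path))
        if not files:
            raise OSError(f"glob pattern {path!r} matched no files")
        frames = _frames_from_arrays([_read_one(f) for f in files])
        return FrameStack(frames, frame_interval, pixel_size, source=path)

    if not os.path.exists(path):
        raise OSError(f"no such file: {path!r}")

    suffix = Path(path).suffix.lower()
    if suffix in _VIDEO_SUFFIXES:
        try:
            raw = iio.imread(path)  # (T, H, W[, C])
        except Exception as exc:  # plugin/codec availability varies
            raise OSError(f"could not decode video {path!r}: {exc}") from exc
        arrays = list(raw)
    elif suffix in {".tif", ".tiff"}:
        raw = tifffile.imread(path)
        if raw.ndim == 2:
            arrays = [raw]
        else:
            arrays = list(raw)
    else:
        arrays = [_read_one(path)]

    if len(arrays) < 2:
        raise ValidationError(f"{path!r} holds {len(arrays)} frame(s); a stack needs >= 2")
    frames = _frames_from_arrays(arrays)
    return FrameStack(frames, frame_interval, pixel_size, source=path)


def save_stack(stack: FrameStack, path: str | os.PathLike, format: str = "tiff") -> None:
    """Write a stack as a float32 multi-page TIFF (lossless), an 8-bit PNG
    sequence (``path`` is treated as a directory), or a video file.
    """
    if not isinstance(stack, FrameStack):
        raise ValidationError("save_stack expects a FrameStack")
    path = str(path)
    if format == "tiff":
        _check_writable(Path(path).parent)
        tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    elif format == "png_sequence":
        outdir = Path(path)
        outdir.mkdir(parents=True, exist_ok=True)
        _check_writable(outdir)
        width = max(4, len(str(stack.n_frames)))
        for t in range(stack.n_frames):
            frame8 = np.round(stack.frames[t] * 255).astype(np.uint8)
            iio.imwrite(outdir / f"frame_{t:0{width}d}.png", frame8)
    elif format == "video":
        _check_writable(Path(path).parent)
        frames8 = np.round(stack.frames * 255).astype(np.uint8)
        try:
            iio.imwrite(path, frames8, fps=10)
        except Exception as exc:
            raise OSError(f"could not encode video {path!r}: {exc}") from exc
    else:
        raise ValidationError(f"unknown format {format!r}; use tiff, png_sequence or video")


def _check_writable(directory: Path) -> None:
    directory = directory if str(directory) else Path(".")
    if not directory.exists():
        raise OSError(f"directory {str(directory)!r} does not exist")
    if not os.access(directory, os.W_OK):
        raise OSError(f"directory {str(directory)!r} is not writable")


def export_trajectory(series, trajectory, path: str | os.PathLike) -> None:
    """Write per-step and cumulative displacements as a CSV table.

    Columns: ``frame, dx, dy, cum_dx, cum_dy`` — one row per frame; the
    per-step values of frame 0 are written as 0.
    """
    import pandas as pd

    steps = np.asarray(series.steps, dtype=float)
    cum = np.asarray(trajectory.cumulative, dtype=float)
    if cum.shape[0] != steps.shape[0] + 1:
        raise ValidationError(
            f"trajectory length {cum.shape[0]} != series length {steps.shape[0]} + 1"
        )
    padded = np.vstack([[0.0, 0.0], steps])
    df = pd.DataFrame(
        {
            "frame": np.arange(cum.shape[0]),
            "dx": padded[:, 0],
            "dy": padded[:, 1],
            "cum_dx": cum[:, 0],
            "cum_dy": cum[:, 1],
        }
    )
    df.to_csv(path, index=False)


def load_trajectory(path: str | os.PathLike):
    """Inverse of :func:`export_trajectory`; returns (series, trajectory)."""
    import pandas as pd

    from .registration import CorrectionTrajectory, TranslationSeries

    df = pd.read_csv(path)
    required = {"frame", "dx", "dy", "cum_dx", "cum_dy"}
    if not required.issubset(df.columns):
        raise ValidationError(f"trajectory table must have columns {sorted(required)}")
    steps = df[["dx", "dy"]].to_numpy()[1:]
    cum = df[["cum_dx", "cum_dy"]].to_numpy()
    return TranslationSeries(steps), CorrectionTrajectory(cum)
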