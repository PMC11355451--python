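"""Sub-pixel frame translation and canvas management (reframing).

After drift correction each frame carries a different residual footprint:
its valid pixels occupy a translated copy of the original field of view.
Four framing policies decide the output canvas:

``maximum``
    Union bounding box of all corrected footprints — keeps every valid
    pixel of every frame (no information loss at the edges).
``minimum``
    Intersection box — the region covered by *all* frames; contains no
    fill pixels by construction.
``center``
    A box of the original frame size centred on the mean corrected
    position.
``reference``
    The footprint of one designated frame; output dimensions equal the
    input dimensions.

Pixels outside a frame's footprint are filled, by default with that
frame's median brightness. Fractional canvas bounds are expanded outward
(floor/ceil) so no valid pixel is clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DegenerateFramingError, ValidationError
from .io_stack import FrameStack

__all__ = ["FramingSpec", "Canvas", "translate_frame", "compute_canvas", "reframe"]

_MODES = ("maximum", "minimum", "center", "reference")
_FILLS = ("median_brightness", "constant")


@dataclass
class FramingSpec:
    """Canvas policy for reframing a corrected stack."""

    mode: str = "maximum"
    reference_index: int = 0
    fill: str = "median_brightness"
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValidationError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.fill not in _FILLS:
            raise ValidationError(f"fill must be one of {_FILLS}, got {self.fill!r}")
        if self.reference_index < 0:
            raise ValidationError("reference_index must be non-negative")


@dataclass
class Canvas:
    """Output geometry: canvas size plus the per-frame translation that
    places each corrected frame onto it."""

    height: int
    width: int
    origin_offset: np.ndarray  # (T, 2) array of per-frame (dx, dy) placements

    def __post_init__(self) -> None:
        self.origin_offset = np.asarray(self.origin_offset, dtype=np.float64)
        if self.height < 1 or self.width < 1:
            raise ValidationError(f"degenerate canvas {self.height}x{self.width}")


def translate_frame(
    frame: np.ndarray,
    dx: float,
    dy: float,
    out_shape: tuple[int, int] | None = None,
    fill: float = 0.0,
) -> np.ndarray:
    """Translate a frame by ``(dx, dy)`` with bilinear interpolation.

    Output pixel ``(y, x)`` samples the input at ``(y - dy, x - dx)``;
    positions outside the input take the fill intensity. ``out_shape``
    defaults to the input shape.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValidationError("translate_frame expects a 2-D frame")
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ValidationError(f"shift must be finite, got ({dx}, {dy})")
    if out_shape is None:
        out_shape = frame.shape
    ys, xs = np.meshgrid(
        np.arange(out_shape[0], dtype=np.float64),
        np.arange(out_shape[1], dtype=np.float64),
        indexing="ij",
    )
    return map_coordinates(
        frame, [ys - dy, xs - dx], order=1, mode="constant", cval=float(fill)
    )


def _corrections(trajectory, spec: FramingSpec) -> np.ndarray:
    """Per-frame correction c(t): the translation applied to frame t.

    The trajectory is anchored at frame 0; reference mode re-offsets it so
    the designated frame stays put.
    """
    cum = np.asarray(trajectory.cumulative, dtype=np.float64)
    if spec.mode == "reference":
        if spec.reference_index >= cum.shape[0]:
            raise ValidationError(
                f"reference_index {spec.reference_index} out of range for T={cum.shape[0]}"
            )
        return cum[spec.reference_index] - cum
    return -cum


def compute_canvas(trajectory, frame_shape: tuple[int, int], spec: FramingSpec) -> Canvas:
    """Canvas geometry for a correction trajectory under a framing policy.

    Frame ``t`` occupies the box ``[c(t), c(t) + (W, H))`` in a global
    coordinate system, where ``c(t)`` is its correction. The canvas is the
    union of those boxes (maximum), their intersection (minimum), an
    original-size box centred on the mean position (center), or the
    designated frame's own box (reference).
    """
    H, W = int(frame_shape[0]), int(frame_shape[1])
    c = _corrections(trajectory, spec)  # (T, 2) as (dx, dy)
    cx, cy = c[:, 0], c[:, 1]

    if spec.mode == "maximum":
        x0, y0 = np.floor(cx.min()), np.floor(cy.min())
        width = int(np.ceil(cx.max()) - x0) + W
        height = int(np.ceil(cy.max()) - y0) + H
    elif spec.mode == "minimum":
        x0, y0 = np.ceil(cx.max()), np.ceil(cy.max())
        width = int(np.floor(cx.min()) + W - x0)
        height = int(np.floor(cy.min()) + H - y0)
        if width <= 0 or height <= 0:
            raise DegenerateFramingError(
                "no common overlap between corrected frames in minimum mode: "
                f"deficit {max(0, 1 - width)} px in x, {max(0, 1 - height)} px in y"
            )
    elif spec.mode == "center":
        x0 = np.round(cx.mean())
        y0 = np.round(cy.mean())
        width, height = W, H
    else:  # reference: canvas is the reference frame's own footprint
        x0, y0 = 0.0, 0.0
        width, height = W, H

    offsets = np.stack([cx - x0, cy - y0], axis=1)
    return Canvas(height=height, width=width, origin_offset=offsets)


def reframe(stack: FrameStack, trajectory, spec: FramingSpec | None = None) -> FrameStack:
    """Apply a correction trajectory to every frame and place the results
    on the canvas chosen by the framing policy.

    With ``fill='median_brightness'`` each frame's own median intensity
    fills its out-of-footprint pixels.
    """
    if spec is None:
        spec = FramingSpec()
    cum = np.asarray(trajectory.cumulative, dtype=np.float64)
    if cum.shape[0] != stack.n_frames:
        raise ValidationError(
            f"trajectory length {cum.shape[0]} != stack length {stack.n_frames}"
        )
    canvas = compute_canvas(trajectory, stack.frame_shape, spec)
    out = np.empty((stack.n_frames, canvas.height, canvas.width), dtype=np.float32)
    for t in range(stack.n_frames):
        frame = stack.frames[t]
        fill = (
            float(np.median(frame))
            if spec.fill == "median_brightness"
            else float(spec.fill_value)
        )
        dx, dy = canvas.origin_offset[t]
        warped = translate_frame(frame, dx, dy, (canvas.height, canvas.width), fill)
        out[t] = np.clip(warped, 0.0, 1.0)
    return FrameStack(
        out,
        frame_interval=stack.frame_interval,
        pixel_size=stack.pixel_size,
        source=f"{stack.source}|reframed:{spec.mode}",
    )
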