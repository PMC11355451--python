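"""Parametric stage-jitter synthesis for ground-truth benchmarks.

Multi-sample microscopes reposition the stage between every acquisition,
so consecutive frames of one sample carry a quasi-periodic lateral
offset. The synthesiser imitates that behaviour with a two-frequency
beat: the per-step displacement at frame t is

    delta(t) = A(t) * cos(omega1 * t) * cos(omega2 * t)   (per axis)

with A(t) drawn uniformly per axis and per step from [0, amplitude_max].
The defaults omega1 = 0.5 rad/frame, omega2 = 1.2 rad/frame and
amplitude_max = 120 px reproduce the beat-modulated jitter traces seen on
an uncompensated plate scanner (primary amplitude ~100 px with a weaker
underlying modulation). Applying the cumulative sum of delta to a stable
stack yields a displaced stack whose ground-truth trajectory is known
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_stack import FrameStack
from .registration import TranslationSeries, accumulate
from .warp import translate_frame

__all__ = ["JitterParams", "synthesize_displacements", "apply_jitter"]


@dataclass
class JitterParams:
    """Parameters of the synthetic stage-jitter model.

    omega1, omega2 : carrier and modulation frequencies, radians/frame.
    amplitude_max : upper bound of the uniform per-axis amplitude draw, px.
    seed : seed for the amplitude draws.
    """

    omega1: float = 0.5
    omega2: float = 1.2
    amplitude_max: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_max < 0:
            raise ValidationError(f"amplitude_max must be >= 0, got {self.amplitude_max}")


def synthesize_displacements(T: int, params: JitterParams | None = None) -> TranslationSeries:
    """Draw a per-step displacement series delta(t), t = 0 .. T-2.

    Deterministic given ``params.seed``; every |delta| component is
    bounded by ``amplitude_max``.
    """
    if params is None:
        params = JitterParams()
    if T < 2:
        raise ValidationError(f"need at least 2 frames, got T={T}")
    rng = np.random.default_rng(params.seed)
    t = np.arange(T - 1)
    amplitude = rng.uniform(0.0, params.amplitude_max, size=(T - 1, 2))
    envelope = np.cos(params.omega1 * t) * np.cos(params.omega2 * t)
    return TranslationSeries(amplitude * envelope[:, None])


def apply_jitter(
    stack: FrameStack,
    series: TranslationSeries,
    canvas_margin: int = 0,
) -> tuple[FrameStack, TranslationSeries]:
    """Displace a (stable) stack by the cumulative sum of a step series.

    Frame t is translated by ``cumsum(delta)[t]`` (frame 0 untouched) and
    placed on a canvas enlarged by ``canvas_margin`` pixels on every side,
    with out-of-footprint pixels filled by the frame's median brightness
    — so the ground truth is not destroyed at the borders. Returns the
    jittered stack and the ground-truth series.
    """
    if series.n_steps != stack.n_frames - 1:
        raise ValidationError(
            f"series has {series.n_steps} steps but stack has {stack.n_frames} frames"
        )
    if canvas_margin < 0:
        raise ValidationError("canvas_margin must be >= 0")
    cum = accumulate(series).cumulative
    required = int(np.ceil(np.abs(cum).max()))
    if required > canvas_margin:
        raise ValidationError(
            f"cumulative displacement reaches {np.abs(cum).max():.2f} px; "
            f"canvas_margin must be at least {required}"
        )
    H, W = stack.frame_shape
    m = int(canvas_margin)
    out = np.empty((stack.n_frames, H + 2 * m, W + 2 * m), dtype=np.float32)
    for t in range(stack.n_frames):
        frame = stack.frames[t]
        fill = float(np.median(frame))
        warped = translate_frame(
            frame, m + cum[t, 0], m + cum[t, 1], (H + 2 * m, W + 2 * m), fill
        )
        out[t] = np.clip(warped, 0.0, 1.0)
    jittered = FrameStack(
        out,
        frame_interval=stack.frame_interval,
        pixel_size=stack.pixel_size,
        source=f"{stack.source}|jittered",
    )
    return jittered, series
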