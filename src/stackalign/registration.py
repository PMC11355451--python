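"""From pairwise estimates to stack-level correction.

The stabilisation pipeline is: estimate the displacement between each
frame and its successor (nearest-neighbour series), accumulate those
steps into a per-frame drift trajectory, then warp every frame by the
negated cumulative displacement — one composed translation per frame,
never a chain of sequential warps, so interpolation blur is applied
exactly once.

For diagnostics the displacement can also be estimated between *every*
ordered frame pair, giving a T x T x 2 matrix whose structure reveals how
registration accuracy decays with temporal distance and whether a backend
is commutative (estimate(i,j) = -estimate(j,i)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backends import BackendConfig, estimate_pair
from .errors import StackAlignError, ValidationError
from .io_stack import FrameStack
from .warp import FramingSpec, reframe

__all__ = [
    "TranslationSeries",
    "CorrectionTrajectory",
    "PairwiseMatrix",
    "estimate_nn_series",
    "accumulate",
    "difference",
    "estimate_pairwise_matrix",
    "stabilize",
]


@dataclass
class TranslationSeries:
    """Per-step global displacements: ``steps[t]`` is the (dx, dy) of
    frame ``t+1`` relative to frame ``t``, in pixels."""

    steps: np.ndarray

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps, dtype=np.float64)
        if steps.ndim != 2 or steps.shape[1] != 2:
            raise ValidationError(f"steps must be (T-1, 2), got shape {steps.shape}")
        if steps.shape[0] < 1:
            raise ValidationError("series must hold at least one step")
        if not np.all(np.isfinite(steps)):
            raise ValidationError("series contains non-finite entries")
        self.steps = steps

    @property
    def n_steps(self) -> int:
        return self.steps.shape[0]


@dataclass
class CorrectionTrajectory:
    """Cumulative displacement per frame, anchored at frame 0.

    ``cumulative[0] = (0, 0)`` exactly; differencing recovers the step
    series without rounding.
    """

    cumulative: np.ndarray

    def __post_init__(self) -> None:
        cum = np.asarray(self.cumulative, dtype=np.float64)
        if cum.ndim != 2 or cum.shape[1] != 2:
            raise ValidationError(f"cumulative must be (T, 2), got shape {cum.shape}")
        if cum.shape[0] < 2:
            raise ValidationError("trajectory must cover at least 2 frames")
        if not np.allclose(cum[0], 0.0):
            raise ValidationError(f"trajectory must start at (0, 0), got {cum[0]}")
        if not np.all(np.isfinite(cum)):
            raise ValidationError("trajectory contains non-finite entries")
        self.cumulative = cum

    @property
    def n_frames(self) -> int:
        return self.cumulative.shape[0]


@dataclass
class PairwiseMatrix:
    """All-pairs displacement estimates: ``dmat[i, j]`` is the (dx, dy)
    of frame j relative to frame i. Unevaluated pairs are NaN."""

    dmat: np.ndarray

    def __post_init__(self) -> None:
        dmat = np.asarray(self.dmat, dtype=np.float64)
        if dmat.ndim != 3 or dmat.shape[0] != dmat.shape[1] or dmat.shape[2] != 2:
            raise ValidationError(f"dmat must be (T, T, 2), got shape {dmat.shape}")
        self.dmat = dmat

    @property
    def n_frames(self) -> int:
        return self.dmat.shape[0]


def estimate_nn_series(stack: FrameStack, config: BackendConfig | None = None) -> TranslationSeries:
    """Estimate the displacement between each consecutive frame pair."""
    if config is None:
        config = BackendConfig()
    steps = np.empty((stack.n_frames - 1, 2))
    for t in range(stack.n_frames - 1):
        try:
            steps[t] = estimate_pair(stack.frames[t], stack.frames[t + 1], config)
        except StackAlignError as exc:
            raise type(exc)(f"frame pair ({t}, {t + 1}): {exc}") from exc
    return TranslationSeries(steps)


def accumulate(series: TranslationSeries) -> CorrectionTrajectory:
    """Prefix-sum of the step series with a leading (0, 0); exact
    floating-point arithmetic, no rounding."""
    cum = np.vstack([[0.0, 0.0], np.cumsum(series.steps, axis=0)])
    return CorrectionTrajectory(cum)


def difference(trajectory: CorrectionTrajectory) -> TranslationSeries:
    """Inverse of :func:`accumulate`: first differences of the cumulative
    trajectory."""
    return TranslationSeries(np.diff(trajectory.cumulative, axis=0))


def _pair_budget(n: int, max_pairs: int | None):
    """Ordered off-diagonal pairs to evaluate. With a budget, unordered
    pairs are subsampled by a deterministic stride over a (distance, i)
    ordering — keeping coverage across frame distances — and both orders
    of each kept pair are evaluated (needed for commutativity checks)."""
    unordered = [(i, j) for d in range(1, n) for i in range(n - d) for j in (i + d,)]
    if max_pairs is not None:
        keep = max(1, max_pairs // 2)
        if len(unordered) > keep:
            stride = int(np.ceil(len(unordered) / keep))
            unordered = unordered[::stride]
    for i, j in unordered:
        yield i, j
        yield j, i


def estimate_pairwise_matrix(
    stack: FrameStack,
    config: BackendConfig | None = None,
    max_pairs: int | None = None,
) -> PairwiseMatrix:
    """Estimate the displacement for every ordered frame pair (optionally
    a deterministic subsample of ``max_pairs`` ordered pairs).

    The diagonal is (0, 0) by construction. Both orders (i, j) and
    (j, i) are evaluated independently so estimator asymmetry is
    observable. Skipped pairs hold NaN.
    """
    if config is None:
        config = BackendConfig()
    n = stack.n_frames
    dmat = np.full((n, n, 2), np.nan)
    dmat[np.arange(n), np.arange(n)] = 0.0
    for i, j in _pair_budget(n, max_pairs):
        try:
            dmat[i, j] = estimate_pair(stack.frames[i], stack.frames[j], config)
        except StackAlignError as exc:
            raise type(exc)(f"frame pair ({i}, {j}): {exc}") from exc
    return PairwiseMatrix(dmat)


def stabilize(
    stack: FrameStack,
    config: BackendConfig | None = None,
    framing: FramingSpec | None = None,
) -> tuple[FrameStack, TranslationSeries, CorrectionTrajectory]:
    """Full pipeline: estimate the NN series, accumulate it, and warp each
    frame by its negated cumulative displacement under the chosen framing.

    Returns the corrected stack together with the series and trajectory
    used, so they can be exported or inspected.
    """
    if config is None:
        config = BackendConfig()
    if framing is None:
        framing = FramingSpec()
    series = estimate_nn_series(stack, config)
    trajectory = accumulate(series)
    corrected = reframe(stack, trajectory, framing)
    return corrected, series, trajectory
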