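"""Benchmark analyses: error dispersion, coherence vs frame distance,
commutativity, and free-parameter sweeps.

All summaries are pure functions of the raw error samples, which are kept
alongside them — every number in a report can be recomputed from the
stored samples, and deterministic backends reproduce reports bit-for-bit
under identical seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .backends import BackendConfig
from .errors import ValidationError
from .registration import (
    CorrectionTrajectory,
    PairwiseMatrix,
    TranslationSeries,
    estimate_nn_series,
)

__all__ = [
    "offset_errors",
    "dispersion_summary",
    "coherence_curve",
    "asymmetry_statistics",
    "parameter_sweep",
]

_AXES = ("x", "y")


def _raw(obj) -> np.ndarray:
    if isinstance(obj, TranslationSeries):
        return obj.steps
    if isinstance(obj, CorrectionTrajectory):
        return obj.cumulative
    if isinstance(obj, PairwiseMatrix):
        return obj.dmat
    return np.asarray(obj, dtype=np.float64)


def offset_errors(estimated, truth) -> np.ndarray:
    """Signed per-entry estimation error (estimated - truth), per axis.

    Accepts a pair of TranslationSeries, CorrectionTrajectory,
    PairwiseMatrix or plain arrays of matching shape; entries that are
    NaN in either operand stay NaN.
    """
    est, tru = _raw(estimated), _raw(truth)
    if est.shape != tru.shape:
        raise ValidationError(f"shape mismatch: {est.shape} vs {tru.shape}")
    return est - tru


def dispersion_summary(samples) -> pd.DataFrame:
    """Order statistics (median, quartiles, max) of absolute errors per
    axis.

    ``samples`` is any array whose last dimension is 2 (x, y) — or a 1-D
    array treated as a single unnamed axis. NaN entries are ignored.
    """
    arr = _raw(samples)
    if arr.size == 0:
        raise ValidationError("empty samples")
    if arr.ndim == 1:
        arr = arr[:, None]
        axes = ("value",)
    else:
        arr = arr.reshape(-1, arr.shape[-1])
        axes = _AXES if arr.shape[-1] == 2 else tuple(str(i) for i in range(arr.shape[-1]))
    rows = []
    for k, axis in enumerate(axes):
        col = np.abs(arr[:, k])
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise ValidationError(f"axis {axis} holds no finite samples")
        q1, med, q3 = np.percentile(col, [25, 50, 75])
        rows.append(
            {"axis": axis, "median": med, "q1": q1, "q3": q3, "max": col.max(), "n": col.size}
        )
    return pd.DataFrame(rows)


def coherence_curve(dmat_error: np.ndarray) -> pd.DataFrame:
    """Mean absolute pairwise error as a function of frame distance.

    ``dmat_error`` is a (T, T, 2) array of signed errors (NaN where a
    pair was not evaluated). Forward (j > i) and reverse (j < i) frame
    orders are aggregated separately, per axis, exposing estimator
    asymmetry: a strictly commutative estimator yields identical forward
    and reverse curves.
    """
    err = np.asarray(dmat_error, dtype=np.float64)
    if err.ndim != 3 or err.shape[0] != err.shape[1] or err.shape[2] != 2:
        raise ValidationError(f"expected (T, T, 2) errors, got shape {err.shape}")
    n = err.shape[0]
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    rows = []
    for direction, sel in (("forward", jj > ii), ("reverse", jj < ii)):
        dist = np.abs(jj - ii)[sel]
        for k, axis in enumerate(_AXES):
            vals = np.abs(err[..., k])[sel]
            ok = np.isfinite(vals)
            for d in np.unique(dist[ok]):
                pick = ok & (dist == d)
                rows.append(
                    {
                        "distance": int(d),
                        "direction": direction,
                        "axis": axis,
                        "mae": float(vals[pick].mean()),
                        "n": int(pick.sum()),
                    }
                )
    return pd.DataFrame(rows)


def asymmetry_statistics(dmat: PairwiseMatrix) -> pd.DataFrame:
    """Commutativity diagnostic: magnitudes of dmat[i,j] + dmat[j,i] for
    every evaluated unordered pair (exactly zero for a perfectly
    anti-symmetric estimator)."""
    m = dmat.dmat
    n = m.shape[0]
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            s = m[i, j] + m[j, i]
            if np.all(np.isfinite(s)):
                rows.append(
                    {"i": i, "j": j, "distance": j - i, "asym_x": s[0], "asym_y": s[1],
                     "asym_mag": float(np.hypot(*s))}
                )
    if not rows:
        raise ValidationError("no evaluated (i, j)/(j, i) pairs in matrix")
    return pd.DataFrame(rows)


def parameter_sweep(
    stack,
    truth: TranslationSeries,
    method: str,
    grid,
    config: BackendConfig | None = None,
) -> pd.DataFrame:
    """Sweep the selected backend's free parameter over ``grid`` and
    summarise the NN estimation error at each value.

    The swept parameter is the one the method consults: upsample factor
    for ``pcc``, window radius for ``lucas_kanade``, refinement
    iterations for ``deep_flow``. A grid point whose run fails is kept in
    the table with ``failed=True`` rather than aborting the sweep.
    Output is tidy: one row per grid value x axis x statistic set.
    """
    grid = list(grid)
    if not grid:
        raise ValidationError("parameter grid is empty")
    base = config if config is not None else BackendConfig()
    param_name = {"pcc": "upsample_factor", "lucas_kanade": "radius", "deep_flow": "iterations"}
    if method not in param_name:
        raise ValidationError(f"unknown method {method!r}")
    rows = []
    for value in grid:
        try:
            cfg = replace(base, method=method, **{param_name[method]: int(value)})
            est = estimate_nn_series(stack, cfg)
        except Exception as exc:
            rows.append(
                {"parameter": param_name[method], "value": value, "axis": "both",
                 "median": np.nan, "q1": np.nan, "q3": np.nan, "max": np.nan,
                 "n": 0, "failed": True, "error": str(exc)}
            )
            continue
        summary = dispersion_summary(offset_errors(est, truth))
        for _, rec in summary.iterrows():
            rows.append(
                {"parameter": param_name[method], "value": value, "axis": rec["axis"],
                 "median": rec["median"], "q1": rec["q1"], "q3": rec["q3"],
                 "max": rec["max"], "n": rec["n"], "failed": False, "error": ""}
            )
    return pd.DataFrame(rows)
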