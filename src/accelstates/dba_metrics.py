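"""Static/dynamic decomposition and the six dynamic-body-acceleration metrics.

Static (gravity/posture) acceleration is estimated per axis with a centred
running median (a running mean is available for sensitivity checks); the
dynamic remainder drives six summary metrics per trailing sampling window:

======== =======================================================
TODBA    sum over the window of per-sample ODBA
TVeDBA   sum of per-sample VeDBA (Euclidean norm of dynamics)
dODBA    sum of the combined consecutive-sample differences
dVeDBA   sum of Euclidean norms of consecutive-sample differences
SDODBA   standard deviation of per-sample ODBA
SDVeDBA  standard deviation of per-sample VeDBA
======== =======================================================

Two conventions exist in the literature for combining the three axes into
ODBA-type quantities: ``sum_of_abs`` (|Xd|+|Yd|+|Zd|, the standard ODBA) and
``abs_of_sum`` (|Xd+Yd+Zd|).  Both are implemented; defaults follow
:class:`MetricConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from accelstates.core_io import (
    AccelTrace,
    Ethogram,
    ValidationError,
    state_habitat,
    state_motion,
)

#: Fixed metric order; also the tie-break preference order during metric
#: selection (delta metrics first).
METRIC_NAMES: tuple[str, ...] = (
    "dODBA",
    "dVeDBA",
    "TODBA",
    "TVeDBA",
    "SDODBA",
    "SDVeDBA",
)

Convention = Literal["sum_of_abs", "abs_of_sum"]


def window_samples(window_seconds: float, frequency: float) -> int:
    """Convert a duration to an odd sample count (>= 3) for the smoother."""
    n = int(round(window_seconds * frequency))
    if n % 2 == 0:
        n += 1
    return max(n, 3)


@dataclass(frozen=True)
class DynamicTrace:
    """Per-sample dynamic components after removing the running median."""

    parent: AccelTrace
    smoothing_window: float  # seconds
    xd: np.ndarray
    yd: np.ndarray
    zd: np.ndarray

    def __len__(self) -> int:
        return len(self.xd)


@dataclass(frozen=True)
class MetricConfig:
    """Windowing and convention choices for metric computation.

    sampling_window is wall-clock seconds (default 10, matching the shortest
    mean natural activity-bout duration); its sample count shrinks at lower
    sampling frequencies and must stay >= 2 samples.
    """

    sampling_window: float = 10.0
    stride: int = 1
    odba_convention: Convention = "sum_of_abs"
    delta_convention: Convention = "abs_of_sum"
    sd_denominator: Literal["n-1", "n"] = "n-1"

    @property
    def ddof(self) -> int:
        return 1 if self.sd_denominator == "n-1" else 0


def decompose(
    trace: AccelTrace,
    window: float,
    method: Literal["median", "mean"] = "median",
) -> DynamicTrace:
    """Split raw acceleration into static + dynamic via a running smoother.

    ``window`` (seconds) must convert to an odd sample count >= 3 and not
    exceed the trace length.  At the edges the smoother uses the truncated
    in-bounds part of the window, so no samples are lost.
    """
    w = int(round(window * trace.sampling_frequency))
    if w % 2 == 0 or w < 3:
        raise ValidationError(
            f"smoothing window must be an odd sample count >= 3 (got {w} samples)"
        )
    if w > len(trace):
        raise ValidationError(
            f"smoothing window of {w} samples exceeds trace length {len(trace)}"
        )
    out = []
    for raw in (trace.ax, trace.ay, trace.az):
        s = pd.Series(raw).rolling(window=w, center=True, min_periods=1)
        static = s.median() if method == "median" else s.mean()
        out.append(raw - static.to_numpy())
    return DynamicTrace(
        parent=trace, smoothing_window=window, xd=out[0], yd=out[1], zd=out[2]
    )


def per_sample_odba(dyn: DynamicTrace, convention: Convention = "sum_of_abs") -> np.ndarray:
    if convention == "sum_of_abs":
        return np.abs(dyn.xd) + np.abs(dyn.yd) + np.abs(dyn.zd)
    return np.abs(dyn.xd + dyn.yd + dyn.zd)


def per_sample_vedba(dyn: DynamicTrace) -> np.ndarray:
    return np.sqrt(dyn.xd**2 + dyn.yd**2 + dyn.zd**2)


def _window_starts_deployment(n: int, nwin: int, stride: int) -> list[int]:
    return list(range(0, n - nwin + 1, stride))


def _window_starts_training(
    timestamps: np.ndarray, bouts: Ethogram, nwin: int, stride: int, period: float
) -> list[tuple[int, str]]:
    """Trailing-window start indices fully inside one bout, with its state."""
    starts: list[tuple[int, str]] = []
    for b in bouts:
        # sample indices whose timestamp lies in [start, end)
        i0 = int(np.searchsorted(timestamps, b.start - 1e-9, side="left"))
        i1 = int(np.searchsorted(timestamps, b.end - 1e-9, side="left"))
        for s in range(i0, i1 - nwin + 1, stride):
            starts.append((s, b.state))
    return starts


def compute_metrics(
    dyn: DynamicTrace,
    config: MetricConfig | None = None,
    bouts: Ethogram | None = None,
) -> pd.DataFrame:
    """Compute the six DBA metrics per trailing sampling window.

    Returns a DataFrame with one row per window: ``t_end`` (timestamp of the
    window's last sample), the six metrics, ``water`` (median sensor reading
    over the window) and, when ``bouts`` is given (training mode, windows
    restricted to lie inside one bout), ``state_true`` / ``habitat_true`` /
    ``motion_true`` labels.  Without ``bouts`` windows slide over the whole
    trace (deployment mode).
    """
    config = config or MetricConfig()
    trace = dyn.parent
    f = trace.sampling_frequency
    nwin = int(round(config.sampling_window * f))
    if nwin < 2:
        raise ValidationError(
            f"sampling window of {config.sampling_window} s contains {nwin} "
            f"sample(s) at {f} Hz; lengthen the window or raise the frequency"
        )
    o = per_sample_odba(dyn, config.odba_convention)
    v = per_sample_vedba(dyn)
    dx = np.diff(dyn.xd)
    dy = np.diff(dyn.yd)
    dz = np.diff(dyn.zd)
    if config.delta_convention == "sum_of_abs":
        do = np.abs(dx) + np.abs(dy) + np.abs(dz)
    else:
        do = np.abs(dx + dy + dz)
    dv = np.sqrt(dx**2 + dy**2 + dz**2)

    if bouts is not None:
        starts = _window_starts_training(
            trace.timestamps, bouts, nwin, config.stride, trace.sample_period
        )
    else:
        starts = [(s, None) for s in _window_starts_deployment(len(dyn), nwin, config.stride)]

    rows = []
    for s, state in starts:
        sl = slice(s, s + nwin)
        dsl = slice(s, s + nwin - 1)  # consecutive pairs within the window
        ow = o[sl]
        vw = v[sl]
        rec = {
            "t_end": trace.timestamps[s + nwin - 1],
            "TODBA": float(ow.sum()),
            "TVeDBA": float(vw.sum()),
            "dODBA": float(do[dsl].sum()),
            "dVeDBA": float(dv[dsl].sum()),
            "SDODBA": float(np.std(ow, ddof=config.ddof)),
            "SDVeDBA": float(np.std(vw, ddof=config.ddof)),
            "water": float(np.median(trace.water[sl])),
        }
        if state is not None:
            rec["state_true"] = state
            rec["habitat_true"] = state_habitat(state)
            rec["motion_true"] = state_motion(state)
        rows.append(rec)
    cols = ["t_end", *METRIC_NAMES, "water"]
    if bouts is not None:
        cols += ["state_true", "habitat_true", "motion_true"]
    # keep the canonical column order even when no window fits
    return pd.DataFrame(rows, columns=cols)


def metric_correlations(windows: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pairwise Pearson correlations between the six metrics.

    Returns the symmetric 6x6 matrix (unit diagonal; NaN rows/columns for
    zero-variance metrics) and the mean of the defined off-diagonal upper
    triangle.
    """
    if len(windows) < 3:
        raise ValidationError("need at least 3 windows for correlations")
    sub = windows[list(METRIC_NAMES)]
    corr = sub.corr()  # pandas leaves zero-variance columns as NaN
    np.fill_diagonal(corr.values, 1.0)
    iu = np.triu_indices(len(METRIC_NAMES), k=1)
    upper = corr.to_numpy()[iu]
    defined = upper[~np.isnan(upper)]
    mean_r = float(defined.mean()) if defined.size else math.nan
    return corr, mean_r
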