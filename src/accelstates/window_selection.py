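"""Smoothing-window sensitivity analysis.

Too short a static-estimation window leaks locomotor signal into the static
component and underestimates dynamic acceleration; too long a window wastes
edge data and blurs posture changes.  The procedure scans candidate running-
median durations, computes mean per-sample ODBA over a habitat's in-motion
samples for each, and picks the shortest window whose mean ODBA is within
95% of the scan maximum *and* statistically comparable (paired two-tailed
t-test) to the next-longer candidate.  One window per habitat; the final
per-dataset window is the longer of the two habitat selections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from accelstates.core_io import (
    AccelTrace,
    Ethogram,
    ValidationError,
    state_habitat,
    state_motion,
)
from accelstates.dba_metrics import Convention, decompose, per_sample_odba

#: Default candidate grid: odd durations 3, 5, ..., 131 s.
DEFAULT_CANDIDATES: tuple[int, ...] = tuple(range(3, 132, 2))


def paired_t(a, b) -> tuple[float, float]:
    """Classical paired two-tailed t-test on matched samples.

    Returns ``(t, p)``.  Degenerate inputs: if every difference is exactly 0
    the samples are indistinguishable and p is defined as 1; zero-variance
    differences with a nonzero mean have no finite t statistic and raise
    :class:`ValidationError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("paired_t requires two equal-length 1-d samples, n >= 2")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0:
        raise ValidationError("zero-variance nonzero differences: t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class WindowScanResult:
    """Mean/SD ODBA per candidate window plus the per-sample curves.

    ``odba_samples[i]`` holds candidate i's per-sample ODBA restricted to the
    habitat's in-motion samples (the paired units for the t-test guard).
    """

    habitat: str
    candidates: tuple[int, ...]
    mean_odba: np.ndarray
    sd_odba: np.ndarray
    odba_samples: np.ndarray  # shape (len(candidates), n_samples)

    @property
    def argmax_window(self) -> int:
        return self.candidates[int(np.argmax(self.mean_odba))]


def scan_windows(
    trace: AccelTrace,
    ethogram: Ethogram,
    habitat: str,
    candidates=DEFAULT_CANDIDATES,
    odba_convention: Convention = "sum_of_abs",
    method: str = "median",
) -> WindowScanResult:
    """Per candidate smoothing window, mean and SD of in-motion ODBA.

    Restricts to samples labelled ``<habitat>-in-motion`` by the ethogram
    (censor bouts first if desired); raises if the habitat has no in-motion
    data.
    """
    labels = ethogram.label_samples(trace.timestamps)
    mask = np.array(
        [
            bool(s) and state_habitat(s) == habitat and state_motion(s) == "in-motion"
            for s in labels
        ]
    )
    if not mask.any():
        raise ValidationError(f"no in-motion samples for habitat {habitat!r}")
    cands = tuple(int(c) if float(c).is_integer() else float(c) for c in candidates)
    # the odd constraint applies to the window's sample count, which equals
    # whole seconds only at 1 Hz
    f = trace.sampling_frequency
    if any(int(round(c * f)) % 2 == 0 for c in cands):
        raise ValidationError("candidate windows must hold an odd sample count")
    means, sds, curves = [], [], []
    for w in cands:
        dyn = decompose(trace, w, method=method)
        o = per_sample_odba(dyn, odba_convention)[mask]
        means.append(float(o.mean()))
        sds.append(float(o.std(ddof=1)) if len(o) > 1 else 0.0)
        curves.append(o)
    return WindowScanResult(
        habitat=habitat,
        candidates=cands,
        mean_odba=np.array(means),
        sd_odba=np.array(sds),
        odba_samples=np.array(curves),
    )


def select_window(scan: WindowScanResult, alpha: float = 0.05) -> int:
    """Apply the 95%-of-maximum rule with the paired t-test guard.

    Eligible candidates have mean ODBA >= 0.95 x the scan maximum.  Walking
    the eligible set from shortest to longest, a candidate is selected if its
    per-sample ODBA does not differ from the next-longer candidate's (paired
    two-tailed t, p >= alpha); the longest candidate passes trivially.  If
    every consecutive test is significant the argmax candidate is returned.
    """
    cands = scan.candidates
    if len(cands) == 1:
        return cands[0]
    m = scan.mean_odba
    cutoff = 0.95 * m.max()
    for i, w in enumerate(cands):
        if m[i] < cutoff:
            continue
        if i == len(cands) - 1:
            return w
        try:
            _, p = paired_t(scan.odba_samples[i], scan.odba_samples[i + 1])
        except ValidationError:
            continue
        if p >= alpha:
            return w
    return scan.argmax_window


def select_final_window(*selections: int) -> int:
    """Per-dataset window = the longest of the per-habitat selections."""
    if not selections:
        raise ValidationError("no habitat selections given")
    return max(selections)
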