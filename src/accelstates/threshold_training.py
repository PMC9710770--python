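"""Threshold training: split, histogram separation, and the threshold scan.

The classifier is deliberately simple — one motion threshold per habitat on
a single DBA metric.  Training is: (1) stratified 70/30 split of labelled
metric windows, (2) choose the metric whose class histograms overlap least
(percent overlap = shared area of the two within-class histograms), and
(3) scan candidate thresholds on a fixed grid (0.1 increments) over the
overlap region, scoring sensitivity/specificity/accuracy, keeping the
candidate where all three are jointly highest (accuracy first, then
sensitivity+specificity, then the smaller, more conservative threshold).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from accelstates.core_io import HABITATS, STATES, ValidationError
from accelstates.dba_metrics import METRIC_NAMES


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split parameters."""

    train_fraction: float = 0.70
    random_seed: int = 0
    stratify_by: str = "state_true"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must be in (0, 1)")


def stratified_split(
    windows: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split labelled windows so each state keeps a similar class ratio.

    Per state, ``round(n_state x train_fraction)`` windows (half-up) are
    sampled without replacement into the training set; the remainder test.
    Deterministic for a fixed seed.
    """
    spec = spec or SplitSpec()
    col = spec.stratify_by
    if col not in windows.columns or windows[col].isna().any():
        raise ValidationError("every window must carry a state label")
    rng = np.random.default_rng(spec.random_seed)
    train_idx: list[np.ndarray] = []
    for state, grp in windows.groupby(col, sort=True):
        n = len(grp)
        if n < 2:
            raise ValidationError(f"state {state!r} has fewer than 2 windows")
        n_train = int(math.floor(n * spec.train_fraction + 0.5))
        n_train = min(max(n_train, 1), n - 1)  # both halves non-empty
        pick = rng.choice(grp.index.to_numpy(), size=n_train, replace=False)
        train_idx.append(pick)
    chosen = np.concatenate(train_idx)
    train = windows.loc[np.sort(chosen)]
    test = windows.drop(index=chosen)
    return train, test


def percent_overlap(values_a, values_b, bin_width: float = 0.1) -> float:
    """Shared area (%) of two within-sample histograms on aligned bins.

    Bins have width ``bin_width``, edges at integer multiples of it, and
    span the pooled range; overlap = 100 x sum over bins of
    min(p_a, p_b) with p the within-sample bin proportions.  100 for
    identical samples, 0 for supports separated by more than one bin.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    lo = math.floor(min(a.min(), b.min()) / bin_width) * bin_width
    hi = math.ceil(max(a.max(), b.max()) / bin_width) * bin_width
    if hi <= lo + 1e-12:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(100.0 * np.minimum(pa / a.size, pb / b.size).sum())


def overlap_report(
    train: pd.DataFrame, bin_width: float = 0.1
) -> dict[str, dict[str, float]]:
    """Percent overlap of every metric for each habitat's motion pairing.

    Returns ``{habitat: {metric: overlap%}}`` comparing in-motion vs
    motionless windows within that habitat.
    """
    report: dict[str, dict[str, float]] = {}
    for habitat in HABITATS:
        sub = train[train["habitat_true"] == habitat]
        moving = sub[sub["motion_true"] == "in-motion"]
        still = sub[sub["motion_true"] == "motionless"]
        if moving.empty or still.empty:
            raise ValidationError(f"missing a motion class for habitat {habitat!r}")
        report[habitat] = {
            m: percent_overlap(still[m], moving[m], bin_width) for m in METRIC_NAMES
        }
    return report


def select_metric(report: Mapping[str, Mapping[str, float]]) -> str:
    """Metric minimising the worst-case (max over habitats) overlap.

    Ties break by the fixed metric preference order (delta metrics first).
    """
    best, best_key = None, None
    for rank, m in enumerate(METRIC_NAMES):
        worst = max(report[h][m] for h in report)
        key = (worst, rank)
        if best_key is None or key < best_key:
            best, best_key = m, key
    return best


def _grid(lo: float, hi: float, increment: float) -> np.ndarray:
    """Multiples of ``increment`` within [lo, hi] (fp-safe)."""
    k0 = math.ceil(round(lo / increment, 9))
    k1 = math.floor(round(hi / increment, 9))
    return np.round(np.arange(k0, k1 + 1) * increment, 9)


def threshold_scan(
    values,
    is_moving,
    increment: float = 0.1,
) -> tuple[float, pd.DataFrame]:
    """Scan candidate motion thresholds on the metric value.

    The decision rule is strict: predict in-motion iff value > theta.
    Candidates are the multiples of ``increment`` covering the two classes'
    overlap region extended one increment each way; when the supports are
    disjoint, candidates lie strictly inside the gap.  Per candidate the
    scan records sensitivity (in-motion positive), specificity and accuracy;
    the returned theta maximises accuracy, breaking ties by the larger
    sensitivity+specificity sum and then the smaller (more conservative)
    threshold.

    Returns ``(theta, curves)`` where ``curves`` has one row per candidate.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(is_moving, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValidationError("values and labels must be equal-length 1-d")
    if not y.any() or y.all():
        raise ValidationError("both motion classes must be present")
    still, moving = v[~y], v[y]
    lo = max(still.min(), moving.min())
    hi = min(still.max(), moving.max())
    if lo <= hi:  # overlapping supports
        grid = _grid(lo - increment, hi + increment, increment)
    else:  # disjoint: candidates strictly inside the gap
        gap_lo, gap_hi = hi, lo
        grid = _grid(gap_lo, gap_hi, increment)
        grid = grid[(grid > gap_lo + 1e-12) & (grid < gap_hi - 1e-12)]
        if grid.size == 0:
            grid = np.array([round((gap_lo + gap_hi) / 2 / increment) * increment])
    rows = []
    for theta in grid:
        pred = v > theta
        tp = int(np.sum(pred & y))
        tn = int(np.sum(~pred & ~y))
        fp = int(np.sum(pred & ~y))
        fn = int(np.sum(~pred & y))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        acc = (tp + tn) / len(v)
        rows.append(
            {"theta": float(theta), "sensitivity": sens, "specificity": spec, "accuracy": acc}
        )
    curves = pd.DataFrame(rows)
    order = sorted(
        range(len(curves)),
        key=lambda i: (
            -curves.accuracy[i],
            -(curves.sensitivity[i] + curves.specificity[i]),
            curves.theta[i],
        ),
    )
    return float(curves.theta[order[0]]), curves


@dataclass
class ThresholdModel:
    """Fitted two-step classifier.

    Step 1 separates motion from motionless with a per-habitat threshold on
    one DBA metric (strict: value > theta -> in-motion); Step 2 separates
    habitats with the water-sensor threshold (reading > threshold -> aquatic).
    """

    smoothing_window: float
    metric_name: str
    theta_terrestrial: float
    theta_aquatic: float
    water_threshold: float = 500.0
    scan_curves: dict = field(default_factory=dict, repr=False)
    provenance: dict = field(default_factory=dict, repr=False)

    def theta(self, habitat: str) -> float:
        if habitat == "terrestrial":
            return self.theta_terrestrial
        if habitat == "aquatic":
            return self.theta_aquatic
        raise ValidationError(f"unknown habitat {habitat!r}")

    def save(self, path) -> None:
        """Persist as a plain-text key=value file."""
        lines = [
            f"smoothing_window={self.smoothing_window!r}",
            f"metric_name={self.metric_name}",
            f"theta_terrestrial={self.theta_terrestrial!r}",
            f"theta_aquatic={self.theta_aquatic!r}",
            f"water_threshold={self.water_threshold!r}",
        ]
        for k, val in sorted(self.provenance.items()):
            lines.append(f"provenance.{k}={val}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "ThresholdModel":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and "=" in line:
                    k, _, val = line.partition("=")
                    kv[k] = val
        prov = {
            k.split(".", 1)[1]: v for k, v in kv.items() if k.startswith("provenance.")
        }
        return cls(
            smoothing_window=float(kv["smoothing_window"]),
            metric_name=kv["metric_name"],
            theta_terrestrial=float(kv["theta_terrestrial"]),
            theta_aquatic=float(kv["theta_aquatic"]),
            water_threshold=float(kv["water_threshold"]),
            provenance=prov,
        )


def fit(
    train: pd.DataFrame,
    smoothing_window: float,
    metric: str | None = None,
    water_threshold: float = 500.0,
    increment: float = 0.1,
) -> ThresholdModel:
    """Fit per-habitat motion thresholds on labelled training windows.

    ``metric=None`` selects the metric by minimal worst-case histogram
    overlap first.  Requires all four states in the training set.
    """
    present = set(train.get("state_true", pd.Series(dtype=object)).dropna())
    missing = set(STATES) - present
    if missing:
        raise ValidationError(f"training set missing states: {sorted(missing)}")
    if metric is None:
        metric = select_metric(overlap_report(train, bin_width=increment))
    if metric not in METRIC_NAMES:
        raise ValidationError(f"unknown metric {metric!r}")
    curves = {}
    thetas = {}
    for habitat in HABITATS:
        sub = train[train["habitat_true"] == habitat]
        theta, c = threshold_scan(
            sub[metric].to_numpy(),
            (sub["motion_true"] == "in-motion").to_numpy(),
            increment=increment,
        )
        thetas[habitat] = theta
        curves[habitat] = c
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(train[list(METRIC_NAMES)], index=False).to_numpy().tobytes()
    ).hexdigest()[:16]
    return ThresholdModel(
        smoothing_window=smoothing_window,
        metric_name=metric,
        theta_terrestrial=thetas["terrestrial"],
        theta_aquatic=thetas["aquatic"],
        water_threshold=water_threshold,
        scan_curves=curves,
        provenance={"train_digest": digest, "n_train": str(len(train))},
    )
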