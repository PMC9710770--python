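"""Two-step decision-tree classification and performance evaluation.

Step 2 (habitat) uses the water sensor: readings strictly above the water
threshold are aquatic, readings at or below it terrestrial.  Step 1
(motion) compares the model's DBA metric against the habitat's threshold
with a strict inequality (value > theta -> in-motion; a value exactly at
the threshold is motionless).  Evaluation produces the 4x4 confusion
matrix (predicted rows x observed columns), one-vs-rest sensitivity and
specificity per state, and overall accuracy with an exact (Clopper-
Pearson) binomial confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from accelstates.core_io import (
    HABITATS,
    STATES,
    ValidationError,
    compose_state,
)
from accelstates.threshold_training import ThresholdModel


def classify_window(window, model: ThresholdModel) -> dict:
    """Classify one metric window (a mapping/Series with the model's metric
    and ``water``); returns a prediction record."""
    try:
        value = float(window[model.metric_name])
        water = float(window["water"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"window lacks a usable metric/water value: {exc}")
    if np.isnan(value) or np.isnan(water):
        raise ValidationError("window has NaN metric or water value")
    habitat = "aquatic" if water > model.water_threshold else "terrestrial"
    motion = "in-motion" if value > model.theta(habitat) else "motionless"
    rec = {
        "t_end": window.get("t_end") if hasattr(window, "get") else None,
        "habitat_pred": habitat,
        "motion_pred": motion,
        "state_pred": compose_state(habitat, motion),
    }
    if hasattr(window, "get") and window.get("state_true") is not None:
        rec["state_true"] = window["state_true"]
    return rec


def classify_step1(window, model: ThresholdModel, habitat_known: str) -> str:
    """Motion label with the habitat supplied externally (accelerometer-only
    evaluation)."""
    if habitat_known not in HABITATS:
        raise ValidationError(f"unknown habitat {habitat_known!r}")
    value = float(window[model.metric_name])
    return "in-motion" if value > model.theta(habitat_known) else "motionless"


def classify(windows: pd.DataFrame, model: ThresholdModel) -> pd.DataFrame:
    """Vectorised two-step classification of a metric table."""
    if model.metric_name not in windows.columns or "water" not in windows.columns:
        raise ValidationError(
            f"metric table must contain {model.metric_name!r} and 'water'"
        )
    value = windows[model.metric_name].to_numpy(dtype=float)
    water = windows["water"].to_numpy(dtype=float)
    if np.isnan(value).any() or np.isnan(water).any():
        raise ValidationError("metric table contains NaN metric or water values")
    aquatic = water > model.water_threshold
    theta = np.where(aquatic, model.theta_aquatic, model.theta_terrestrial)
    moving = value > theta
    out = pd.DataFrame(
        {
            "habitat_pred": np.where(aquatic, "aquatic", "terrestrial"),
            "motion_pred": np.where(moving, "in-motion", "motionless"),
        },
        index=windows.index,
    )
    out["state_pred"] = out["habitat_pred"] + "-" + out["motion_pred"]
    if "t_end" in windows.columns:
        out.insert(0, "t_end", windows["t_end"])
    if "state_true" in windows.columns:
        out["state_true"] = windows["state_true"]
    return out


def accuracy_ci(correct: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial CI for an accuracy, in percent."""
    if n < 1 or not 0 <= correct <= n:
        raise ValidationError(f"invalid counts: {correct}/{n}")
    lo, hi = proportion_confint(correct, n, alpha=1 - level, method="beta")
    return float(lo * 100.0), float(hi * 100.0)


@dataclass
class PerformanceReport:
    """4x4 confusion matrix with per-class and overall performance.

    ``confusion`` rows are predicted states, columns observed states, both
    in the canonical order of :data:`accelstates.core_io.STATES`.
    Sensitivity/specificity are one-vs-rest percentages; overall accuracy
    carries an exact binomial 95% CI.
    """

    confusion: pd.DataFrame
    sensitivity: dict
    specificity: dict
    accuracy: float
    ci95: tuple[float, float]
    n: int
    tags: dict | None = None

    def to_text(self) -> str:
        lines = ["Confusion matrix (rows: predicted, columns: observed)", ""]
        lines.append(self.confusion.to_string())
        lines.append("")
        for s in self.confusion.columns:
            lines.append(
                f"{s:>24}:  sensitivity {self.sensitivity[s]:5.1f}%   "
                f"specificity {self.specificity[s]:5.1f}%"
            )
        lines.append(
            f"\nOverall accuracy: {self.accuracy:.1f}% "
            f"(95% CI: {self.ci95[0]:.1f}, {self.ci95[1]:.1f}%)  n={self.n}"
        )
        return "\n".join(lines)


def evaluate(
    predictions: pd.DataFrame,
    states: Sequence[str] = STATES,
    tags: dict | None = None,
) -> PerformanceReport:
    """Score predictions against their true labels.

    ``predictions`` must carry ``state_pred`` and ``state_true``.  Per-class
    TP/FP/TN/FN come one-vs-rest from the 4x4 matrix; overall accuracy is
    the diagonal fraction with a Clopper-Pearson 95% CI.
    """
    if predictions.empty:
        raise ValidationError("no predictions to evaluate")
    if "state_true" not in predictions.columns or predictions["state_true"].isna().any():
        raise ValidationError("every prediction must carry a true state")
    counts = np.zeros((len(states), len(states)), dtype=int)
    idx = {s: i for i, s in enumerate(states)}
    for pred, true in zip(predictions["state_pred"], predictions["state_true"]):
        counts[idx[pred], idx[true]] += 1
    confusion = pd.DataFrame(counts, index=list(states), columns=list(states))
    return evaluate_confusion(confusion, tags=tags)


def evaluate_confusion(
    confusion: pd.DataFrame, tags: dict | None = None
) -> PerformanceReport:
    """Build a :class:`PerformanceReport` from a predicted x observed matrix."""
    counts = confusion.to_numpy()
    n = int(counts.sum())
    if n == 0:
        raise ValidationError("empty confusion matrix")
    correct = int(np.trace(counts))
    sens, spec = {}, {}
    for i, s in enumerate(confusion.columns):
        tp = counts[i, i]
        fn = counts[:, i].sum() - tp
        fp = counts[i, :].sum() - tp
        tn = n - tp - fn - fp
        sens[s] = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        spec[s] = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    accuracy = 100.0 * correct / n
    return PerformanceReport(
        confusion=confusion,
        sensitivity=sens,
        specificity=spec,
        accuracy=accuracy,
        ci95=accuracy_ci(correct, n),
        n=n,
        tags=tags,
    )


def cross_apply(
    model_a: ThresholdModel, windows_b: pd.DataFrame, tags: dict | None = None
) -> PerformanceReport:
    """Apply one population's fitted model to another's labelled windows."""
    preds = classify(windows_b, model_a)
    merged = dict(tags or {})
    merged.setdefault("model", model_a.provenance.get("train_digest", ""))
    return evaluate(preds, tags=merged)
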