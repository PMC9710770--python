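"""Data model, logger/annotation readers and the censoring preprocessing.

The central containers are :class:`AccelTrace` (one individual's uniformly
sampled tri-axial acceleration plus water-sensor channel) and
:class:`Ethogram` (its labelled activity bouts).  Bout intervals are
half-open ``[start, end)`` in seconds; a sample belongs to a bout iff its
timestamp falls in that interval, which gives unambiguous per-second
labelling at 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical state labels, in the display order used by performance reports
#: (aquatic-motionless, terrestrial-motionless, aquatic-in-motion,
#: terrestrial-in-motion).
STATES: tuple[str, ...] = (
    "aquatic-motionless",
    "terrestrial-motionless",
    "aquatic-in-motion",
    "terrestrial-in-motion",
)

HABITATS: tuple[str, str] = ("terrestrial", "aquatic")
MOTIONS: tuple[str, str] = ("motionless", "in-motion")

#: Accepted spelling variants, folded to canonical labels after lowercasing
#: and normalising separators.  Extendable through config.
_STATE_SYNONYMS: dict[str, str] = {
    "aquatic-motionless": "aquatic-motionless",
    "aquatic-in-motion": "aquatic-in-motion",
    "aquatic-inmotion": "aquatic-in-motion",
    "terrestrial-motionless": "terrestrial-motionless",
    "terrestrial-in-motion": "terrestrial-in-motion",
    "terrestrial-inmotion": "terrestrial-in-motion",
}


class ConfigurationError(ValueError):
    """A required column or configuration entry is missing."""


class FormatError(ValueError):
    """Input file violates the expected layout (e.g. non-uniform spacing)."""


class ValidationError(ValueError):
    """Input values violate a domain invariant."""


def normalize_state(label: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Fold a state label to its canonical form.

    Lowercases, converts spaces/underscores to hyphens, then looks the result
    up in the synonym table.  Raises :class:`ValidationError` for unknown
    labels, listing the allowed ones.
    """
    key = str(label).strip().lower().replace(" ", "-").replace("_", "-")
    table = dict(_STATE_SYNONYMS)
    if synonyms:
        table.update({k.lower(): v for k, v in synonyms.items()})
    try:
        return table[key]
    except KeyError:
        raise ValidationError(
            f"unknown state label {label!r}; allowed: {', '.join(STATES)}"
        ) from None


def state_habitat(state: str) -> str:
    """'terrestrial' or 'aquatic' component of a canonical state label."""
    return state.split("-", 1)[0]


def state_motion(state: str) -> str:
    """'motionless' or 'in-motion' component of a canonical state label."""
    return state.split("-", 1)[1]


def compose_state(habitat: str, motion: str) -> str:
    return f"{habitat}-{motion}"


@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled tri-axial acceleration + water channel.

    Parameters
    ----------
    individual_id, species_label
        Identity metadata carried through the pipeline.
    sampling_frequency
        Hz, > 0.
    timestamps
        Seconds, strictly increasing with uniform spacing ``1/f``.
    ax, ay, az
        Acceleration per sample in g-force (surge, sway, heave).
    water
        Water-conductivity sensor reading per sample, device units
        (10-bit loggers report 0-1023; values are not clipped here).
    clip_g
        Sensor clip range in g; channels are validated against it.
    """

    individual_id: str
    species_label: str
    sampling_frequency: float
    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    water: np.ndarray
    clip_g: float = 2.0

    def __post_init__(self) -> None:
        if self.sampling_frequency <= 0:
            raise ValidationError("sampling_frequency must be > 0")
        arrays = {}
        for name in ("timestamps", "ax", "ay", "az", "water"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arrays[name] = arr
            object.__setattr__(self, name, arr)
        n = len(arrays["timestamps"])
        for name, arr in arrays.items():
            if arr.ndim != 1 or len(arr) != n:
                raise ValidationError(f"channel {name} length mismatch")
        if n >= 2:
            period = 1.0 / self.sampling_frequency
            dt = np.diff(arrays["timestamps"])
            bad = np.nonzero(np.abs(dt - period) > 1e-6 * period)[0]
            if bad.size:
                raise FormatError(
                    f"non-uniform timestamp spacing at index {int(bad[0]) + 1}: "
                    f"dt={dt[bad[0]]!r}, expected {period!r}"
                )
        for name in ("ax", "ay", "az"):
            if n and np.nanmax(np.abs(arrays[name])) > self.clip_g + 1e-12:
                raise ValidationError(
                    f"|{name}| exceeds clip range {self.clip_g} g"
                )
        if n and np.nanmin(arrays["water"]) < 0:
            raise ValidationError("water channel must be non-negative")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def sample_period(self) -> float:
        return 1.0 / self.sampling_frequency

    @property
    def duration(self) -> float:
        return len(self) * self.sample_period

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "ax": self.ax,
                "ay": self.ay,
                "az": self.az,
                "water": self.water,
            }
        )


@dataclass(frozen=True)
class BoutAnnotation:
    """One labelled activity interval ``[start, end)`` in seconds."""

    individual_id: str
    state: str
    start: float
    end: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "state", normalize_state(self.state))
        if not self.end > self.start:
            raise ValidationError(
                f"bout end must exceed start (got [{self.start}, {self.end}))"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def habitat(self) -> str:
        return state_habitat(self.state)

    @property
    def motion(self) -> str:
        return state_motion(self.state)


@dataclass(frozen=True)
class Ethogram:
    """Ordered, non-overlapping bouts for one individual; gaps allowed.

    ``censored`` marks output of :func:`censor_bouts`; the trim models
    annotation-edge sync uncertainty, so re-censoring an already-censored
    ethogram is a no-op.
    """

    bouts: tuple[BoutAnnotation, ...] = field(default_factory=tuple)
    censored: bool = False

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.bouts, key=lambda b: (b.start, b.end)))
        for i in range(1, len(ordered)):
            prev, cur = ordered[i - 1], ordered[i]
            if cur.start < prev.end - 1e-12:
                raise ValidationError(
                    f"overlapping bouts: [{prev.start}, {prev.end}) "
                    f"({prev.state}) and [{cur.start}, {cur.end}) ({cur.state})"
                )
        object.__setattr__(self, "bouts", ordered)

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self) -> Iterator[BoutAnnotation]:
        return iter(self.bouts)

    @property
    def total_duration(self) -> float:
        return float(sum(b.duration for b in self.bouts))

    def states_present(self) -> set[str]:
        return {b.state for b in self.bouts}

    def label_samples(self, timestamps: np.ndarray) -> np.ndarray:
        """State label per timestamp ('' where unannotated)."""
        t = np.asarray(timestamps, dtype=float)
        out = np.full(len(t), "", dtype=object)
        for b in self.bouts:
            out[(t >= b.start) & (t < b.end)] = b.state
        return out


@dataclass
class LoadReport:
    """Summary of one file-ingestion call."""

    path: str
    rows_read: int
    rows_dropped: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        noun = "row" if self.rows_dropped == 1 else "rows"
        return f"{self.path}: {self.rows_read} rows read, {self.rows_dropped} {noun} dropped"


DEFAULT_COLUMN_MAP = {
    "timestamp": "timestamp",
    "ax": "ax",
    "ay": "ay",
    "az": "az",
    "water": "water",
}


def read_accel_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    sampling_frequency: float = 1.0,
    individual_id: str = "",
    species_label: str = "",
    clip_g: float = 2.0,
) -> tuple[AccelTrace, LoadReport]:
    """Read a logger export into an :class:`AccelTrace`.

    ``column_map`` maps canonical channel names (timestamp, ax, ay, az,
    water) to the file's column headers; logger exports vary.  Timestamps
    may be epoch/relative seconds or ISO-8601 datetimes (converted to epoch
    seconds).  Rows with unparseable values in any mapped column are dropped
    and counted in the returned :class:`LoadReport`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    for canon, col in cmap.items():
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} (for {canon!r}) not found in {path}"
            )
    raw_n = len(df)
    ts = pd.to_numeric(df[cmap["timestamp"]], errors="coerce")
    if ts.isna().any():
        # fall back to datetime parsing (ISO-8601 exports) -> epoch seconds
        ts_dt = pd.to_datetime(df[cmap["timestamp"]], errors="coerce", utc=True)
        epoch = ts_dt.map(lambda d: d.timestamp() if pd.notna(d) else np.nan)
        ts = ts.fillna(epoch)
    cols = {"timestamp": ts}
    for canon in ("ax", "ay", "az", "water"):
        cols[canon] = pd.to_numeric(df[cmap[canon]], errors="coerce")
    parsed = pd.DataFrame(cols)
    keep = parsed.dropna()
    report = LoadReport(path=str(path), rows_read=raw_n, rows_dropped=raw_n - len(keep))
    trace = AccelTrace(
        individual_id=individual_id,
        species_label=species_label,
        sampling_frequency=sampling_frequency,
        timestamps=keep["timestamp"].to_numpy(),
        ax=keep["ax"].to_numpy(),
        ay=keep["ay"].to_numpy(),
        az=keep["az"].to_numpy(),
        water=keep["water"].to_numpy(),
        clip_g=clip_g,
    )
    return trace, report


def read_annotations(
    path,
    synonyms: Mapping[str, str] | None = None,
) -> Ethogram:
    """Read behaviour annotations (individual, state, start, end) to an Ethogram.

    State labels are case-folded to the four canonical categories; rows with
    unknown labels or ``end <= start`` raise :class:`ValidationError`, and
    overlapping bouts are rejected by the Ethogram invariant.
    """
    df = pd.read_csv(path)
    required = {"individual_id", "state", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"annotation file missing columns: {sorted(missing)}")
    bouts = [
        BoutAnnotation(
            individual_id=str(row.individual_id),
            state=normalize_state(row.state, synonyms),
            start=float(row.start),
            end=float(row.end),
        )
        for row in df.itertuples()
    ]
    return Ethogram(tuple(bouts))


def write_annotations_csv(ethogram: Ethogram, path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": b.individual_id,
                "state": b.state,
                "start": b.start,
                "end": b.end,
            }
            for b in ethogram
        ],
        columns=["individual_id", "state", "start", "end"],
    ).to_csv(path, index=False)


def apply_time_offset(ethogram: Ethogram, offset: float) -> Ethogram:
    """Shift every bout by ``offset`` seconds (video-to-logger sync)."""
    return Ethogram(
        tuple(
            replace(b, start=b.start + offset, end=b.end + offset)
            for b in ethogram
        ),
        censored=ethogram.censored,
    )


def censor_bouts(ethogram: Ethogram, sample_period: float = 1.0) -> Ethogram:
    """Drop sync-uncertain bout edges: remove bouts < 2 s, trim the rest.

    Bouts shorter than ``2 * sample_period`` are removed outright; surviving
    bouts lose one sample period at each end (the first and last annotated
    second, at 1 Hz), and any bout whose trimmed duration is <= 0 is removed.
    Expressing the trim in sample periods keeps the rule meaningful after
    rarefaction to lower sampling frequencies.  Idempotent: an already-
    censored ethogram is returned unchanged (the trim models annotation-edge
    uncertainty, which trimmed bouts no longer carry).
    """
    if ethogram.censored:
        return ethogram
    kept = []
    for b in ethogram:
        if b.duration < 2 * sample_period - 1e-12:
            continue
        start, end = b.start + sample_period, b.end - sample_period
        if end - start > 1e-12:
            kept.append(replace(b, start=start, end=end))
    return Ethogram(tuple(kept), censored=True)
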