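"""Synthetic labelled four-state traces for calibration and testing.

Emulates what a carapace-mounted 1 Hz logger records from a slow-moving
semi-aquatic animal: per state, a gravity/posture vector plus (for
in-motion states) a slow locomotor sinusoid on the surge axis, Gaussian
sensor noise, and a bimodal water-conductivity channel that sits below the
habitat threshold on land and above it in water.  Bout durations follow a
geometric (discretised exponential) distribution, giving the alternating
bout structure the threshold classifier assumes.

The default preset is the package's reference study condition: gravity
(0, 0, 1) g on land and a tilted, re-normalised (0.3, 0, 0.95) in water;
locomotion amplitude 0.25 g with a 3.7 s stroke period; sensor noise
0.02 g; water channel mean 100 (terrestrial) / 800 (aquatic) device units
with SD 20; mean bout duration 60 s for every state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from accelstates.core_io import (
    STATES,
    AccelTrace,
    BoutAnnotation,
    Ethogram,
    ValidationError,
)


def _unit(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(a))
    return tuple(a / n) if n else tuple(a)


@dataclass(frozen=True)
class StateSignature:
    """Per-state generative parameters.

    dynamic_amplitude is the half peak-to-peak amplitude (g) of the surge
    sinusoid; it is 0 for motionless states.  water_mean/water_sd are in
    device units on the logger's 0-1023 scale.
    """

    state: str
    gravity_vector: tuple[float, float, float] = (0.0, 0.0, 1.0)
    dynamic_amplitude: float = 0.0
    dynamic_period: float = 3.7
    noise_sd: float = 0.02
    water_mean: float = 100.0
    water_sd: float = 20.0
    mean_bout_duration: float = 60.0

    def __post_init__(self) -> None:
        if self.dynamic_amplitude < 0 or self.noise_sd < 0:
            raise ValidationError("amplitudes and noise_sd must be >= 0")
        if self.dynamic_period <= 0:
            raise ValidationError("dynamic_period must be > 0")


DEFAULT_SIGNATURES: dict[str, StateSignature] = {
    "terrestrial-motionless": StateSignature(
        state="terrestrial-motionless",
        gravity_vector=(0.0, 0.0, 1.0),
        water_mean=100.0,
    ),
    "terrestrial-in-motion": StateSignature(
        state="terrestrial-in-motion",
        gravity_vector=(0.0, 0.0, 1.0),
        dynamic_amplitude=0.25,
        dynamic_period=3.7,
        water_mean=100.0,
    ),
    "aquatic-motionless": StateSignature(
        state="aquatic-motionless",
        gravity_vector=_unit((0.3, 0.0, 0.95)),
        water_mean=800.0,
    ),
    "aquatic-in-motion": StateSignature(
        state="aquatic-in-motion",
        gravity_vector=_unit((0.3, 0.0, 0.95)),
        dynamic_amplitude=0.25,
        dynamic_period=3.7,
        water_mean=800.0,
    ),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition bundle for one simulated individual."""

    signatures: Mapping[str, StateSignature] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURES)
    )
    sampling_frequency: float = 1.0
    total_duration: float = 7200.0
    random_seed: int = 0
    individual_id: str = "sim-01"
    species_label: str = "synthetic"
    #: relative weight of each state when drawing the next bout's state;
    #: a state with weight 0 never occurs.
    state_weights: Mapping[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in STATES}
    )

    def __post_init__(self) -> None:
        missing = set(STATES) - set(self.signatures)
        if missing:
            raise ValidationError(f"signatures missing for states: {sorted(missing)}")
        longest = max(s.mean_bout_duration for s in self.signatures.values())
        if self.total_duration < 10 * longest:
            raise ValidationError(
                "total_duration must be >= 10 x the longest mean bout duration"
            )


def simulate_state_sequence(config: SimulationConfig) -> Ethogram:
    """Draw an alternating bout sequence covering total_duration exactly.

    Bout durations are geometric in whole sample periods with the state's
    mean; the next state is drawn among the *other* states proportionally to
    ``state_weights``.  Deterministic for a fixed ``random_seed``.
    """
    rng = np.random.default_rng(config.random_seed)
    period = 1.0 / config.sampling_frequency
    for sig in config.signatures.values():
        if sig.mean_bout_duration <= period:
            raise ValidationError(
                f"mean bout duration for {sig.state} must exceed one sample period"
            )
    weights = {s: float(config.state_weights.get(s, 0.0)) for s in STATES}
    active = [s for s in STATES if weights[s] > 0]
    if not active:
        raise ValidationError("all state weights are zero")

    def draw_state(exclude: str | None) -> str:
        pool = [s for s in active if s != exclude] or active
        w = np.array([weights[s] for s in pool])
        return pool[rng.choice(len(pool), p=w / w.sum())]

    bouts: list[BoutAnnotation] = []
    t, prev = 0.0, None
    while t < config.total_duration - 1e-9:
        state = draw_state(prev)
        mean_samples = config.signatures[state].mean_bout_duration / period
        dur = rng.geometric(1.0 / mean_samples) * period
        dur = min(dur, config.total_duration - t)
        bouts.append(
            BoutAnnotation(
                individual_id=config.individual_id,
                state=state,
                start=t,
                end=t + dur,
            )
        )
        t += dur
        prev = state
    return Ethogram(tuple(bouts))


def synthesize_trace(ethogram: Ethogram, config: SimulationConfig) -> AccelTrace:
    """Render an ethogram into logger channels.

    Per sample: acceleration = gravity vector + locomotor sinusoid (surge
    axis, random phase per bout) + isotropic Gaussian noise; water channel =
    Gaussian around the state's mean, clipped at 0.  Uses a seed derived
    from the config's, so sequence and trace draws are independent streams.
    """
    rng = np.random.default_rng((config.random_seed, 1))
    f = config.sampling_frequency
    n = int(round(config.total_duration * f))
    t = np.arange(n) / f
    ax = np.zeros(n)
    ay = np.zeros(n)
    az = np.zeros(n)
    water = np.zeros(n)
    for bout in ethogram:
        sig = config.signatures[bout.state]
        idx = (t >= bout.start) & (t < bout.end)
        m = int(idx.sum())
        if m == 0:
            continue
        gx, gy, gz = sig.gravity_vector
        dyn = np.zeros(m)
        # amplitude 0 encodes stillness; a small nonzero amplitude on a
        # motionless state emulates passive motion (waves, currents)
        if sig.dynamic_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            dyn = sig.dynamic_amplitude * np.sin(
                2 * np.pi * (t[idx] - bout.start) / sig.dynamic_period + phase
            )
        noise = rng.normal(0.0, sig.noise_sd, size=(m, 3)) if sig.noise_sd else np.zeros((m, 3))
        ax[idx] = gx + dyn + noise[:, 0]
        ay[idx] = gy + noise[:, 1]
        az[idx] = gz + noise[:, 2]
        w = rng.normal(sig.water_mean, sig.water_sd, size=m) if sig.water_sd else np.full(m, sig.water_mean)
        water[idx] = np.clip(w, 0.0, None)
    clip = max(2.0, float(np.max(np.abs(np.concatenate([ax, ay, az]))) if n else 2.0))
    return AccelTrace(
        individual_id=config.individual_id,
        species_label=config.species_label,
        sampling_frequency=f,
        timestamps=t,
        ax=ax,
        ay=ay,
        az=az,
        water=water,
        clip_g=clip,
    )


def simulate(config: SimulationConfig) -> tuple[AccelTrace, Ethogram]:
    """Convenience: sequence + trace in one call."""
    eth = simulate_state_sequence(config)
    return synthesize_trace(eth, config), eth


def write_logger_csv(trace: AccelTrace, path) -> None:
    """Write the canonical comma-separated logger dialect (round-trips
    bit-identically through :func:`accelstates.core_io.read_accel_csv`)."""
    df = trace.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
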