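"""Scalar descriptors of simulated contractions.

Twitch timing follows standard electrophysiology practice: contraction time
(CT) is measured from the stimulus to the peak of active force and
half-relaxation time (HRT) from the peak to the first 50%-of-peak crossing
on the decay limb.  Peak time/value are refined by a three-point parabolic
fit and the half crossing by linear interpolation, so both are sub-sample
accurate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .params import MuscleParams
from .simulate import (
    ContractionRecord,
    brief_tetanus,
    simulate_fixed_end,
    train,
    twitch,
)

__all__ = [
    "TwitchMetrics",
    "ForceFrequencyCurve",
    "twitch_metrics",
    "twitch_metrics_from_series",
    "simulate_twitch_metrics",
    "steady_train_force",
    "force_frequency_curve",
    "summation_ratio",
]


@dataclass(frozen=True)
class TwitchMetrics:
    peak_force: float
    contraction_time_ms: float
    half_relaxation_time_ms: float

    def __post_init__(self) -> None:
        if min(self.peak_force, self.contraction_time_ms,
               self.half_relaxation_time_ms) <= 0:
            raise ValueError("twitch metrics must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "peak_force": self.peak_force,
            "contraction_time_ms": self.contraction_time_ms,
            "half_relaxation_time_ms": self.half_relaxation_time_ms,
        }


def _refine_peak(t: np.ndarray, f: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic refinement of the peak at grid index ``i``."""
    if i == 0 or i == len(f) - 1:
        return float(t[i]), float(f[i])
    y0, y1, y2 = f[i - 1], f[i], f[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(t[i]), float(f[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = t[i + 1] - t[i]
    t_pk = float(t[i] + delta * dt)
    f_pk = float(y1 - 0.25 * (y0 - y2) * delta)
    return t_pk, f_pk


def twitch_metrics_from_series(
    t: Sequence[float],
    force: Sequence[float],
    stim_time: float = 0.0,
) -> TwitchMetrics:
    """Twitch metrics for a single force transient sampled at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    f = np.asarray(force, dtype=float)
    if t.size != f.size or t.size < 3:
        raise ValueError("need matching time/force series of length >= 3")
    i_pk = int(np.argmax(f))
    t_pk, f_pk = _refine_peak(t, f, i_pk)
    if f_pk <= 0:
        raise ValueError("waveform has no positive peak")
    half = 0.5 * f_pk
    below = np.nonzero(f[i_pk:] <= half)[0]
    if below.size == 0:
        raise ValueError(
            "force never decays below half of peak; record too short"
        )
    j = i_pk + below[0]
    if j == i_pk:
        t_half = t_pk
    else:
        # linear interpolation of the crossing between samples j-1 and j
        f0, f1 = f[j - 1], f[j]
        t_half = t[j - 1] + (f0 - half) / (f0 - f1) * (t[j] - t[j - 1])
    return TwitchMetrics(
        peak_force=f_pk,
        contraction_time_ms=(t_pk - stim_time) * 1e3,
        half_relaxation_time_ms=(t_half - t_pk) * 1e3,
    )


def twitch_metrics(record: ContractionRecord) -> TwitchMetrics:
    """Metrics of a simulated twitch (single transient of active force)."""
    if record.protocol.n_pulses == 0:
        raise ValueError("record contains no stimulus")
    stim = record.protocol.pulse_times[0]
    return twitch_metrics_from_series(record.t, record.active_force, stim)


def simulate_twitch_metrics(
    params: MuscleParams,
    initial_l_ce: float = 1.23,
    release_scale: float = 1.0,
    dt: float = 1e-4,
    duration: float = 1.0,
) -> TwitchMetrics:
    """Convenience wrapper: simulate a twitch and summarise it."""
    rec = simulate_fixed_end(
        params, twitch(params, duration), initial_l_ce, release_scale, dt
    )
    return twitch_metrics(rec)


@dataclass(frozen=True)
class ForceFrequencyCurve:
    frequencies: np.ndarray
    steady_force: np.ndarray          # normalised mean force, final period
    peak_force: np.ndarray            # normalised peak force, final period
    reference_force: float            # absolute force used for normalisation

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "force_rel_P0": self.steady_force,
                "peak_force_rel_P0": self.peak_force,
            }
        ).to_csv(path, index=False)


def steady_train_force(
    params: MuscleParams,
    frequency: float,
    release_scale: float = 1.0,
    initial_l_ce: float = 1.23,
    dt: float = 1e-4,
    min_duration: float = 1.0,
    max_duration: float = 5.0,
    tol: float = 0.005,
) -> tuple[float, float]:
    """Mean and peak active force over the final interpulse period.

    Trains start at ``min_duration`` seconds and are extended (doubling, up
    to ``max_duration``) until the mean force over the last two complete
    periods changes by less than ``tol`` relative.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    T = 1.0 / frequency
    duration = max(min_duration, 3.0 * T)
    while True:
        n_periods = int(np.floor(duration / T))
        duration = n_periods * T
        rec = simulate_fixed_end(
            params,
            train(params, frequency, duration=duration - 0.5 * T,
                  record_duration=duration),
            initial_l_ce,
            release_scale,
            dt,
        )
        f = rec.active_force
        t = rec.t
        last = (t >= duration - T - 0.5 * dt)
        prev = (t >= duration - 2 * T - 0.5 * dt) & (t < duration - T - 0.5 * dt)
        mean_last = float(np.mean(f[last]))
        mean_prev = float(np.mean(f[prev]))
        scale = max(abs(mean_last), 1e-12)
        if abs(mean_last - mean_prev) / scale < tol:
            return mean_last, float(np.max(f[last]))
        if duration >= max_duration:
            raise RuntimeError(
                f"steady state not reached within {max_duration} s at "
                f"{frequency} Hz"
            )
        duration = min(2.0 * duration, max_duration)


def force_frequency_curve(
    params: MuscleParams,
    frequencies: Sequence[float],
    release_scale: float = 1.0,
    initial_l_ce: float = 1.23,
    dt: float = 1e-4,
    reference_force: float | None = None,
    reference_frequency: float = 200.0,
    train_duration: float = 1.0,
) -> ForceFrequencyCurve:
    """Steady force versus stimulation frequency.

    Forces are normalised to ``reference_force``; by default that is the
    steady force of *these* parameters at ``reference_frequency`` (200 Hz),
    so pass the control-condition maximum explicitly to express scenario
    curves relative to the control P0.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0 or np.any(freqs <= 0) or np.any(np.diff(freqs) <= 0):
        raise ValueError("frequencies must be positive and strictly increasing")
    if reference_force is None:
        reference_force, _ = steady_train_force(
            params, reference_frequency, release_scale, initial_l_ce, dt,
            min_duration=train_duration,
        )
    means = np.empty(freqs.size)
    peaks = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        means[i], peaks[i] = steady_train_force(
            params, f, release_scale, initial_l_ce, dt,
            min_duration=train_duration,
        )
    return ForceFrequencyCurve(
        freqs, means / reference_force, peaks / reference_force,
        reference_force,
    )


def summation_ratio(
    params: MuscleParams,
    release_scale: float = 1.0,
    initial_l_ce: float = 1.23,
    dt: float = 1e-4,
) -> float:
    """Peak force of a brief tetanus (50 ms, 100 Hz) over twitch peak force."""
    rec_tw = simulate_fixed_end(
        params, twitch(params), initial_l_ce, release_scale, dt
    )
    peak_tw = rec_tw.peak_active_force
    if peak_tw <= 0:
        raise ValueError("twitch produced no force; ratio undefined")
    rec_tet = simulate_fixed_end(
        params, brief_tetanus(params), initial_l_ce, release_scale, dt
    )
    return rec_tet.peak_active_force / peak_tw
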