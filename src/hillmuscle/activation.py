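"""Single-compartment activator (Ca2+) kinetics.

Each stimulus opens a release window of duration ``pulse_width`` during
which da/dt = (1 - a)/tau1; outside release windows the activator is removed
with da/dt = -a/tau2.  Both phases are linear, so the trace is propagated
analytically between event boundaries; the sampling step only controls the
output grid.

Release for closely spaced stimuli is attenuated ("inactivation of
release"): the effective release window of pulse i >= 2 is
``pulse_width * (1 - (1 - A) exp(-isi/r))`` where ``isi`` is the interval to
the immediately preceding pulse, ``A`` the minimum relative release reached
at vanishing isi and ``r`` the recovery time constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mechanics import activation_from_activator
from .params import MuscleParams

__all__ = [
    "StimulationProtocol",
    "ActivatorTrace",
    "relative_release",
    "build_release_schedule",
    "simulate_activator",
    "steady_state_activator",
]


@dataclass(frozen=True)
class StimulationProtocol:
    """Ordered stimulus times with per-pulse effective release widths (s)."""

    pulse_times: tuple
    effective_widths: tuple
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.pulse_times, dtype=float)
        w = np.asarray(self.effective_widths, dtype=float)
        if t.size != w.size:
            raise ValueError("pulse_times and effective_widths differ in length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("pulse times must be non-negative and strictly increasing")
        if np.any(w <= 0):
            raise ValueError("effective release widths must be positive")
        if self.duration <= (t[-1] if t.size else 0.0):
            raise ValueError("duration must extend beyond the last pulse")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_times)

    def release_windows(self) -> list[tuple[float, float]]:
        """(on, off) release intervals, truncated at the next stimulus."""
        t = list(self.pulse_times)
        out = []
        for i, (ti, wi) in enumerate(zip(t, self.effective_widths)):
            off = ti + wi
            if i + 1 < len(t):
                off = min(off, t[i + 1])
            out.append((ti, min(off, self.duration)))
        return out


def relative_release(isi, params: MuscleParams):
    """Fraction of full Ca2+ release recovered after an interstimulus interval."""
    isi_arr = np.asarray(isi, dtype=float)
    if np.any(isi_arr <= 0):
        raise ValueError("interstimulus interval must be positive")
    out = 1.0 - (1.0 - params.inact_A) * np.exp(-isi_arr / params.inact_r)
    return float(out) if np.isscalar(isi) else out


def build_release_schedule(
    pulse_times: Sequence[float],
    params: MuscleParams,
    duration: float | None = None,
) -> StimulationProtocol:
    """Turn stimulus times into a protocol with inactivation-reduced widths.

    The first pulse releases at full width; every later pulse is scaled by
    :func:`relative_release` of the interval to its predecessor.
    """
    t = np.asarray(pulse_times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("pulse_times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) <= 0):
        raise ValueError("pulse times must be strictly increasing")
    if t[0] < 0:
        raise ValueError("pulse times must be non-negative")
    widths = np.full(t.size, params.pulse_width)
    if t.size > 1:
        widths[1:] *= relative_release(np.diff(t), params)
    if duration is None:
        duration = float(t[-1]) + 1.0
    return StimulationProtocol(tuple(t), tuple(widths), float(duration))


@dataclass(frozen=True)
class ActivatorTrace:
    """Sampled activator and activation time series.

    ``a`` is the raw activator (saturation 1); the trace the force model
    sees is ``a * release_scale`` and ``act`` is the activation sigmoid of
    that scaled trace.
    """

    t: np.ndarray
    a: np.ndarray
    act: np.ndarray
    release_scale: float = 1.0

    @property
    def a_effective(self) -> np.ndarray:
        return self.a * self.release_scale

    def to_csv(self, path: str | Path, include_activation: bool = True) -> None:
        cols = {"time_s": self.t, "activator": self.a_effective}
        if include_activation:
            cols["activation"] = self.act
        pd.DataFrame(cols).to_csv(path, index=False)


def _activator_samples(
    protocol: StimulationProtocol, params: MuscleParams, h: float, n: int
) -> np.ndarray:
    """Activator at ``n`` grid points spaced ``h`` seconds apart (analytic)."""
    times = np.arange(n) * h
    a = np.empty(n)
    # segment boundaries: alternate decay / release phases
    events: list[tuple[float, bool]] = [(0.0, False)]
    for on, off in protocol.release_windows():
        events.append((on, True))
        events.append((off, False))
    events.append((n * h + h, False))  # sentinel
    a_cur = 0.0
    for (t0, is_release), (t1, _) in zip(events[:-1], events[1:]):
        if t1 <= t0:
            continue
        i0 = int(np.searchsorted(times, t0 - 1e-15))
        i1 = int(np.searchsorted(times, t1 - 1e-15))
        dt_seg = times[i0:i1] - t0
        if is_release:
            a[i0:i1] = 1.0 - (1.0 - a_cur) * np.exp(-dt_seg / params.tau1)
            a_cur = 1.0 - (1.0 - a_cur) * math.exp(-(t1 - t0) / params.tau1)
        else:
            a[i0:i1] = a_cur * np.exp(-dt_seg / params.tau2)
            a_cur = a_cur * math.exp(-(t1 - t0) / params.tau2)
    return a


def simulate_activator(
    protocol: StimulationProtocol,
    params: MuscleParams,
    release_scale: float = 1.0,
    dt: float = 1e-4,
) -> ActivatorTrace:
    """Exact piecewise-exponential activator transient on a regular grid.

    ``release_scale`` models an ageing deficit in instantaneous Ca2+
    availability: the dynamics are untouched and the reported trace seen by
    the activation sigmoid is scaled pointwise.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0 < release_scale <= 1:
        raise ValueError("release_scale must lie in (0, 1]")
    n = int(round(protocol.duration / dt)) + 1
    a = _activator_samples(protocol, params, dt, n)
    act = activation_from_activator(a * release_scale, params.a50, params.nH)
    return ActivatorTrace(np.arange(n) * dt, a, act, release_scale)


def _periodic_map(frequency: float, params: MuscleParams):
    """One-period affine map a -> alpha*beta*a + beta*(1-alpha) and widths."""
    T = 1.0 / frequency
    w = min(params.pulse_width * float(relative_release(T, params)), T)
    alpha = math.exp(-w / params.tau1)          # release phase contraction
    beta = math.exp(-(T - w) / params.tau2)     # decay phase contraction
    return T, w, alpha, beta


def steady_state_activator(
    frequency: float,
    params: MuscleParams,
    release_scale: float = 1.0,
) -> float:
    """Mean activator over one interpulse period at periodic steady state.

    The per-period map is affine in ``a`` (both phases are linear ODEs), so
    the steady state is its fixed point and the period mean follows in
    closed form.  The returned value includes the ``release_scale`` factor,
    i.e. it is the level the activation sigmoid sees.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    T, w, alpha, beta = _periodic_map(frequency, params)
    a0 = beta * (1.0 - alpha) / (1.0 - alpha * beta)   # start of period
    a_peak = 1.0 - (1.0 - a0) * alpha                  # end of release
    mean = (
        w - (1.0 - a0) * params.tau1 * (1.0 - alpha)
        + a_peak * params.tau2 * (1.0 - beta)
    ) / T
    return release_scale * mean
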