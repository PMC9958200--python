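"""Synthetic twitch waveforms emulating experimental plantar-flexion data.

Group-mean targets (unpotentiated plantar-flexion twitches of healthy men):
young CT 123.6 +/- 8.6 ms, HRT 100.2 +/- 17.2 ms; older CT 154.8 +/- 24.7 ms,
HRT 129.0 +/- 24.4 ms, with an 18% lower amplitude.

The waveform family is a gamma-shaped transient

    f(t) = peak * (t / CT)^k * exp(k - t / theta),       CT = k * theta,

which peaks exactly at CT; the shape exponent ``k`` is solved numerically
so the half-relaxation time matches, and covers any HRT/CT ratio > 0
(large k gives a narrow, fast-relaxing pulse; k -> 0 a long exponential
tail).  Gaussian noise, when requested, is added after shaping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "WaveformSpec",
    "YOUNG_GROUP",
    "OLD_GROUP",
    "solve_shape",
    "generate_twitch_waveform",
    "cohort_sample",
    "waveform_to_csv",
]

#: truncation bounds (ms) for sampled timing parameters
CT_BOUNDS = (40.0, 400.0)
HRT_BOUNDS = (40.0, 400.0)

#: group means and SDs used as generator defaults
YOUNG_GROUP = {
    "peak": 1.0, "peak_sd": 0.15,
    "contraction_time_ms": 123.6, "contraction_time_sd": 8.6,
    "half_relaxation_time_ms": 100.2, "half_relaxation_time_sd": 17.2,
}
OLD_GROUP = {
    "peak": 0.82, "peak_sd": 0.18,
    "contraction_time_ms": 154.8, "contraction_time_sd": 24.7,
    "half_relaxation_time_ms": 129.0, "half_relaxation_time_sd": 24.4,
}


@dataclass(frozen=True)
class WaveformSpec:
    peak: float = 1.0
    contraction_time_ms: float = 123.6
    half_relaxation_time_ms: float = 100.2
    noise_sd: float = 0.0
    seed: int = 0
    duration_ms: float = 1000.0
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.peak <= 0:
            raise ValueError("peak must be strictly positive")
        if self.contraction_time_ms <= 0 or self.half_relaxation_time_ms <= 0:
            raise ValueError("CT and HRT must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dt_ms <= 0 or self.duration_ms <= self.contraction_time_ms:
            raise ValueError("duration must exceed CT and dt must be positive")


def _half_decay_ratio(k: float) -> float:
    """(t_half - t_peak)/t_peak for the unit-scale gamma pulse of shape k."""
    # g(x) = x^k exp(k(1-x)) with x = t/CT; find x > 1 where g = 1/2
    def g(x: float) -> float:
        return k * np.log(x) + k * (1.0 - x) - np.log(0.5)

    hi = 2.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - defensive
            raise RuntimeError("half-decay bracket not found")
    x_half = brentq(g, 1.0, hi, xtol=1e-12, rtol=1e-14)
    return x_half - 1.0


def solve_shape(contraction_time_ms: float, half_relaxation_time_ms: float
                ) -> tuple[float, float]:
    """Shape exponent ``k`` and timescale ``theta`` (ms) matching CT and HRT."""
    ratio = half_relaxation_time_ms / contraction_time_ms
    lo, hi = 1e-3, 1e5

    def h(k: float) -> float:
        return _half_decay_ratio(k) - ratio

    if h(lo) < 0 or h(hi) > 0:
        raise ValueError(
            f"infeasible CT/HRT combination (HRT/CT = {ratio:.3g}); the "
            f"gamma family covers ratios in roughly "
            f"({_half_decay_ratio(hi):.2g}, {_half_decay_ratio(lo):.3g})"
        )
    k = brentq(h, lo, hi, xtol=1e-12, rtol=1e-14)
    return k, contraction_time_ms / k


def generate_twitch_waveform(spec: WaveformSpec) -> tuple[np.ndarray, np.ndarray]:
    """Time (ms) and force arrays for the requested twitch transient.

    The noise-free waveform peaks at ``spec.peak`` exactly at
    ``contraction_time_ms`` and crosses half-peak ``half_relaxation_time_ms``
    later.  Identical specs (including seed) give bit-identical output.
    """
    k, theta = solve_shape(spec.contraction_time_ms,
                           spec.half_relaxation_time_ms)
    t = np.arange(0.0, spec.duration_ms + 0.5 * spec.dt_ms, spec.dt_ms)
    with np.errstate(divide="ignore"):
        logg = np.where(
            t > 0, k * np.log(t / spec.contraction_time_ms) + k - t / theta,
            -np.inf,
        )
    f = spec.peak * np.exp(logg)
    f[t == 0] = 0.0
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sd, size=f.size)
    return t, f


def cohort_sample(
    n: int,
    group_means: dict | None = None,
    group_sds: dict | None = None,
    seed: int = 0,
    group: str = "young",
) -> list[WaveformSpec]:
    """Draw ``n`` per-subject waveform specs from group statistics.

    CT, HRT and peak are independent truncated normals (CT/HRT within
    physiological bounds, peak strictly positive); draws are reproducible
    from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = YOUNG_GROUP if group == "young" else OLD_GROUP
    means = dict(base)
    if group_means:
        means.update(group_means)
    sds = {
        "contraction_time_ms": means["contraction_time_sd"],
        "half_relaxation_time_ms": means["half_relaxation_time_sd"],
        "peak": means["peak_sd"],
    }
    if group_sds:
        sds.update(group_sds)
    rng = np.random.default_rng(seed)

    def draw(mean: float, sd: float, lo: float, hi: float) -> float:
        if sd == 0:
            return mean
        for _ in range(1000):
            x = rng.normal(mean, sd)
            if lo < x < hi:
                return x
        raise RuntimeError("truncated-normal sampling failed")  # pragma: no cover

    out = []
    for i in range(n):
        out.append(
            WaveformSpec(
                peak=draw(means["peak"], sds["peak"], 1e-6, np.inf),
                contraction_time_ms=draw(
                    means["contraction_time_ms"],
                    sds["contraction_time_ms"], *CT_BOUNDS,
                ),
                half_relaxation_time_ms=draw(
                    means["half_relaxation_time_ms"],
                    sds["half_relaxation_time_ms"], *HRT_BOUNDS,
                ),
                seed=seed + i + 1,
            )
        )
    return out


def waveform_to_csv(t_ms: np.ndarray, force: np.ndarray,
                    path: str | Path) -> None:
    """Two-column CSV dialect (time_ms, force) read by the fitting CLI."""
    pd.DataFrame({"time_ms": t_ms, "force": force}).to_csv(path, index=False)
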