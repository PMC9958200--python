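"""Optimisation of model parameters to target twitch descriptors.

The objective is the sum of squared *relative* errors in contraction time
and half-relaxation time plus a quadratic penalty on the relative twitch
amplitude outside a tolerance band (the amplitude requirement is soft,
"about 0.2 P0").  Minimisation uses bounded Nelder-Mead with seeded
restarts: one twitch simulation costs milliseconds and the objective is
non-smooth at metric crossings, so a derivative-free simplex is adequate
and reproducible.

Two modes mirror the study design: a *young* (control) fit with nH and
Vmax held at 3 and 6, and an *old* fit anchored at the young solution with
directional bounds (tau2 may only increase; Vmax, k_SEE and the
force-generating capacity FGC may only decrease; a50 may only increase,
i.e. Ca2+ sensitivity may only fall).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .metrics import TwitchMetrics, twitch_metrics
from .params import MuscleParams
from .simulate import simulate_fixed_end, twitch

__all__ = ["FitSpec", "FitResult", "fit_twitch", "fit_old_twitch",
           "FITTABLE_PARAMETERS"]

FITTABLE_PARAMETERS = ("tau1", "tau2", "a50", "nH", "vmax", "k_see", "fgc")

_DEFAULT_BOUNDS = {
    "tau1": (0.005, 0.20),
    "tau2": (0.05, 1.0),
    "a50": (0.02, 0.5),
    "nH": (1.0, 6.0),
    "vmax": (1.0, 12.0),
    "k_see": (1.0, 10.0),
    "fgc": (0.3, 1.0),
}


def _get_param(params: MuscleParams, name: str) -> float:
    return params.k_see if name == "k_see" else getattr(params, name)


def _set_params(params: MuscleParams, names: Sequence[str],
                values: Sequence[float]) -> MuscleParams:
    out = params
    plain = {n: v for n, v in zip(names, values) if n != "k_see"}
    if plain:
        out = out.replace(**plain)
    for n, v in zip(names, values):
        if n == "k_see":
            out = out.with_k_see(v)
    return out


@dataclass(frozen=True)
class FitSpec:
    free_parameters: tuple = ("tau1", "tau2", "a50")
    bounds: dict = field(default_factory=dict)
    amplitude_target: float = 0.2     # fraction of P0
    amplitude_tolerance: float = 0.10  # relative half-width of the free band
    amplitude_weight: float = 10.0
    initial_l_ce: float = 1.0
    dt: float = 2e-4
    sim_duration: float = 0.8
    max_iter: int = 400
    n_restarts: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.free_parameters) - set(FITTABLE_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")
        if self.amplitude_target <= 0:
            raise ValueError("amplitude_target must be strictly positive")

    def resolved_bounds(self) -> dict:
        out = dict(_DEFAULT_BOUNDS)
        out.update(self.bounds)
        for name, (lo, hi) in out.items():
            if not lo < hi or not np.isfinite(lo) or not np.isfinite(hi):
                raise ValueError(f"bounds for {name} must be finite with lo < hi")
        return out


@dataclass(frozen=True)
class FitResult:
    params: MuscleParams
    contraction_time_ms: float
    half_relaxation_time_ms: float
    amplitude: float
    objective: float
    converged: bool
    n_evaluations: int
    multiple_solutions: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        p = self.params
        return {
            # Table-style column order
            "tau1": p.tau1, "tau2": p.tau2, "a50": p.a50, "pCa50": p.pCa50,
            "nH": p.nH, "vmax": p.vmax, "k_see": p.k_see, "fgc": p.fgc,
            "contraction_time_ms": self.contraction_time_ms,
            "half_relaxation_time_ms": self.half_relaxation_time_ms,
            "amplitude": self.amplitude,
            "objective": self.objective,
            "converged": self.converged,
            "multiple_solutions": self.multiple_solutions,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _simulate_metrics(params: MuscleParams, spec: FitSpec) -> TwitchMetrics:
    rec = simulate_fixed_end(
        params,
        twitch(params, duration=spec.sim_duration),
        initial_l_ce=spec.initial_l_ce,
        dt=spec.dt,
    )
    return twitch_metrics(rec)


def _objective_factory(target: TwitchMetrics, spec: FitSpec,
                       base: MuscleParams, names: Sequence[str]):
    counter = {"n": 0}

    def objective(x: np.ndarray) -> float:
        counter["n"] += 1
        try:
            p = _set_params(base, names, x)
            m = _simulate_metrics(p, spec)
        except (ValueError, RuntimeError):
            return 1e6
        err = (
            ((m.contraction_time_ms - target.contraction_time_ms)
             / target.contraction_time_ms) ** 2
            + ((m.half_relaxation_time_ms - target.half_relaxation_time_ms)
               / target.half_relaxation_time_ms) ** 2
        )
        rel_amp = (m.peak_force - spec.amplitude_target) / spec.amplitude_target
        excess = max(0.0, abs(rel_amp) - spec.amplitude_tolerance)
        return err + spec.amplitude_weight * excess ** 2

    return objective, counter


def fit_twitch(
    target: TwitchMetrics,
    spec: FitSpec = FitSpec(),
    params_init: MuscleParams = MuscleParams(),
) -> FitResult:
    """Fit the free parameters so the simulated twitch matches ``target``.

    Runs ``n_restarts + 1`` bounded Nelder-Mead searches (the first from
    ``params_init``, the rest from seeded perturbations) and keeps the best.
    Non-convergence is reported in the result flag, never raised.
    """
    names = tuple(spec.free_parameters)
    if not names:
        raise ValueError("free_parameters must not be empty")
    bounds_map = spec.resolved_bounds()
    bounds = [bounds_map[n] for n in names]
    x0 = np.array([
        float(np.clip(_get_param(params_init, n), *bounds_map[n]))
        for n in names
    ])
    objective, counter = _objective_factory(target, spec, params_init, names)

    rng = np.random.default_rng(spec.seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    # keep simplex starts off the bounds so the initial simplex is not
    # degenerate when a directional bound is anchored at the start value
    x_interior = np.clip(x0, lo + 0.01 * (hi - lo), hi - 0.01 * (hi - lo))
    f_x0 = objective(x0)
    best_x, best_f, best_success, best_message = x0, f_x0, True, "initial point"
    if f_x0 > 1e-10:
        starts = [x_interior]
        for _ in range(spec.n_restarts):
            jitter = x0 * (1.0 + rng.uniform(-0.15, 0.15, size=x0.size))
            starts.append(np.clip(jitter, lo, hi))
        for start in starts:
            res = minimize(
                objective, start, method="Nelder-Mead", bounds=bounds,
                options={"maxiter": spec.max_iter, "xatol": 1e-5,
                         "fatol": 1e-8},
            )
            if res.fun < best_f:
                best_x, best_f = res.x, float(res.fun)
                best_success, best_message = bool(res.success), str(res.message)
            if best_f < 1e-8:
                break

    params_best = _set_params(params_init, names, best_x)
    achieved = _simulate_metrics(params_best, spec)

    multiple = False
    if {"fgc", "tau2"} <= set(names):
        # probe the FGC-tau2 trade-off direction for a flat objective valley
        for s in (-0.05, 0.05):
            probe = dict(zip(names, best_x))
            probe["fgc"] = float(np.clip(probe["fgc"] * (1 + s),
                                         *bounds_map["fgc"]))
            probe["tau2"] = float(np.clip(probe["tau2"] * (1 - 0.6 * s),
                                          *bounds_map["tau2"]))
            if objective(np.array([probe[n] for n in names])) < best_f + 1e-3:
                multiple = True
                break

    return FitResult(
        params=params_best,
        contraction_time_ms=achieved.contraction_time_ms,
        half_relaxation_time_ms=achieved.half_relaxation_time_ms,
        amplitude=achieved.peak_force,
        objective=best_f,
        converged=best_success or best_f < 1e-6,
        n_evaluations=counter["n"],
        multiple_solutions=multiple,
        message=best_message,
    )


def fit_old_twitch(
    target: TwitchMetrics,
    young_params: MuscleParams,
    spec: FitSpec | None = None,
) -> FitResult:
    """Fit an aged twitch with directional limits anchored at the young fit.

    Default free parameters are tau2, vmax, k_see and fgc; bounds only allow
    each to move in the direction of age-related impairment.  The amplitude
    target should carry the observed relative deficit (e.g. 0.82 x young).
    """
    y = young_params
    directional = {
        "tau1": (y.tau1, 2.0 * y.tau1),
        "tau2": (y.tau2, 2.0 * y.tau2),
        "a50": (y.a50, min(y.a50 * 10 ** 0.15, 0.9)),
        "nH": (max(1.0, 0.5 * y.nH), y.nH),
        "vmax": (0.5 * y.vmax, y.vmax),
        "k_see": (0.5 * y.k_see, y.k_see),
        "fgc": (0.5, y.fgc),
    }
    if spec is None:
        spec = FitSpec(free_parameters=("tau2", "vmax", "k_see", "fgc"))
    merged = dict(directional)
    merged.update(spec.bounds)
    spec = replace(spec, bounds=merged)
    return fit_twitch(target, spec, params_init=y)
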