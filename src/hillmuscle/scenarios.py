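"""Ageing-scenario perturbation engine.

A :class:`Scenario` is a named, composable set of parameter modifications
expressing literature-informed ageing adaptations: scaled instantaneous
Ca2+ availability, slower Ca2+ removal, reduced Ca2+ sensitivity, altered
cooperativity, slower intrinsic shortening, altered SEE stiffness, reduced
force-generating capacity, and an increased type I fibre fractional area.

The fibre-type shift recomputes composite whole-muscle parameters from
fibre-type-specific values obtained by inverting the area-weighted mixing
rule ``x_slow * p_slow + x_fast * p_fast = x_whole`` with a fixed
slow/fast ratio (or additive pCa offset) per property.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace
from importlib import resources

import yaml

from .params import MuscleParams

__all__ = [
    "Scenario",
    "FiberTypeSpec",
    "IDENTITY",
    "apply_scenario",
    "decompose_fiber_values",
    "compose_fiber_values",
    "fiber_shift_params",
    "load_catalogue",
]


@dataclass(frozen=True)
class Scenario:
    """Field-wise parameter perturbation.

    ``release_scale`` is not a :class:`MuscleParams` field: it scales the
    activator trace at simulation time and is consumed by the drivers (see
    :func:`hillmuscle.simulate.simulate_fixed_end`).
    """

    name: str
    release_scale: float = 1.0
    tau2_multiplier: float = 1.0
    delta_pca50: float = 0.0          # negative = desensitised
    delta_nH: float = 0.0
    vmax_multiplier: float = 1.0
    aP0_delta: float = 0.0
    k_see_multiplier: float = 1.0
    p_slow_new: float | None = None
    fgc: float = 1.0

    def __post_init__(self) -> None:
        for name in ("release_scale", "tau2_multiplier", "vmax_multiplier",
                     "k_see_multiplier", "fgc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.p_slow_new is not None and not 0 < self.p_slow_new < 1:
            raise ValueError("p_slow_new must lie in (0, 1)")

    def combine(self, other: "Scenario", name: str | None = None) -> "Scenario":
        """Field-wise composition (multipliers multiply, deltas add)."""
        return Scenario(
            name=name or f"{self.name}+{other.name}",
            release_scale=self.release_scale * other.release_scale,
            tau2_multiplier=self.tau2_multiplier * other.tau2_multiplier,
            delta_pca50=self.delta_pca50 + other.delta_pca50,
            delta_nH=self.delta_nH + other.delta_nH,
            vmax_multiplier=self.vmax_multiplier * other.vmax_multiplier,
            aP0_delta=self.aP0_delta + other.aP0_delta,
            k_see_multiplier=self.k_see_multiplier * other.k_see_multiplier,
            p_slow_new=other.p_slow_new if other.p_slow_new is not None
            else self.p_slow_new,
            fgc=self.fgc * other.fgc,
        )

    def is_identity(self) -> bool:
        return self == Scenario(self.name)


IDENTITY = Scenario("identity")


@dataclass(frozen=True)
class FiberTypeSpec:
    """Slow/fast (type I / type II) property differences.

    Ratios are slow over fast; the pCa50 difference is additive in pCa
    units (slow minus fast).
    """

    ratio_removal_rate: float = 0.5      # slow removal rate = half the fast
    delta_pca50_slow_minus_fast: float = 0.15
    ratio_nH: float = 0.6
    ratio_vmax: float = 0.3

    def __post_init__(self) -> None:
        for name in ("ratio_removal_rate", "ratio_nH", "ratio_vmax"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


def decompose_fiber_values(
    whole_value: float, p_slow: float, ratio_y: float
) -> tuple[float, float]:
    """Fibre-type-specific values from a whole-muscle composite.

    Solves ``x_slow * p_slow + x_fast * (1 - p_slow) = whole`` with
    ``x_slow / x_fast = y``.  Degenerate fractions (0 or 1) pass the whole
    value through with a warning.
    """
    if ratio_y <= 0:
        raise ValueError("ratio must be strictly positive")
    if p_slow in (0.0, 1.0):
        warnings.warn(
            "degenerate fibre fraction; decomposition passes the whole value "
            "through", stacklevel=2,
        )
        return whole_value, whole_value
    if not 0 < p_slow < 1:
        raise ValueError("p_slow must lie in [0, 1]")
    x_fast = whole_value / (p_slow * ratio_y + 1.0 - p_slow)
    return ratio_y * x_fast, x_fast


def compose_fiber_values(x_slow: float, x_fast: float, p_slow: float) -> float:
    """Area-weighted recomposition of fibre-type-specific values."""
    return x_slow * p_slow + x_fast * (1.0 - p_slow)


def fiber_shift_params(
    params: MuscleParams,
    p_slow_new: float,
    spec: FiberTypeSpec = FiberTypeSpec(),
) -> MuscleParams:
    """Composite parameters after changing the type I fractional area.

    The Ca2+ removal *rate constant* (1/tau2), Vmax and nH are decomposed
    with their slow/fast ratios at the current ``p_slow`` and recomposed at
    ``p_slow_new``; pCa50 uses the additive-offset form (the fibre
    difference is stated in pCa units).
    """
    if not 0 < p_slow_new < 1:
        raise ValueError("p_slow_new must lie in (0, 1)")
    if p_slow_new == params.p_slow:  # exact fixed point, skip float round-trip
        return params
    p0 = params.p_slow

    def shifted(whole: float, ratio: float) -> float:
        slow, fast = decompose_fiber_values(whole, p0, ratio)
        return compose_fiber_values(slow, fast, p_slow_new)

    rate_new = shifted(1.0 / params.tau2, spec.ratio_removal_rate)
    vmax_new = shifted(params.vmax, spec.ratio_vmax)
    nh_new = shifted(params.nH, spec.ratio_nH)
    # additive decomposition: pCa50_slow = pCa50_fast + gap
    gap = spec.delta_pca50_slow_minus_fast
    pca_fast = params.pCa50 - p0 * gap
    pca_new = pca_fast + p_slow_new * gap
    return params.replace(
        tau2=1.0 / rate_new,
        vmax=vmax_new,
        nH=nh_new,
        a50=10.0 ** (5.0 - pca_new),
        p_slow=p_slow_new,
    )


def apply_scenario(
    params: MuscleParams,
    scenario: Scenario,
    fiber_spec: FiberTypeSpec = FiberTypeSpec(),
) -> MuscleParams:
    """Return the parameter set under ``scenario``.

    ``scenario.release_scale`` must be passed to the simulator separately;
    everything else maps onto :class:`MuscleParams` fields.  pCa50 shifts
    act multiplicatively on a50 (``a50 * 10**-delta``); SEE stiffness
    changes rescale the deformation axis so the normalised stiffness
    changes by the stated factor while preserving the power-law exponent.
    """
    out = params
    if scenario.p_slow_new is not None:
        out = fiber_shift_params(out, scenario.p_slow_new, fiber_spec)
    changes: dict[str, float] = {}
    if scenario.tau2_multiplier != 1.0:
        changes["tau2"] = out.tau2 * scenario.tau2_multiplier
    if scenario.delta_pca50 != 0.0:
        changes["a50"] = out.a50 * 10.0 ** (-scenario.delta_pca50)
    if scenario.delta_nH != 0.0:
        changes["nH"] = out.nH + scenario.delta_nH
    if scenario.vmax_multiplier != 1.0:
        changes["vmax"] = out.vmax * scenario.vmax_multiplier
    if scenario.aP0_delta != 0.0:
        changes["aP0"] = out.aP0 + scenario.aP0_delta
    if scenario.fgc != 1.0:
        changes["fgc"] = out.fgc * scenario.fgc
    if changes:
        out = out.replace(**changes)
    if scenario.k_see_multiplier != 1.0:
        out = out.with_k_see(out.k_see * scenario.k_see_multiplier)
    return out


def load_catalogue() -> dict[str, Scenario]:
    """The shipped scenario presets, keyed by name."""
    text = resources.files("hillmuscle").joinpath("scenarios.yaml").read_text()
    raw = yaml.safe_load(text)
    out: dict[str, Scenario] = {}
    valid = {f.name for f in fields(Scenario)} - {"name"}
    for name, entry in raw.items():
        entry = entry or {}
        unknown = set(entry) - valid
        if unknown:
            raise ValueError(
                f"scenario '{name}' has unknown field(s): {sorted(unknown)}"
            )
        out[name] = Scenario(name=name, **entry)
    return out
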