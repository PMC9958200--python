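"""Fixed-end muscle-tendon-unit simulation.

At constant MTU length, the CE shortens against the stretch of the SEE.
With a massless junction the SEE force must equal CE active force plus PEE
force at every instant; at each step the SEE deformation follows from the
constraint, the required CE force from the balance, and the CE velocity
from the inverse force-velocity relation.  The CE length is integrated with
explicit RK4 (the per-step velocity is an algebraic function of state).

When activation is essentially zero (``fgc * Act * FL`` below a small
floor) the force-velocity relation no longer determines the velocity; the
CE is then relaxed toward the passive-equilibrium length with a bounded
first-order rule, which keeps an unstimulated muscle exactly stationary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import mechanics
from .activation import StimulationProtocol, _activator_samples, build_release_schedule
from .mechanics import activation_from_activator
from .params import MuscleParams

__all__ = [
    "ContractionRecord",
    "equilibrium_ce_length",
    "simulate_fixed_end",
    "twitch",
    "train",
    "brief_tetanus",
]

#: below this value of fgc*Act*FL the CE is treated as passive
ACTIVATION_FLOOR = 1e-6
#: time constant (s) of the passive relaxation toward equilibrium length
PASSIVE_RELAX_TAU = 0.005


# ---------------------------------------------------------------------------
# protocol builders

def twitch(params: MuscleParams, duration: float = 1.0) -> StimulationProtocol:
    """Single supramaximal stimulus at t = 0."""
    return build_release_schedule([0.0], params, duration=duration)


def train(
    params: MuscleParams,
    frequency: float,
    duration: float = 1.0,
    record_duration: float | None = None,
) -> StimulationProtocol:
    """Periodic stimulation at ``frequency`` Hz; pulses at t < duration."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    times = np.arange(0.0, duration, 1.0 / frequency)
    if record_duration is None:
        record_duration = duration
    return build_release_schedule(times, params, duration=record_duration)


def brief_tetanus(params: MuscleParams, duration: float = 1.0) -> StimulationProtocol:
    """Brief tetanic contraction: 6 pulses at 100 Hz spanning 50 ms."""
    times = np.arange(6) * 0.010
    return build_release_schedule(times, params, duration=duration)


# ---------------------------------------------------------------------------

def equilibrium_ce_length(
    initial_l_ce: float, params: MuscleParams
) -> tuple[float, float]:
    """Passive equilibrium of the unstimulated MTU.

    Returns ``(d_star, mtu_length)``: the SEE deformation (mm) balancing the
    PEE at the requested CE length, and the fixed MTU length (mm)
    ``initial_l_ce * L0 + L_see + d_star``.
    """
    if not params.fl_zero_low < initial_l_ce < params.fl_zero_high:
        raise ValueError("initial CE length outside the force-length domain")
    f_pee = mechanics.pee_force(initial_l_ce, params)
    d_star = mechanics.see_deformation(f_pee, params)
    residual = mechanics.see_force(d_star, params) - f_pee
    if abs(residual) > 1e-9:
        raise RuntimeError("passive equilibrium residual exceeds tolerance")
    return d_star, initial_l_ce * params.L0 + params.L_see + d_star


@dataclass(frozen=True)
class ContractionRecord:
    """Time series of one fixed-end contraction.

    ``total_force`` is the force transmitted through the SEE; ``active_force``
    is the CE contribution ``fgc * Act * FL * FV`` at the realized velocity
    and ``passive_force`` the PEE contribution.
    """

    t: np.ndarray
    l_ce: np.ndarray
    v_ce: np.ndarray
    activator: np.ndarray
    activation: np.ndarray
    active_force: np.ndarray
    passive_force: np.ndarray
    total_force: np.ndarray
    params: MuscleParams
    protocol: StimulationProtocol
    initial_l_ce: float
    release_scale: float
    mtu_length: float
    dt: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "l_ce": self.l_ce,
                "v_ce": self.v_ce,
                "activator": self.activator,
                "activation": self.activation,
                "active_force": self.active_force,
                "passive_force": self.passive_force,
                "total_force": self.total_force,
            }
        )

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the tidy CSV; optionally a JSON provenance sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {
                "params": self.params.to_dict(),
                "protocol": {
                    "pulse_times": list(self.protocol.pulse_times),
                    "effective_widths": list(self.protocol.effective_widths),
                    "duration": self.protocol.duration,
                },
                "initial_l_ce": self.initial_l_ce,
                "release_scale": self.release_scale,
                "mtu_length_mm": self.mtu_length,
                "dt": self.dt,
            }
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @property
    def see_deformation(self) -> np.ndarray:
        return self.mtu_length - self.l_ce * self.params.L0 - self.params.L_see

    @property
    def peak_active_force(self) -> float:
        return float(np.max(self.active_force))


def simulate_fixed_end(
    params: MuscleParams,
    protocol: StimulationProtocol,
    initial_l_ce: float = 1.23,
    release_scale: float = 1.0,
    dt: float = 1e-4,
) -> ContractionRecord:
    """Simulate a fixed-end contraction driven by ``protocol``.

    The MTU length is fixed at the passive equilibrium for ``initial_l_ce``.
    ``release_scale`` scales the activator seen by the activation sigmoid
    (ageing deficit in instantaneous Ca2+ availability).  ``dt`` is the RK4
    step and output sampling interval.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0 < release_scale <= 1:
        raise ValueError("release_scale must lie in (0, 1]")
    _, mtu = equilibrium_ce_length(initial_l_ce, params)

    n_steps = int(round(protocol.duration / dt))
    h = dt / 2.0
    a_half = _activator_samples(protocol, params, h, 2 * n_steps + 1)
    act_half = activation_from_activator(
        a_half * release_scale, params.a50, params.nH
    )

    l_grid = _integrate(params, mtu, act_half, dt, n_steps, initial_l_ce)

    # vectorized post-pass: recompute forces/velocities on the saved grid
    t = np.arange(n_steps + 1) * dt
    act = act_half[::2]
    a_raw = a_half[::2]
    d = np.maximum(mtu - l_grid * params.L0 - params.L_see, 0.0)
    f_see = mechanics.see_force(d, params)
    f_pee = mechanics.pee_force(l_grid, params)
    denom = params.fgc * act * mechanics.force_length(l_grid, params)
    p_rel = np.clip(
        (f_see - f_pee) / np.maximum(denom, ACTIVATION_FLOOR), 0.0, params.ecc_c
    )
    v = mechanics.inverse_force_velocity(p_rel, params)
    l_eq = initial_l_ce
    passive = denom < ACTIVATION_FLOOR
    v_passive = np.clip(
        (l_grid - l_eq) / PASSIVE_RELAX_TAU, -params.vmax, params.vmax
    )
    v = np.where(passive, v_passive, v)
    active = np.where(passive, 0.0, denom * p_rel)

    return ContractionRecord(
        t=t,
        l_ce=l_grid,
        v_ce=v,
        activator=a_raw,
        activation=act,
        active_force=active,
        passive_force=f_pee,
        total_force=active + f_pee,
        params=params,
        protocol=protocol,
        initial_l_ce=initial_l_ce,
        release_scale=release_scale,
        mtu_length=mtu,
        dt=dt,
    )


def _integrate(
    params: MuscleParams,
    mtu: float,
    act_half: np.ndarray,
    dt: float,
    n_steps: int,
    l_eq: float,
) -> np.ndarray:
    """RK4 on the CE length; returns l_ce at every output sample.

    The inner loop uses plain-float math for speed; the vectorized
    post-pass in :func:`simulate_fixed_end` mirrors the same formulas via
    the public mechanics functions (consistency is asserted in the tests).
    """
    L0, L_see = params.L0, params.L_see
    d0 = params.see_deformation_at_p0
    b = params.see_exponent
    kpee, lsl, epee = params.k_pee, params.l_slack_pee, params.eps_pee
    pee_denom = math.expm1(kpee)
    K, vmax = params.aP0, params.vmax
    c, kk, q = params.ecc_c, params.ecc_k, params.ecc_q
    fgc = params.fgc
    fl0, fl1, fl2, fl3 = (
        params.fl_zero_low,
        params.fl_plateau_low,
        params.fl_plateau_high,
        params.fl_zero_high,
    )
    asc = fl1 - fl0
    desc = fl3 - fl2
    floor = ACTIVATION_FLOOR
    tau_r = PASSIVE_RELAX_TAU
    exp = math.exp

    def dldt(l: float, act: float) -> float:
        # force-length factor
        if l <= fl0 or l >= fl3:
            fl = 0.0
        elif l < fl1:
            fl = (l - fl0) / asc
        elif l <= fl2:
            fl = 1.0
        else:
            fl = (fl3 - l) / desc
        denom = fgc * act * fl
        if denom < floor:
            v = (l - l_eq) / tau_r
            if v > vmax:
                v = vmax
            elif v < -vmax:
                v = -vmax
            return -v
        d = mtu - l * L0 - L_see
        f_see = (d / d0) ** b if d > 0.0 else 0.0
        strain = l - lsl
        f_pee = math.expm1(kpee * strain / epee) / pee_denom if strain > 0.0 else 0.0
        p = (f_see - f_pee) / denom
        if p < 0.0:
            p = 0.0
        elif p > c:
            p = c
        if p <= 1.0:
            u = K * (1.0 - p) / (p + K)
        else:
            cp = c - p
            u = (cp - kk) / (kk + cp * q)
        return -u * vmax  # v shortening-positive, l decreases

    out = np.empty(n_steps + 1)
    l = l_eq
    out[0] = l
    for i in range(n_steps):
        j = 2 * i
        a1 = act_half[j]
        a2 = act_half[j + 1]
        a3 = act_half[j + 2]
        k1 = dldt(l, a1)
        k2 = dldt(l + 0.5 * dt * k1, a2)
        k3 = dldt(l + 0.5 * dt * k2, a2)
        k4 = dldt(l + dt * k3, a3)
        l = l + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
        out[i + 1] = l
    return out
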