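"""Constitutive relations of the muscle model.

All functions accept scalars or numpy arrays and return floats/arrays of the
matching shape.  Conventions:

* CE length in units of the optimal length ``L0``.
* CE velocity in ``L0/s``, shortening positive; eccentric (lengthening)
  velocities are negative.
* Forces in units of the maximum isometric force ``P0``.
* SEE deformation in millimetres.
"""

from __future__ import annotations

import numpy as np

from .params import MuscleParams

__all__ = [
    "force_length",
    "force_velocity",
    "inverse_force_velocity",
    "pee_force",
    "see_force",
    "see_deformation",
    "activation_from_activator",
    "a50_to_pca50",
    "pca50_to_a50",
    "pca_to_activator",
    "activator_to_pca",
    "activation_from_pca",
]


def force_length(l_ce, params: MuscleParams):
    """Active force-length scaling factor in [0, 1].

    Piecewise linear: zero below ``fl_zero_low``, ascending limb to the
    plateau [``fl_plateau_low``, ``fl_plateau_high``] at 1.0, descending
    limb to zero at ``fl_zero_high`` (loss of filament overlap).
    """
    l = np.asarray(l_ce, dtype=float)
    if np.any(l <= 0):
        raise ValueError("CE length must be strictly positive")
    xp = [params.fl_zero_low, params.fl_plateau_low,
          params.fl_plateau_high, params.fl_zero_high]
    out = np.interp(l, xp, [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0)
    return float(out) if np.isscalar(l_ce) else out


def force_velocity(v, params: MuscleParams):
    """Force scaling factor for CE velocity ``v`` (shortening positive).

    Concentric branch: P/P0 = K(1 - V/Vmax) / (K + V/Vmax) with K = a/P0.
    Eccentric branch (V < 0): P/P0 = c - k(1 + V/Vmax)/(1 - q V/Vmax),
    continuous at V = 0 with value 1 since c - k = 1.  Concentric force is
    clamped at zero beyond Vmax.
    """
    u = np.asarray(v, dtype=float) / params.vmax
    K, c, k, q = params.aP0, params.ecc_c, params.ecc_k, params.ecc_q
    conc = K * (1.0 - u) / (K + u)
    with np.errstate(divide="ignore", invalid="ignore"):
        ecc = c - k * (1.0 + u) / (1.0 - q * u)
    out = np.where(u >= 0, np.maximum(conc, 0.0), ecc)
    return float(out) if np.isscalar(v) else out


def inverse_force_velocity(p_rel, params: MuscleParams):
    """CE velocity (L0/s) at which the CE bears relative force ``p_rel``.

    Closed-form inversion of both branches of :func:`force_velocity`.
    ``p_rel`` below 1 gives shortening, above 1 lengthening.  Demands at or
    above the eccentric ceiling ``ecc_c`` are clamped to the velocity at
    ``p_rel = ecc_c``, which is exactly ``-vmax``.
    """
    p = np.asarray(p_rel, dtype=float)
    if np.any(p < 0):
        raise ValueError("relative force demand must be non-negative")
    K, c, k, q = params.aP0, params.ecc_c, params.ecc_k, params.ecc_q
    p = np.minimum(p, c)
    u_conc = K * (1.0 - p) / (p + K)
    u_ecc = ((c - p) - k) / (k + (c - p) * q)
    out = params.vmax * np.where(p <= 1.0, u_conc, u_ecc)
    return float(out) if np.isscalar(p_rel) else out


def pee_force(l_ce, params: MuscleParams):
    """Passive force of the parallel elastic element, in P0.

    Exponential toe region: zero at or below the slack length, 1.0 P0 at
    ``l_slack_pee + eps_pee``.
    """
    l = np.asarray(l_ce, dtype=float)
    if np.any(l <= 0):
        raise ValueError("CE length must be strictly positive")
    strain = np.maximum(l - params.l_slack_pee, 0.0)
    num = np.expm1(params.k_pee * strain / params.eps_pee)
    out = num / np.expm1(params.k_pee)
    return float(out) if np.isscalar(l_ce) else out


def see_force(deformation, params: MuscleParams):
    """SEE force (P0) for a deformation in mm: power law P = (x/x0)^b.

    ``x0 = eps_see * L_see`` is the deformation at P0.
    """
    x = np.asarray(deformation, dtype=float)
    if np.any(x < 0):
        raise ValueError("SEE deformation must be non-negative")
    out = (x / params.see_deformation_at_p0) ** params.see_exponent
    return float(out) if np.isscalar(deformation) else out


def see_deformation(force, params: MuscleParams):
    """Inverse of :func:`see_force`: deformation (mm) carrying ``force`` P0."""
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("SEE force must be non-negative")
    out = params.see_deformation_at_p0 * f ** (1.0 / params.see_exponent)
    return float(out) if np.isscalar(force) else out


def activation_from_activator(a, a50: float, nH: float):
    """Sigmoidal activation Act = a^nH / (a^nH + a50^nH), in [0, 1)."""
    arr = np.asarray(a, dtype=float)
    if np.any(arr < 0):
        raise ValueError("activator concentration must be non-negative")
    an = arr ** nH
    out = an / (an + a50 ** nH)
    return float(out) if np.isscalar(a) else out


def a50_to_pca50(a50):
    """pCa50 of the force-pCa curve; activator saturation (a=1) is pCa 5."""
    arr = np.asarray(a50, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("a50 must be strictly positive")
    out = 5.0 - np.log10(arr)
    return float(out) if np.isscalar(a50) else out


def pca50_to_a50(pca50):
    arr = np.asarray(pca50, dtype=float)
    out = 10.0 ** (5.0 - arr)
    return float(out) if np.isscalar(pca50) else out


def pca_to_activator(pca):
    """Relative activator concentration for a pCa (a = 1 at pCa 5)."""
    arr = np.asarray(pca, dtype=float)
    out = 10.0 ** (5.0 - arr)
    return float(out) if np.isscalar(pca) else out


def activator_to_pca(a):
    arr = np.asarray(a, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("activator concentration must be strictly positive")
    out = 5.0 - np.log10(arr)
    return float(out) if np.isscalar(a) else out


def activation_from_pca(pca, pca50: float, nH: float):
    """Hill form of the force-pCa curve, P/P0 = 1/(1 + 10^{nH (pCa - pCa50)}).

    Algebraically identical to composing :func:`pca_to_activator` with
    :func:`activation_from_activator`.
    """
    arr = np.asarray(pca, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** (nH * (arr - pca50)))
    return float(out) if np.isscalar(pca) else out
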