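"""Parameter set for the three-element Hill-type muscle model.

The model consists of a contractile element (CE) and a parallel elastic
element (PEE) in series with an elastic element (SEE).  Forces are expressed
in units of the maximum isometric force ``P0`` and CE lengths in units of the
optimal CE length ``L0``; absolute lengths (``L0``, ``L_see``, SEE
deformation) are in millimetres and times in seconds.

Defaults describe the human plantar flexors of young adult men:

========== ========= =====================================================
field      default   meaning
========== ========= =====================================================
pulse_width 0.0048   duration of Ca2+ release per stimulus (s)
tau1        0.0422   time constant of activator rise during release (s)
tau2        0.256    time constant of activator removal (SR Ca2+ uptake) (s)
a50         0.1025   activator level at half-maximal activation
nH          3        Hill coefficient of the activation sigmoid
vmax        6        maximum unloaded CE shortening velocity (L0/s)
aP0         0.10     curvature a/P0 of the concentric force-velocity branch
eps_see     0.05     SEE strain at P0 (gives k_see = 3.33 P0/L0)
L0          50       optimal CE length (mm)
L_see       300      SEE rest length (mm)
========== ========= =====================================================

``inact_A`` is the *minimum* relative Ca2+ release for vanishing
interstimulus interval (maximum inactivation = 1 - inact_A) and ``inact_r``
the recovery time constant.  ``fgc`` is a force-generating-capacity scale
analogous to PCSA, used to model atrophy; ``p_slow`` is the fraction of
cross-sectional area occupied by type I fibres.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["MuscleParams", "DERIVED_FIELDS"]

#: serialised but read-only (recomputed from the primary fields on load)
DERIVED_FIELDS = ("pCa50", "k_see")


@dataclass(frozen=True)
class MuscleParams:
    # activation dynamics
    pulse_width: float = 0.0048
    tau1: float = 0.0422
    tau2: float = 0.256
    a50: float = 0.1025
    nH: float = 3.0
    inact_A: float = 0.20
    inact_r: float = 0.350
    # contractile element
    vmax: float = 6.0
    aP0: float = 0.10
    ecc_c: float = 1.8
    ecc_k: float = 0.8
    ecc_q: float = 7.0
    # force-length breakpoints (piecewise linear, in L0)
    fl_zero_low: float = 0.35
    fl_plateau_low: float = 0.90
    fl_plateau_high: float = 1.05
    fl_zero_high: float = 1.8
    # parallel elastic element
    k_pee: float = 4.0
    l_slack_pee: float = 0.98
    eps_pee: float = 0.57
    # series elastic element
    eps_see: float = 0.05
    see_exponent: float = 2.0
    L0: float = 50.0
    L_see: float = 300.0
    # study-level scales
    fgc: float = 1.0
    p_slow: float = 0.60

    def __post_init__(self) -> None:
        positive = (
            "pulse_width", "tau1", "tau2", "inact_r", "vmax", "aP0",
            "ecc_q", "k_pee", "l_slack_pee", "eps_pee", "eps_see",
            "see_exponent", "L0", "L_see",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.a50 < 1:
            raise ValueError("a50 must lie in (0, 1)")
        if self.nH < 1:
            raise ValueError("nH must be >= 1")
        if not 0 <= self.fgc <= 1:
            raise ValueError("fgc must lie in [0, 1]")
        if not 0 <= self.p_slow <= 1:
            raise ValueError("p_slow must lie in [0, 1]")
        if not 0 <= self.inact_A <= 1:
            raise ValueError("inact_A must lie in [0, 1]")
        if abs(self.ecc_c - self.ecc_k - 1.0) > 1e-9:
            raise ValueError("eccentric constants must satisfy c - k = 1")
        if not (0 < self.fl_zero_low < self.fl_plateau_low
                <= self.fl_plateau_high < self.fl_zero_high):
            raise ValueError("force-length breakpoints must be ordered")

    # -- derived quantities -------------------------------------------------

    @property
    def pCa50(self) -> float:
        """Ca2+ sensitivity as pCa; activator saturation (a=1) is pCa 5."""
        return 5.0 - math.log10(self.a50)

    @property
    def k_see(self) -> float:
        """Normalised SEE stiffness in P0 per L0 of deformation at P0."""
        return self.L0 / (self.eps_see * self.L_see)

    @property
    def see_deformation_at_p0(self) -> float:
        """SEE deformation at maximal force, in mm."""
        return self.eps_see * self.L_see

    # -- functional updates -------------------------------------------------

    def replace(self, **changes: float) -> "MuscleParams":
        return dataclasses.replace(self, **changes)

    def with_k_see(self, k_see: float) -> "MuscleParams":
        """Return a copy with the SEE deformation axis rescaled to ``k_see``."""
        if k_see <= 0:
            raise ValueError("k_see must be strictly positive")
        return self.replace(eps_see=self.L0 / (k_see * self.L_see))

    def with_pca50(self, pca50: float) -> "MuscleParams":
        return self.replace(a50=10.0 ** (5.0 - pca50))

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["pCa50"] = self.pCa50
        out["k_see"] = self.k_see
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "MuscleParams":
        payload = {k: v for k, v in data.items() if k not in DERIVED_FIELDS}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - valid
        if unknown:
            raise ValueError(f"unknown parameter field(s): {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "MuscleParams":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("parameter YAML must contain a mapping")
        return cls.from_dict(data)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text
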