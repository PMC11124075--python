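"""sobEDAw recombination of DFT component energies into SAPT-like terms.

The DFT energy decomposition splits the host-guest interaction energy into
electrostatic (els), exchange (x), Pauli repulsion (rep), orbital (orb), DFT
correlation (dftc), and dispersion-correction (dc) components.  To make the
result comparable with symmetry-adapted perturbation theory, a weight

    omega = exp[-r (dc/els - a)] (1 - c) + c

partitions the correlation energy between the dispersion term and the
exchange-repulsion term:

    E_xrep = (x + rep) + (1 - omega) dftc
    E_disp = dc + omega dftc

The total interaction energy E_int = els + x + rep + orb + dftc + dc is
independent of omega, as is the sum E_xrep + E_disp - (x + rep) - els ...
i.e. the correlation energy is merely re-apportioned.  Adding geometry
deformation, solvation, and thermal-correction bookkeeping gives the
binding free energy

    G_bind = E_int + (def_host + def_guest) + (polar + nonpolar) + G_corr.

All energies are in kcal/mol.  The only built-in weight-parameter preset is
the B3LYP-D3(BJ)/6-31+G(d,p) set (r = 2.571, a = 0.071, c = 0.575); other
levels of theory require user-supplied parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError

__all__ = [
    "SobEDAComponents",
    "SobEDAWParams",
    "SobEDAWResult",
    "PARAM_PRESETS",
    "DEFAULT_LEVEL",
    "omega_weight",
    "recombine",
    "binding_free_energy",
]

DEFAULT_LEVEL = "B3LYP-D3(BJ)/6-31+G(d,p)"

#: Weight parameters (r, a, c) keyed by level-of-theory label.
PARAM_PRESETS = {DEFAULT_LEVEL: (2.571, 0.071, 0.575)}


@dataclass(frozen=True)
class SobEDAWParams:
    """Dimensionless omega-weight parameters."""

    r: float = PARAM_PRESETS[DEFAULT_LEVEL][0]
    a: float = PARAM_PRESETS[DEFAULT_LEVEL][1]
    c: float = PARAM_PRESETS[DEFAULT_LEVEL][2]

    def __post_init__(self):
        if self.r <= 0:
            raise ParameterError("require r > 0")
        if not 0.0 <= self.c <= 1.0:
            raise ParameterError("require c in [0, 1]")

    @classmethod
    def from_level(cls, level: str) -> "SobEDAWParams":
        try:
            r, a, c = PARAM_PRESETS[level]
        except KeyError:
            raise ParameterError(
                f"no built-in omega parameters for level {level!r}; "
                "supply r, a, c explicitly"
            ) from None
        return cls(r=r, a=a, c=c)


@dataclass(frozen=True)
class SobEDAComponents:
    """DFT component energies plus bookkeeping terms (kcal/mol)."""

    els: float
    x: float
    rep: float
    orb: float
    dftc: float
    dc: float
    def_h: float = 0.0
    def_g: float = 0.0
    polar: float = 0.0
    nonpolar: float = 0.0
    gcorr: float = 0.0

    def __post_init__(self):
        for name in ("els", "x", "rep", "orb", "dftc", "dc", "def_h",
                     "def_g", "polar", "nonpolar", "gcorr"):
            if not math.isfinite(getattr(self, name)):
                raise ParameterError(f"component {name} is not finite")


@dataclass(frozen=True)
class SobEDAWResult:
    """Recombined SAPT-like terms and the binding-free-energy ledger."""

    omega: float
    xrep: float
    disp: float
    c_total: float
    eint: float
    def_total: float
    sol_total: float
    gbind: float


def omega_weight(dc: float, els: float,
                 params: SobEDAWParams = SobEDAWParams()) -> float:
    """Correlation-partition weight omega = exp[-r(dc/els - a)](1-c) + c."""
    if els == 0.0:
        raise ParameterError("omega is undefined for els = 0 (dc/els ratio)")
    return math.exp(-params.r * (dc / els - params.a)) * (1.0 - params.c) + params.c


def recombine(components: SobEDAComponents,
              params: SobEDAWParams = SobEDAWParams()) -> SobEDAWResult:
    """Full sobEDAw recombination of one component set."""
    w = omega_weight(components.dc, components.els, params)
    xrep = (components.x + components.rep) + (1.0 - w) * components.dftc
    disp = components.dc + w * components.dftc
    c_total = components.dftc + components.dc
    eint = (components.els + components.x + components.rep + components.orb
            + components.dftc + components.dc)
    def_total = components.def_h + components.def_g
    sol_total = components.polar + components.nonpolar
    gbind = eint + def_total + sol_total + components.gcorr
    return SobEDAWResult(omega=w, xrep=xrep, disp=disp, c_total=c_total,
                         eint=eint, def_total=def_total, sol_total=sol_total,
                         gbind=gbind)


def binding_free_energy(eint: float, def_total: float, sol_total: float,
                        gcorr: float) -> float:
    """Ledger sum G_bind = E_int + E_def + E_sol + G_corr.

    The terms are passed explicitly so that printed aggregates (which may
    differ from re-summed sub-components by one-decimal rounding) can be
    used directly; ``recombine`` covers the from-components path.
    """
    return eint + def_total + sol_total + gcorr
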