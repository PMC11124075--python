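"""Force-field energy decomposition (EDA-FF) of inter-fragment interactions.

The interaction energy between two rigid fragments A and B is summed over
all inter-fragment atom pairs, with no cutoff and no exclusions (the
fragments are different molecules):

    E_FF = E_elec + E_vdw
    E_elec = k_C sum_ij Q_i Q_j / r_ij
    E_vdw  = sum_ij eps_ij [ (Rmin_ij / r_ij)^12 - 2 (Rmin_ij / r_ij)^6 ]

with the Amber-family Coulomb constant k_C = 332.0522 kcal A / (mol e^2) and
Lorentz-Berthelot-style combination eps_ij = sqrt(eps_i eps_j),
Rmin_ij = Rmin_i/2 + Rmin_j/2.  The repulsive (r^-12) and dispersive (r^-6)
parts are reported separately; the dispersion carries the factor 2 so that
the pair potential reaches its minimum -eps_ij exactly at Rmin_ij.  A
literal form without that factor is available for sensitivity checks via
``literal_lj=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError
from .structure import MolecularStructure

__all__ = [
    "COULOMB_CONSTANT",
    "ChargeSet",
    "LJParamSet",
    "Fragment",
    "EDAFFResult",
    "combine_lj",
    "pairwise_eda",
    "blend_charges",
    "load_fragment_params",
]

#: Amber's Coulomb conversion constant (18.2223^2), kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0522


@dataclass(frozen=True)
class ChargeSet:
    """Per-atom partial charges (elementary charge units) for one fragment."""

    charges: np.ndarray
    label: str = "custom"

    def __post_init__(self):
        q = np.asarray(self.charges, dtype=float)
        if q.ndim != 1 or not np.all(np.isfinite(q)):
            raise ParameterError("charges must be a finite 1-D array")
        object.__setattr__(self, "charges", q)

    def __len__(self):
        return self.charges.size


@dataclass(frozen=True)
class LJParamSet:
    """Per-atom Lennard-Jones well depths (kcal/mol) and Rmin/2 values (A)."""

    epsilon: np.ndarray
    rmin_half: np.ndarray

    def __post_init__(self):
        eps = np.asarray(self.epsilon, dtype=float)
        rmh = np.asarray(self.rmin_half, dtype=float)
        if eps.shape != rmh.shape or eps.ndim != 1:
            raise ParameterError("epsilon and rmin_half must be 1-D and aligned")
        if np.any(eps < 0) or np.any(rmh <= 0):
            raise ParameterError("require epsilon >= 0 and rmin_half > 0")
        object.__setattr__(self, "epsilon", eps)
        object.__setattr__(self, "rmin_half", rmh)

    def __len__(self):
        return self.epsilon.size


@dataclass(frozen=True)
class Fragment:
    """A molecular fragment with its charge and LJ parameter tables."""

    structure: MolecularStructure
    charges: ChargeSet
    lj: LJParamSet

    def __post_init__(self):
        n = self.structure.n_atoms
        if len(self.charges) != n or len(self.lj) != n:
            raise ParameterError(
                "charge/LJ tables must provide one entry per fragment atom"
            )


@dataclass(frozen=True)
class EDAFFResult:
    """EDA-FF terms (kcal/mol); vdw = rep + disp, total = elec + vdw."""

    elec: float
    rep: float
    disp: float

    @property
    def vdw(self) -> float:
        return self.rep + self.disp

    @property
    def total(self) -> float:
        return self.elec + self.vdw


def combine_lj(eps_i: float, rmin_half_i: float,
               eps_j: float, rmin_half_j: float) -> tuple[float, float]:
    """Pair LJ parameters: geometric-mean well depth, summed Rmin/2 values."""
    return float(np.sqrt(eps_i * eps_j)), float(rmin_half_i + rmin_half_j)


def pairwise_eda(frag_a: Fragment, frag_b: Fragment,
                 coulomb_constant: float = COULOMB_CONSTANT,
                 literal_lj: bool = False) -> EDAFFResult:
    """Inter-fragment Coulomb + LJ 12-6 decomposition over all atom pairs."""
    xa, xb = frag_a.structure.positions, frag_b.structure.positions
    r = cdist(xa, xb)
    if r.min() < 1e-6:
        raise ParameterError(
            "coincident atoms across fragments (r < 1e-6 A); "
            "fragments must not overlap"
        )
    qq = np.outer(frag_a.charges.charges, frag_b.charges.charges)
    elec = coulomb_constant * float((qq / r).sum())

    eps = np.sqrt(np.outer(frag_a.lj.epsilon, frag_b.lj.epsilon))
    rmin = frag_a.lj.rmin_half[:, None] + frag_b.lj.rmin_half[None, :]
    ratio6 = (rmin / r) ** 6
    rep = float((eps * ratio6 ** 2).sum())
    disp_factor = 1.0 if literal_lj else 2.0
    disp = -disp_factor * float((eps * ratio6).sum())
    return EDAFFResult(elec=elec, rep=rep, disp=disp)


def blend_charges(q_gas: ChargeSet, q_solvent: ChargeSet,
                  delta: float = 0.5) -> ChargeSet:
    """RESP2-style blend q = delta*q_solvent + (1-delta)*q_gas per atom.

    The default delta = 0.5 averages gas- and water-phase charge sets.
    """
    if len(q_gas) != len(q_solvent):
        raise ParameterError("gas and solvent charge sets differ in length")
    q = delta * q_solvent.charges + (1.0 - delta) * q_gas.charges
    return ChargeSet(charges=q, label="RESP2")


def load_fragment_params(path) -> tuple[ChargeSet, LJParamSet]:
    """Read a per-atom parameter table.

    JSON: an object with ``charge_e``, ``epsilon_kcal``, ``rmin_half_A``
    arrays (optionally ``label``).  Plain text: whitespace-delimited columns
    ``serial charge_e epsilon_kcal rmin_half_A``, ``#`` comments allowed.
    """
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        return (
            ChargeSet(np.asarray(data["charge_e"], dtype=float),
                      label=data.get("label", "custom")),
            LJParamSet(np.asarray(data["epsilon_kcal"], dtype=float),
                       np.asarray(data["rmin_half_A"], dtype=float)),
        )
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParameterError(
                f"{path}: line {lineno}: expected 4 columns "
                "(serial charge_e epsilon_kcal rmin_half_A)"
            )
        rows.append([float(x) for x in parts[1:]])
    if not rows:
        raise ParameterError(f"{path}: empty parameter table")
    arr = np.asarray(rows)
    return ChargeSet(arr[:, 0]), LJParamSet(arr[:, 1], arr[:, 2])
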