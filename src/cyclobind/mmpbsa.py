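"""MM-PBSA binding-energy bookkeeping.

The end-state binding energy decomposes as

    E_MM   = E_bonded + E_nonbonded = (E_bonded,H + E_bonded,G) + E_vdW + E_elec
    G_sol  = G_polar + G_nonpolar
    E_bind = E_MM + G_sol

The entropy term -T*dS is an explicit optional field that defaults to
absent; when absent the output is a binding *energy* (e_bind), never
relabelled a free energy.  Components may be scalars (table means) or
aligned per-frame series, in which case uncertainties come from block
averaging.  The polar/nonpolar solvation terms are upstream-solver outputs
consumed as numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .stats import BlockAverage, block_average

__all__ = [
    "MMPBSAComponents",
    "MMPBSASummary",
    "ledger",
    "consistency_check",
]

_FIELDS = ("bonded_h", "bonded_g", "vdw", "elec", "polar", "nonpolar")


@dataclass(frozen=True)
class MMPBSAComponents:
    """Per-term components (kcal/mol): scalars or aligned per-frame series."""

    bonded_h: float | np.ndarray
    bonded_g: float | np.ndarray
    vdw: float | np.ndarray
    elec: float | np.ndarray
    polar: float | np.ndarray
    nonpolar: float | np.ndarray
    minus_t_ds: float | None = None  # optional entropy term, absent by default

    def as_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        length = None
        for name in _FIELDS:
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if not np.all(np.isfinite(v)):
                raise ParameterError(f"MM-PBSA component {name} is not finite")
            if length is None or v.size == length:
                length = max(length or 1, v.size)
            elif v.size != 1:
                raise ParameterError("per-frame component series are misaligned")
            out[name] = v
        return {k: (np.full(length, v[0]) if v.size == 1 else v)
                for k, v in out.items()}

    def __add__(self, other: "MMPBSAComponents") -> "MMPBSAComponents":
        return MMPBSAComponents(*[
            np.asarray(getattr(self, f)) + np.asarray(getattr(other, f))
            for f in _FIELDS
        ])


@dataclass(frozen=True)
class MMPBSASummary:
    """Aggregate terms; sd fields are block-averaged SDs (None for scalars)."""

    bonded: float
    nonbonded: float
    e_mm: float
    g_sol: float
    e_bind: float
    g_bind: float | None = None  # only when -T*dS was supplied
    sd: dict | None = None


def ledger(components: MMPBSAComponents, n_blocks: int = 5) -> MMPBSASummary:
    """Sum the decomposition ledger; block-average uncertainties for series."""
    arrs = components.as_arrays()
    per_frame = next(iter(arrs.values())).size > 1
    bonded = arrs["bonded_h"] + arrs["bonded_g"]
    nonbonded = arrs["vdw"] + arrs["elec"]
    e_mm = bonded + nonbonded
    g_sol = arrs["polar"] + arrs["nonpolar"]
    e_bind = e_mm + g_sol

    sd = None
    if per_frame:
        sd = {name: block_average(series, n_blocks=n_blocks).sd_of_block_means
              for name, series in (("bonded", bonded), ("nonbonded", nonbonded),
                                   ("e_mm", e_mm), ("g_sol", g_sol),
                                   ("e_bind", e_bind))}
    g_bind = None
    if components.minus_t_ds is not None:
        g_bind = float(e_bind.mean()) + float(components.minus_t_ds)
    return MMPBSASummary(
        bonded=float(bonded.mean()), nonbonded=float(nonbonded.mean()),
        e_mm=float(e_mm.mean()), g_sol=float(g_sol.mean()),
        e_bind=float(e_bind.mean()), g_bind=g_bind, sd=sd,
    )


#: Additivity relations checked against a printed table: each aggregate is
#: recomputed from its immediate children.
_RELATIONS = {
    "bonded": ("bonded_h", "bonded_g"),
    "nonbonded": ("vdw", "elec"),
    "e_mm": ("bonded", "nonbonded"),
    "g_sol": ("polar", "nonpolar"),
    "e_bind": ("e_mm", "g_sol"),
}


def consistency_check(column: dict, tolerance: float = 0.15,
                      exact_band: float = 0.05) -> list[dict]:
    """Verify additivity of one printed table column.

    ``column`` maps term names (bonded_h, bonded_g, vdw, elec, polar,
    nonpolar plus the printed aggregates bonded, nonbonded, e_mm, g_sol,
    e_bind) to printed values.  Each aggregate is recomputed from its
    immediate children; deviations within ``exact_band`` pass, within
    ``tolerance`` are flagged as rounding of unrounded sums, and larger ones
    fail.  Returns one report row per relation.
    """
    missing = [k for ks in _RELATIONS.values() for k in ks if k not in column]
    missing += [k for k in _RELATIONS if k not in column]
    if missing:
        raise ParameterError(f"table column is missing rows: {sorted(set(missing))}")
    report = []
    for agg, children in _RELATIONS.items():
        recomputed = sum(float(column[c]) for c in children)
        printed = float(column[agg])
        dev = printed - recomputed
        if abs(dev) <= exact_band:
            status = "pass"
        elif abs(dev) <= tolerance:
            status = "rounding"
        else:
            status = "fail"
        report.append({
            "quantity": agg, "printed": printed,
            "recomputed": recomputed, "deviation": dev, "status": status,
        })
    return report
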