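"""Table-wide consistency suites over the bundled (or user) component tables.

Each check recomputes a printed aggregate from its printed immediate inputs
and classifies the deviation: within ``exact_band`` it passes, within
``tolerance`` it is flagged as rounding of an unrounded sum (the printed
tables carry one decimal), and beyond that it fails.
"""

from __future__ import annotations

from .datasets import (
    load_edaff_table,
    load_mmpbsa_table,
    load_sobedaw_table,
    mmpbsa_column,
    sobedaw_column,
)
from .mmpbsa import consistency_check
from .sobeda import SobEDAWParams, binding_free_energy, recombine

__all__ = [
    "check_mmpbsa_table",
    "check_sobedaw_table",
    "check_edaff_table",
]

_HOSTS = ("alpha", "beta", "gamma")
_MODES = ("BS", "BP")
_PHASES = ("gas", "water")


def _status(dev: float, exact_band: float, tolerance: float) -> str:
    if abs(dev) <= exact_band:
        return "pass"
    return "rounding" if abs(dev) <= tolerance else "fail"


def check_mmpbsa_table(path=None, tolerance: float = 0.15,
                       exact_band: float = 0.05) -> list[dict]:
    """Additivity of every host/mode column of the MM-PBSA table."""
    table = load_mmpbsa_table(path)
    report = []
    for host in _HOSTS:
        for mode in _MODES:
            column = mmpbsa_column(host, mode, table=table)
            for row in consistency_check(column, tolerance=tolerance,
                                         exact_band=exact_band):
                row.update(host=host, mode=mode)
                report.append(row)
    return report


def check_sobedaw_table(path=None, tolerance: float = 0.15,
                        exact_band: float = 0.05,
                        params: SobEDAWParams = SobEDAWParams()) -> list[dict]:
    """Recombination of every sobEDAw column against its printed aggregates.

    The binding free energy is recomputed from its *printed* immediate
    inputs (eint, def, sol) rather than re-summed sub-components, so a
    rounding flag lower in the ledger does not cascade into gbind.
    """
    table = load_sobedaw_table(path)
    report = []
    for phase in _PHASES:
        for host in _HOSTS:
            for mode in _MODES:
                comps, printed = sobedaw_column(host, mode, phase, table=table)
                res = recombine(comps, params)
                recomputed = {
                    "xrep": res.xrep,
                    "c": res.c_total,
                    "disp": res.disp,
                    "eint": res.eint,
                    "def": res.def_total,
                    "sol": res.sol_total,
                }
                if "eint" in printed:
                    recomputed["gbind"] = binding_free_energy(
                        printed["eint"],
                        printed.get("def", res.def_total),
                        printed.get("sol", res.sol_total),
                        comps.gcorr)
                for term, value in recomputed.items():
                    if term not in printed:
                        continue
                    dev = printed[term] - value
                    report.append({
                        "host": host, "mode": mode, "phase": phase,
                        "quantity": term, "printed": printed[term],
                        "recomputed": value, "deviation": dev,
                        "status": _status(dev, exact_band, tolerance),
                    })
    return report


def check_edaff_table(path=None, tolerance: float = 0.15,
                      exact_band: float = 0.05) -> list[dict]:
    """Additivity ff = elec + rep + disp of every EDA-FF table row."""
    table = load_edaff_table(path)
    report = []
    for _, row in table.iterrows():
        recomputed = float(row["elec"] + row["rep"] + row["disp"])
        dev = float(row["ff"]) - recomputed
        report.append({
            "host": row["host"], "charge_method": row["charge_method"],
            "phase": row["phase"], "mode": row["mode"],
            "quantity": "ff", "printed": float(row["ff"]),
            "recomputed": recomputed, "deviation": dev,
            "status": _status(dev, exact_band, tolerance),
        })
    return report
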