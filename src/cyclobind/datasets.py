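"""Bundled reference tables and their loaders.

Three published component tables ship with the package as plain CSV: the
MM-PBSA decomposition of the three cyclodextrin:DOPO complexes in both
binding modes, the EDA-FF decomposition of the QM-optimized complexes under
five charge methods, and the sobEDAw DFT component energies in gas and
water.  These are *inputs* to the bookkeeping code (the upstream MD/QM
calculations are out of scope); the recombination and consistency machinery
recomputes every aggregate from them at run time.

Hosts are labelled ``alpha``/``beta``/``gamma``, binding modes ``BS``/``BP``
(guest B ring near the secondary / primary rim), phases ``gas``/``water``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import ParameterError
from .sobeda import SobEDAComponents

__all__ = [
    "load_sobedaw_table",
    "load_mmpbsa_table",
    "load_edaff_table",
    "sobedaw_column",
    "mmpbsa_column",
    "SOBEDAW_INPUT_TERMS",
    "SOBEDAW_PRINTED_AGGREGATES",
]

#: Terms of the sobEDAw table that are inputs to the recombination.
SOBEDAW_INPUT_TERMS = ("els", "x", "rep", "orb", "dftc", "dc",
                       "def_h", "def_g", "polar", "nonpolar", "gcorr")
#: Terms that are printed aggregates, reproduced (not consumed) by the code.
SOBEDAW_PRINTED_AGGREGATES = ("xrep", "c", "disp", "eint", "def", "sol", "gbind")


def _read_bundled(name: str) -> pd.DataFrame:
    with resources.files("cyclobind.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_sobedaw_table(path=None) -> pd.DataFrame:
    """Long-format sobEDAw component table (host, mode, phase, term, value)."""
    df = pd.read_csv(path) if path is not None else _read_bundled(
        "sobedaw_components.csv")
    required = {"host", "mode", "phase", "term", "value"}
    if not required.issubset(df.columns):
        # accept wide format: one row per (host, mode, phase), one column per term
        id_cols = [c for c in ("host", "mode", "phase") if c in df.columns]
        if not id_cols:
            raise ParameterError(
                "sobEDAw table needs host/mode/phase/term/value columns "
                "(long) or host/mode/phase plus one column per term (wide)"
            )
        df = df.melt(id_vars=id_cols, var_name="term", value_name="value")
    return df


def load_mmpbsa_table(path=None) -> pd.DataFrame:
    """Long-format MM-PBSA table (host, mode, term, value[, sd])."""
    df = pd.read_csv(path) if path is not None else _read_bundled(
        "mmpbsa_components.csv")
    if not {"host", "mode", "term", "value"}.issubset(df.columns):
        raise ParameterError("MM-PBSA table needs host/mode/term/value columns")
    return df


def load_edaff_table(path=None) -> pd.DataFrame:
    """EDA-FF table (host, charge_method, phase, mode, elec, rep, disp, ff)."""
    df = pd.read_csv(path) if path is not None else _read_bundled(
        "edaff_components.csv")
    needed = {"host", "charge_method", "phase", "mode", "elec", "rep", "disp", "ff"}
    if not needed.issubset(df.columns):
        raise ParameterError(f"EDA-FF table needs columns {sorted(needed)}")
    return df


def _column_dict(df: pd.DataFrame, **filters) -> dict[str, float]:
    mask = pd.Series(True, index=df.index)
    for key, val in filters.items():
        mask &= df[key] == val
    sub = df[mask]
    if sub.empty:
        raise ParameterError(f"no table rows match {filters}")
    return dict(zip(sub["term"], sub["value"].astype(float)))


def sobedaw_column(host: str, mode: str, phase: str,
                   table: pd.DataFrame | None = None,
                   ) -> tuple[SobEDAComponents, dict[str, float]]:
    """One table column as (input components, printed aggregates)."""
    df = table if table is not None else load_sobedaw_table()
    col = _column_dict(df, host=host, mode=mode, phase=phase)
    missing = [t for t in SOBEDAW_INPUT_TERMS if t not in col]
    if missing:
        raise ParameterError(
            f"sobEDAw column {host}/{mode}/{phase} lacks terms {missing}")
    components = SobEDAComponents(**{t: col[t] for t in SOBEDAW_INPUT_TERMS})
    printed = {t: col[t] for t in SOBEDAW_PRINTED_AGGREGATES if t in col}
    return components, printed


def mmpbsa_column(host: str, mode: str,
                  table: pd.DataFrame | None = None) -> dict[str, float]:
    """One MM-PBSA table column as a term -> printed value mapping."""
    df = table if table is not None else load_mmpbsa_table()
    return _column_dict(df, host=host, mode=mode)
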