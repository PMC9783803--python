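"""QTAIM bond-critical-point bookkeeping and SAPT component accounting.

These are the static (single-geometry) descriptors of hydrogen-bond
strength and character:

* The Espinosa estimate of a closed-shell bond energy from the potential
  energy density at the bond critical point, E = ½ |V_BCP|, reported here
  in kcal/mol (hartree → kcal/mol with 627.5095).  Shared-shell (covalent)
  bonds, flagged by a negative density Laplacian, are outside the
  correlation's validity and return no value.
* The standard QTAIM covalency classification: ∇²ρ < 0 → shared-shell
  covalent; ∇²ρ > 0 with H_BCP > 0 → closed-shell electrostatic;
  ∇²ρ > 0 with H_BCP < 0 → closed-shell with partial covalency.
* SAPT component totals E_elst + E_exch + E_ind + E_disp and a
  consistency audit against an independently reported total, including
  the sign of the steric balance E_elst + E_exch.

Inputs are delimited-text tables of tabulated descriptors (the package
performs no electronic-structure computation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import DataError, FormatError
from .units import HARTREE_TO_KCAL

logger = logging.getLogger(__name__)

__all__ = [
    "CriticalPoint",
    "SAPTComponents",
    "espinosa_energy",
    "classify_interaction",
    "sapt_total",
    "audit_sapt",
    "read_descriptor_tables",
]

#: |H_BCP| below this (a.u.) is treated as an exact zero in classification
H_ZERO_THRESHOLD = 1.0e-6

INTERACTION_CLASSES = (
    "shared_shell_covalent",
    "closed_shell_electrostatic",
    "closed_shell_partially_covalent",
)


@dataclass(frozen=True)
class CriticalPoint:
    """One electron-density critical point (atomic units throughout)."""

    label: str
    rho: float                    # e·a0⁻³
    laplacian: float              # e·a0⁻⁵
    V_BCP: float                  # hartree·a0⁻³
    H_BCP: Optional[float] = None  # a.u.
    cp_type: str = "BCP"
    system: str = ""

    def __post_init__(self):
        if self.cp_type not in ("BCP", "RCP"):
            raise DataError(f"unknown critical point type {self.cp_type!r}")
        if self.rho <= 0:
            raise DataError(f"{self.label}: electron density must be positive")


@dataclass(frozen=True)
class SAPTComponents:
    """One SAPT decomposition row, kcal/mol."""

    E_elst: float
    E_exch: float
    E_ind: float
    E_disp: float
    E_total_reported: Optional[float] = None
    label: str = ""
    level_label: str = "SAPT2+/aDZ"

    def __post_init__(self):
        for name in ("E_elst", "E_exch", "E_ind", "E_disp"):
            if not math.isfinite(getattr(self, name)):
                raise DataError(f"{self.label}: non-finite {name}")


def espinosa_energy(cp: CriticalPoint, signed: bool = False) -> Optional[float]:
    """Espinosa bond energy, kcal/mol, or ``None`` for shared-shell bonds.

    E = ½ |V_BCP| × 627.5095 for closed-shell contacts (∇²ρ > 0); by
    default the positive magnitude is returned, ``signed=True`` gives the
    (negative) stabilization energy.
    """
    if cp.cp_type != "BCP":
        raise TypeError("Espinosa energy is defined at bond critical points only")
    if cp.laplacian < 0:
        return None
    energy = 0.5 * abs(cp.V_BCP) * HARTREE_TO_KCAL
    return -energy if signed else energy


def classify_interaction(cp: CriticalPoint) -> str:
    """QTAIM covalency class of a BCP (see module docstring for the rules)."""
    if cp.cp_type != "BCP":
        raise TypeError("classification is defined at bond critical points only")
    if cp.H_BCP is None:
        raise DataError(f"{cp.label}: H_BCP required for classification")
    if cp.laplacian < 0:
        return "shared_shell_covalent"
    h = cp.H_BCP
    if abs(h) < H_ZERO_THRESHOLD:
        logger.info("%s: H_BCP within zero threshold; classed electrostatic",
                    cp.label)
        h = 0.0
    return ("closed_shell_electrostatic" if h >= 0
            else "closed_shell_partially_covalent")


def sapt_total(c: SAPTComponents) -> float:
    """Total interaction energy as the sum of the four components."""
    return c.E_elst + c.E_exch + c.E_ind + c.E_disp


def audit_sapt(c: SAPTComponents, tol: float = 0.01) -> dict:
    """Consistency report: component sum vs reported total, steric balance.

    Flags ``|sum − reported| > tol`` (kcal/mol) and reports whether the
    electrostatics + exchange balance is net repulsive.
    """
    if c.E_total_reported is None:
        raise DataError(f"{c.label}: no reported total to audit against")
    total = sapt_total(c)
    discrepancy = total - c.E_total_reported
    steric = c.E_elst + c.E_exch
    return {
        "label": c.label,
        "component_sum": total,
        "reported_total": c.E_total_reported,
        "discrepancy": discrepancy,
        "tolerance": tol,
        "consistent": abs(discrepancy) <= tol,
        "steric_balance": steric,
        "steric_repulsive": steric > 0,
    }


# ---------------------------------------------------------------------------
# table ingestion
# ---------------------------------------------------------------------------

_UNICODE_FIXES = str.maketrans({"−": "-", "–": "-", "—": "-"})

_QTAIM_COLUMNS = {"label", "rho", "laplacian", "V_BCP"}
_SAPT_COLUMNS = {"label", "E_elst", "E_exch", "E_ind", "E_disp"}
_KNOWN = _QTAIM_COLUMNS | _SAPT_COLUMNS | {
    "H_BCP", "cp_type", "system", "E1", "E_total", "level"}


def _clean_cell(val):
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return None
    if isinstance(val, str):
        return val.translate(_UNICODE_FIXES).strip()
    return val


def _to_float(val, row_label, column):
    val = _clean_cell(val)
    if val is None or val == "" or val == "-" or (
            isinstance(val, float) and math.isnan(val)):
        return None
    try:
        return float(val)
    except (TypeError, ValueError):
        raise FormatError(
            f"row {row_label!r}: non-numeric value {val!r} in column {column!r}"
        ) from None


def read_descriptor_tables(path) -> list:
    """Read a delimited descriptor table into typed records.

    The header decides the flavour: QTAIM tables need columns
    ``label, rho, laplacian, V_BCP`` (``H_BCP``, ``cp_type``, ``system``,
    ``E1`` optional) and yield :class:`CriticalPoint` records; SAPT tables
    need ``label, E_elst, E_exch, E_ind, E_disp`` (``E_total`` optional)
    and yield :class:`SAPTComponents`.  Unicode minus signs and ellipses in
    labels are normalized.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         skip_blank_lines=True, dtype=str)
    except Exception as exc:
        raise FormatError(f"{path.name}: cannot parse table ({exc})") from None
    df.columns = [str(c).strip() for c in df.columns]
    cols = set(df.columns)
    unknown = cols - _KNOWN
    if unknown:
        raise FormatError(
            f"{path.name}: unknown column(s) {sorted(unknown)}; "
            f"known columns: {sorted(_KNOWN)}")
    if _QTAIM_COLUMNS <= cols:
        return _parse_qtaim(df)
    if _SAPT_COLUMNS <= cols:
        return _parse_sapt(df)
    missing_q = _QTAIM_COLUMNS - cols
    missing_s = _SAPT_COLUMNS - cols
    raise FormatError(
        f"{path.name}: header matches neither table type "
        f"(QTAIM missing {sorted(missing_q)}, SAPT missing {sorted(missing_s)})")


def _parse_qtaim(df) -> list[CriticalPoint]:
    records = []
    for _, row in df.iterrows():
        label = _clean_cell(row["label"])
        records.append(CriticalPoint(
            label=label,
            rho=_to_float(row["rho"], label, "rho"),
            laplacian=_to_float(row["laplacian"], label, "laplacian"),
            V_BCP=_to_float(row["V_BCP"], label, "V_BCP"),
            H_BCP=_to_float(row.get("H_BCP"), label, "H_BCP"),
            cp_type=_clean_cell(row.get("cp_type")) or "BCP",
            system=_clean_cell(row.get("system")) or "",
        ))
    return records


def _parse_sapt(df) -> list[SAPTComponents]:
    records = []
    for _, row in df.iterrows():
        label = _clean_cell(row["label"])
        records.append(SAPTComponents(
            E_elst=_to_float(row["E_elst"], label, "E_elst"),
            E_exch=_to_float(row["E_exch"], label, "E_exch"),
            E_ind=_to_float(row["E_ind"], label, "E_ind"),
            E_disp=_to_float(row["E_disp"], label, "E_disp"),
            E_total_reported=_to_float(row.get("E_total"), label, "E_total"),
            label=label,
        ))
    return records
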