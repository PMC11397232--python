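"""Binding-energy bookkeeping for template-monomer complexes.

The binding energy of a complex is

    dE_bind = E_complex - E_template - sum(E_monomer),

with all electronic energies computed upstream by a quantum-chemistry
package (geometry optimization, single-point energies, counterpoise/BSSE
correction all happen there; this module only records whether the inputs
are CP-corrected).  Negative dE_bind means favorable binding, and a more
negative value ranks a complex as a stronger binder.

Energies may be supplied in kJ/mol or hartree; results are always reported
in kJ/mol (1 hartree = 2625.4996 kJ/mol, CODATA).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "EnergyUnits",
    "EnergyTerms",
    "ComplexRow",
    "HARTREE_TO_KJ_PER_MOL",
    "delta_e_bind",
    "complex_table",
]

HARTREE_TO_KJ_PER_MOL = 2625.4996


class EnergyUnits(str, enum.Enum):
    KJ_PER_MOL = "kJ/mol"
    HARTREE = "hartree"


@dataclass(frozen=True)
class EnergyTerms:
    """Electronic energies of a complex and its isolated components.

    All terms must share one unit.  ``cp_corrected`` is a provenance flag:
    it records that the upstream QC applied the counterpoise correction; it
    changes no arithmetic here.
    """

    e_complex: float
    e_template: float
    e_monomers: tuple[float, ...]
    units: EnergyUnits = EnergyUnits.KJ_PER_MOL
    cp_corrected: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", EnergyUnits(self.units))
        object.__setattr__(self, "e_monomers", tuple(self.e_monomers))
        if len(self.e_monomers) < 1:
            raise ValueError("at least one monomer energy is required")


def delta_e_bind(terms: EnergyTerms) -> float:
    """dE_bind = E_complex - E_template - sum(E_monomer), in kJ/mol."""
    value = terms.e_complex - terms.e_template - sum(terms.e_monomers)
    if terms.units is EnergyUnits.HARTREE:
        value *= HARTREE_TO_KJ_PER_MOL
    return value


@dataclass(frozen=True)
class ComplexRow:
    """One template-monomer complex for the ranking table."""

    name: str
    hbond_count: int
    delta_e_kjmol: float
    bonds: tuple[tuple[str, float, float], ...] = ()
    """(label, bond length nm, bond angle deg) per hydrogen bond."""


def complex_table(rows: Sequence[ComplexRow]) -> pd.DataFrame:
    """Ranking table of complexes, strongest binder (most negative dE) first.

    One output line per hydrogen bond, with the complex name and dE repeated
    so the table stays a flat TSV; the sort is stable, so equal dE values
    keep their input order.  Empty input yields a header-only table.
    """
    columns = [
        "complex",
        "hbond_count",
        "delta_e_kjmol",
        "hbond",
        "bond_length_nm",
        "bond_angle_deg",
    ]
    ordered = sorted(rows, key=lambda r: r.delta_e_kjmol)
    records = []
    for row in ordered:
        bonds = row.bonds or ((None, None, None),)
        for label, length, angle in bonds:
            records.append(
                {
                    "complex": row.name,
                    "hbond_count": row.hbond_count,
                    "delta_e_kjmol": row.delta_e_kjmol,
                    "hbond": label,
                    "bond_length_nm": length,
                    "bond_angle_deg": angle,
                }
            )
    return pd.DataFrame(records, columns=columns)
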