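"""Chemical-system description consumed by every analysis.

A pre-polymerization box contains one template molecule (the imprinting
target, e.g. the sulfonamide drug sulfadimethoxine), a population of
functional monomers (carboxylic acids such as AA/MAA/TFMAA, or carboxylic
esters such as EMA/EHMA/MMA), optionally a crosslinker (EGDMA) and solvent.
Hydrogen bonds between these species are detected geometrically; this module
defines which atoms can participate (donor heavy atoms with their covalent
hydrogens, acceptor heavy atoms) and under which geometric criteria a
contact counts as a hydrogen bond.

Only "strong" hydrogen bonds between N and O heavy atoms are counted by
default; weak C-H...F-type contacts can be enabled by extending
``heavy_atom_elements``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "AngleConvention",
    "SiteRole",
    "MoleculeRole",
    "HBondCriteria",
    "AtomSite",
    "MoleculeGroup",
    "SystemSelection",
    "SelectionError",
    "load_selection",
    "serialize_selection",
    "infer_sites",
]


class SelectionError(ValueError):
    """Raised when a selection/config is malformed or inconsistent."""


class AngleConvention(str, enum.Enum):
    """How the angular hydrogen-bond cutoff is interpreted.

    HDA: the angle at the donor between the donor->hydrogen and
    donor->acceptor vectors must not exceed ``angle_max`` (the convention of
    the GROMACS H-bond analysis tool).

    DHA_DEVIATION: the deviation of the donor-hydrogen-acceptor angle from
    linearity (180 deg) must not exceed ``angle_max`` (the VMD convention).
    """

    HDA = "HDA"
    DHA_DEVIATION = "DHA-deviation"


class SiteRole(str, enum.Enum):
    DONOR = "donor"
    HYDROGEN = "hydrogen"
    ACCEPTOR = "acceptor"


class MoleculeRole(str, enum.Enum):
    TEMPLATE = "template"
    MONOMER = "monomer"
    CROSSLINKER = "crosslinker"
    SOLVENT = "solvent"


#: Default geometric criteria: donor-acceptor distance <= 0.35 nm and
#: donor angle <= 30 deg, strong bonds between N/O heavy atoms only.
DEFAULT_D_MAX_NM = 0.35
DEFAULT_ANGLE_MAX_DEG = 30.0
DEFAULT_HEAVY_ELEMENTS = frozenset({"N", "O"})


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (inclusive cutoffs)."""

    d_max: float = DEFAULT_D_MAX_NM
    angle_max: float = DEFAULT_ANGLE_MAX_DEG
    angle_convention: AngleConvention = AngleConvention.HDA
    heavy_atom_elements: frozenset[str] = DEFAULT_HEAVY_ELEMENTS

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise SelectionError(f"d_max must be > 0, got {self.d_max}")
        if not 0 < self.angle_max <= 180:
            raise SelectionError(
                f"angle_max must be in (0, 180], got {self.angle_max}"
            )
        object.__setattr__(
            self, "angle_convention", AngleConvention(self.angle_convention)
        )
        object.__setattr__(
            self, "heavy_atom_elements", frozenset(self.heavy_atom_elements)
        )


@dataclass(frozen=True)
class AtomSite:
    """One hydrogen-bond-capable atom.

    ``attached_hydrogens`` is populated for donor sites only; a hydrogen
    site must appear in exactly one donor's ``attached_hydrogens``.
    ``site_label`` is a free chemical label ("S=O", "pyrimidine para-N", ...)
    used in occupancy tables and RDF selections.
    """

    atom_index: int
    element: str
    role: SiteRole
    molecule_id: int
    attached_hydrogens: tuple[int, ...] = ()
    site_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", SiteRole(self.role))
        object.__setattr__(
            self, "attached_hydrogens", tuple(self.attached_hydrogens)
        )
        if self.atom_index < 0:
            raise SelectionError(f"negative atom_index {self.atom_index}")
        if self.role is SiteRole.DONOR and not self.attached_hydrogens:
            raise SelectionError(
                f"donor site at atom {self.atom_index} has no attached hydrogens"
            )
        if self.role is not SiteRole.DONOR and self.attached_hydrogens:
            raise SelectionError(
                f"{self.role.value} site at atom {self.atom_index} must not "
                "list attached_hydrogens"
            )


@dataclass(frozen=True)
class MoleculeGroup:
    molecule_id: int
    role: MoleculeRole
    name: str
    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", MoleculeRole(self.role))
        object.__setattr__(self, "atom_indices", tuple(self.atom_indices))
        if not self.atom_indices:
            raise SelectionError(
                f"molecule {self.molecule_id} ({self.name}) has no atoms"
            )


@dataclass
class SystemSelection:
    """Validated set of molecules, H-bond sites and criteria.

    Exactly one template molecule is required (the one-template box of the
    screening protocol); monomer/crosslinker/solvent groups are optional.
    """

    molecules: list[MoleculeGroup]
    sites: list[AtomSite]
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    n_atoms: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        mol_ids = [m.molecule_id for m in self.molecules]
        if len(set(mol_ids)) != len(mol_ids):
            raise SelectionError("molecule_ids are not unique")
        n_templates = sum(
            m.role is MoleculeRole.TEMPLATE for m in self.molecules
        )
        if n_templates != 1:
            raise SelectionError(
                f"exactly one template molecule required, found {n_templates}"
            )
        atom_to_mol: dict[int, int] = {}
        for m in self.molecules:
            for a in m.atom_indices:
                if a in atom_to_mol:
                    raise SelectionError(
                        f"atom {a} assigned to molecules "
                        f"{atom_to_mol[a]} and {m.molecule_id}"
                    )
                atom_to_mol[a] = m.molecule_id
        if self.n_atoms is not None:
            bad = [a for a in atom_to_mol if a >= self.n_atoms]
            if bad:
                raise SelectionError(
                    f"atom indices {bad[:5]} exceed declared n_atoms={self.n_atoms}"
                )
        seen: set[tuple[int, SiteRole]] = set()
        heavy = self.criteria.heavy_atom_elements
        donors_by_h: dict[int, list[int]] = {}
        for s in self.sites:
            key = (s.atom_index, s.role)
            if key in seen:
                raise SelectionError(
                    f"duplicate site ({s.atom_index}, {s.role.value})"
                )
            seen.add(key)
            if s.atom_index not in atom_to_mol:
                raise SelectionError(
                    f"site atom {s.atom_index} belongs to no declared molecule"
                )
            if atom_to_mol[s.atom_index] != s.molecule_id:
                raise SelectionError(
                    f"site atom {s.atom_index} declares molecule "
                    f"{s.molecule_id} but belongs to {atom_to_mol[s.atom_index]}"
                )
            if s.role in (SiteRole.DONOR, SiteRole.ACCEPTOR) and s.element not in heavy:
                raise SelectionError(
                    f"{s.role.value} element {s.element!r} at atom "
                    f"{s.atom_index} not in heavy_atom_elements {sorted(heavy)}"
                )
            if s.role is SiteRole.DONOR:
                for h in s.attached_hydrogens:
                    donors_by_h.setdefault(h, []).append(s.atom_index)
                    if atom_to_mol.get(h) != s.molecule_id:
                        raise SelectionError(
                            f"hydrogen {h} of donor {s.atom_index} is not in "
                            "the same molecule"
                        )
        for s in self.sites:
            if s.role is SiteRole.HYDROGEN:
                parents = donors_by_h.get(s.atom_index, [])
                if len(parents) != 1:
                    raise SelectionError(
                        f"hydrogen site {s.atom_index} must have exactly one "
                        f"parent donor, found {len(parents)}"
                    )
        for h, parents in donors_by_h.items():
            if len(parents) > 1:
                raise SelectionError(
                    f"hydrogen {h} attached to multiple donors {parents}"
                )
        self._atom_to_molecule = atom_to_mol

    # -- convenience lookups --------------------------------------------

    @property
    def molecule_roles(self) -> dict[int, MoleculeRole]:
        return {m.molecule_id: m.role for m in self.molecules}

    def molecule_of_atom(self, atom_index: int) -> int:
        return self._atom_to_molecule[atom_index]

    def donors(self) -> list[AtomSite]:
        return [s for s in self.sites if s.role is SiteRole.DONOR]

    def acceptors(self) -> list[AtomSite]:
        return [s for s in self.sites if s.role is SiteRole.ACCEPTOR]

    def molecules_with_role(self, role: MoleculeRole | str) -> list[MoleculeGroup]:
        role = MoleculeRole(role)
        return [m for m in self.molecules if m.role is role]

    def with_criteria(self, criteria: HBondCriteria) -> "SystemSelection":
        return SystemSelection(
            molecules=list(self.molecules),
            sites=list(self.sites),
            criteria=criteria,
            n_atoms=self.n_atoms,
        )


# -- config (de)serialization -------------------------------------------

_TOP_KEYS = {"molecules", "sites", "criteria", "n_atoms"}
_MOL_KEYS = {"molecule_id", "role", "name", "atom_indices"}
_SITE_KEYS = {
    "atom_index",
    "element",
    "role",
    "molecule_id",
    "attached_hydrogens",
    "site_label",
}
_CRIT_KEYS = {"d_max_nm", "angle_max_deg", "angle_convention", "heavy_atom_elements"}


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise SelectionError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_selection(config_text: str) -> SystemSelection:
    """Parse a YAML/JSON selection config into a validated SystemSelection.

    Schema (all physical units explicit in key names)::

        n_atoms: 42            # optional declared atom count
        criteria:              # optional; defaults 0.35 nm / 30 deg / HDA / {N,O}
          d_max_nm: 0.35
          angle_max_deg: 30.0
          angle_convention: HDA
          heavy_atom_elements: [N, O]
        molecules:
          - {molecule_id: 0, role: template, name: SDM, atom_indices: [0, 1]}
        sites:
          - {atom_index: 0, element: N, role: donor, molecule_id: 0,
             attached_hydrogens: [1], site_label: "N-H"}
    """
    try:
        data = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise SelectionError(f"config does not parse as YAML/JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise SelectionError("config root must be a mapping")
    _reject_unknown(data, _TOP_KEYS, "config root")
    if "molecules" not in data:
        raise SelectionError("config missing required key 'molecules'")

    crit_data = data.get("criteria") or {}
    if not isinstance(crit_data, dict):
        raise SelectionError("'criteria' must be a mapping")
    _reject_unknown(crit_data, _CRIT_KEYS, "criteria")
    criteria = HBondCriteria(
        d_max=float(crit_data.get("d_max_nm", DEFAULT_D_MAX_NM)),
        angle_max=float(crit_data.get("angle_max_deg", DEFAULT_ANGLE_MAX_DEG)),
        angle_convention=AngleConvention(
            crit_data.get("angle_convention", AngleConvention.HDA)
        ),
        heavy_atom_elements=frozenset(
            crit_data.get("heavy_atom_elements", DEFAULT_HEAVY_ELEMENTS)
        ),
    )

    molecules = []
    for i, m in enumerate(data["molecules"] or []):
        if not isinstance(m, dict):
            raise SelectionError(f"molecules[{i}] must be a mapping")
        _reject_unknown(m, _MOL_KEYS, f"molecules[{i}]")
        try:
            molecules.append(
                MoleculeGroup(
                    molecule_id=int(m["molecule_id"]),
                    role=MoleculeRole(m["role"]),
                    name=str(m.get("name", f"mol{m['molecule_id']}")),
                    atom_indices=tuple(int(a) for a in m["atom_indices"]),
                )
            )
        except KeyError as exc:
            raise SelectionError(f"molecules[{i}] missing field {exc}") from exc

    sites = []
    for i, s in enumerate(data.get("sites") or []):
        if not isinstance(s, dict):
            raise SelectionError(f"sites[{i}] must be a mapping")
        _reject_unknown(s, _SITE_KEYS, f"sites[{i}]")
        try:
            sites.append(
                AtomSite(
                    atom_index=int(s["atom_index"]),
                    element=str(s["element"]),
                    role=SiteRole(s["role"]),
                    molecule_id=int(s["molecule_id"]),
                    attached_hydrogens=tuple(
                        int(h) for h in s.get("attached_hydrogens", ())
                    ),
                    site_label=str(s.get("site_label", "")),
                )
            )
        except KeyError as exc:
            raise SelectionError(f"sites[{i}] missing field {exc}") from exc

    n_atoms = data.get("n_atoms")
    return SystemSelection(
        molecules=molecules,
        sites=sites,
        criteria=criteria,
        n_atoms=None if n_atoms is None else int(n_atoms),
    )


def serialize_selection(selection: SystemSelection) -> str:
    """Serialize to the YAML schema accepted by :func:`load_selection`."""
    data: dict = {
        "criteria": {
            "d_max_nm": selection.criteria.d_max,
            "angle_max_deg": selection.criteria.angle_max,
            "angle_convention": selection.criteria.angle_convention.value,
            "heavy_atom_elements": sorted(selection.criteria.heavy_atom_elements),
        },
        "molecules": [
            {
                "molecule_id": m.molecule_id,
                "role": m.role.value,
                "name": m.name,
                "atom_indices": list(m.atom_indices),
            }
            for m in selection.molecules
        ],
        "sites": [
            {
                "atom_index": s.atom_index,
                "element": s.element,
                "role": s.role.value,
                "molecule_id": s.molecule_id,
                **(
                    {"attached_hydrogens": list(s.attached_hydrogens)}
                    if s.attached_hydrogens
                    else {}
                ),
                **({"site_label": s.site_label} if s.site_label else {}),
            }
            for s in selection.sites
        ],
    }
    if selection.n_atoms is not None:
        data["n_atoms"] = selection.n_atoms
    return yaml.safe_dump(data, sort_keys=False)


# -- site inference heuristic -------------------------------------------


def infer_sites(
    elements: list[str],
    bonds: list[tuple[int, int]],
    molecules: list[MoleculeGroup],
    criteria: HBondCriteria | None = None,
    explicit_sites: list[AtomSite] = (),
) -> list[AtomSite]:
    """Heuristic site assignment from elements + covalent connectivity.

    Every heavy atom (element in ``criteria.heavy_atom_elements``) becomes an
    acceptor; a heavy atom with at least one covalently bonded hydrogen
    additionally becomes a donor carrying those hydrogens (so a hydroxyl
    oxygen is both donor and acceptor, while an ester carbonyl oxygen is
    acceptor only).  C-H hydrogens produce no site under the default N/O
    element set.  Atoms covered by ``explicit_sites`` are not inferred; the
    explicit sites are returned verbatim instead.
    """
    criteria = criteria or HBondCriteria()
    n = len(elements)
    atom_to_mol: dict[int, int] = {}
    for m in molecules:
        for a in m.atom_indices:
            atom_to_mol[a] = m.molecule_id

    adjacency: dict[int, list[int]] = {}
    for a, b in bonds:
        if not (0 <= a < n and 0 <= b < n):
            raise SelectionError(f"bond ({a}, {b}) outside atom count {n}")
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)

    explicit_atoms = {s.atom_index for s in explicit_sites}
    heavy = criteria.heavy_atom_elements
    sites: list[AtomSite] = list(explicit_sites)
    for a in sorted(atom_to_mol):
        if a in explicit_atoms:
            continue
        el = elements[a]
        if el is None or el == "":
            raise SelectionError(f"atom {a} has no element assigned")
        if el not in heavy:
            continue
        hydrogens = tuple(
            sorted(h for h in adjacency.get(a, []) if elements[h] == "H")
        )
        mol = atom_to_mol[a]
        label = f"{el}{a}"
        if hydrogens:
            sites.append(
                AtomSite(a, el, SiteRole.DONOR, mol, hydrogens, site_label=label)
            )
        sites.append(AtomSite(a, el, SiteRole.ACCEPTOR, mol, site_label=label))
    sites.sort(key=lambda s: (s.atom_index, s.role.value))
    return sites
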