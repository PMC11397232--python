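import numpy as np
import pytest

from mipscreen.selection import (
    AtomSite,
    HBondCriteria,
    MoleculeGroup,
    MoleculeRole,
    SiteRole,
    SystemSelection,
)
from mipscreen.trajectory import Frame


def make_bipartite_system(n_donors: int, n_acceptors: int) -> dict:
    """N-H donor molecules and O acceptor molecules, one molecule each.

    Every atom sits in its own molecule so no pair is excluded by the
    intra-molecular rule; used for randomized detector/oracle comparisons.
    Atom 0 is a dummy single-atom template (selections require one).
    """
    mols = [MoleculeGroup(0, MoleculeRole.TEMPLATE, "T", (0,))]
    sites: list[AtomSite] = []
    idx, mol = 1, 1
    donor_atoms, h_atoms, acceptor_atoms = [], [], []
    for _ in range(n_donors):
        mols.append(MoleculeGroup(mol, MoleculeRole.MONOMER, "D", (idx, idx + 1)))
        sites.append(AtomSite(idx, "N", SiteRole.DONOR, mol, (idx + 1,)))
        donor_atoms.append(idx)
        h_atoms.append(idx + 1)
        idx += 2
        mol += 1
    for _ in range(n_acceptors):
        mols.append(MoleculeGroup(mol, MoleculeRole.MONOMER, "A", (idx,)))
        sites.append(AtomSite(idx, "O", SiteRole.ACCEPTOR, mol))
        acceptor_atoms.append(idx)
        idx += 1
        mol += 1
    selection = SystemSelection(mols, sites, HBondCriteria(), n_atoms=idx)
    return {
        "selection": selection,
        "n_atoms": idx,
        "donor_atoms": donor_atoms,
        "h_atoms": h_atoms,
        "acceptor_atoms": acceptor_atoms,
    }


def random_bipartite_frame(system: dict, rng, box_edge: float = 3.0) -> Frame:
    """Random coordinates for a bipartite system; hydrogens near their donors."""
    coords = rng.random((system["n_atoms"], 3)) * box_edge
    for d, h in zip(system["donor_atoms"], system["h_atoms"]):
        coords[h] = coords[d] + rng.normal(scale=0.05, size=3)
    return Frame(coords=coords, box=np.full(3, box_edge))


@pytest.fixture(scope="session")
def bipartite_200():
    """200 hydrogen-bond-capable molecules (100 donors + 100 acceptors)."""
    return make_bipartite_system(100, 100)


@pytest.fixture
def simple_selection() -> SystemSelection:
    """One template (N-H donor + O acceptor) and one monomer (C=O + O-H).

    Atom map: 0 N(tpl donor), 1 H, 2 O(tpl acceptor), 3 O(mon carbonyl
    acceptor), 4 O(mon hydroxyl donor+acceptor), 5 H.
    """
    mols = [
        MoleculeGroup(0, MoleculeRole.TEMPLATE, "SDM", (0, 1, 2)),
        MoleculeGroup(1, MoleculeRole.MONOMER, "AA", (3, 4, 5)),
    ]
    sites = [
        AtomSite(0, "N", SiteRole.DONOR, 0, (1,), site_label="N-H"),
        AtomSite(2, "O", SiteRole.ACCEPTOR, 0, site_label="S=O"),
        AtomSite(3, "O", SiteRole.ACCEPTOR, 1, site_label="C=O"),
        AtomSite(4, "O", SiteRole.DONOR, 1, (5,), site_label="O-H"),
        AtomSite(4, "O", SiteRole.ACCEPTOR, 1, site_label="O-H"),
    ]
    return SystemSelection(mols, sites, HBondCriteria(), n_atoms=6)


def place_simple_frame(
    donor_xyz=(0.0, 0.0, 0.0),
    h_xyz=(0.10, 0.0, 0.0),
    acceptor_xyz=(0.29, 0.0, 0.0),
    box_edge: float = 3.0,
) -> Frame:
    """Frame for ``simple_selection`` with a scripted template-donor geometry.

    Unused atoms are parked far from everything.
    """
    coords = np.full((6, 3), 2.0)
    coords[0] = donor_xyz
    coords[1] = h_xyz
    coords[3] = acceptor_xyz
    coords[2] = (0.0, 2.0, 2.0)  # template acceptor, far away
    coords[4] = (2.0, 0.0, 2.0)  # monomer hydroxyl O, far away
    coords[5] = (2.0, 0.1, 2.0)
    return Frame(coords=coords, box=np.full(3, box_edge))
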