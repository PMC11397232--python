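"""Synthetic pre-polymerization trajectories with exact ground truth.

The generator emulates the composition of a screening box — one template
molecule fixed at the centre of a cubic periodic box with a small set of
donor/acceptor sites at fixed local geometry, N functional monomers that
bind and unbind at hydrogen-bond geometry following a two-state Markov
(telegraph) process per monomer, and inert filler particles — while keeping
full bookkeeping of the binding state.  Every frame is internally
consistent: a monomer recorded as bound with multiplicity m satisfies the
geometric hydrogen-bond criteria for exactly m template-monomer bonds, and
an unbound monomer keeps all of its sites farther than d_max from every
template site.

Molecules are rigid dummies with no internal dynamics; frames are i.i.d.
conditional on the Markov binding state.  This is sufficient to test the
counting statistics of the screening pipeline, not the physics.

Template sites sit on mutually orthogonal (or antipodal) directions at
0.35 nm from the centre, which keeps any two sites >= 0.49 nm apart so a
bound monomer can never satisfy the distance cutoff against an unintended
site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .selection import (
    AtomSite,
    HBondCriteria,
    MoleculeGroup,
    MoleculeRole,
    SiteRole,
    SystemSelection,
)
from .trajectory import Frame, Trajectory

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "TelegraphSeries",
    "generate",
    "telegraph_series",
]

_SITE_RADIUS = 0.35  # nm, template heavy-atom sites from the centre
_H_OFFSET = 0.10  # nm, covalent X-H length
_AXES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic system.

    Rates are per-ps Markov on/off rates per monomer; ``max_simultaneous``
    caps the number of concurrently bound monomers (a monomer attempting to
    bind at the cap stays free).  ``double_bond_prob`` is the probability
    that a binding monomer attaches in double-hydrogen-bond geometry
    (multiplicity 2).  ``monomer_sites`` is ``"acid"`` (carboxylic-acid-like:
    one carbonyl acceptor plus a hydroxyl that is both donor and acceptor)
    or ``"ester"`` (two acceptors, no donor — such monomers cannot
    self-polymerize).
    """

    box: float = 4.0
    n_monomers: int = 5
    n_filler: int = 8
    template_n_donor_sites: int = 3
    template_n_acceptor_sites: int = 3
    monomer_sites: str = "acid"
    k_on: float = 0.01
    k_off: float = 0.02
    max_simultaneous: int = 2
    double_bond_prob: float = 0.5
    bound_distance_range: tuple[float, float] = (0.18, 0.30)
    n_frames: int = 2000
    dt: float = 1.0
    seed: int = 0

    def validate(self, criteria: HBondCriteria) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.max_simultaneous <= self.n_monomers:
            raise ValueError("max_simultaneous must lie in [0, n_monomers]")
        if self.max_simultaneous > self.template_n_donor_sites:
            raise ValueError(
                "max_simultaneous cannot exceed the template donor site count"
            )
        k = self.template_n_donor_sites + self.template_n_acceptor_sites
        if not 1 <= k <= len(_AXES):
            raise ValueError(
                f"template needs 1..{len(_AXES)} sites total, got {k}"
            )
        lo, hi = self.bound_distance_range
        if not 0 < lo <= hi < criteria.d_max:
            raise ValueError(
                "bound_distance_range must lie strictly inside (0, d_max)"
            )
        if self.monomer_sites not in {"acid", "ester"}:
            raise ValueError("monomer_sites must be 'acid' or 'ester'")
        if not 0 <= self.double_bond_prob <= 1:
            raise ValueError("double_bond_prob must lie in [0, 1]")
        # unbound monomers are rejection-sampled outside an exclusion sphere;
        # the box must leave room for that sphere plus the monomer extent
        r_excl = _SITE_RADIUS + _H_OFFSET + criteria.d_max + 0.25
        if self.box / 2 <= r_excl + 0.2:
            raise ValueError(
                f"box edge {self.box} nm too small for the exclusion sphere "
                f"(needs > {2 * (r_excl + 0.2):.2f} nm)"
            )


@dataclass
class GroundTruth:
    """Exact binding bookkeeping emitted alongside the coordinates."""

    bound: list[dict[int, int]]
    """Per frame: {monomer molecule_id: bond multiplicity}."""
    ebn: int
    hbn_max: int
    frames_at_ebn: float
    occupancy_per_monomer: dict[int, float]
    """Mean bonds per frame for each (template, monomer) pair."""
    episode_lengths: list[int]
    """Length in frames of each maximal bound run (ends included)."""


@dataclass
class TelegraphSeries:
    """A stationary two-state Markov chain with its analytic expectations."""

    states: np.ndarray
    k_on: float
    k_off: float
    dt: float
    occupancy_expected: float
    occupancy_sigma: float
    """Std of the empirical mean occupancy, autocorrelation included."""
    mean_dwell_expected_ps: float
    """Expected bound-run length: dt / p_off, ~ 1/k_off for small rates."""


def _transition_probs(k_on: float, k_off: float, dt: float) -> tuple[float, float]:
    return 1.0 - math.exp(-k_on * dt), 1.0 - math.exp(-k_off * dt)


def telegraph_series(
    k_on: float,
    k_off: float,
    n_frames: int,
    dt: float = 1.0,
    seed: int = 0,
    start: str = "stationary",
) -> TelegraphSeries:
    """Sample a two-state (bound/unbound) Markov chain at frame resolution.

    ``start`` is ``"stationary"`` (default; falls back to unbound when both
    rates vanish), ``"bound"`` or ``"unbound"``.  The analytic stationary
    occupancy is p_on/(p_on + p_off) (which tends to k_on/(k_on + k_off)
    as dt -> 0) and the expected bound dwell time is dt/p_off ~ 1/k_off.
    """
    if k_on < 0 or k_off < 0:
        raise ValueError("rates must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    p_on, p_off = _transition_probs(k_on, k_off, dt)
    rng = np.random.default_rng(seed)
    u = rng.random(n_frames)
    if p_on + p_off > 0:
        p_stat = p_on / (p_on + p_off)
    else:
        p_stat = 0.0
    if start == "stationary":
        state = bool(u[0] < p_stat) if p_on + p_off > 0 else False
    elif start in {"bound", "unbound"}:
        state = start == "bound"
    else:
        raise ValueError(f"unknown start {start!r}")
    states = np.empty(n_frames, dtype=bool)
    states[0] = state
    for t in range(1, n_frames):
        if state:
            state = not (u[t] < p_off)
        else:
            state = u[t] < p_on
        states[t] = state
    rho = 1.0 - p_on - p_off
    if p_on + p_off > 0:
        var = p_stat * (1 - p_stat) / n_frames * (1 + rho) / (1 - rho)
    else:
        var = 0.0
    dwell = dt / p_off if p_off > 0 else math.inf
    return TelegraphSeries(
        states=states,
        k_on=k_on,
        k_off=k_off,
        dt=dt,
        occupancy_expected=p_stat,
        occupancy_sigma=math.sqrt(max(var, 0.0)),
        mean_dwell_expected_ps=dwell,
    )


# -- system layout ------------------------------------------------------


def _unit_perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to each row of u (vectorized)."""
    u = np.atleast_2d(u)
    ref = np.where(
        np.abs(u[:, [0]]) < 0.9, np.array([[1.0, 0, 0]]), np.array([[0, 1.0, 0]])
    )
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u, e1)
    return e1, e2


def _tilted(u: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rows of u tilted by polar angle theta about a random azimuth phi."""
    e1, e2 = _unit_perp_basis(u)
    theta = theta[:, None]
    phi = phi[:, None]
    return (
        np.cos(theta) * np.atleast_2d(u)
        + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    )


class _Layout:
    """Atom/site numbering for one synthetic system."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        k, m = spec.template_n_donor_sites, spec.template_n_acceptor_sites
        self.donor_dirs = _AXES[:k]
        self.acceptor_dirs = _AXES[k : k + m]
        # template: C centre, then (N, H) per donor site, then O per acceptor
        self.tpl_center = 0
        self.tpl_donor_N = [1 + 2 * i for i in range(k)]
        self.tpl_donor_H = [2 + 2 * i for i in range(k)]
        self.tpl_acceptor_O = [1 + 2 * k + j for j in range(m)]
        self.n_template_atoms = 1 + 2 * k + m
        self.atoms_per_monomer = 4 if spec.monomer_sites == "acid" else 3
        self.mon_start = self.n_template_atoms
        self.filler_start = (
            self.mon_start + spec.n_monomers * self.atoms_per_monomer
        )
        self.n_atoms = self.filler_start + spec.n_filler

    def monomer_atoms(self, i: int) -> dict[str, int]:
        base = self.mon_start + i * self.atoms_per_monomer
        if self.spec.monomer_sites == "acid":
            return {"C": base, "Oacc": base + 1, "Odon": base + 2, "Hdon": base + 3}
        return {"C": base, "Oacc": base + 1, "Oest": base + 2}

    def template_coords(self, center: np.ndarray) -> np.ndarray:
        coords = np.zeros((self.n_template_atoms, 3))
        coords[self.tpl_center] = center
        for i, u in enumerate(self.donor_dirs):
            coords[self.tpl_donor_N[i]] = center + _SITE_RADIUS * u
            coords[self.tpl_donor_H[i]] = center + (_SITE_RADIUS + _H_OFFSET) * u
        for j, v in enumerate(self.acceptor_dirs):
            coords[self.tpl_acceptor_O[j]] = center + _SITE_RADIUS * v
        return coords

    def build_selection(self, criteria: HBondCriteria) -> SystemSelection:
        spec = self.spec
        molecules = [
            MoleculeGroup(0, MoleculeRole.TEMPLATE, "TPL",
                          tuple(range(self.n_template_atoms)))
        ]
        sites: list[AtomSite] = []
        for i in range(spec.template_n_donor_sites):
            sites.append(
                AtomSite(self.tpl_donor_N[i], "N", SiteRole.DONOR, 0,
                         (self.tpl_donor_H[i],), site_label=f"tpl-NH{i}")
            )
        for j in range(spec.template_n_acceptor_sites):
            sites.append(
                AtomSite(self.tpl_acceptor_O[j], "O", SiteRole.ACCEPTOR, 0,
                         site_label=f"tpl-O{j}")
            )
        for i in range(spec.n_monomers):
            mol_id = 1 + i
            atoms = self.monomer_atoms(i)
            molecules.append(
                MoleculeGroup(mol_id, MoleculeRole.MONOMER,
                              spec.monomer_sites.upper(),
                              tuple(sorted(atoms.values())))
            )
            sites.append(
                AtomSite(atoms["Oacc"], "O", SiteRole.ACCEPTOR, mol_id,
                         site_label="C=O")
            )
            if spec.monomer_sites == "acid":
                sites.append(
                    AtomSite(atoms["Odon"], "O", SiteRole.DONOR, mol_id,
                             (atoms["Hdon"],), site_label="O-H")
                )
                sites.append(
                    AtomSite(atoms["Odon"], "O", SiteRole.ACCEPTOR, mol_id,
                             site_label="O-H")
                )
            else:
                sites.append(
                    AtomSite(atoms["Oest"], "O", SiteRole.ACCEPTOR, mol_id,
                             site_label="-O-")
                )
        for f in range(spec.n_filler):
            mol_id = 1 + spec.n_monomers + f
            molecules.append(
                MoleculeGroup(mol_id, MoleculeRole.SOLVENT, "FIL",
                              (self.filler_start + f,))
            )
        return SystemSelection(
            molecules=molecules, sites=sites, criteria=criteria,
            n_atoms=self.n_atoms,
        )


# -- dynamics + coordinates ---------------------------------------------


def _simulate_states(spec: SyntheticSpec, rng: np.random.Generator):
    """Run the capped per-monomer telegraph dynamics.

    Returns (mult, site1, site2) integer arrays of shape
    (n_frames, n_monomers); site entries are -1 where unused.  site1 is the
    template donor serving the monomer's acceptor; for double bonds site2 is
    the template acceptor engaged by the monomer's hydroxyl (acid) or a
    second template donor (ester, which has no donor of its own).
    """
    F, M = spec.n_frames, spec.n_monomers
    p_on, p_off = _transition_probs(spec.k_on, spec.k_off, spec.dt)
    u_flip = rng.random((F, M))
    u_mult = rng.random((F, M))
    mult = np.zeros((F, M), dtype=np.int8)
    site1 = np.full((F, M), -1, dtype=np.int8)  # template donor index
    site2 = np.full((F, M), -1, dtype=np.int8)  # acceptor (acid) / 2nd donor (ester)
    free_donors = list(range(spec.template_n_donor_sites))
    free_acceptors = list(range(spec.template_n_acceptor_sites))
    state = [0] * M  # multiplicity per monomer
    s1 = [-1] * M
    s2 = [-1] * M
    acid = spec.monomer_sites == "acid"
    for t in range(F):
        n_bound = sum(1 for s in state if s > 0)
        for i in range(M):
            if state[i] > 0:
                if u_flip[t, i] < p_off:
                    free_donors.append(s1[i])
                    if s2[i] >= 0:
                        (free_acceptors if acid else free_donors).append(s2[i])
                    state[i], s1[i], s2[i] = 0, -1, -1
                    n_bound -= 1
            else:
                if u_flip[t, i] < p_on and n_bound < spec.max_simultaneous:
                    if not free_donors:
                        continue
                    free_donors.sort()
                    s1[i] = free_donors.pop(0)
                    want_double = u_mult[t, i] < spec.double_bond_prob
                    pool = free_acceptors if acid else free_donors
                    if want_double and pool:
                        pool.sort()
                        s2[i] = pool.pop(0)
                        state[i] = 2
                    else:
                        state[i] = 1
                    n_bound += 1
        for i in range(M):
            mult[t, i] = state[i]
            site1[t, i] = s1[i]
            site2[t, i] = s2[i]
    return mult, site1, site2


def _sample_outside_sphere(
    rng: np.random.Generator, n: int, box: float, r_excl: float
) -> np.ndarray:
    """Uniform points in the box at distance > r_excl from the centre."""
    out = np.empty((n, 3))
    filled = 0
    center = box / 2
    while filled < n:
        cand = rng.random((max(2 * (n - filled), 16), 3)) * box
        d = np.linalg.norm(cand - center, axis=1)
        ok = cand[d > r_excl]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _random_units(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate(
    spec: SyntheticSpec,
    criteria: HBondCriteria | None = None,
) -> tuple[Trajectory, SystemSelection, GroundTruth]:
    """Generate a synthetic trajectory, its selection, and its ground truth.

    Identical specs (including the seed) produce byte-identical output.
    """
    criteria = criteria or HBondCriteria()
    spec.validate(criteria)
    layout = _Layout(spec)
    selection = layout.build_selection(criteria)
    rng = np.random.default_rng(spec.seed)

    F, M = spec.n_frames, spec.n_monomers
    box = np.full(3, float(spec.box))
    center = box / 2
    mult, site1, site2 = _simulate_states(spec, rng)

    coords = np.empty((F, layout.n_atoms, 3))
    coords[:, : layout.n_template_atoms] = layout.template_coords(center)

    theta_max = math.radians(criteria.angle_max) * 0.9
    d_lo, d_hi = spec.bound_distance_range
    acid = spec.monomer_sites == "acid"
    atoms = [layout.monomer_atoms(i) for i in range(M)]

    # unbound monomers: anchor outside the exclusion sphere, random rigid
    # orientation of small fixed local offsets
    unbound_f, unbound_m = np.nonzero(mult == 0)
    n_un = unbound_f.size
    r_excl = _SITE_RADIUS + _H_OFFSET + criteria.d_max + 0.25
    anchors = _sample_outside_sphere(rng, n_un, spec.box, r_excl)
    ax1 = _random_units(rng, n_un)
    e1, e2 = _unit_perp_basis(ax1)
    phi = rng.random(n_un) * 2 * np.pi
    ax2 = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2
    c_idx = np.array([a["C"] for a in atoms])
    oacc_idx = np.array([a["Oacc"] for a in atoms])
    third_idx = np.array([a["Odon" if acid else "Oest"] for a in atoms])
    coords[unbound_f, c_idx[unbound_m]] = anchors
    coords[unbound_f, oacc_idx[unbound_m]] = anchors + 0.12 * ax1
    coords[unbound_f, third_idx[unbound_m]] = anchors - 0.12 * ax1
    if acid:
        hdon_idx = np.array([a["Hdon"] for a in atoms])
        coords[unbound_f, hdon_idx[unbound_m]] = (
            anchors - 0.12 * ax1 + 0.10 * ax2
        )

    # bound monomers: place the carbonyl acceptor at hydrogen-bond geometry
    # against the assigned template donor; doubles additionally place the
    # hydroxyl donor against a template acceptor (acid) or the second
    # acceptor against a second template donor (ester)
    bound_f, bound_m = np.nonzero(mult > 0)
    n_b = bound_f.size
    if n_b:
        u1 = layout.donor_dirs[site1[bound_f, bound_m]]
        d1 = rng.uniform(d_lo, d_hi, n_b)
        th1 = rng.uniform(0, theta_max, n_b)
        ph1 = rng.uniform(0, 2 * np.pi, n_b)
        w1 = _tilted(u1, th1, ph1)
        donor_pos = center + _SITE_RADIUS * u1
        oacc = donor_pos + d1[:, None] * w1
        d2 = rng.uniform(d_lo, d_hi, n_b)
        thp = rng.uniform(0, theta_max, n_b)  # positional tilt of site 2
        php = rng.uniform(0, 2 * np.pi, n_b)
        th2 = rng.uniform(0, theta_max, n_b)  # H tilt (acid doubles)
        ph2 = rng.uniform(0, 2 * np.pi, n_b)
        coords[bound_f, oacc_idx[bound_m]] = oacc
        is_double = mult[bound_f, bound_m] == 2
        single = ~is_double
        # singles: remaining atoms trail outward along the bond direction,
        # clear of every template site
        sf, sm = bound_f[single], bound_m[single]
        coords[sf, c_idx[sm]] = oacc[single] + 0.20 * w1[single]
        coords[sf, third_idx[sm]] = oacc[single] + 0.35 * w1[single]
        if acid:
            coords[sf, hdon_idx[sm]] = oacc[single] + 0.45 * w1[single]
        df, dm = bound_f[is_double], bound_m[is_double]
        if df.size:
            if acid:
                v = layout.acceptor_dirs[site2[df, dm]]
                w2 = _tilted(v, thp[is_double], php[is_double])
                acc_pos = center + _SITE_RADIUS * v
                odon = acc_pos + d2[is_double][:, None] * w2
                to_acc = acc_pos - odon
                to_acc /= np.linalg.norm(to_acc, axis=1, keepdims=True)
                hdir = _tilted(to_acc, th2[is_double], ph2[is_double])
                coords[df, third_idx[dm]] = odon
                coords[df, hdon_idx[dm]] = odon + _H_OFFSET * hdir
                coords[df, c_idx[dm]] = odon + 0.15 * w2
            else:
                u2 = layout.donor_dirs[site2[df, dm]]
                w2 = _tilted(u2, thp[is_double], php[is_double])
                coords[df, third_idx[dm]] = (
                    center + _SITE_RADIUS * u2 + d2[is_double][:, None] * w2
                )
                coords[df, c_idx[dm]] = oacc[is_double] + 0.20 * w1[is_double]

    if spec.n_filler:
        coords[:, layout.filler_start :] = (
            rng.random((F, spec.n_filler, 3)) * spec.box
        )

    frames = [
        Frame(coords=coords[f], box=box.copy(), time=f * spec.dt)
        for f in range(F)
    ]
    traj = Trajectory(frames, dt=spec.dt, n_atoms=layout.n_atoms)

    bound_dicts: list[dict[int, int]] = []
    for t in range(F):
        bound_dicts.append(
            {1 + i: int(mult[t, i]) for i in range(M) if mult[t, i] > 0}
        )
    sizes = (mult > 0).sum(axis=1)
    ebn = int(sizes.max()) if F else 0
    frames_at = float(np.mean(sizes == ebn)) if F else 1.0
    hbn = int(mult.sum(axis=1).max()) if F else 0
    occ = {1 + i: float(mult[:, i].mean()) for i in range(M)}
    episodes: list[int] = []
    for i in range(M):
        bound_i = mult[:, i] > 0
        idx = np.nonzero(bound_i)[0]
        if idx.size:
            breaks = np.nonzero(np.diff(idx) > 1)[0]
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [idx.size - 1]))
            episodes.extend(int(idx[e] - idx[s] + 1) for s, e in zip(starts, ends))
    truth = GroundTruth(
        bound=bound_dicts,
        ebn=ebn,
        hbn_max=hbn,
        frames_at_ebn=frames_at,
        occupancy_per_monomer=occ,
        episode_lengths=episodes,
    )
    return traj, selection, truth
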