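"""Geometric hydrogen-bond detection under periodic boundary conditions.

A hydrogen bond D-H...A is recorded when the donor-acceptor distance does
not exceed ``criteria.d_max`` (default 0.35 nm) and the angular criterion
does not exceed ``criteria.angle_max`` (default 30 deg), both inclusive.
Two angle conventions are available (see
:class:`mipscreen.selection.AngleConvention`).  Distances use the minimum
image convention in an orthorhombic box.

Detection offers three interchangeable search strategies:

* ``"brute"`` — all donor x acceptor pairs (the reference oracle);
* ``"cell"``  — a cell list with bin edge >= d_max, falling back to brute
  force when the box is smaller than 3 x d_max in any direction;
* ``"auto"``  — cell list for large site counts, brute otherwise.

All strategies return the identical, deterministically ordered event set
(ordered by donor atom, then acceptor atom, then hydrogen).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .selection import (
    AngleConvention,
    AtomSite,
    MoleculeRole,
    SiteRole,
    SystemSelection,
)
from .trajectory import Frame, Trajectory

__all__ = [
    "HBondEvent",
    "minimum_image_displacement",
    "minimum_image_distance",
    "detect_frame_hbonds",
    "detect_trajectory_hbonds",
    "brute_force_reference_events",
]


@dataclass(frozen=True)
class HBondEvent:
    """One detected hydrogen bond in one frame."""

    frame_index: int
    donor: AtomSite
    hydrogen: int
    acceptor: AtomSite
    d_DA: float
    angle: float

    @property
    def donor_molecule(self) -> int:
        return self.donor.molecule_id

    @property
    def acceptor_molecule(self) -> int:
        return self.acceptor.molecule_id

    @property
    def key(self) -> tuple[int, int, int, int]:
        """(frame, donor atom, hydrogen, acceptor atom) identity."""
        return (
            self.frame_index,
            self.donor.atom_index,
            self.hydrogen,
            self.acceptor.atom_index,
        )


# -- periodic geometry --------------------------------------------------


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Displacement a - b with each component wrapped into [-L/2, L/2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    d = a - b
    return d - box * np.round(d / box)


def minimum_image_distance(a, b, box) -> float | np.ndarray:
    """Euclidean distance under the minimum image convention."""
    d = minimum_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def _angles_deg(
    h_pos: np.ndarray,
    d_pos: np.ndarray,
    a_pos: np.ndarray,
    box: np.ndarray,
    convention: AngleConvention,
) -> np.ndarray:
    """Angular criterion value for stacked (n, 3) site positions."""
    if convention is AngleConvention.HDA:
        u = minimum_image_displacement(h_pos, d_pos, box)
        v = minimum_image_displacement(a_pos, d_pos, box)
        deviation_from = 0.0
    else:  # DHA deviation from linearity
        u = minimum_image_displacement(d_pos, h_pos, box)
        v = minimum_image_displacement(a_pos, h_pos, box)
        deviation_from = 180.0
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = np.where(nu * nv == 0, 1.0, nu * nv)
    cos = np.clip(np.sum(u * v, axis=-1) / denom, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    return np.abs(deviation_from - ang)


# -- pair tables (cached on the selection) ------------------------------


class _PairTable:
    """Flattened (donor, hydrogen) x acceptor candidate table."""

    def __init__(
        self,
        selection: SystemSelection,
        pair_filter: tuple[MoleculeRole, MoleculeRole] | None,
        exclude_intramolecular: bool,
    ):
        donors = selection.donors()
        acceptors = selection.acceptors()
        roles = selection.molecule_roles
        wanted = None
        if pair_filter is not None:
            a, b = (MoleculeRole(r) for r in pair_filter)
            wanted = {(a, b), (b, a)}

        dh: list[tuple[AtomSite, int]] = [
            (d, h) for d in donors for h in d.attached_hydrogens
        ]
        # candidate (dh, acceptor) pairs, pre-sorted for deterministic output
        rows = []
        for d, h in dh:
            for acc in acceptors:
                if acc.atom_index == d.atom_index:
                    continue  # never the same heavy atom
                if exclude_intramolecular and acc.molecule_id == d.molecule_id:
                    continue
                if wanted is not None:
                    pair = (roles[d.molecule_id], roles[acc.molecule_id])
                    if pair not in wanted:
                        continue
                rows.append((d, h, acc))
        rows.sort(key=lambda r: (r[0].atom_index, r[2].atom_index, r[1]))
        self.rows = rows
        self.d_idx = np.array([r[0].atom_index for r in rows], dtype=int)
        self.h_idx = np.array([r[1] for r in rows], dtype=int)
        self.a_idx = np.array([r[2].atom_index for r in rows], dtype=int)

    def __len__(self) -> int:
        return len(self.rows)


def _get_pair_table(
    selection: SystemSelection,
    pair_filter,
    exclude_intramolecular: bool,
) -> _PairTable:
    cache = getattr(selection, "_pair_table_cache", None)
    if cache is None:
        cache = {}
        selection._pair_table_cache = cache
    if pair_filter is not None:
        pair_filter = tuple(MoleculeRole(r) for r in pair_filter)
    key = (pair_filter, exclude_intramolecular)
    if key not in cache:
        cache[key] = _PairTable(selection, pair_filter, exclude_intramolecular)
    return cache[key]


# -- neighbor search ----------------------------------------------------


def _brute_candidate_mask(
    d_pos: np.ndarray, a_pos: np.ndarray, box: np.ndarray, cutoff: float
) -> np.ndarray:
    """Boolean mask over pair rows: d(D, A) <= cutoff, all pairs at once."""
    disp = d_pos - a_pos
    disp -= box * np.round(disp / box)
    d2 = np.einsum("ij,ij->i", disp, disp)
    return d2 <= cutoff * cutoff


def _cell_candidate_mask(
    coords: np.ndarray,
    table: _PairTable,
    box: np.ndarray,
    cutoff: float,
) -> np.ndarray | None:
    """Cell-list distance screen over the pair table.

    Returns None when the box is below 3 x cutoff in any direction (caller
    falls back to brute force).
    """
    n_cells = np.floor(box / cutoff).astype(int)
    if np.any(n_cells < 3):
        return None
    cell_size = box / n_cells

    unique_d, d_inverse = np.unique(table.d_idx, return_inverse=True)
    unique_a, a_inverse = np.unique(table.a_idx, return_inverse=True)
    d_pos = coords[unique_d] % box
    a_pos = coords[unique_a] % box

    a_cells = np.minimum((a_pos / cell_size).astype(int), n_cells - 1)
    cell_of_a: dict[tuple[int, int, int], list[int]] = {}
    for j, c in enumerate(map(tuple, a_cells)):
        cell_of_a.setdefault(c, []).append(j)

    d_cells = np.minimum((d_pos / cell_size).astype(int), n_cells - 1)
    near: list[set[int]] = []
    offsets = list(itertools.product((-1, 0, 1), repeat=3))
    for i in range(len(unique_d)):
        cx, cy, cz = d_cells[i]
        neighbors: set[int] = set()
        for ox, oy, oz in offsets:
            c = (
                (cx + ox) % n_cells[0],
                (cy + oy) % n_cells[1],
                (cz + oz) % n_cells[2],
            )
            neighbors.update(cell_of_a.get(c, ()))
        near.append(neighbors)

    mask = np.zeros(len(table), dtype=bool)
    for row in range(len(table)):
        i = d_inverse[row]
        j = a_inverse[row]
        if j in near[i]:
            d = d_pos[i] - a_pos[j]
            d -= box * np.round(d / box)
            mask[row] = d @ d <= cutoff * cutoff
    return mask


# -- detection ----------------------------------------------------------


def detect_frame_hbonds(
    frame: Frame,
    selection: SystemSelection,
    frame_index: int = 0,
    pair_filter: tuple[MoleculeRole, MoleculeRole] | None = None,
    exclude_intramolecular: bool = True,
    method: str = "auto",
) -> list[HBondEvent]:
    """Detect all hydrogen bonds in one frame.

    One event per (donor-hydrogen, acceptor) pair satisfying both inclusive
    cutoffs; intra-molecular pairs are excluded by default (which also
    removes 1-2/1-3 bonded pairs); events are ordered by (donor atom,
    acceptor atom, hydrogen).
    """
    if selection.n_atoms is not None and frame.n_atoms != selection.n_atoms:
        raise ValueError(
            f"frame has {frame.n_atoms} atoms, selection declares "
            f"{selection.n_atoms}"
        )
    table = _get_pair_table(selection, pair_filter, exclude_intramolecular)
    if not len(table):
        return []
    crit = selection.criteria
    coords = frame.coords
    box = frame.box

    if method == "auto":
        method = "cell" if len(table) > 4096 else "brute"
    if method == "cell":
        mask = _cell_candidate_mask(coords, table, box, crit.d_max)
        if mask is None:
            method = "brute"
    if method == "brute":
        mask = _brute_candidate_mask(
            coords[table.d_idx], coords[table.a_idx], box, crit.d_max
        )
    elif method != "cell":
        raise ValueError(f"unknown method {method!r}")

    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    angles = _angles_deg(
        coords[table.h_idx[idx]],
        coords[table.d_idx[idx]],
        coords[table.a_idx[idx]],
        box,
        crit.angle_convention,
    )
    keep = angles <= crit.angle_max
    dists = minimum_image_distance(
        coords[table.d_idx[idx][keep]], coords[table.a_idx[idx][keep]], box
    )
    events = []
    for row, ang, dist in zip(idx[keep], angles[keep], np.atleast_1d(dists)):
        d, h, acc = table.rows[row]
        events.append(
            HBondEvent(
                frame_index=frame_index,
                donor=d,
                hydrogen=h,
                acceptor=acc,
                d_DA=float(dist),
                angle=float(ang),
            )
        )
    return events


def detect_trajectory_hbonds(
    traj: Trajectory,
    selection: SystemSelection,
    pair_filter: tuple[MoleculeRole, MoleculeRole] | None = None,
    exclude_intramolecular: bool = True,
    chunk_frames: int = 2000,
) -> Iterator[list[HBondEvent]]:
    """Yield the per-frame event lists over a whole trajectory.

    Frames are processed in vectorized chunks with the brute-force distance
    screen over the (typically small) candidate pair table; results are
    identical to calling :func:`detect_frame_hbonds` frame by frame.
    ``pair_filter`` restricts events to one molecule-role pairing, e.g.
    ``(MoleculeRole.TEMPLATE, MoleculeRole.MONOMER)``.
    """
    table = _get_pair_table(selection, pair_filter, exclude_intramolecular)
    crit = selection.criteria
    n_pairs = len(table)
    if n_pairs == 0:
        for _ in range(traj.n_frames):
            yield []
        return

    for start in range(0, traj.n_frames, chunk_frames):
        chunk = traj.frames[start : start + chunk_frames]
        coords = np.stack([f.coords for f in chunk])  # (F, natoms, 3)
        boxes = np.stack([f.box for f in chunk])  # (F, 3)
        disp = coords[:, table.d_idx] - coords[:, table.a_idx]  # (F, P, 3)
        b = boxes[:, None, :]
        disp -= b * np.round(disp / b)
        d2 = np.einsum("fpk,fpk->fp", disp, disp)
        within = d2 <= crit.d_max**2
        f_hit, p_hit = np.nonzero(within)
        if f_hit.size:
            box_hit = boxes[f_hit]
            angles = _angles_deg(
                coords[f_hit, table.h_idx[p_hit]],
                coords[f_hit, table.d_idx[p_hit]],
                coords[f_hit, table.a_idx[p_hit]],
                box_hit,
                crit.angle_convention,
            )
            keep = angles <= crit.angle_max
            f_hit, p_hit, angles = f_hit[keep], p_hit[keep], angles[keep]
            dists = np.sqrt(d2[f_hit, p_hit])
        else:
            angles = dists = np.empty(0)
        per_frame: dict[int, list[HBondEvent]] = {}
        for f, p, ang, dist in zip(f_hit, p_hit, angles, dists):
            d, h, acc = table.rows[p]
            per_frame.setdefault(int(f), []).append(
                HBondEvent(
                    frame_index=start + int(f),
                    donor=d,
                    hydrogen=h,
                    acceptor=acc,
                    d_DA=float(dist),
                    angle=float(ang),
                )
            )
        for f in range(len(chunk)):
            yield per_frame.get(f, [])


# -- independent oracle -------------------------------------------------


def brute_force_reference_events(
    frame: Frame,
    selection: SystemSelection,
    frame_index: int = 0,
    pair_filter=None,
    exclude_intramolecular: bool = True,
) -> list[HBondEvent]:
    """All-pairs O(N^2) reference detector with explicit 27-image distances.

    Coordinates are first wrapped into the primary box (after which the 27
    neighbouring images are exhaustive), then every donor x acceptor pair is
    scored by the minimum distance over the explicitly enumerated images,
    and the same inclusive cutoffs are applied.  No cell list, no
    minimum-image rounding trick: this is the oracle the fast paths are
    validated against.
    """
    crit = selection.criteria
    roles = selection.molecule_roles
    wanted = None
    if pair_filter is not None:
        a, b = (MoleculeRole(r) for r in pair_filter)
        wanted = {(a, b), (b, a)}
    box = frame.box
    wrapped = frame.coords % box
    shifts = np.array(list(itertools.product((-1, 0, 1), repeat=3))) * box

    donors = selection.donors()
    acceptors = selection.acceptors()
    if not donors or not acceptors:
        return []
    p_d = wrapped[[d.atom_index for d in donors]]  # (nd, 3)
    p_a = wrapped[[a.atom_index for a in acceptors]]  # (na, 3)
    # (nd, na, 27) distances over all explicit images
    diff = p_d[:, None, None, :] - (p_a[None, :, None, :] + shifts)
    dist_images = np.sqrt(np.einsum("ijkl,ijkl->ijk", diff, diff))
    best = dist_images.argmin(axis=2)
    d_da_all = np.take_along_axis(dist_images, best[..., None], axis=2)[..., 0]

    events = []
    for i, d in enumerate(donors):
        for j, acc in enumerate(acceptors):
            if acc.atom_index == d.atom_index:
                continue
            if exclude_intramolecular and acc.molecule_id == d.molecule_id:
                continue
            if wanted is not None and (
                roles[d.molecule_id],
                roles[acc.molecule_id],
            ) not in wanted:
                continue
            d_da = float(d_da_all[i, j])
            if d_da > crit.d_max:
                continue
            p_a_best = wrapped[acc.atom_index] + shifts[best[i, j]]
            for h in d.attached_hydrogens:
                p_h_images = wrapped[h] + shifts
                dists_h = np.linalg.norm(p_h_images - p_d[i], axis=1)
                p_h = p_h_images[int(dists_h.argmin())]
                if crit.angle_convention is AngleConvention.HDA:
                    ang = _vec_angle_deg(p_h - p_d[i], p_a_best - p_d[i])
                else:
                    ang = 180.0 - _vec_angle_deg(p_d[i] - p_h, p_a_best - p_h)
                if ang <= crit.angle_max:
                    events.append(
                        HBondEvent(frame_index, d, h, acc, d_da, float(ang))
                    )
    events.sort(key=lambda e: (e.donor.atom_index, e.acceptor.atom_index, e.hydrogen))
    return events


def _vec_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cos = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(max(-1.0, min(1.0, cos)))))
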