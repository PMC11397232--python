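"""Screening statistics for template-monomer binding.

From the per-frame hydrogen-bond events this module derives the two
headline screening scores and their supporting statistics:

* **EBN** (effective binding number) — the maximum number of functional
  monomer molecules simultaneously hydrogen-bonded to the template in any
  frame.  A monomer bound by a double hydrogen bond still counts once.
* **HBN_Max** (maximum hydrogen bond number) — the maximum count of
  simultaneous template-monomer hydrogen bonds in any frame.  A frame with
  one double-bonded and one single-bonded monomer contributes 3.
* **Occupancy** — average number of hydrogen bonds per frame for a chosen
  grouping (molecule-role pair or donor/acceptor site-label pair); the
  fraction of frames with at least one bond is reported alongside as a
  clearly labelled secondary definition.
* **Lifetimes** — continuous (mean length of uninterrupted bonded runs) or
  intermittent (integral of the bond-existence autocorrelation).

Higher EBN and HBN_Max indicate higher effective binding efficiency of a
functional monomer; monomers are ranked lexicographically by
(EBN, HBN_Max, template-monomer occupancy).
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hbonds import HBondEvent, detect_trajectory_hbonds
from .selection import MoleculeRole, SystemSelection
from .trajectory import Trajectory

__all__ = [
    "BindingTimeSeries",
    "MonomerScorecard",
    "LifetimeResult",
    "binding_series",
    "effective_binding_number",
    "max_hbond_number",
    "occupancy",
    "bond_indicator_series",
    "lifetimes",
    "lifetimes_from_events",
    "scorecard",
    "rank_monomers",
]


def _flatten(events) -> list[HBondEvent]:
    """Accept a flat event list or per-frame lists; return a flat list."""
    flat: list[HBondEvent] = []
    for item in events:
        if isinstance(item, HBondEvent):
            flat.append(item)
        else:
            flat.extend(item)
    return flat


@dataclass
class BindingTimeSeries:
    """Per-frame template-monomer binding state.

    ``bound_sets[f]`` is the set of monomer molecule_ids hydrogen-bonded to
    the template in frame f; ``multiplicities[f]`` maps each bound monomer
    to its simultaneous bond count (1 = single, 2 = double hydrogen bond);
    ``hbond_counts[f]`` is the total template-monomer bond count.
    """

    n_frames: int
    bound_sets: list[set[int]]
    multiplicities: list[dict[int, int]]
    hbond_counts: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.array([len(s) for s in self.bound_sets])
        if np.any(self.hbond_counts < sizes):
            raise ValueError(
                "hydrogen-bond count below bound-monomer count in some frame"
            )


def binding_series(
    events,
    n_frames: int,
    selection: SystemSelection,
) -> BindingTimeSeries:
    """Reduce template-monomer events to a per-frame binding series.

    Events involving molecule pairs other than template-monomer are ignored,
    so the full event stream may be passed unfiltered.
    """
    roles = selection.molecule_roles
    bound: list[set[int]] = [set() for _ in range(n_frames)]
    mult: list[dict[int, int]] = [dict() for _ in range(n_frames)]
    counts = np.zeros(n_frames, dtype=int)
    for ev in _flatten(events):
        if ev.frame_index >= n_frames:
            raise ValueError(
                f"event frame {ev.frame_index} >= n_frames {n_frames}"
            )
        pair = (roles[ev.donor_molecule], roles[ev.acceptor_molecule])
        if MoleculeRole.TEMPLATE not in pair or MoleculeRole.MONOMER not in pair:
            continue
        monomer = (
            ev.donor_molecule
            if roles[ev.donor_molecule] is MoleculeRole.MONOMER
            else ev.acceptor_molecule
        )
        f = ev.frame_index
        bound[f].add(monomer)
        mult[f][monomer] = mult[f].get(monomer, 0) + 1
        counts[f] += 1
    return BindingTimeSeries(n_frames, bound, mult, counts)


def effective_binding_number(series: BindingTimeSeries) -> tuple[int, float]:
    """(EBN, fraction of frames attaining it).

    EBN is the strict maximum over frames of the bound-monomer count; an
    all-empty series has EBN 0 attained in every frame.
    """
    sizes = np.array([len(s) for s in series.bound_sets])
    ebn = int(sizes.max()) if sizes.size else 0
    frac = float(np.mean(sizes == ebn)) if sizes.size else 1.0
    return ebn, frac


def max_hbond_number(series: BindingTimeSeries) -> int:
    """Maximum simultaneous template-monomer hydrogen bonds over frames."""
    return int(series.hbond_counts.max()) if series.n_frames else 0


# -- occupancy ----------------------------------------------------------


def _role_pair_key(ev: HBondEvent, roles: Mapping[int, MoleculeRole]) -> str:
    a = roles[ev.donor_molecule].value
    b = roles[ev.acceptor_molecule].value
    return "-".join(sorted((a, b)))


def occupancy(
    events,
    n_frames: int,
    selection: SystemSelection,
    grouping: str = "role-pair",
) -> pd.DataFrame:
    """Hydrogen-bond occupancy per grouping.

    Primary column ``avg_bonds_per_frame`` is (total events)/(n_frames);
    ``frac_frames_bonded`` (fraction of frames with >= 1 bond in the group)
    is a secondary definition.  ``grouping`` is ``"role-pair"``
    (template-monomer, monomer-monomer, ...) or ``"site-pair"``
    (donor site_label, acceptor site_label).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    roles = selection.molecule_roles
    totals: Counter = Counter()
    frames_with: dict = defaultdict(set)
    for ev in _flatten(events):
        if grouping == "role-pair":
            key = _role_pair_key(ev, roles)
        elif grouping == "site-pair":
            key = (
                ev.donor.site_label or f"{ev.donor.element}{ev.donor.atom_index}",
                ev.acceptor.site_label
                or f"{ev.acceptor.element}{ev.acceptor.atom_index}",
            )
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        totals[key] += 1
        frames_with[key].add(ev.frame_index)
    rows = []
    for key in sorted(totals, key=str):
        rows.append(
            {
                "group": key,
                "avg_bonds_per_frame": totals[key] / n_frames,
                "frac_frames_bonded": len(frames_with[key]) / n_frames,
                "n_events": totals[key],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group", "avg_bonds_per_frame", "frac_frames_bonded", "n_events"],
    )


# -- lifetimes ----------------------------------------------------------


@dataclass
class LifetimeResult:
    """Mean hydrogen-bond lifetime with its supporting survival curve.

    ``mean_lifetime_ps`` is None when no bonded frames exist (a missing
    value, deliberately not zero).  The survival curve S(t) is the fraction
    of bond episodes lasting at least t.
    """

    mean_lifetime_ps: float | None
    n_episodes: int
    mode: str
    survival_t_ps: np.ndarray = field(default_factory=lambda: np.empty(0))
    survival: np.ndarray = field(default_factory=lambda: np.empty(0))


def bond_indicator_series(
    events, n_frames: int
) -> tuple[list[tuple[int, int, int]], np.ndarray]:
    """Per-bond-identity boolean time series.

    A bond identity is the (donor atom, hydrogen, acceptor atom) triple.
    Returns (keys, indicator matrix of shape (n_bonds, n_frames)).
    """
    keys: dict[tuple[int, int, int], int] = {}
    rows: list[list[int]] = []
    for ev in _flatten(events):
        k = (ev.donor.atom_index, ev.hydrogen, ev.acceptor.atom_index)
        if k not in keys:
            keys[k] = len(keys)
            rows.append([])
        rows[keys[k]].append(ev.frame_index)
    mat = np.zeros((len(keys), n_frames), dtype=bool)
    for i, frames in enumerate(rows):
        mat[i, frames] = True
    return list(keys), mat


def _run_lengths(x: np.ndarray, gap_tolerance: int = 0) -> list[int]:
    """Lengths of maximal True runs, merging gaps <= gap_tolerance frames."""
    idx = np.nonzero(x)[0]
    if idx.size == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= gap_tolerance:
            prev = i
        else:
            runs.append(prev - start + 1)
            start = prev = i
    runs.append(prev - start + 1)
    return runs


def lifetimes(
    indicators: np.ndarray,
    dt: float,
    mode: str = "continuous",
    gap_tolerance: int = 0,
    max_lag: int | None = None,
) -> LifetimeResult:
    """Mean bond lifetime from boolean indicator series.

    ``indicators`` is (n_bonds, n_frames) or a single 1-D series.

    continuous: mean length of maximal uninterrupted bonded runs x dt
    (gaps up to ``gap_tolerance`` frames may be bridged).  Runs truncated by
    the trajectory ends are included.

    intermittent: integral of the bond-existence autocorrelation
    C(t) = <h(0) h(t)> / <h(0) h(0)> pooled over bonds, integrated by the
    trapezoid rule up to ``max_lag`` frames (default n_frames // 2).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x = np.atleast_2d(np.asarray(indicators, dtype=bool))
    n_frames = x.shape[1]
    if not x.any():
        return LifetimeResult(None, 0, mode)

    if mode == "continuous":
        runs: list[int] = []
        for row in x:
            runs.extend(_run_lengths(row, gap_tolerance))
        lengths = np.array(runs, dtype=float) * dt
        ts = np.sort(np.unique(lengths))
        survival = np.array([(lengths >= t).mean() for t in ts])
        return LifetimeResult(
            float(lengths.mean()), len(runs), mode, ts, survival
        )
    if mode == "intermittent":
        lag_max = max_lag if max_lag is not None else n_frames // 2
        lag_max = max(1, min(lag_max, n_frames - 1))
        xf = x.astype(float)
        # FFT-based <h(0) h(t)> pooled over all bond identities
        nfft = 2 * n_frames
        spec = np.fft.rfft(xf, n=nfft, axis=1)
        corr = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, : lag_max + 1]
        norm = (n_frames - np.arange(lag_max + 1)).astype(float)
        pooled = corr.sum(axis=0) / norm
        c = pooled / pooled[0]
        tau = float(np.trapezoid(c, dx=dt))
        return LifetimeResult(
            tau, int(x.shape[0]), mode, np.arange(lag_max + 1) * dt, c
        )
    raise ValueError(f"unknown lifetime mode {mode!r}")


def lifetimes_from_events(
    events,
    n_frames: int,
    dt: float,
    mode: str = "continuous",
    gap_tolerance: int = 0,
) -> LifetimeResult:
    """Lifetime statistics straight from an event stream."""
    _, mat = bond_indicator_series(events, n_frames)
    if mat.size == 0:
        return LifetimeResult(None, 0, mode)
    return lifetimes(mat, dt, mode=mode, gap_tolerance=gap_tolerance)


# -- scorecard ----------------------------------------------------------


@dataclass
class MonomerScorecard:
    """All screening statistics for one template-monomer system."""

    monomer_name: str
    ebn: int
    hbn_max: int
    frames_at_ebn: float
    occupancy_site_pairs: dict[tuple[str, str], float]
    occupancy_role_pairs: dict[str, float]
    mean_lifetime_ps: dict[str, float | None]
    ratio: str | None = None
    n_frames: int = 0

    def __post_init__(self) -> None:
        if self.ebn > self.hbn_max:
            raise ValueError("EBN cannot exceed HBN_Max")
        if not 0 <= self.frames_at_ebn <= 1:
            raise ValueError("frames_at_ebn must lie in [0, 1]")

    @property
    def template_monomer_occupancy(self) -> float:
        return self.occupancy_role_pairs.get("monomer-template", 0.0)

    def to_dict(self) -> dict:
        return {
            "monomer_name": self.monomer_name,
            "ebn": self.ebn,
            "hbn_max": self.hbn_max,
            "frames_at_ebn": self.frames_at_ebn,
            "occupancy_site_pairs": {
                f"{d}|{a}": v for (d, a), v in self.occupancy_site_pairs.items()
            },
            "occupancy_role_pairs": self.occupancy_role_pairs,
            "mean_lifetime_ps": self.mean_lifetime_ps,
            "ratio": self.ratio,
            "n_frames": self.n_frames,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "MonomerScorecard":
        occ = {
            tuple(k.split("|", 1)): v
            for k, v in data.get("occupancy_site_pairs", {}).items()
        }
        return cls(
            monomer_name=data["monomer_name"],
            ebn=int(data["ebn"]),
            hbn_max=int(data["hbn_max"]),
            frames_at_ebn=float(data["frames_at_ebn"]),
            occupancy_site_pairs=occ,
            occupancy_role_pairs=dict(data.get("occupancy_role_pairs", {})),
            mean_lifetime_ps=dict(data.get("mean_lifetime_ps", {})),
            ratio=data.get("ratio"),
            n_frames=int(data.get("n_frames", 0)),
        )


def scorecard(
    traj: Trajectory,
    selection: SystemSelection,
    monomer_name: str | None = None,
    ratio: str | None = None,
    lifetime_mode: str = "continuous",
    gap_tolerance: int = 0,
) -> MonomerScorecard:
    """Run the full screening pipeline on one system.

    Detects all inter-molecular hydrogen bonds, reduces the template-monomer
    stream to EBN/HBN_Max, and tabulates occupancies (by role pair and, for
    template-monomer bonds, by site-label pair) and continuous lifetimes per
    role pair.  Deterministic given the trajectory.
    """
    n_frames = traj.n_frames
    all_events = _flatten(detect_trajectory_hbonds(traj, selection))
    roles = selection.molecule_roles
    series = binding_series(all_events, n_frames, selection)
    ebn, frac = effective_binding_number(series)
    hbn = max_hbond_number(series)

    role_occ = occupancy(all_events, n_frames, selection, grouping="role-pair")
    role_occ_map = dict(
        zip(role_occ["group"], role_occ["avg_bonds_per_frame"])
    )
    tm_events = [
        ev
        for ev in all_events
        if {roles[ev.donor_molecule], roles[ev.acceptor_molecule]}
        == {MoleculeRole.TEMPLATE, MoleculeRole.MONOMER}
    ]
    site_occ = occupancy(tm_events, n_frames, selection, grouping="site-pair")
    site_occ_map = {
        tuple(g): v
        for g, v in zip(site_occ["group"], site_occ["avg_bonds_per_frame"])
    }

    lifetimes_by_pair: dict[str, float | None] = {}
    by_pair: dict[str, list[HBondEvent]] = defaultdict(list)
    for ev in all_events:
        by_pair[_role_pair_key(ev, roles)].append(ev)
    for pair_key in sorted(by_pair):
        res = lifetimes_from_events(
            by_pair[pair_key], n_frames, traj.dt,
            mode=lifetime_mode, gap_tolerance=gap_tolerance,
        )
        lifetimes_by_pair[pair_key] = res.mean_lifetime_ps

    if monomer_name is None:
        monomers = selection.molecules_with_role(MoleculeRole.MONOMER)
        monomer_name = monomers[0].name if monomers else "(no monomer)"
    return MonomerScorecard(
        monomer_name=monomer_name,
        ebn=ebn,
        hbn_max=hbn,
        frames_at_ebn=frac,
        occupancy_site_pairs=site_occ_map,
        occupancy_role_pairs=role_occ_map,
        mean_lifetime_ps=lifetimes_by_pair,
        ratio=ratio,
        n_frames=n_frames,
    )


def rank_monomers(scorecards: Sequence[MonomerScorecard]) -> list[MonomerScorecard]:
    """Rank monomers by (EBN, HBN_Max, template-monomer occupancy) descending.

    The sort is stable: fully tied scorecards keep their input order.
    """
    if not scorecards:
        raise ValueError("need at least one scorecard")
    return sorted(
        scorecards,
        key=lambda c: (c.ebn, c.hbn_max, c.template_monomer_occupancy),
        reverse=True,
    )
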