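"""Trajectory and structure I/O.

Coordinates are carried in nanometres and times in picoseconds throughout
the package.  Standard structure formats (GRO, PDB) and compressed
trajectories (XTC, DCD) are read through MDAnalysis; a plain-text FIXTURE
trajectory format is provided so tests and synthetic data need no binary
codec:

    line 1:            natoms dt
    per frame:         time boxx boxy boxz
                       natoms lines of "x y z"      (nm, ps)

Only orthorhombic boxes are supported (the screening protocol uses a cubic
box); triclinic input raises an explicit error.  Coordinates are not wrapped
on read — minimum-image handling happens in the geometry code.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Frame",
    "Trajectory",
    "TrajectoryError",
    "read_structure",
    "read_trajectory",
    "iter_fixture_frames",
    "write_fixture_trajectory",
    "expected_frame_count",
]

ANGSTROM_TO_NM = 0.1


class TrajectoryError(ValueError):
    """Raised for malformed or unsupported trajectory/structure input."""


@dataclass
class Frame:
    """One snapshot: per-atom coordinates (nm), box edges (nm), time (ps)."""

    coords: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TrajectoryError(
                f"coords must be (n_atoms, 3), got {self.coords.shape}"
            )
        if self.box.shape != (3,):
            raise TrajectoryError(f"box must be a 3-vector, got {self.box.shape}")
        if not np.all(self.box > 0):
            raise TrajectoryError(f"box edges must be > 0, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Ordered frames with a nominal inter-frame spacing dt (ps).

    ``uniform_dt`` is False when the frame times were not uniformly spaced;
    in that case ``dt`` is the median spacing.
    """

    frames: list[Frame]
    dt: float
    n_atoms: int
    uniform_dt: bool = True

    def __post_init__(self) -> None:
        for i, f in enumerate(self.frames):
            if f.n_atoms != self.n_atoms:
                raise TrajectoryError(
                    f"frame {i} has {f.n_atoms} atoms, expected {self.n_atoms}"
                )
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise TrajectoryError("frame times must be strictly increasing")

    @classmethod
    def from_frames(cls, frames: Iterable[Frame]) -> "Trajectory":
        frames = list(frames)
        if not frames:
            raise TrajectoryError("cannot build a trajectory from zero frames")
        times = np.array([f.time for f in frames])
        if len(frames) > 1:
            spacings = np.diff(times)
            dt = float(np.median(spacings))
            uniform = bool(np.allclose(spacings, spacings[0], rtol=1e-6, atol=1e-9))
            if not uniform:
                warnings.warn(
                    "nonuniform frame spacing; dt reported as the median",
                    stacklevel=2,
                )
        else:
            dt, uniform = 1.0, True
        return cls(frames, dt=dt, n_atoms=frames[0].n_atoms, uniform_dt=uniform)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def coordinate_array(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames])

    def box_array(self) -> np.ndarray:
        return np.stack([f.box for f in self.frames])


# -- structures ---------------------------------------------------------


def _guess_element(name: str) -> str:
    """Element from an atom name: first alphabetic character, upper-cased.

    Sufficient for the organic (H/C/N/O/S/F) systems this package targets;
    two-letter organics like Cl/Br are recognised explicitly.
    """
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        raise TrajectoryError(f"cannot guess element from atom name {name!r}")
    two = stripped[:2].capitalize()
    if two in {"Cl", "Br"}:
        return two
    return stripped[0].upper()


def _check_orthorhombic(dimensions: np.ndarray, path: str) -> np.ndarray:
    if dimensions is None or not np.all(dimensions[:3] > 0):
        raise TrajectoryError(f"{path}: missing or degenerate box")
    angles = dimensions[3:6]
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise TrajectoryError(
            f"{path}: triclinic box (angles {angles}) is unsupported; "
            "only orthorhombic boxes are handled"
        )
    return dimensions[:3] * ANGSTROM_TO_NM


def read_structure(path: str | os.PathLike, format: str | None = None):
    """Read a GRO or PDB structure.

    Returns ``(elements, names, frame)`` with coordinates converted to nm
    and the original atom order preserved.
    """
    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise TrajectoryError(f"{path}: empty file")
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in {"GRO", "PDB"}:
        raise TrajectoryError(f"unsupported structure format {fmt!r}")
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # MDAnalysis raises assorted parse errors
        raise TrajectoryError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    names = [str(n) for n in u.atoms.names]
    try:
        elements = [str(e).capitalize() for e in u.atoms.elements]
    except Exception:
        elements = [_guess_element(n) for n in names]
    box = _check_orthorhombic(u.dimensions, str(path))
    coords = u.atoms.positions.astype(float) * ANGSTROM_TO_NM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        time = float(getattr(u.trajectory.ts, "time", 0.0) or 0.0)
    return elements, names, Frame(coords=coords, box=box, time=time)


# -- trajectories -------------------------------------------------------


def iter_fixture_frames(path: str | os.PathLike) -> Iterator[Frame]:
    """Stream frames from a FIXTURE text trajectory."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise TrajectoryError(f"{path}:1: empty or missing header")
        parts = header.split()
        if len(parts) != 2:
            raise TrajectoryError(
                f"{path}:1: header must be 'natoms dt', got {header.strip()!r}"
            )
        n_atoms = int(parts[0])
        lineno = 1
        while True:
            frame_line = fh.readline()
            lineno += 1
            if not frame_line.strip():
                return
            parts = frame_line.split()
            if len(parts) != 4:
                raise TrajectoryError(
                    f"{path}:{lineno}: expected 'time boxx boxy boxz', "
                    f"got {frame_line.strip()!r}"
                )
            time = float(parts[0])
            box = np.array([float(x) for x in parts[1:]])
            coords = np.empty((n_atoms, 3))
            for i in range(n_atoms):
                line = fh.readline()
                lineno += 1
                if not line:
                    raise TrajectoryError(
                        f"{path}:{lineno}: truncated frame (expected "
                        f"{n_atoms} coordinate lines, got {i})"
                    )
                vals = line.split()
                if len(vals) != 3:
                    raise TrajectoryError(
                        f"{path}:{lineno}: expected 'x y z', got {line.strip()!r}"
                    )
                coords[i] = [float(v) for v in vals]
            yield Frame(coords=coords, box=box, time=time)


def _fixture_header(path: str | os.PathLike) -> tuple[int, float]:
    with open(path) as fh:
        parts = fh.readline().split()
    if len(parts) != 2:
        raise TrajectoryError(f"{path}:1: header must be 'natoms dt'")
    return int(parts[0]), float(parts[1])


def read_trajectory(
    path: str | os.PathLike,
    format: str | None = None,
    n_atoms: int | None = None,
    structure: str | os.PathLike | None = None,
) -> Trajectory:
    """Read a trajectory (XTC/DCD via MDAnalysis, FIXTURE via the text codec).

    XTC/DCD need a ``structure`` (GRO/PDB) for the atom roster; the FIXTURE
    format is self-contained.  ``n_atoms``, when given, is validated against
    the file.
    """
    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"{path}: no such file")
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt in {"FIXTURE", "TRAJ", "TXT"}:
        file_n_atoms, dt_declared = _fixture_header(path)
        if n_atoms is not None and n_atoms != file_n_atoms:
            raise TrajectoryError(
                f"{path}: atom-count mismatch (file {file_n_atoms}, "
                f"expected {n_atoms})"
            )
        frames = list(iter_fixture_frames(path))
        if not frames:
            raise TrajectoryError(f"{path}: trajectory contains no frames")
        traj = Trajectory.from_frames(frames)
        if len(frames) == 1:
            traj.dt = dt_declared
        return traj
    if fmt in {"XTC", "DCD"}:
        if structure is None:
            raise TrajectoryError(
                f"{fmt} trajectories need a GRO/PDB structure for the atom roster"
            )
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(structure), str(path))
        if n_atoms is not None and len(u.atoms) != n_atoms:
            raise TrajectoryError(
                f"{path}: atom-count mismatch (file {len(u.atoms)}, "
                f"expected {n_atoms})"
            )
        frames = []
        for ts in u.trajectory:
            box = _check_orthorhombic(ts.dimensions, str(path))
            frames.append(
                Frame(
                    coords=u.atoms.positions.astype(float) * ANGSTROM_TO_NM,
                    box=box,
                    time=float(ts.time),
                )
            )
        return Trajectory.from_frames(frames)
    raise TrajectoryError(f"unsupported trajectory format {fmt!r}")


def write_fixture_trajectory(
    traj: Trajectory, path: str | os.PathLike, precision: int = 6
) -> None:
    """Write a trajectory in the FIXTURE text format (nm / ps)."""
    fmt = f"%.{precision}f"
    with open(path, "w") as fh:
        fh.write(f"{traj.n_atoms} {fmt % traj.dt}\n")
        for frame in traj.frames:
            fh.write(
                " ".join(fmt % v for v in (frame.time, *frame.box)) + "\n"
            )
            np.savetxt(fh, frame.coords, fmt=fmt, delimiter=" ")


# -- bookkeeping --------------------------------------------------------


def expected_frame_count(
    production_length_ns: float,
    save_interval_steps: int,
    timestep_fs: float,
) -> int:
    """Number of saved frames for a production run.

    A ``production_length_ns`` run integrated at ``timestep_fs`` with
    coordinates stored every ``save_interval_steps`` steps yields
    ``floor(length / (interval * timestep))`` frames; e.g. 20 ns saved every
    500 steps at 2 fs gives 20,000 frames at 1 ps spacing.
    """
    if production_length_ns <= 0 or save_interval_steps <= 0 or timestep_fs <= 0:
        raise ValueError("all inputs must be > 0")
    total_fs = production_length_ns * 1e6
    return int(math.floor(total_fs / (save_interval_steps * timestep_fs)))
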