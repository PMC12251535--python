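"""Trajectory containers and extended-XYZ I/O.

The canonical on-disk format is extended XYZ: per frame, an atom-count line, a
comment line that may carry ``dt=<fs>``, then one line per atom with columns

    element  x  y  z  [vx  vy  vz]

Coordinates are in Å, velocities in Å/fs, masses in amu (one internal unit
system; conversions happen only at the I/O boundary). Binary trajectory
formats and periodic-box metadata are out of scope: the target simulations
are non-periodic droplets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import ATOMIC_MASSES


class TrajectoryError(ValueError):
    """Base class for trajectory-layer errors."""


class ParseError(TrajectoryError):
    """Malformed trajectory file; the message names the offending line."""


class MassResolutionError(TrajectoryError):
    """Element symbol with no known mass and no override supplied."""


class SelectionError(TrajectoryError):
    """Invalid atom selection."""


class InsufficientDataError(TrajectoryError):
    """Operation needs more frames than the trajectory provides."""


@dataclass
class AtomTable:
    """Per-atom static metadata: element symbol, mass (amu), free-text label."""

    elements: list[str]
    masses: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.elements) != self.masses.shape[0]:
            raise TrajectoryError("elements and masses length mismatch")
        if np.any(self.masses <= 0):
            raise TrajectoryError("atomic masses must be strictly positive")
        if not self.labels:
            self.labels = [""] * len(self.elements)
        elif len(self.labels) != len(self.elements):
            raise TrajectoryError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.elements)

    def subset(self, indices: Sequence[int]) -> "AtomTable":
        idx = list(indices)
        return AtomTable(
            [self.elements[i] for i in idx],
            self.masses[idx],
            [self.labels[i] for i in idx],
        )


@dataclass
class Trajectory:
    """Frames of Cartesian positions (and optionally velocities) plus metadata.

    positions  : (n_frames, n_atoms, 3) in Å
    velocities : (n_frames, n_atoms, 3) in Å/fs, or None
    dt         : sampling interval in fs
    """

    atoms: AtomTable
    positions: np.ndarray
    velocities: np.ndarray | None
    dt: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise TrajectoryError("positions must have shape (n_frames, n_atoms, 3)")
        if self.positions.shape[1] != len(self.atoms):
            raise TrajectoryError("atom table does not match frame atom count")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise TrajectoryError("velocities shape differs from positions")
        if not self.dt > 0:
            raise TrajectoryError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def has_velocities(self) -> bool:
        return self.velocities is not None

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in fs (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.dt

    @property
    def masses(self) -> np.ndarray:
        return self.atoms.masses


def resolve_masses(
    elements: Sequence[str], overrides: dict[str | int, float] | None = None
) -> np.ndarray:
    """Masses (amu) for element symbols; per-symbol or per-index overrides win."""
    overrides = overrides or {}
    masses = np.empty(len(elements))
    for i, el in enumerate(elements):
        if i in overrides:
            masses[i] = overrides[i]
        elif el in overrides:
            masses[i] = overrides[el]
        elif el in ATOMIC_MASSES:
            masses[i] = ATOMIC_MASSES[el]
        else:
            raise MassResolutionError(
                f"no mass known for element {el!r} (atom {i}); supply a mass table"
            )
    return masses


def read_mass_table(path: str | Path) -> dict[str | int, float]:
    """Read a two-column TSV mass-override table (element-or-index, amu)."""
    overrides: dict[str | int, float] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{ln}: expected 'key<TAB>mass', got {line!r}")
        key: str | int = int(parts[0]) if parts[0].isdigit() else parts[0]
        overrides[key] = float(parts[1])
    return overrides


_DT_RE = re.compile(r"\bdt\s*=\s*([0-9.eE+-]+)")


def read_trajectory(
    path: str | Path,
    dt: float | None = None,
    mass_overrides: dict[str | int, float] | None = None,
) -> Trajectory:
    """Read an (extended-)XYZ trajectory.

    Velocities are populated iff velocity columns (7 per-atom fields) are
    present. ``dt`` is taken from a ``dt=<fs>`` token on the comment line of
    the first frame unless given explicitly (an explicit value wins).
    """
    lines = Path(path).read_text().splitlines()
    if not any(s.strip() for s in lines):
        raise ParseError(f"{path}: empty file")

    frames_pos: list[np.ndarray] = []
    frames_vel: list[np.ndarray] = []
    elements: list[str] | None = None
    file_dt: float | None = None
    has_vel: bool | None = None

    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(
                f"{path}:{i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        if natoms <= 0:
            raise ParseError(f"{path}:{i + 1}: non-positive atom count")
        if i + 1 >= len(lines):
            raise ParseError(f"{path}:{i + 1}: truncated frame header")
        comment = lines[i + 1]
        if file_dt is None:
            m = _DT_RE.search(comment)
            if m:
                file_dt = float(m.group(1))
        if i + 2 + natoms > len(lines):
            raise ParseError(f"{path}:{i + 1}: frame truncated ({natoms} atoms expected)")
        pos = np.empty((natoms, 3))
        vel = np.empty((natoms, 3))
        els: list[str] = []
        for a in range(natoms):
            ln = i + 2 + a
            parts = lines[ln].split()
            if len(parts) not in (4, 7):
                raise ParseError(
                    f"{path}:{ln + 1}: expected 4 or 7 columns, got {len(parts)}"
                )
            frame_has_vel = len(parts) == 7
            if has_vel is None:
                has_vel = frame_has_vel
            elif has_vel != frame_has_vel:
                raise ParseError(f"{path}:{ln + 1}: inconsistent velocity columns")
            els.append(parts[0])
            try:
                pos[a] = [float(v) for v in parts[1:4]]
                if frame_has_vel:
                    vel[a] = [float(v) for v in parts[4:7]]
            except ValueError as exc:
                raise ParseError(f"{path}:{ln + 1}: non-numeric field") from exc
        if elements is None:
            elements = els
        elif elements != els:
            raise ParseError(f"{path}:{i + 1}: element order differs between frames")
        frames_pos.append(pos)
        if has_vel:
            frames_vel.append(vel)
        i += 2 + natoms

    assert elements is not None
    eff_dt = dt if dt is not None else file_dt
    if eff_dt is None:
        raise ParseError(
            f"{path}: no 'dt=<fs>' on the comment line and no dt argument given"
        )
    atoms = AtomTable(elements, resolve_masses(elements, mass_overrides))
    return Trajectory(
        atoms,
        np.stack(frames_pos),
        np.stack(frames_vel) if frames_vel else None,
        eff_dt,
    )


def write_trajectory(
    traj: Trajectory, path: str | Path, precision: int = 10
) -> None:
    """Write extended XYZ, with velocity columns when present.

    Lossless to ``precision`` decimal places; ``dt`` is recorded on every
    comment line so the file round-trips without external metadata.
    """
    if traj.n_atoms == 0:
        raise TrajectoryError("refusing to write a zero-atom trajectory")
    fmt = f"%.{precision}f"
    out = []
    for f in range(traj.n_frames):
        out.append(str(traj.n_atoms))
        out.append(f"frame={f} dt={traj.dt!r}")
        for a in range(traj.n_atoms):
            fields = [traj.atoms.elements[a]]
            fields += [fmt % v for v in traj.positions[f, a]]
            if traj.velocities is not None:
                fields += [fmt % v for v in traj.velocities[f, a]]
            out.append(" ".join(fields))
    Path(path).write_text("\n".join(out) + "\n")


def finite_difference_velocities(traj: Trajectory) -> Trajectory:
    """Derive velocities by central differences, dropping both endpoint frames.

    v(t) = [x(t+δt) − x(t−δt)] / (2δt); exact for linear motion, with a
    relative error of ω²δt²/6 for a sinusoid of angular frequency ω.
    Endpoints are dropped, never extrapolated, to avoid spectral artifacts.
    """
    if traj.n_frames < 3:
        raise InsufficientDataError(
            f"central differences need ≥ 3 frames, got {traj.n_frames}"
        )
    vel = (traj.positions[2:] - traj.positions[:-2]) / (2.0 * traj.dt)
    return Trajectory(traj.atoms, traj.positions[1:-1].copy(), vel, traj.dt)


def select_subsystem(traj: Trajectory, indices: Sequence[int]) -> Trajectory:
    """Restrict the trajectory to the given atoms, in the given order."""
    idx = list(indices)
    if not idx:
        raise SelectionError("empty atom selection")
    if len(set(idx)) != len(idx):
        raise SelectionError("duplicate atom indices in selection")
    for i in idx:
        if not 0 <= i < traj.n_atoms:
            raise SelectionError(f"atom index {i} out of range (N={traj.n_atoms})")
    return Trajectory(
        traj.atoms.subset(idx),
        traj.positions[:, idx].copy(),
        traj.velocities[:, idx].copy() if traj.velocities is not None else None,
        traj.dt,
    )


def time_window(traj: Trajectory, t_start: float, t_end: float) -> Trajectory:
    """Frames with timestamps in the half-open interval [t_start, t_end) fs."""
    if not (0 <= t_start < t_end):
        raise TrajectoryError(f"invalid window [{t_start}, {t_end})")
    mask = (traj.times >= t_start) & (traj.times < t_end)
    if not mask.any():
        raise TrajectoryError(f"window [{t_start}, {t_end}) fs selects no frames")
    return Trajectory(
        traj.atoms,
        traj.positions[mask].copy(),
        traj.velocities[mask].copy() if traj.velocities is not None else None,
        traj.dt,
    )


def _replace_velocities(traj: Trajectory, velocities: np.ndarray) -> Trajectory:
    return replace(traj, velocities=velocities)
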