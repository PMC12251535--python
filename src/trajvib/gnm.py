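"""Generalized normal modes from the mass-weighted velocity covariance matrix.

The analysis assumes that well-separated vibrations produce statistically
uncorrelated atomic momenta over the sampled trajectory. The covariance
matrix of mass-weighted Cartesian velocities,

    K_ij = ½ √(m_i m_j) ⟨(q̇_i − ⟨q̇_i⟩)(q̇_j − ⟨q̇_j⟩)⟩,

is diagonalized; its orthonormal eigenvectors are the generalized modes and
each eigenvalue is that mode's mean kinetic energy (amu·Å²/fs²). Per-frame
generalized velocities are the projections Q̇(t) = Lᵀ·√m·q̇(t); their power
spectra locate the mode frequencies.

The ensemble average ⟨·⟩ is a plain time average over the single collected
trajectory (population convention, divisor N). The projection acts on
mass-weighted velocities: that is the only convention under which L is
orthogonal and the eigenvalue-equals-mean-KE identity is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .trajio import AtomTable, Trajectory


class GNMError(ValueError):
    """Invalid input to the generalized-normal-mode analysis."""


@dataclass
class VelocityCovariance:
    """½·mass-weighted velocity covariance (Eq. K above), kinetic-energy scale.

    matrix          : (3N, 3N), symmetric PSD, amu·Å²/fs²
    mean_velocities : the subtracted per-coordinate mean velocities ⟨q̇_i⟩ (Å/fs)
    masses          : per-coordinate masses m_i (amu), length 3N
    n_frames_used   : frames entering the time average
    """

    matrix: np.ndarray
    mean_velocities: np.ndarray
    masses: np.ndarray
    n_frames_used: int

    @property
    def trace(self) -> float:
        """Mean total kinetic energy of the analyzed atoms."""
        return float(np.trace(self.matrix))


@dataclass
class GeneralizedModeSet:
    """Eigenvectors (columns of ``modes``) and eigenvalues of K.

    Modes are sorted by descending eigenvalue (mean kinetic energy per mode).
    Columns live in the mass-weighted Cartesian basis and are orthonormal;
    the sign convention makes each column's largest-magnitude component
    positive. ``degenerate_blocks`` lists index ranges whose eigenvalues
    agree to a relative gap < ``degeneracy_rtol``: within a block only the
    spanned subspace is meaningful, not individual vectors.
    """

    modes: np.ndarray
    kinetic_energies: np.ndarray
    masses: np.ndarray
    mean_velocities: np.ndarray
    degenerate_blocks: list[tuple[int, int]] = field(default_factory=list)
    external_flags: np.ndarray | None = None

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]


@dataclass
class ModeVelocitySeries:
    """Per-frame generalized mode velocities Q̇(t), one channel per mode."""

    series: np.ndarray  # (n_frames, n_modes)
    dt: float
    mode_index_map: np.ndarray  # column -> mode index in the GeneralizedModeSet

    @property
    def n_channels(self) -> int:
        return self.series.shape[1]

    def channel(self, mode_index: int) -> np.ndarray:
        cols = np.nonzero(self.mode_index_map == mode_index)[0]
        if cols.size == 0:
            raise IndexError(f"mode {mode_index} not in this series")
        return self.series[:, cols[0]]


def _require_velocities(traj: Trajectory) -> np.ndarray:
    if traj.velocities is None:
        raise GNMError(
            "trajectory has no velocities; derive them first "
            "(trajio.finite_difference_velocities)"
        )
    return traj.velocities.reshape(traj.n_frames, -1)


def coordinate_masses(traj: Trajectory) -> np.ndarray:
    """Per-coordinate masses: each atom's mass repeated for x, y, z."""
    return np.repeat(traj.masses, 3)


def mass_weighted_velocities(traj: Trajectory) -> np.ndarray:
    """(n_frames, 3N) matrix with entries √m_i·q̇_i."""
    vel = _require_velocities(traj)
    return vel * np.sqrt(coordinate_masses(traj))


def remove_com_drift(traj: Trajectory) -> Trajectory:
    """Subtract the centre-of-mass velocity frame-wise (optional pre-clean)."""
    vel = _require_velocities(traj).reshape(traj.n_frames, traj.n_atoms, 3)
    m = traj.masses[None, :, None]
    vcom = (m * vel).sum(axis=1, keepdims=True) / traj.masses.sum()
    return Trajectory(traj.atoms, traj.positions.copy(), vel - vcom, traj.dt)


def velocity_covariance(traj: Trajectory) -> VelocityCovariance:
    """Build K_ij = ½√(m_i m_j)·⟨δq̇_i·δq̇_j⟩ by time-averaging (divisor N)."""
    vel = _require_velocities(traj)
    if traj.n_frames < 2:
        raise GNMError("covariance needs at least 2 frames")
    mean_v = vel.mean(axis=0)
    mw = (vel - mean_v) * np.sqrt(coordinate_masses(traj))
    K = 0.5 * (mw.T @ mw) / traj.n_frames
    K = 0.5 * (K + K.T)  # enforce exact symmetry against rounding
    return VelocityCovariance(K, mean_v, coordinate_masses(traj), traj.n_frames)


def velocity_covariance_bruteforce(traj: Trajectory) -> np.ndarray:
    """Explicit double-loop evaluation of K; independent check for tiny systems."""
    vel = _require_velocities(traj)
    m = coordinate_masses(traj)
    n = vel.shape[1]
    mean_v = vel.mean(axis=0)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for t in range(traj.n_frames):
                acc += (vel[t, i] - mean_v[i]) * (vel[t, j] - mean_v[j])
            K[i, j] = 0.5 * np.sqrt(m[i] * m[j]) * acc / traj.n_frames
    return K


def diagonalize_covariance(
    K: VelocityCovariance, *, symmetry_tol: float = 1e-8, degeneracy_rtol: float = 1e-8
) -> GeneralizedModeSet:
    """Eigendecompose K; modes sorted by descending mean kinetic energy.

    Sign convention: the largest-magnitude component of every eigenvector is
    made positive, so the decomposition is deterministic across BLAS builds.
    """
    A = np.asarray(K.matrix)
    scale = max(1.0, float(np.abs(A).max()))
    if np.abs(A - A.T).max() > symmetry_tol * scale:
        raise GNMError("covariance matrix is not symmetric within tolerance")
    evals, evecs = scipy.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for a in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, a]))
        if evecs[k, a] < 0:
            evecs[:, a] = -evecs[:, a]
    blocks: list[tuple[int, int]] = []
    ref = max(abs(evals[0]), 1e-300)
    start = 0
    for a in range(1, len(evals) + 1):
        if a == len(evals) or abs(evals[a - 1] - evals[a]) > degeneracy_rtol * ref:
            if a - start > 1:
                blocks.append((start, a))
            start = a
    return GeneralizedModeSet(
        evecs, evals, K.masses, K.mean_velocities, degenerate_blocks=blocks
    )


def project_mode_velocities(
    traj: Trajectory, modes: GeneralizedModeSet, *, subtract_mean: bool = True
) -> ModeVelocitySeries:
    """Per-frame generalized velocities Q̇(t) = Lᵀ·√m·(q̇(t) − ⟨q̇⟩).

    With ``subtract_mean`` (the default, matching the covariance definition)
    the time average of ½Q̇α² reproduces mode α's eigenvalue exactly on the
    frames used to build K. With ``subtract_mean=False`` raw velocities are
    projected and the per-frame Parseval identity Σα Q̇α² = Σᵢ m_i q̇_i²
    (twice the kinetic energy) holds instead.
    """
    vel = _require_velocities(traj)
    if vel.shape[1] != modes.modes.shape[0]:
        raise GNMError(
            f"mode dimension {modes.modes.shape[0]} does not match 3N={vel.shape[1]}"
        )
    if subtract_mean:
        vel = vel - vel.mean(axis=0)
    mw = vel * np.sqrt(coordinate_masses(traj))
    return ModeVelocitySeries(
        mw @ modes.modes, traj.dt, np.arange(modes.n_modes)
    )


def external_generator_matrix(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation generators (3N, n_ext).

    Built at the given geometry about its centre of mass: 3 rigid
    translations always; up to 3 rigid rotations, fewer for linear molecules
    or single atoms (near-zero-norm generators are dropped, not an error).
    """
    positions = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    n_atoms = positions.shape[0]
    if n_atoms < 1:
        raise GNMError("need at least one atom")
    com = (masses[:, None] * positions).sum(axis=0) / masses.sum()
    r = positions - com
    sqm = np.sqrt(masses)
    gens = []
    for ax in range(3):
        g = np.zeros((n_atoms, 3))
        g[:, ax] = sqm
        gens.append(g.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        g = sqm[:, None] * np.cross(e, r)
        gens.append(g.ravel())
    G = np.column_stack(gens)
    # Orthonormalize and drop rank-deficient directions (linear/monoatomic).
    Q, R, _ = scipy.linalg.qr(G, mode="economic", pivoting=True)
    tol = max(G.shape) * np.finfo(float).eps * abs(R[0, 0])
    rank = int((np.abs(np.diag(R)) > tol).sum())
    return Q[:, :rank]


def external_generators(traj: Trajectory) -> np.ndarray:
    """Translation/rotation generators at the trajectory's mean geometry."""
    return external_generator_matrix(traj.positions.mean(axis=0), traj.masses)


def classify_external_modes(
    traj: Trajectory, modes: GeneralizedModeSet, *, threshold: float = 0.5
) -> np.ndarray:
    """Flag modes dominated by rigid translation/rotation.

    A mode is external when the squared norm of its projection onto the
    span of the mass-weighted translation and rigid-rotation generators
    exceeds ``threshold``. For a non-linear molecule 6 flags are expected;
    fewer generators exist for linear molecules and single atoms.
    """
    G = external_generators(traj)
    overlap_sq = (G.T @ modes.modes) ** 2
    flags = overlap_sq.sum(axis=0) > threshold
    modes.external_flags = flags
    return flags


def mode_composition(
    modes: GeneralizedModeSet,
    atoms: AtomTable,
    grouping: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Fraction of each mode's squared eigenvector norm on each atom group.

    ``grouping`` maps group names to atom indices; atoms covered by no group
    are pooled under ``"other"`` so fractions sum to 1 per mode. With no
    grouping, the atom labels of ``atoms`` define the groups. A group
    covering no atoms yields a zero column and a warning.
    """
    n_atoms = len(atoms)
    if modes.modes.shape[0] != 3 * n_atoms:
        raise GNMError("atom table does not match mode dimension")
    if grouping is None:
        grouping = {}
        for i, lab in enumerate(atoms.labels):
            grouping.setdefault(lab or "unlabelled", []).append(i)  # type: ignore[union-attr]
    grouping = {k: list(v) for k, v in grouping.items()}
    covered = set()
    for name, idx in grouping.items():
        if not idx:
            warnings.warn(f"atom group {name!r} covers no atoms", stacklevel=2)
        for i in idx:
            if not 0 <= i < n_atoms:
                raise GNMError(f"group {name!r}: atom index {i} out of range")
        covered.update(idx)
    rest = sorted(set(range(n_atoms)) - covered)
    if rest:
        grouping = {**grouping, "other": rest}
    # per-atom squared weight of each mode
    w = (modes.modes ** 2).reshape(n_atoms, 3, modes.n_modes).sum(axis=1)
    data = {
        name: w[idx].sum(axis=0) if idx else np.zeros(modes.n_modes)
        for name, idx in grouping.items()
    }
    df = pd.DataFrame(data, index=pd.RangeIndex(modes.n_modes, name="mode"))
    return df.div(df.sum(axis=1), axis=0)


def analyze(
    traj: Trajectory, *, subtract_com_drift: bool = False
) -> tuple[VelocityCovariance, GeneralizedModeSet, ModeVelocitySeries]:
    """Full pipeline: covariance → modes (+external flags) → projections."""
    if subtract_com_drift:
        traj = remove_com_drift(traj)
    K = velocity_covariance(traj)
    modes = diagonalize_covariance(K)
    classify_external_modes(traj, modes)
    series = project_mode_velocities(traj, modes)
    return K, modes, series


def modes_to_tsv(modes: GeneralizedModeSet, path) -> None:
    """Eigenvalue table as TSV (mode, kinetic energy, external flag)."""
    flags = (
        modes.external_flags
        if modes.external_flags is not None
        else np.zeros(modes.n_modes, dtype=bool)
    )
    df = pd.DataFrame(
        {
            "mode": np.arange(modes.n_modes),
            "kinetic_energy_amu_A2_fs2": modes.kinetic_energies,
            "external": flags.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)
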