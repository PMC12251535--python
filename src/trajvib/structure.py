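"""Microsolvation and geometry statistics for non-periodic droplet trajectories.

Pair radial distribution functions with running coordination numbers,
structural-parameter distributions (bonds / angles / dihedrals), a geometric
hydrogen-bond persistence analysis, and closest-water selection for feeding
a fixed solute+shell subsystem to the mode analysis.

The simulations this targets confine solute plus explicit water in a
spherical cavity (no periodic box), so the default RDF normalization
estimates the ideal-gas pair counts by uniform Monte-Carlo sampling of the
same cavity; the conventional bulk 4πr²Δr·ρ normalization is kept for
ordinary inputs.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .trajio import SelectionError, Trajectory

logger = logging.getLogger(__name__)

#: Default geometric hydrogen-bond criterion: heavy-atom distance (Å) and
#: D–H⋯A angle (degrees). Configurable; the analysis itself is criterion-free.
HBOND_DCUT = 3.5
HBOND_ANGLE_CUT = 150.0

#: Water probe radius (Å) used when a cavity radius must be inferred.
PROBE_RADIUS = 1.4

# Default histogram bin widths for structural distributions.
BOND_BIN_WIDTH = 0.001  # Å
ANGLE_BIN_WIDTH = 0.05  # degrees


class StructureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Radial distribution functions


@dataclass
class RDFResult:
    """g(r) with its running coordination number on bin midpoints.

    n(r) = 4πρ·Σ_{r'≤r} g(r')·r'²·Δr (midpoint quadrature), with ρ the
    reference number density of group b in the cavity (Å⁻³).
    """

    r: np.ndarray  # bin midpoints, Å
    g: np.ndarray
    bin_width: float
    density: float
    pair_spec: tuple[str, str] = ("a", "b")
    raw_counts: np.ndarray | None = None  # mean observed pairs per bin per a-site

    @property
    def n(self) -> np.ndarray:
        return running_coordination(self)

    def n_at(self, r_cut: float) -> float:
        """Running coordination number at a distance cutoff (Å)."""
        idx = np.searchsorted(self.r + 0.5 * self.bin_width, r_cut)
        if idx == 0:
            return 0.0
        return float(self.n[min(idx, self.r.size) - 1])

    def first_minimum(self, after_peak: bool = True) -> float:
        """r of the first local minimum of g after its first peak (Å)."""
        g = self.g
        peak = int(np.argmax(g))
        for i in range(peak + 1, g.size - 1):
            if g[i] <= g[i - 1] and g[i] <= g[i + 1]:
                return float(self.r[i])
        return float(self.r[-1])

    def to_tsv(self, path: str | Path) -> None:
        n = self.n
        body = "\n".join(
            f"{r:.6g}\t{gg:.8g}\t{nn:.8g}" for r, gg, nn in zip(self.r, self.g, n)
        )
        Path(path).write_text(
            f"# pair={self.pair_spec[0]}:{self.pair_spec[1]} "
            f"bin_width_A={self.bin_width} density_A-3={self.density:.8g}\n"
            f"r_A\tg\tn\n{body}\n"
        )


def running_coordination(rdf: RDFResult) -> np.ndarray:
    """n(r) by midpoint quadrature of 4πρ·g(r)·r²·dr; non-decreasing for g ≥ 0."""
    if rdf.density <= 0:
        raise StructureError("RDF has no reference density")
    shell = 4.0 * np.pi * rdf.density * rdf.g * rdf.r**2 * rdf.bin_width
    return np.cumsum(shell)


def infer_cavity_radius(traj: Trajectory) -> float:
    """Largest atom distance from the mean-geometry centroid plus a probe radius."""
    center = traj.positions.mean(axis=(0, 1))
    rmax = np.linalg.norm(traj.positions - center, axis=2).max()
    return float(rmax + PROBE_RADIUS)


def radial_distribution(
    traj: Trajectory,
    group_a: Sequence[int],
    group_b: Sequence[int],
    *,
    bin_width: float = 0.05,
    r_max: float | None = None,
    normalization: str = "cavity-mc",
    cavity_radius: float | None = None,
    cavity_center: np.ndarray | None = None,
    n_mc: int = 200_000,
    seed: int = 0,
) -> RDFResult:
    """Pair RDF between two atom groups over all frames.

    ``bulk`` normalizes by 4πr²Δr·ρ with ρ = N_b/V_cavity; ``cavity-mc``
    estimates the ideal pair counts for each a-site by uniformly sampling
    ``n_mc`` points in the spherical cavity (seeded), which stays correct
    near the cavity wall where the spherical shell is truncated. Self-pairs
    are excluded when the groups overlap.
    """
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise SelectionError("RDF groups must be non-empty")
    for i in ga + gb:
        if not 0 <= i < traj.n_atoms:
            raise SelectionError(f"atom index {i} out of range")
    if cavity_radius is None:
        cavity_radius = infer_cavity_radius(traj)
    if cavity_center is None:
        cavity_center = traj.positions.mean(axis=(0, 1))
    if r_max is None:
        r_max = cavity_radius
    if r_max > 2 * cavity_radius:
        raise StructureError("r_max exceeds the cavity diameter")

    nbins = int(np.ceil(r_max / bin_width))
    edges = np.arange(nbins + 1) * bin_width
    mids = 0.5 * (edges[:-1] + edges[1:])
    volume = (4.0 / 3.0) * np.pi * cavity_radius**3
    density = len(gb) / volume

    pair_mask = np.array([[b != a for b in gb] for a in ga])  # exclude self-pairs
    counts = np.zeros(nbins)
    for f in range(traj.n_frames):
        pa = traj.positions[f, ga]
        pb = traj.positions[f, gb]
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        counts += np.histogram(d[pair_mask], bins=edges)[0]
    # mean observed pairs per frame per a-site
    obs = counts / (traj.n_frames * len(ga))

    if normalization == "bulk":
        ideal = 4.0 * np.pi * mids**2 * bin_width * density
    elif normalization == "cavity-mc":
        rng = np.random.default_rng(seed)
        pts = _uniform_in_sphere(rng, n_mc, cavity_radius) + cavity_center
        ideal_counts = np.zeros(nbins)
        mean_pa = traj.positions[:, ga].mean(axis=0)
        for site in mean_pa:
            d = np.linalg.norm(pts - site, axis=1)
            ideal_counts += np.histogram(d, bins=edges)[0]
        n_excluded = pair_mask.size - pair_mask.sum()  # self-pairs removed
        eff_b = len(gb) - n_excluded / len(ga)
        ideal = ideal_counts / (n_mc * len(ga)) * eff_b
    else:
        raise StructureError(f"unknown normalization {normalization!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(ideal > 0, obs / ideal, 0.0)
    return RDFResult(mids, g, bin_width, density, raw_counts=obs)


def _uniform_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    u = rng.random(n)
    r = radius * np.cbrt(u)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return r[:, None] * v


# ---------------------------------------------------------------------------
# Structural distributions


@dataclass
class StructuralHistogram:
    """Histogram of a bond length, angle, or dihedral over the trajectory.

    Default bin widths: 0.001 Å for bonds, 0.05° for angles and dihedrals.
    Dihedrals live on (−180°, 180°] with periodic binning; their mean is the
    circular mean. ``n_dropped`` counts NaN samples from degenerate
    geometries (e.g. collinear atoms in an angle).
    """

    kind: str  # bond | angle | dihedral
    definition: tuple[int, ...]
    bin_centers: np.ndarray
    counts: np.ndarray
    mean: float
    std: float
    bin_width: float
    n_dropped: int = 0

    def to_tsv(self, path: str | Path) -> None:
        body = "\n".join(
            f"{c:.8g}\t{k}" for c, k in zip(self.bin_centers, self.counts)
        )
        Path(path).write_text(
            f"# kind={self.kind} definition={','.join(map(str, self.definition))} "
            f"mean={self.mean:.8g} std={self.std:.8g} bin_width={self.bin_width}\n"
            f"bin_center\tcount\n{body}\n"
        )


def bond_lengths(traj: Trajectory, i: int, j: int) -> np.ndarray:
    return np.linalg.norm(traj.positions[:, i] - traj.positions[:, j], axis=1)


def bond_angles(traj: Trajectory, i: int, j: int, k: int) -> np.ndarray:
    """i–j–k angle in degrees per frame; NaN where an arm has zero length."""
    v1 = traj.positions[:, i] - traj.positions[:, j]
    v2 = traj.positions[:, k] - traj.positions[:, j]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral_angles(traj: Trajectory, i: int, j: int, k: int, l: int) -> np.ndarray:
    """Signed i–j–k–l dihedral in (−180°, 180°] per frame."""
    b1 = traj.positions[:, j] - traj.positions[:, i]
    b2 = traj.positions[:, k] - traj.positions[:, j]
    b3 = traj.positions[:, l] - traj.positions[:, k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    # sign: right-handed rotation of the l half-plane about the j→k axis,
    # measured from the i half-plane, is positive
    ang = np.degrees(np.arctan2(-y, x))
    # map -180 -> +180 so the domain is (−180, 180]
    ang[ang <= -180.0] += 360.0
    return ang


def circular_mean_deg(samples: np.ndarray) -> float:
    rad = np.radians(samples)
    return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))


def structural_distributions(
    traj: Trajectory,
    definitions: Sequence[tuple[int, ...]],
    *,
    bond_bin: float = BOND_BIN_WIDTH,
    angle_bin: float = ANGLE_BIN_WIDTH,
) -> list[StructuralHistogram]:
    """Histograms, means, and population stds for bond/angle/dihedral tuples.

    The tuple length selects the kind: 2 → bond, 3 → angle, 4 → dihedral.
    """
    if traj.n_frames < 1:
        raise StructureError("need at least one frame")
    out = []
    for d in definitions:
        if len(d) == 2:
            kind, samples, width = "bond", bond_lengths(traj, *d), bond_bin
        elif len(d) == 3:
            kind, samples, width = "angle", bond_angles(traj, *d), angle_bin
        elif len(d) == 4:
            kind, samples, width = "dihedral", dihedral_angles(traj, *d), angle_bin
        else:
            raise StructureError(f"definition {d} must have 2, 3, or 4 indices")
        n_dropped = int(np.isnan(samples).sum())
        if n_dropped:
            logger.warning("%s %s: dropped %d degenerate samples", kind, d, n_dropped)
            samples = samples[~np.isnan(samples)]
        if samples.size == 0:
            raise StructureError(f"{kind} {d}: no valid samples")
        if kind == "dihedral":
            edges = np.arange(-180.0, 180.0 + width, width)
            counts, _ = np.histogram(samples, bins=edges)
            mean = circular_mean_deg(samples)
            dev = (samples - mean + 180.0) % 360.0 - 180.0
            std = float(np.sqrt(np.mean(dev**2)))
        else:
            lo = np.floor(samples.min() / width) * width
            hi = np.ceil(samples.max() / width) * width
            nb = max(1, int(round((hi - lo) / width)))
            edges = lo + np.arange(nb + 1) * width
            counts, _ = np.histogram(samples, bins=edges)
            mean = float(samples.mean())
            std = float(samples.std())
        centers = 0.5 * (edges[:-1] + edges[1:])
        out.append(
            StructuralHistogram(
                kind, tuple(d), centers, counts, mean, std, width, n_dropped
            )
        )
    return out


# ---------------------------------------------------------------------------
# Hydrogen-bond persistence


@dataclass
class HBondSeries:
    """Frame-wise hydrogen-bond booleans and the surviving intervals."""

    bonded: np.ndarray  # (n_frames,) bool
    intervals: list[tuple[float, float]]  # maximal true-intervals, fs, half-open
    dt: float

    @property
    def longest_interval(self) -> tuple[float, float] | None:
        if not self.intervals:
            return None
        return max(self.intervals, key=lambda iv: iv[1] - iv[0])


def hbond_series(
    traj: Trajectory,
    donor: tuple[int, int],
    acceptor: int,
    *,
    d_cut: float = HBOND_DCUT,
    angle_cut: float = HBOND_ANGLE_CUT,
    distance_atom: str = "donor",
) -> HBondSeries:
    """Geometric hydrogen-bond criterion per frame, plus surviving intervals.

    ``donor`` is the (D, H) atom pair. A frame is bonded when the
    donor⋯acceptor (or H⋯acceptor, with ``distance_atom='hydrogen'``)
    distance is below ``d_cut`` Å and the D–H⋯A angle exceeds
    ``angle_cut`` degrees. The default criterion (3.5 Å heavy-atom, 150°)
    is a standard geometric choice and fully configurable.
    """
    d_idx, h_idx = donor
    for i in (d_idx, h_idx, acceptor):
        if not 0 <= i < traj.n_atoms:
            raise SelectionError(f"atom index {i} out of range")
    ref = d_idx if distance_atom == "donor" else h_idx
    dist = np.linalg.norm(traj.positions[:, ref] - traj.positions[:, acceptor], axis=1)
    angle = bond_angles(traj, d_idx, h_idx, acceptor)
    bonded = (dist < d_cut) & (angle > angle_cut)
    intervals: list[tuple[float, float]] = []
    start = None
    for f, b in enumerate(bonded):
        if b and start is None:
            start = f
        elif not b and start is not None:
            intervals.append((start * traj.dt, f * traj.dt))
            start = None
    if start is not None:
        intervals.append((start * traj.dt, traj.n_frames * traj.dt))
    return HBondSeries(bonded, intervals, traj.dt)


# ---------------------------------------------------------------------------
# Closest-water selection


@dataclass
class SolvationSelection:
    """Closest-water bookkeeping around a set of solute sites.

    ``per_frame`` ranks whole waters by their minimum site–oxygen distance
    each frame; ``fixed`` is the trajectory-mode set (the ``fixed_count``
    waters most frequently among the per-frame closest), which is the set
    suitable for covariance analysis since that needs a fixed atom list.
    """

    per_frame: list[list[int]]  # frame -> water residue indices (into waters)
    fixed: list[int]
    fixed_count: int
    waters: list[tuple[int, int, int]]  # (O, H, H) atom index triples

    def fixed_atom_indices(self) -> list[int]:
        """Flat atom indices of the fixed water set (O, H, H per water)."""
        out: list[int] = []
        for w in self.fixed:
            out.extend(self.waters[w])
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "fixed_count": self.fixed_count,
                    "fixed_waters": self.fixed,
                    "waters": [list(w) for w in self.waters],
                    "per_frame": [list(f) for f in self.per_frame],
                },
                indent=1,
            )
        )


def find_waters(traj: Trajectory) -> list[tuple[int, int, int]]:
    """Detect waters as consecutive O,H,H element triples."""
    els = traj.atoms.elements
    waters = []
    i = 0
    while i < len(els) - 2:
        if els[i] == "O" and els[i + 1] == "H" and els[i + 2] == "H":
            waters.append((i, i + 1, i + 2))
            i += 3
        else:
            i += 1
    return waters


def select_closest_waters(
    traj: Trajectory,
    sites: Sequence[int],
    count: int,
    *,
    strategy: str = "trajectory-mode",
    waters: Sequence[tuple[int, int, int]] | None = None,
) -> SolvationSelection:
    """Select the ``count`` whole waters closest to any of the solute sites.

    Per frame, waters are ranked by the minimum distance from their oxygen
    to any site; a water near two sites is counted once. The
    ``trajectory-mode`` strategy additionally reduces the per-frame lists to
    the single fixed set of the most frequently selected waters.
    """
    if count < 1:
        raise SelectionError("count must be ≥ 1")
    if waters is None:
        waters = find_waters(traj)
    waters = [tuple(w) for w in waters]
    if len(waters) < count:
        raise SelectionError(
            f"only {len(waters)} waters available, {count} requested"
        )
    if strategy not in ("per-frame", "trajectory-mode"):
        raise StructureError(f"unknown strategy {strategy!r}")
    site_idx = list(sites)
    if not site_idx:
        raise SelectionError("no solute sites given")
    oxy = np.array([w[0] for w in waters])
    per_frame: list[list[int]] = []
    for f in range(traj.n_frames):
        d = np.linalg.norm(
            traj.positions[f, oxy][:, None, :] - traj.positions[f, site_idx][None],
            axis=2,
        ).min(axis=1)
        order = np.argsort(d, kind="stable")
        per_frame.append(sorted(int(w) for w in order[:count]))
    freq = Counter(w for frame in per_frame for w in frame)
    # most frequent first; ties broken by water index for determinism
    fixed = sorted(sorted(freq), key=lambda w: -freq[w])[:count]
    return SolvationSelection(per_frame, sorted(fixed), count, list(waters))
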