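"""Seeded generators of trajectories and signals with known ground truth.

The target simulations (peptides in water droplets at T = 300 K, 0.2 fs
time step) are not reproducible without an electronic-structure engine, so
every analysis stage is exercised instead on synthetic data whose answer is
known by construction: multi-mode harmonic molecules sampled from the
classical canonical distribution, frequency-modulated tones emulating
transient hydrogen-bond-induced shifts, a two-coordinate oscillator with a
time-dependent coupling, droplet solvent configurations with prescribed
solvation shells, and one flexible three-site water (equilibrium H–O–H
angle 104.52°, bend force constant 50 kJ mol⁻¹ rad⁻²) integrated with
velocity Verlet.

All randomness flows through ``numpy.random.default_rng`` (PCG64); every
generator is bit-exact reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import KB, KJ_PER_MOL, wavenumber_to_angular_frequency
from .gnm import external_generator_matrix
from .trajio import AtomTable, Trajectory

#: Flexible-water geometry and force field (amu·Å²/fs² energy scale).
WATER_OH_LENGTH = 0.9572  # Å
WATER_HOH_ANGLE = 104.52  # degrees
WATER_K_BEND = 50.0 * KJ_PER_MOL  # per rad², E = ½k(θ−θ₀)²
#: O–H stretch stiffness, a package default (≈3700 cm⁻¹ harmonic O–H).
WATER_K_STRETCH = 4500.0 * KJ_PER_MOL  # per Å², E = ½k(r−r₀)²


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Harmonic molecules


@dataclass
class HarmonicModelSpec:
    """A molecule whose internal dynamics is a set of independent harmonic
    modes in mass-weighted coordinates.

    mode_vectors : (3N, n_modes), orthonormal mass-weighted displacement
                   vectors (columns)
    amplitude_mode : ``"thermal"`` draws amplitudes from the classical
                   canonical distribution (Rayleigh amplitude, uniform
                   phase; mean kinetic energy k_BT/2 per mode);
                   ``"fixed"`` sets every amplitude so the time-averaged
                   kinetic energy is exactly k_BT/2.
    """

    elements: list[str]
    masses: np.ndarray
    ref_positions: np.ndarray  # (N, 3), Å
    mode_frequencies: np.ndarray  # cm⁻¹
    mode_vectors: np.ndarray  # (3N, n_modes)
    temperature: float = 300.0  # K
    dt: float = 0.2  # fs
    n_frames: int = 2**15
    seed: int = 0
    amplitude_mode: str = "thermal"
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.ref_positions = np.asarray(self.ref_positions, dtype=float)
        self.mode_frequencies = np.asarray(self.mode_frequencies, dtype=float)
        self.mode_vectors = np.asarray(self.mode_vectors, dtype=float)
        if np.any(self.mode_frequencies <= 0):
            raise SynthError("mode frequencies must be positive")
        if self.dt <= 0:
            raise SynthError("dt must be positive")
        L = self.mode_vectors
        if L.shape[0] != 3 * len(self.masses) or L.shape[1] != len(
            self.mode_frequencies
        ):
            raise SynthError("mode_vectors shape mismatch")
        if not np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8):
            raise SynthError("mode vectors are not orthonormal")
        if self.amplitude_mode not in ("thermal", "fixed"):
            raise SynthError("amplitude_mode must be 'thermal' or 'fixed'")


def harmonic_trajectory(spec: HarmonicModelSpec) -> Trajectory:
    """Analytic trajectory of a multi-mode harmonic molecule.

    Each mode evolves as Q_k(t) = A_k·cos(ω_k t + φ_k); Cartesian positions
    and velocities are reconstructed through the mass-weighted mode vectors,
    x(t) = x₀ + M^(−1/2)·L·Q(t). With thermal amplitudes the expected mean
    kinetic energy per mode is k_BT/2.
    """
    rng = np.random.default_rng(spec.seed)
    n_modes = spec.mode_frequencies.size
    omega = wavenumber_to_angular_frequency(spec.mode_frequencies)  # rad/fs
    phases = rng.uniform(0.0, 2.0 * np.pi, n_modes)
    if spec.temperature == 0:
        amps = np.zeros(n_modes)
    elif spec.amplitude_mode == "fixed":
        amps = np.sqrt(2.0 * KB * spec.temperature) / omega
    else:
        sigma = np.sqrt(KB * spec.temperature) / omega
        amps = sigma * np.sqrt(rng.standard_exponential(n_modes) * 2.0)  # Rayleigh
    t = np.arange(spec.n_frames) * spec.dt
    phase = omega[:, None] * t[None, :] + phases[:, None]  # (modes, frames)
    Q = amps[:, None] * np.cos(phase)
    Qdot = -amps[:, None] * omega[:, None] * np.sin(phase)
    inv_sqm = 1.0 / np.sqrt(np.repeat(spec.masses, 3))  # (3N,)
    disp = (spec.mode_vectors @ Q).T * inv_sqm  # (frames, 3N)
    vel = (spec.mode_vectors @ Qdot).T * inv_sqm
    n_atoms = len(spec.masses)
    positions = spec.ref_positions[None] + disp.reshape(-1, n_atoms, 3)
    atoms = AtomTable(list(spec.elements), spec.masses, list(spec.labels))
    return Trajectory(atoms, positions, vel.reshape(-1, n_atoms, 3), spec.dt)


def internal_mode_vectors(
    positions: np.ndarray, masses: np.ndarray, n_modes: int, seed: int = 0
) -> np.ndarray:
    """Random orthonormal mass-weighted vectors orthogonal to rigid motions.

    Seeded Gaussian vectors are projected off the translation/rotation
    generator span and orthonormalized, giving purely internal (vibrational)
    displacement patterns.
    """
    rng = np.random.default_rng(seed)
    G = external_generator_matrix(positions, masses)
    n3 = 3 * len(masses)
    if n_modes > n3 - G.shape[1]:
        raise SynthError(f"at most {n3 - G.shape[1]} internal modes exist")
    R = rng.standard_normal((n3, n_modes))
    R -= G @ (G.T @ R)
    Q, _ = np.linalg.qr(R)
    return Q[:, :n_modes]


def water_like_spec(
    mode_frequencies: Sequence[float] = (1600.0, 3650.0, 3750.0),
    *,
    temperature: float = 300.0,
    dt: float = 0.2,
    n_frames: int = 2**15,
    seed: int = 0,
    amplitude_mode: str = "thermal",
    external_librations: Sequence[float] = (),
) -> HarmonicModelSpec:
    """Three-atom bent-molecule fixture with the given internal frequencies.

    ``external_librations`` optionally adds low-frequency modes along the six
    translation/rotation generators (librational stand-ins), useful for
    exercising external-mode classification on a thermal fixture.
    """
    positions = water_geometry()
    masses = np.array([15.999, 1.008, 1.008])
    vibs = internal_mode_vectors(positions, masses, len(mode_frequencies), seed)
    freqs = list(mode_frequencies)
    if external_librations:
        G = external_generator_matrix(positions, masses)
        ext = list(external_librations)
        if len(ext) > G.shape[1]:
            raise SynthError(f"at most {G.shape[1]} external generators exist")
        vibs = np.column_stack([vibs, G[:, : len(ext)]])
        freqs += ext
    return HarmonicModelSpec(
        ["O", "H", "H"],
        masses,
        positions,
        np.array(freqs),
        vibs,
        temperature=temperature,
        dt=dt,
        n_frames=n_frames,
        seed=seed,
        amplitude_mode=amplitude_mode,
    )


# ---------------------------------------------------------------------------
# Frequency-modulated tones


@dataclass
class ModulationSchedule:
    """Instantaneous-wavenumber program for a phase-continuous oscillation.

    Either piecewise segments of (duration fs, wavenumber cm⁻¹) or a
    continuous wavenumber function of time (fs → cm⁻¹).
    """

    segments: list[tuple[float, float]] | None = None
    function: Callable[[np.ndarray], np.ndarray] | None = None
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.segments is None) == (self.function is None):
            raise SynthError("give exactly one of segments or function")
        if self.segments is not None:
            for dur, wn in self.segments:
                if dur <= 0 or wn <= 0:
                    raise SynthError("durations and wavenumbers must be positive")

    def total_duration(self) -> float | None:
        if self.segments is None:
            return None
        return sum(d for d, _ in self.segments)

    def wavenumber_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.function is not None:
            return np.asarray(self.function(t), dtype=float)
        assert self.segments is not None
        bounds = np.cumsum([d for d, _ in self.segments])
        vals = np.array([wn for _, wn in self.segments])
        idx = np.searchsorted(bounds, t, side="right")
        if np.any(idx >= len(vals)):
            # allow the final instant t == total duration
            idx = np.minimum(idx, len(vals) - 1)
        return vals[idx]


def modulated_tone(schedule: ModulationSchedule, dt: float, n: int) -> np.ndarray:
    """Real series whose instantaneous wavenumber follows the schedule.

    The phase is the cumulative integral φ(t) = φ₀ + 2π·c·∫ν̃(t′)dt′, so
    frequency switches are phase-continuous. φ₀ is drawn from the seed.
    """
    total = schedule.total_duration()
    if total is not None and total + 1e-9 < n * dt:
        raise SynthError(
            f"schedule covers {total} fs but {n * dt} fs requested (gap)"
        )
    rng = np.random.default_rng(schedule.seed)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) * dt
    # midpoint rule keeps the integral exact for piecewise-constant schedules
    # (up to the bin containing each switch)
    wn_mid = schedule.wavenumber_at(t + 0.5 * dt)
    omega = wavenumber_to_angular_frequency(wn_mid)
    phase = phi0 + np.concatenate([[0.0], np.cumsum(omega[:-1] * dt)])
    return schedule.amplitude * np.cos(phase)


# ---------------------------------------------------------------------------
# Coupled oscillators


def coupled_oscillator_trajectory(
    freqs: tuple[float, float],
    coupling: Callable[[float], float] | float,
    *,
    masses: tuple[float, float] = (1.0, 1.0),
    temperature: float = 300.0,
    dt: float = 0.2,
    n_frames: int = 2**14,
    seed: int = 0,
) -> Trajectory:
    """Two coordinates with a (possibly time-dependent) bilinear coupling.

    V(x, t) = ½k₁x₁² + ½k₂x₂² + c(t)·x₁x₂ with k_i = m_i·ω_i² from the two
    wavenumbers; integrated with velocity Verlet. The stiffness matrix must
    stay positive definite (|c| < √(k₁k₂)) and dt must resolve the fastest
    period (dt ≤ T_min/20). The two coordinates are returned as the x
    displacements of two pseudo-atoms.
    """
    w = wavenumber_to_angular_frequency(np.asarray(freqs, dtype=float))
    m = np.asarray(masses, dtype=float)
    k = m * w**2
    cfun = coupling if callable(coupling) else (lambda t, c=coupling: c)
    t_end = n_frames * dt
    for tc in np.linspace(0.0, t_end, 101):
        if cfun(tc) ** 2 >= k[0] * k[1]:
            raise SynthError("coupling makes the stiffness matrix indefinite")
    min_period = 2.0 * np.pi / w.max()
    if dt > min_period / 20.0:
        raise SynthError(
            f"dt={dt} fs too large for the stiffest mode (need ≤ {min_period / 20:.3g})"
        )
    rng = np.random.default_rng(seed)
    kT = KB * temperature
    x = rng.normal(0.0, np.sqrt(kT / k))
    v = rng.normal(0.0, np.sqrt(kT / m))

    def force(x: np.ndarray, t: float) -> np.ndarray:
        c = cfun(t)
        return -np.array([k[0] * x[0] + c * x[1], k[1] * x[1] + c * x[0]])

    xs = np.empty((n_frames, 2))
    vs = np.empty((n_frames, 2))
    a = force(x, 0.0) / m
    for f in range(n_frames):
        xs[f], vs[f] = x, v
        x = x + v * dt + 0.5 * a * dt**2
        a_new = force(x, (f + 1) * dt) / m
        v = v + 0.5 * (a + a_new) * dt
        a = a_new
    ref = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
    positions = np.repeat(ref[None], n_frames, axis=0)
    positions[:, 0, 0] += xs[:, 0]
    positions[:, 1, 0] += xs[:, 1]
    velocities = np.zeros_like(positions)
    velocities[:, 0, 0] = vs[:, 0]
    velocities[:, 1, 0] = vs[:, 1]
    atoms = AtomTable(["X", "X"], m, ["osc1", "osc2"])
    # AtomTable validates masses; "X" has no tabulated mass, which is fine
    # because the masses are supplied explicitly.
    return Trajectory(atoms, positions, velocities, dt)


# ---------------------------------------------------------------------------
# Droplet solvent configurations


def water_geometry() -> np.ndarray:
    """One water at the model equilibrium geometry, O at the origin (Å)."""
    th = np.radians(WATER_HOH_ANGLE / 2.0)
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [WATER_OH_LENGTH * np.sin(th), 0.0, WATER_OH_LENGTH * np.cos(th)],
            [-WATER_OH_LENGTH * np.sin(th), 0.0, WATER_OH_LENGTH * np.cos(th)],
        ]
    )


def _rotation_aligning(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rotation taking unit vector a to unit vector b, with random azimuth."""
    phi = rng.uniform(0.0, 2.0 * np.pi)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    R_az = np.eye(3) + np.sin(phi) * K + (1 - np.cos(phi)) * (K @ K)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c < -1 + 1e-12:  # antiparallel: rotate π about any perpendicular
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        perp -= a * np.dot(a, perp)
        perp /= np.linalg.norm(perp)
        K2 = np.array(
            [[0, -perp[2], perp[1]], [perp[2], 0, -perp[0]], [-perp[1], perp[0], 0]]
        )
        R_al = np.eye(3) + 2.0 * (K2 @ K2)
    else:
        K2 = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R_al = np.eye(3) + K2 + (K2 @ K2) / (1.0 + c)
    return R_al @ R_az


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass
class ShellSpec:
    """A prescribed solvation shell: ``count`` waters whose oxygens sit at
    ``distance`` ± Gaussian ``jitter`` (Å) from solute atom ``site``.

    ``orientation="toward-site"`` points one O–H bond at the site
    (hydrogen-bond-donor geometry, putting that H at ``distance`` − r_OH
    from the site); ``"random"`` rotates each water uniformly.
    """

    site: int
    distance: float
    count: int
    jitter: float = 0.0
    orientation: str = "random"


def droplet_configurations(
    solute_positions: np.ndarray,
    solute_elements: Sequence[str],
    shells: Sequence[ShellSpec],
    *,
    n_uniform: int = 0,
    cavity_radius: float | None = None,
    n_frames: int = 1,
    seed: int = 0,
    min_separation: float = 2.0,
    max_attempts: int = 2000,
) -> tuple[Trajectory, dict]:
    """Static-solute droplet frames with prescribed solvation shells.

    Shell waters keep a fixed direction from their site across frames, with
    their site distance re-jittered per frame; the remaining ``n_uniform``
    waters are resampled uniformly in the spherical cavity every frame.
    Returns the trajectory (no velocities) and a ground-truth dict with the
    shell water residue indices and the seed.
    """
    rng = np.random.default_rng(seed)
    solute_positions = np.asarray(solute_positions, dtype=float)
    n_solute = solute_positions.shape[0]
    if cavity_radius is None:
        reach = max((s.distance for s in shells), default=0.0)
        base = np.linalg.norm(
            solute_positions - solute_positions.mean(axis=0), axis=1
        ).max()
        cavity_radius = base + reach + 3.0
    center = solute_positions.mean(axis=0)

    # fixed shell directions, rejection-sampled for mutual separation
    shell_sites: list[tuple[int, float, float, np.ndarray]] = []
    placed: list[np.ndarray] = []
    for shell in shells:
        if not 0 <= shell.site < n_solute:
            raise SynthError(f"shell site {shell.site} out of range")
        for _ in range(shell.count):
            for attempt in range(max_attempts):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                o_pos = solute_positions[shell.site] + shell.distance * u
                if np.linalg.norm(o_pos - center) > cavity_radius:
                    continue
                if all(
                    np.linalg.norm(o_pos - p) >= min_separation for p in placed
                ):
                    placed.append(o_pos)
                    shell_sites.append(
                        (shell.site, shell.distance, shell.jitter, u, shell.orientation)
                    )
                    break
            else:
                raise SynthError(
                    "cannot place shell waters without overlap; loosen the "
                    "jitter, separation, or shell geometry"
                )

    n_waters = len(shell_sites) + n_uniform
    elements = list(solute_elements) + ["O", "H", "H"] * n_waters
    labels = ["solute"] * n_solute + sum(
        [["shell"] * 3] * len(shell_sites) + [["bulk"] * 3] * n_uniform, []
    )
    wat0 = water_geometry()
    frames = np.empty((n_frames, n_solute + 3 * n_waters, 3))
    for f in range(n_frames):
        frames[f, :n_solute] = solute_positions
        at = n_solute
        for site, dist, jitter, u, orientation in shell_sites:
            d = dist + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
            o_pos = solute_positions[site] + d * u
            if orientation == "toward-site":
                oh = wat0[1] - wat0[0]
                R = _rotation_aligning(oh / np.linalg.norm(oh), -u, rng)
            else:
                R = _random_rotation(rng)
            frames[f, at : at + 3] = o_pos + (wat0 - wat0[0]) @ R.T
            at += 3
        for _ in range(n_uniform):
            u = rng.random()
            r = cavity_radius * np.cbrt(u)
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            o_pos = center + r * v
            R = _random_rotation(rng)
            frames[f, at : at + 3] = o_pos + (wat0 - wat0[0]) @ R.T
            at += 3
    from .trajio import resolve_masses

    atoms = AtomTable(elements, resolve_masses(elements), labels)
    traj = Trajectory(atoms, frames, None, 1.0)
    truth = {
        "seed": seed,
        "cavity_radius": cavity_radius,
        "shell_waters": list(range(len(shell_sites))),
        "uniform_waters": list(range(len(shell_sites), n_waters)),
        "n_solute_atoms": n_solute,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# Flexible three-site water


def water_potential_energy(positions: np.ndarray) -> float:
    """Harmonic bend + two harmonic O–H stretches (amu·Å²/fs²)."""
    o, h1, h2 = positions
    e = 0.0
    for h in (h1, h2):
        r = np.linalg.norm(h - o)
        e += 0.5 * WATER_K_STRETCH * (r - WATER_OH_LENGTH) ** 2
    u, v = h1 - o, h2 - o
    theta = np.arccos(
        np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
    )
    e += 0.5 * WATER_K_BEND * (theta - np.radians(WATER_HOH_ANGLE)) ** 2
    return float(e)


def water_forces(positions: np.ndarray) -> np.ndarray:
    """Analytic forces of the flexible-water potential, (3, 3) array."""
    o, h1, h2 = positions
    f = np.zeros((3, 3))
    for idx, h in ((1, h1), (2, h2)):
        d = h - o
        r = np.linalg.norm(d)
        fmag = -WATER_K_STRETCH * (r - WATER_OH_LENGTH)
        fvec = fmag * d / r
        f[idx] += fvec
        f[0] -= fvec
    u, v = h1 - o, h2 - o
    ru, rv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / ru, v / rv
    cos_t = np.clip(np.dot(uh, vh), -1.0, 1.0)
    sin_t = np.sqrt(max(1.0 - cos_t**2, 1e-12))
    theta = np.arccos(cos_t)
    dE = WATER_K_BEND * (theta - np.radians(WATER_HOH_ANGLE))
    dth_dh1 = (cos_t * uh - vh) / (ru * sin_t)
    dth_dh2 = (cos_t * vh - uh) / (rv * sin_t)
    f[1] += -dE * dth_dh1
    f[2] += -dE * dth_dh2
    f[0] += dE * (dth_dh1 + dth_dh2)
    return f


def water_hessian(positions: np.ndarray | None = None, h: float = 1e-5) -> np.ndarray:
    """Numeric (finite-difference) Hessian of the water potential, (9, 9)."""
    if positions is None:
        positions = water_geometry()
    x0 = np.asarray(positions, dtype=float).ravel()
    n = x0.size
    H = np.empty((n, n))
    for i in range(n):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        gp = -water_forces(xp.reshape(3, 3)).ravel()
        gm = -water_forces(xm.reshape(3, 3)).ravel()
        H[i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def water_normal_modes() -> tuple[np.ndarray, np.ndarray]:
    """Vibrational frequencies (cm⁻¹) and mass-weighted mode vectors of the
    flexible-water model from its numeric Hessian (zero modes dropped)."""
    from .constants import C_CM_PER_FS

    masses = np.array([15.999, 1.008, 1.008])
    sqm = np.sqrt(np.repeat(masses, 3))
    Hmw = water_hessian() / np.outer(sqm, sqm)
    evals, evecs = np.linalg.eigh(Hmw)
    keep = evals > 1e-8 * max(evals.max(), 1.0)
    omega = np.sqrt(evals[keep])  # rad/fs
    wavenumbers = omega / (2.0 * np.pi * C_CM_PER_FS)
    return wavenumbers, evecs[:, keep]


def model_water_trajectory(
    n_frames: int = 2**14,
    dt: float = 0.2,
    temperature: float = 300.0,
    seed: int = 0,
    *,
    amplitude_mode: str = "thermal",
) -> Trajectory:
    """Velocity-Verlet trajectory of one flexible water.

    Initial conditions populate the three vibrational normal modes (from the
    numeric Hessian) with either canonically sampled amplitudes and phases
    (``"thermal"``: mean mode energy k_BT) or fixed amplitudes carrying
    exactly k_BT each; rigid translations and rotations start at rest. The
    stiffest mode must satisfy dt ≤ T_min/20.
    """
    masses = np.array([15.999, 1.008, 1.008])
    wavenumbers, L = water_normal_modes()
    omega = wavenumber_to_angular_frequency(wavenumbers)
    min_period = 2.0 * np.pi / omega.max()
    if dt > min_period / 20.0:
        raise SynthError(f"dt={dt} fs unstable for the stiffest mode")
    rng = np.random.default_rng(seed)
    kT = KB * temperature
    if temperature == 0:
        Q0 = Qd0 = np.zeros(omega.size)
    elif amplitude_mode == "fixed":
        phi = rng.uniform(0, 2 * np.pi, omega.size)
        A = np.sqrt(2.0 * kT) / omega
        Q0 = A * np.cos(phi)
        Qd0 = -A * omega * np.sin(phi)
    else:
        Q0 = rng.normal(0.0, np.sqrt(kT) / omega)
        Qd0 = rng.normal(0.0, np.sqrt(kT), omega.size)
    sqm = np.sqrt(np.repeat(masses, 3))
    x = water_geometry().ravel() + (L @ Q0) / sqm
    v = (L @ Qd0) / sqm
    m3 = np.repeat(masses, 3)
    pos = np.empty((n_frames, 3, 3))
    vel = np.empty((n_frames, 3, 3))
    a = water_forces(x.reshape(3, 3)).ravel() / m3
    for f in range(n_frames):
        pos[f] = x.reshape(3, 3)
        vel[f] = v.reshape(3, 3)
        x = x + v * dt + 0.5 * a * dt**2
        a_new = water_forces(x.reshape(3, 3)).ravel() / m3
        v = v + 0.5 * (a + a_new) * dt
        a = a_new
    atoms = AtomTable(["O", "H", "H"], masses, ["water"] * 3)
    return Trajectory(atoms, pos, vel, dt)


def total_energy_series(traj: Trajectory) -> np.ndarray:
    """Kinetic + potential energy per frame for the flexible-water model."""
    if traj.velocities is None:
        raise SynthError("trajectory has no velocities")
    m3 = np.repeat(traj.masses, 3)
    ke = 0.5 * (m3 * traj.velocities.reshape(traj.n_frames, -1) ** 2).sum(axis=1)
    pe = np.array([water_potential_energy(p) for p in traj.positions])
    return ke + pe
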