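# Methods

## Units and constants

One internal unit system everywhere: Å, fs, amu; energies in amu·Å²/fs²
(1 amu·Å²/fs² = 10⁷/N_A J). Boltzmann's constant is then
k_B = 8.3145×10⁻⁷ amu·Å²·fs⁻²·K⁻¹, so k_BT/2 = 1.247×10⁻⁴ amu·Å²/fs² at
300 K. Spectral axes are wavenumbers, ν̃[cm⁻¹] = f[fs⁻¹]/c with
c = 2.99792458×10⁻⁵ cm/fs. All conversions happen at the I/O boundary.

## Generalized normal modes

The covariance matrix K of mass-weighted velocities is built with a plain
time average over the supplied frames (population convention, divisor N)
and mean subtraction per coordinate. An option removes centre-of-mass
drift frame-wise instead; the default is the literal mean-subtracted
covariance.

The projection Q̇ = Lᵀ √m q̇ acts on *mass-weighted* velocities. This is a
deliberate convention choice: only in the mass-weighted basis is L
orthogonal, the per-frame Parseval identity Σ_α Q̇_α² = Σ_i m_i q̇_i² exact,
and the eigenvalue-equals-mean-kinetic-energy statement an algebraic
identity. With `subtract_mean=True` (default) the time mean of ½Q̇_α²
reproduces eigenvalue α exactly on the frames used to build K; with
`subtract_mean=False` the raw-velocity Parseval identity holds instead.

Eigenvectors follow a deterministic sign convention (largest-magnitude
component positive). Eigenvalues agreeing to a relative gap below 10⁻⁸ are
reported as a degenerate block; within a block only the spanned subspace is
meaningful.

External (translational/rotational) modes are flagged when the squared
projection of an eigenvector onto the orthonormalized span of the 3
mass-weighted translation generators and up to 3 rigid-rotation generators
(built at the mean geometry about the centre of mass) exceeds 0.5. The
threshold is a package choice: for clean fixtures the projection is
essentially 0 or 1, so any mid-range value works; 0.5 is the symmetric
default. Linear molecules and single atoms yield fewer generators and are
reported with the reduced count, not an error.

### What the covariance method can and cannot identify

A property worth stating explicitly, because it governs fixture design and
what passing tests mean: the eigenvectors of K are well-determined only
where mode kinetic energies are *non-degenerate*. For a harmonic molecule
whose modes all carry exactly k_BT/2, K approaches a multiple of the
identity and its eigenvectors are arbitrary; the residual off-diagonal
couplings (which decay as 1/N alongside the diagonal gaps) then set the
mixing. Concretely, on the 3-atom fixture with fixed canonical amplitudes
the 3650/3750 cm⁻¹ pair mixes at ~45° regardless of trajectory length,
while with canonically *sampled* (Rayleigh) amplitudes the energy scatter
separates the eigenvalues and mode vectors are recovered with overlaps
> 0.99. Real anharmonic trajectories behave like the latter: mode energies
are never exactly equal. The test suite therefore checks mode-vector
recovery on canonically sampled amplitudes and the k_BT/2 energy scale on
the fixed-amplitude variant — each claim on the fixture that can express
it.

## Power spectra

The default estimator is the Hann-windowed periodogram with 4× zero
padding; padding interpolates the spectrum for peak readability and adds no
resolution. The literal route — biased autocorrelation
C(τ) = (1/N)Σ x(t)x(t+τ), even-symmetrized, cosine-transformed — is also
provided and equals the unwindowed periodogram (Wiener–Khinchin), which the
tests assert to 10⁻¹⁰. Autocorrelations are computed by FFT with ≥2N
padding so circular wrap never contaminates a lag. Normalization: with no
window, Σ power·Δν̃ equals the mean square of the input; the Hann window is
power-corrected (division by mean w²) so the same holds for stationary
signals.

## Morlet wavelet transform

Conventions (all fixed across the package):

* analytic Morlet, ψ̂(aω) = π^(−1/4)·H(ω)·exp(−(aω−ω₀)²/2); negative
  frequencies carry nothing, halving redundancy for real signals;
* unit energy per scale: each row of the scalogram is
  ifft(x̂·√(2πa/δt)·ψ̂*(aω)), making |W|² comparable across scales;
* scale grid a_j = a₀·2^{jδj}, j = 0…⌊J⌋, J = δj⁻¹·log₂(Nδt/a₀); defaults
  a₀ = 2δt (smallest resolvable scale) and δj = 0.5, which is adequate
  sampling for the Morlet. For band-resolving analyses (separating lines
  closer than ~20%) use δj ≤ 0.1 — and remember the Morlet's own relative
  bandwidth is ≈1/ω₀, so nearby bands may need a larger ω₀ no matter how
  fine the grid;
* scale-to-period factor 4π/(ω₀+√(2+ω₀²)): 1.03 at ω₀ = 6, i.e. scale and
  Fourier period nearly coincide. The cosine-substitution procedure that
  defines this factor is implemented as a brute-force cross-check;
* ω₀ defaults to 6; smaller values only approximately satisfy
  admissibility and trigger a logged warning rather than an error;
* cone of influence: per-time maximum trustworthy period from the e-folding
  time √2·a, reported but never masked — consumers (e.g. ridge tracking)
  flag out-of-cone points instead.

Both |W| and |W|² are available; exports write power and, on request, the
complex coefficients.

The frequency-domain evaluation equals direct time-domain quadrature of the
CWT integral to better than 10⁻⁶ away from the edges, for scales between
4δt (below which the sampled time kernel nears Nyquist) and the scale whose
Gaussian envelope still vanishes at the comparison boundary; the oracle
test pins both limits.

## Structure analysis

RDFs target non-periodic droplet systems (solute plus waters in a spherical
cavity). Two normalizations:

* `bulk`: ideal counts 4πr²Δr·ρ with ρ = N_b/V_cavity — correct far from
  the wall;
* `cavity-mc` (default): ideal counts estimated by seeded uniform
  Monte-Carlo sampling of the same cavity against each a-site's mean
  position — correct up to the wall, where spherical shells truncate.

Both agree within ~2% for r well inside the cavity (tested on ideal-gas
droplets). The running coordination number uses midpoint quadrature
n(r) = 4πρ·Σ g r² Δr, whose cumulative error is below 1% for r ≳ 10 bins;
under bulk normalization it reduces exactly to the mean observed pair count
per a-site (a bookkeeping identity the tests pin at 10⁻¹⁰). The cavity
radius is user-supplied or inferred as the maximal atom excursion plus a
1.4 Å probe. RDF bins default to 0.05 Å.

Structural distributions use 0.001 Å bins for bonds and 0.05° for angles
and dihedrals. Dihedrals live on (−180°, 180°] with periodic binning and a
circular mean; the sign is a right-handed rotation of the far half-plane
about the central bond. Degenerate geometries (zero-length arms) drop NaN
samples with a logged count.

Hydrogen bonds use a geometric criterion: donor⋯acceptor distance < 3.5 Å
and D–H⋯A angle > 150°, both configurable (the literature's survival facts
come without a stated criterion, so the default is the field's common
choice). The analysis returns the frame-wise boolean series, all maximal
surviving intervals, and the longest one as a time window ready for
`time_window`.

Closest-water selection ranks whole waters (O,H,H triples, auto-detected or
supplied) by minimum site–oxygen distance. The per-frame lists serve
structural analysis; the `trajectory-mode` reduction — the fixed set of
most-frequently-closest waters — feeds `select_subsystem`, because a
covariance analysis needs a fixed atom list.

## Synthetic generators

All generators draw from `numpy.random.default_rng` (PCG64) and are
bit-exact reproducible from their seed; seeds are recorded in every output
header. Defaults mirror the target simulations: T = 300 K, δt = 0.2 fs.

* **Harmonic molecules** evolve each mode as A·cos(ωt+φ) with uniform
  phases. Amplitudes are either canonically sampled (Rayleigh, mean kinetic
  energy k_BT/2 per mode — the default) or fixed so the time-averaged
  kinetic energy is exactly k_BT/2 (for deterministic energy checks; see
  the identifiability note above). Mode vectors are validated orthonormal;
  the bundled 3-atom fixture builds internal vectors orthogonal to the
  translation/rotation generators, with optional low-frequency librations
  along those generators.
* **Modulated tones** integrate the instantaneous wavenumber schedule into
  a continuous phase, so frequency hops are phase-continuous.
* **Coupled oscillators**: two coordinates under V = ½k₁x₁² + ½k₂x₂² +
  c(t)x₁x₂, velocity-Verlet integrated; the stiffness matrix must stay
  positive definite and δt ≤ T_min/20. Coupling on only in a window makes
  the cross band appear in the partner's scalogram exactly there — the
  testable time-frequency signature that a Fourier spectrum cannot
  localize.
* **Droplets** place shell waters at prescribed site distances (fixed
  directions, per-frame Gaussian distance jitter, random or
  hydrogen-bond-donor orientation) plus uniform cavity waters resampled
  every frame, and return ground-truth shell membership.
* **Flexible water**: one three-site water with harmonic bend
  (θ₀ = 104.52°, k_bend = 50 kJ mol⁻¹ rad⁻², E = ½k(θ−θ₀)²) and harmonic
  O–H stretches (r₀ = 0.9572 Å, k = 4500 kJ mol⁻¹ Å⁻², a package default —
  only the bend is externally prescribed). With E = ½k conventions this
  bend constant places the bend near 400 cm⁻¹; the model is a fixture whose
  oracle is its own numeric Hessian, not a claim about real water. Initial
  conditions populate the three Hessian normal modes canonically (or with
  fixed energies k_BT); Verlet energy drift stays below 1% over the tested
  windows.

### What the generators do and do not emulate

They reproduce the *analysis-relevant* features of finite-temperature MD:
thermal mode energies, incommensurate mode phases, transient frequency
shifts and couplings, prescribed solvation shells, droplet geometry. They
do not emulate anharmonic force fields, mode-energy exchange
(thermalization), solvent dynamics, or real amide frequencies. Passing
tests therefore demonstrate that the analysis chain recovers known inputs
under realistic sampling conditions — not that any specific molecular
system has particular bands.

## Problem sizes

Test fixtures use 2¹³–2¹⁶ frames at δt = 0.2 fs (1.6–13 ps), 1600-sample
scale grids for the conversion-factor brute force, 2×10⁵–2×10⁶ Monte-Carlo
points for cavity normalization, and ≤4-atom systems for the O(N²)/double-
loop oracles. These sizes put every stochastic tolerance at ≥3σ margins
while keeping the whole suite under a minute of compute.

## Known limitations

* Extended-XYZ only; no binary trajectory formats, no periodic boxes.
* The GNM eigenvectors are undefined between modes of equal mean kinetic
  energy (see identifiability note); degenerate blocks are reported so
  consumers can compare subspaces.
* No wavelet significance testing, inverse CWT, or cross-wavelet
  coherence; no IR/Raman intensities (band positions only).
* The cavity-MC RDF normalization assumes a spherical cavity and a static
  (or nearly static) solute site distribution; strongly diffusing solutes
  would need per-frame site sampling.
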