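# Methods

This note records the models, estimators, numerical choices and known
limitations behind `confdyn`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and units

A trajectory is a `frames × atoms × 3` array in Å with a constant frame
spacing `dt` in ns and a per-atom record (name, residue name, residue
index, chain, element). The default shapes mirror a typical production
run: 1000 stored frames over 100 ns (`dt = 0.1` ns). XTC's native nm are
converted to Å on read; frame indexing is 0-based with half-open ranges.
Energies are per-frame scalars in kcal/mol aligned 1:1 with frames
(`frame,value` CSV, header required, `.` decimal).

Atom selections use a deliberately small grammar — `all`, `backbone`
(names N, CA, C, O), `calpha`, `resid N[-M]`, `chain X`, joined by
`and` — resolved to unique sorted indices, independent of atom-record
order. The two conventions that matter downstream are backbone atoms
(RMSD) and α-carbons (RMSF, featurization).

## Superposition metrics

Kabsch alignment minimizes least-squares deviation via SVD of the
cross-covariance, with the determinant sign correction that forbids
reflections; inputs with fewer than 3 points or collinear geometry are
rejected. RMSD uses frame 0 as reference by default (`reference="mean"`
is available); each frame is aligned before the deviation is measured,
so rigid-body motion contributes exactly zero. RMSF superposes every
frame onto an iteratively computed mean structure (two passes: align to
frame 0 → average → re-align to the average → re-average), which removes
drift contamination. Mass weighting is off (all atoms weight 1).

Finite-size caveat, quantified in the tests: superposition absorbs 6 of
the 3N coordinate degrees of freedom per frame, deflating apparent
per-atom variance by ≈(3N−6)/3N, and anchor atoms far from the centroid
give the fitted rotation a lever arm that can absorb ~10% of a single
atom's motion. Closed-form RMSF checks must use geometries that control
both effects.

## Signal diagnostics

Autocorrelation uses the biased (divide-by-N) estimator
ρ(k) = Σ(x_t−x̄)(x_{t+k}−x̄)/Σ(x_t−x̄)², computed by FFT and normalized
by its own zero-lag value so ρ(0) = 1 exactly and |ρ| ≤ 1 always.
Zero-variance input is an error, not a NaN.

The Welch PSD delegates to `scipy.signal.welch`: Hann window, segment
length N/8 rounded down to a power of two, 50% overlap, linear
detrending per segment — the method's canonical defaults, all
overridable. The one-sided density integrates to the series variance
(Parseval, checked to 10% on white noise). Frequencies are reported in
cycles/frame and, given `dt`, cycles/ns. The spectral centroid
(power-weighted mean frequency) is the scalar used to compare how slow
two signals are.

## Embeddings

**Featurization** flattens the selected atoms' coordinates per frame,
optionally Kabsch-aligning each frame to frame 0 first (default) so that
rigid-body motion carries no variance.

**Diffusion maps.** Gaussian kernel `K_ij = exp(−‖x_i−x_j‖²/ε)`;
density normalization `K̃ = D^{−α} K D^{−α}` with α = 1
(Laplace–Beltrami), which removes sampling-density bias — appropriate
because trajectory frames are not equilibrium-weighted samples; row
normalization to a Markov operator; eigendecomposition through the
symmetric conjugate `D̃^{−1/2} K̃ D̃^{−1/2}` (exact, and numerically
stabler than the nonsymmetric matrix). The trivial eigenpair (λ = 1,
constant eigenvector) is verified to 1e-6 and dropped; coordinates are
λᵢψᵢ with a deterministic sign convention (largest-magnitude entry
positive). ε `"auto"` is the median squared pairwise distance on a
≤1000-point subsample — scale-free and adequate for the dense path used
up to N = 2000 (distances are computed blockwise, O(block·N) memory). A
kernel row with no off-diagonal mass, or a non-constant leading
eigenvector (disconnected graph), raises a bandwidth error advising a
larger ε.

**TICA.** On mean-free features, solve `C(τ)v = λC(0)v` with the
time-lagged covariance symmetrized, `C(τ) = (A+Aᵀ)/2`,
`A = X₀ᵀX_τ/(N−τ)`. Two regularizations, both load-bearing:

1. *PCA truncation of the whitening basis* to the components explaining
   99.9% of total variance (at least k). Without it, near-zero-variance
   directions — rigid-body residuals of the superposition, per-atom
   jitter — are whitened to unit variance, and their sampling
   autocorrelation (order 2√(d/N); ≈0.7 for 150 features over 500
   frames) buries the true slow modes. This was observed directly
   during development, not hypothesized.
2. An eigenvalue floor of 1e-10·λ_max on the retained C(0) spectrum,
   with a warning.

Eigenvalues above 1 (finite-sample noise) are clipped with a warning, so
the reported spectrum lies in (0, 1]. The default lag is 500 frames
(half the canonical 1000-frame trajectory); for the synthetic fixtures,
whose exchange correlation time is a few frames, tests and examples use
lags of 1–5 frames — the lag must sit inside the correlation window or
the slow mode is unidentifiable (λ₁(τ) = λ₁(1)^τ decays below noise).

**2-D manifold view.** Delegated to UMAP, seeded for determinism, and
used for visualization only; no quantitative claim in this package
depends on it.

## Landscapes

The free-energy surface over two embedding components is the Boltzmann
inversion of a 2-D occupancy histogram, `F_b = −kT ln(n_b/n_max)`:
exactly one bin attains F = 0, empty bins are masked (NaN) rather than
given a pseudo-count — a pseudo-count would fabricate barrier heights.
Default 50×50 bins with a warning when frames < 10·bins; well counting
in the pipeline report uses 8-connected components of bins within 1 kT
of the minimum and is explicitly resolution-dependent (too-fine grids
fragment basins). kT defaults to the 300 K thermostat value,
1.9872×10⁻³ kcal/mol/K × 300 K = 0.5962 kcal/mol.

The binding-energy combination is `ΔG = E_complex − (E_ligand +
E_receptor)`, vectorized over aligned per-frame series. "Integrating"
energies into the landscape means per-bin means with standard errors
(SE only for count ≥ 2; counts sum to n_frames) — the most conservative
reading — plus per-state means over cluster labels. Both the per-frame
and the binned views are produced.

## State models

OPTICS (scikit-learn) provides density-based state discovery with noise
label −1; defaults `min_samples = 20`, `ξ = 0.05`. Two caveats
established empirically: the ξ-extraction fragments cluster shoulders at
small `min_samples` (ξ = 0.1 is more stable there), and the noise
fraction is *not* globally monotone in `min_samples` — below ~5 the
reachability profile itself is noisy and more points get labeled noise.
Cluster counts from OPTICS should be treated as parameter-dependent
descriptions, never as acceptance-grade numbers. The all-points-identical
corner case short-circuits to a single cluster.

Microstates come from Ward-linkage hierarchical clustering on TICA
coordinates (default 15 states, no noise label) — standard MSM practice.

MSM estimation: sliding-window transition counts `C_ij(τ)`, with noise
frames breaking the pairs they touch by default (`ignore-transition`;
`drop` splices across gaps and therefore fabricates transitions — it
exists but is not the default). Estimation is restricted to the largest
strongly connected component of the count graph (eigenanalysis requires
connectivity); discarded states are warned about. The non-reversible
estimator is plain row normalization; the reversible variant
row-normalizes the symmetrized counts (C+Cᵀ)/2 — an approximation to
the reversible MLE that satisfies detailed balance exactly and whose
stationary distribution is the normalized row sums. Implied timescales
`tᵢ = −τ/ln λᵢ` drop the stationary eigenvalue, mark λ ≤ 0 and
λ ≥ 1−1e-12 as undefined (NaN, with warnings), and take real parts of
complex eigenvalues with a 1e-8 imaginary-magnitude guard. The lag scan
flags convergence when t₂ varies by <10% over the top half of the lag
range.

## Synthetic generator: what it emulates, what it does not

The generator produces the one thing real trajectories never provide:
exact ground truth. Overdamped Euler–Maruyama dynamics
`x' = x − ∇V·dt + √(2kT·dt)ξ` in a quartic double well (optionally
tilted, optionally with harmonic fast dimensions) or a
Gaussian-mixture-well potential; equilibrium is Boltzmann, verified
against quadrature. Well labels are by nearest well center (Voronoi) —
frames at the barrier top are ambiguous by construction, matching the
microstate-assignment convention downstream. A fixed random linear lift
(entries scaled so latent motion moves atoms by ~5 Å) plus isotropic
Gaussian jitter (0.1 Å) maps the latent path to coordinates; the lift
matrix, true labels and latent path are stored in the ensemble metadata
for oracle tests. Energy series are state means (−50, −30 kcal/mol by
default, the scale of MM-GBSA binding energies) plus N(0, σ²) noise,
σ = 2 kcal/mol. The two-state Markov chain with matrix
[[1−p, p], [q, 1−q]] is the exact discrete oracle: stationary
distribution (q, p)/(p+q), relaxation eigenvalue 1−p−q.

Defaults for the end-to-end fixture: 2-D double well, kT = 0.5, barrier
height 1 (= 2 kT), `dt_sim = 0.01`, 10⁵ latent steps strided to 1000
stored frames, 50 atoms — the data shape of a real 100 ns/1000-frame
run. One global seed fans out to per-operation child streams by fixed
offsets, so all generators are bit-reproducible and independent.

What the generator does *not* emulate — hence what a green test does not
establish: real force-field energetics, anharmonic couplings between
many slow modes, solvent/membrane degrees of freedom, periodic-boundary
artifacts, or the non-Gaussian noise of real MM-GBSA series. Passing
tests certify the *estimators* (they recover known structure at
realistic sample sizes), not any biological conclusion.

## Numerical choices and degenerate inputs

* Integrator divergence (|x| > 10³) raises an error naming `dt_sim`.
* Selections resolving to nothing, zero-variance signals, lags ≥ series
  length, single-frame RMSF, single-state timescale scans: all typed
  errors, not NaN returns.
* Diffusion-map and TICA component signs follow a
  largest-magnitude-entry-positive convention so reruns and permuted
  inputs are comparable.
* DCD round-trips hold to 1e-3 Å (float32); XTC to 1e-2 Å — its lossy
  compression quantizes at 1e-3 nm, so a tighter bound is impossible.
* The pipeline serializes its resolved configuration and a config hash
  into every run directory; identical config + seed reproduces
  deterministic stages bit-identically. A failed stage leaves a `FAILED`
  marker naming the stage, with completed stage outputs retained.

## Known limitations

* The reversible MSM estimator is the symmetrized-count approximation,
  not the iterative MLE; for strongly non-reversible counts it biases
  toward the symmetric part. The non-reversible estimator is default.
* TICA assumes a linear map from features suffices to express the slow
  modes — true for the synthetic lift by construction, approximate for
  real proteins.
* The FES mask means barrier heights through unsampled regions are
  *lower bounds* only.
* UMAP coordinates are not metric; OPTICS cluster counts are
  parameter-dependent. Neither is used for quantitative claims.
* No periodic-boundary imaging, no mass weighting, no multi-chain
  assembly handling; variable-timestep trajectories are out of scope.
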