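"""Synthetic trajectories and energy series with known metastable structure.

Every downstream stage (RMSD/RMSF, spectra, embeddings, free-energy
surfaces, clustering, Markov state models) is validated against data from
this module, because here the ground truth — well assignments, exchange
rates, Boltzmann weights, the linear map from latent space to atomic
coordinates — is known exactly.

The generative model is deliberately minimal:

1. an overdamped (Brownian) particle in a low-dimensional metastable
   potential, integrated by Euler–Maruyama:
   ``x_{t+1} = x_t - grad V(x_t) dt + sqrt(2 kT dt) xi``;
2. a fixed random linear "lift" from the latent coordinate to 3*n_atoms
   Cartesian coordinates plus isotropic Gaussian jitter, emulating the
   (x, y, z) per-frame atomic coordinates of a protein ensemble;
3. a per-frame energy whose mean depends on the occupied well, with
   additive Gaussian noise, emulating a per-frame MM-GBSA series;
4. a discrete two-state Markov chain as an exact oracle for the MSM
   machinery.

All generators are bit-reproducible given a seed. A single global seed
fans out to per-operation child seeds by fixed offsets (see
:func:`child_seed`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegratorError
from .trajectory import EnergySeries, TrajectoryEnsemble

__all__ = [
    "PotentialSpec",
    "DoubleWellPotential",
    "GaussianWellsPotential",
    "LatentTrajectory",
    "simulate_langevin",
    "lift_to_trajectory",
    "synthetic_energy_series",
    "make_two_state_chain",
    "make_two_well_dataset",
    "child_seed",
]

#: Fixed offsets fanning one global seed out to independent streams.
SEED_OFFSETS = {"langevin": 11, "lift": 23, "energy": 37, "chain": 53, "embed": 71}

#: Positions beyond this magnitude are treated as integrator divergence.
DIVERGENCE_BOUND = 1.0e3


def child_seed(seed: int, stream: str) -> int:
    """Derive a per-operation child seed from one global integer seed."""
    return (int(seed) + SEED_OFFSETS[stream]) % (2**31 - 1)


class PotentialSpec:
    """Base class for low-dimensional metastable potentials.

    Subclasses provide ``energy``, ``gradient`` and ``well_centers``.
    Energies are in units of a reference kT=1; well label assignment is
    by nearest well center (Voronoi), so frames near the barrier top may
    carry either label — accepted noise that mirrors the microstate
    assignment convention used downstream.
    """

    dim: int
    well_centers: np.ndarray  # (n_wells, dim)

    def energy(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_wells(self) -> int:
        return self.well_centers.shape[0]

    def assign_wells(self, x: np.ndarray) -> np.ndarray:
        """Nearest-well-center (Voronoi) labels for positions ``x``."""
        x = np.atleast_2d(x)
        d2 = ((x[:, None, :] - self.well_centers[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


@dataclass
class DoubleWellPotential(PotentialSpec):
    """Quartic double well, optionally tilted and extended to 2-D.

    ``V(x, y) = height*(x^2 - 1)^2 + tilt*x + 0.5*kappa*y^2``

    The slow coordinate is x with minima near +-1; extra dimensions are
    harmonic (fast). ``tilt != 0`` makes the wells inequivalent with a
    Boltzmann weight ratio computable by quadrature.
    """

    height: float = 1.0
    tilt: float = 0.0
    dim: int = 1
    kappa: float = 4.0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ConfigurationError("dim must be >= 1")
        if not np.isfinite([self.height, self.tilt, self.kappa]).all():
            raise ConfigurationError("potential parameters must be finite")
        centers = np.zeros((2, self.dim))
        centers[0, 0] = -1.0
        centers[1, 0] = 1.0
        self.well_centers = centers

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        v = self.height * (x[:, 0] ** 2 - 1.0) ** 2 + self.tilt * x[:, 0]
        if self.dim > 1:
            v = v + 0.5 * self.kappa * (x[:, 1:] ** 2).sum(axis=1)
        return v

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        g = np.empty_like(x)
        g[:, 0] = 4.0 * self.height * x[:, 0] * (x[:, 0] ** 2 - 1.0) + self.tilt
        if self.dim > 1:
            g[:, 1:] = self.kappa * x[:, 1:]
        return g

    def boltzmann_weight_ratio(self, kT: float) -> float:
        """Quadrature ratio Z_right/Z_left of the two basins at ``kT``.

        Basins are split at the Voronoi boundary x=0; extra harmonic
        dimensions factor out of the ratio.
        """
        from scipy.integrate import quad

        def boltz(x: float) -> float:
            return float(np.exp(-(self.height * (x * x - 1.0) ** 2 + self.tilt * x) / kT))

        z_left, _ = quad(boltz, -8.0, 0.0, limit=200)
        z_right, _ = quad(boltz, 0.0, 8.0, limit=200)
        return z_right / z_left


@dataclass
class GaussianWellsPotential(PotentialSpec):
    """Mixture-of-Gaussian-wells potential: ``V = -log sum_i w_i N(x; c_i, s_i)``.

    ``depths`` are the log-weights (kT units); deeper wells attract more
    density. Bounded below by construction.
    """

    centers: np.ndarray = field(default_factory=lambda: np.array([[-1.0], [1.0]]))
    depths: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0]))
    widths: np.ndarray = field(default_factory=lambda: np.array([0.3, 0.3]))

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.depths = np.asarray(self.depths, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.centers.shape[0] < 2:
            raise ConfigurationError("need >= 2 wells for metastability")
        if not (np.isfinite(self.centers).all() and np.isfinite(self.depths).all()):
            raise ConfigurationError("well parameters must be finite")
        if self.depths.shape[0] != self.centers.shape[0]:
            raise ConfigurationError("one depth per well required")
        self.dim = self.centers.shape[1]
        self.well_centers = self.centers

    def _log_mix(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.atleast_2d(x)
        d2 = ((x[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        logs = self.depths[None, :] - d2 / (2.0 * self.widths[None, :] ** 2)
        m = logs.max(axis=1, keepdims=True)
        w = np.exp(logs - m)
        return m[:, 0] + np.log(w.sum(axis=1)), w / w.sum(axis=1, keepdims=True)

    def energy(self, x: np.ndarray) -> np.ndarray:
        log_mix, _ = self._log_mix(x)
        return -log_mix

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        _, resp = self._log_mix(x)
        # grad of -logsumexp: responsibility-weighted pull toward centers
        diffs = (x[:, None, :] - self.centers[None, :, :]) / self.widths[None, :, None] ** 2
        return (resp[:, :, None] * diffs).sum(axis=1)


@dataclass
class LatentTrajectory:
    """Latent positions with their true well labels."""

    positions: np.ndarray  # (n_steps, dim)
    labels: np.ndarray  # (n_steps,) int, in [0, n_wells)
    dt_sim: float
    kT: float
    potential: PotentialSpec

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.positions) < 2:
            raise ConfigurationError("latent trajectory needs >= 2 steps")

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0]

    def stride(self, step: int) -> "LatentTrajectory":
        return LatentTrajectory(
            positions=self.positions[::step].copy(),
            labels=self.labels[::step].copy(),
            dt_sim=self.dt_sim * step,
            kT=self.kT,
            potential=self.potential,
        )


def simulate_langevin(
    pot: PotentialSpec,
    n_steps: int,
    dt_sim: float = 0.01,
    kT: float = 0.5,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> LatentTrajectory:
    """Overdamped Euler–Maruyama integration of ``dx = -grad V dt + sqrt(2 kT dt) dW``.

    The equilibrium distribution is Boltzmann, ``p ~ exp(-V/kT)``, which
    the test suite checks by quadrature. With ``kT=0`` and ``x0`` at a
    minimum the position stays fixed (zero-noise fixed point).

    Raises
    ------
    IntegratorError
        If any position exceeds the documented divergence bound (1e3);
        the fix is a smaller ``dt_sim``.
    """
    if n_steps < 2:
        raise ConfigurationError("n_steps must be >= 2")
    if dt_sim <= 0:
        raise ConfigurationError("dt_sim must be positive")
    if kT < 0:
        raise ConfigurationError("kT must be >= 0")
    rng = np.random.default_rng(child_seed(seed, "langevin"))
    dim = pot.dim
    x = np.array(pot.well_centers[0], dtype=float) if x0 is None else np.asarray(x0, float)
    noise_scale = np.sqrt(2.0 * kT * dt_sim)
    positions = np.empty((n_steps, dim))
    # pre-draw noise in one block: bit-reproducible and fast
    noise = rng.standard_normal((n_steps, dim)) * noise_scale
    for t in range(n_steps):
        positions[t] = x
        x = x - pot.gradient(x[None, :])[0] * dt_sim + noise[t]
        if np.abs(x).max() > DIVERGENCE_BOUND:
            raise IntegratorError(
                f"position exceeded {DIVERGENCE_BOUND:g} at step {t}; "
                f"reduce dt_sim (currently {dt_sim})"
            )
    labels = pot.assign_wells(positions)
    return LatentTrajectory(positions=positions, labels=labels, dt_sim=dt_sim, kT=kT, potential=pot)


def lift_to_trajectory(
    latent: LatentTrajectory,
    n_atoms: int = 50,
    noise_sigma: float = 0.1,
    seed: int = 0,
    frame_dt: float = 0.1,
    scale: float = 5.0,
) -> TrajectoryEnsemble:
    """Lift a latent trajectory to a frames x atoms x 3 coordinate ensemble.

    Each frame is ``base + A @ latent_t + jitter`` where ``A`` is a fixed
    random linear map (one 3-vector row per atom per latent dimension,
    Gaussian entries scaled so latent motion moves atoms by ~``scale`` Å)
    and the jitter is isotropic Gaussian of width ``noise_sigma`` Å. The
    slow latent dynamics are therefore linearly recoverable from the
    coordinates; the lift matrix is stored in ``metadata['lift_matrix']``
    for oracle tests, along with the true labels.
    """
    if n_atoms < 4:
        raise ConfigurationError("n_atoms must be >= 4")
    if noise_sigma < 0:
        raise ConfigurationError("noise_sigma must be >= 0")
    rng = np.random.default_rng(child_seed(seed, "lift"))
    n_frames, dim = latent.positions.shape
    lift = rng.standard_normal((n_atoms, 3, dim)) * (scale / np.sqrt(3.0))
    base = rng.uniform(-20.0, 20.0, size=(n_atoms, 3))
    coords = base[None, :, :] + np.einsum("akd,td->tak", lift, latent.positions)
    if noise_sigma > 0:
        coords = coords + rng.standard_normal(coords.shape) * noise_sigma

    atoms = pd.DataFrame(
        {
            "name": ["CA"] * n_atoms,
            "resname": ["ALA"] * n_atoms,
            "resid": np.arange(1, n_atoms + 1),
            "chain": ["A"] * n_atoms,
            "element": ["C"] * n_atoms,
        }
    )
    return TrajectoryEnsemble(
        coords=coords,
        dt=frame_dt,
        atoms=atoms,
        metadata={
            "lift_matrix": lift,
            "base_coords": base,
            "true_labels": latent.labels.copy(),
            "latent_positions": latent.positions.copy(),
            "noise_sigma": noise_sigma,
        },
    )


def synthetic_energy_series(
    latent: LatentTrajectory,
    state_means: np.ndarray,
    sigma: float = 2.0,
    seed: int = 0,
    label: str = "synthetic dG_bind",
) -> EnergySeries:
    """Per-frame energy: the occupied well's mean plus N(0, sigma^2) noise.

    Emulates a per-frame MM-GBSA binding-energy series whose level tracks
    the conformational state.
    """
    state_means = np.asarray(state_means, dtype=float)
    if state_means.shape[0] != latent.potential.n_wells:
        raise ConfigurationError(
            f"need one mean per well: got {state_means.shape[0]} means "
            f"for {latent.potential.n_wells} wells"
        )
    if sigma < 0:
        raise ConfigurationError("sigma must be >= 0")
    rng = np.random.default_rng(child_seed(seed, "energy"))
    values = state_means[latent.labels]
    if sigma > 0:
        values = values + rng.standard_normal(values.shape) * sigma
    return EnergySeries(values=values, label=label)


def make_two_state_chain(p: float, q: float, n_steps: int, seed: int = 0) -> np.ndarray:
    """Sample a two-state Markov chain with transition matrix [[1-p, p], [q, 1-q]].

    Returns per-step integer labels (0/1). The stationary distribution is
    ``(q, p)/(p+q)`` and the relaxation eigenvalue is ``1-p-q``, giving an
    exact oracle for MSM implied timescales.
    """
    if not (0.0 < p < 1.0 and 0.0 < q < 1.0):
        raise ConfigurationError("transition probabilities must be in (0, 1)")
    if n_steps < 2:
        raise ConfigurationError("n_steps must be >= 2")
    rng = np.random.default_rng(child_seed(seed, "chain"))
    u = rng.random(n_steps)
    labels = np.empty(n_steps, dtype=int)
    # start from the stationary distribution
    state = 0 if u[0] < q / (p + q) else 1
    labels[0] = state
    for t in range(1, n_steps):
        if state == 0:
            state = 1 if u[t] < p else 0
        else:
            state = 0 if u[t] < q else 1
        labels[t] = state
    return labels


def make_two_well_dataset(
    seed: int = 0,
    n_latent_steps: int = 100_000,
    n_frames: int = 1000,
    n_atoms: int = 50,
    kT: float = 0.5,
    dt_sim: float = 0.01,
    noise_sigma: float = 0.1,
    tilt: float = 0.0,
    state_means: tuple[float, float] = (-50.0, -30.0),
    energy_sigma: float = 2.0,
):
    """Build the default end-to-end fixture: 2-D two-well, 50 atoms, 1000 frames.

    Mirrors the shape of the study's data (1000 stored frames over 100 ns,
    dt = 0.1 ns). Returns ``(latent_strided, trajectory, energy_series)``
    where the strided latent carries the true per-frame labels.
    """
    if n_latent_steps % n_frames:
        raise ConfigurationError("n_latent_steps must be a multiple of n_frames")
    pot = DoubleWellPotential(height=1.0, tilt=tilt, dim=2, kappa=4.0)
    latent = simulate_langevin(pot, n_latent_steps, dt_sim=dt_sim, kT=kT, seed=seed)
    strided = latent.stride(n_latent_steps // n_frames)
    traj = lift_to_trajectory(strided, n_atoms=n_atoms, noise_sigma=noise_sigma, seed=seed)
    energies = synthetic_energy_series(
        strided, np.asarray(state_means), sigma=energy_sigma, seed=seed
    )
    return strided, traj, energies
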