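"""Dimensionality reduction of the frame ensemble.

Three routes from a frames x features matrix to a low-dimensional view
of the conformational landscape:

* **Diffusion maps** — a Gaussian similarity kernel over frames,
  density-normalized (``K~ = D^-a K D^-a``), row-normalized to a Markov
  operator and eigendecomposed. The leading eigenvector is constant with
  eigenvalue 1 (row-stochasticity) and is dropped; the remaining
  eigenvectors, scaled by their eigenvalues, are the diffusion
  coordinates. Connectivity geometry — which frames interconvert — is
  preserved.
* **TICA** — time-lagged independent component analysis: the generalized
  eigenproblem ``C(tau) v = lambda C(0) v`` on mean-free features with a
  symmetrized time-lagged covariance. Components maximize
  autocorrelation at lag tau, isolating the slowest collective motions.
  Default lag: 500 frames.
* **2-D manifold embedding** — delegated to UMAP for visualization only;
  never used for quantitative claims.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sp_linalg

from .errors import BandwidthError, ConfigurationError, SelectionError
from .metrics import apply_superposition, kabsch_superpose
from .trajectory import AtomSelection, TrajectoryEnsemble

__all__ = [
    "FeatureMatrix",
    "Embedding",
    "featurize",
    "diffusion_map",
    "tica",
    "embed_2d",
    "DEFAULT_TICA_LAG",
]

#: Default TICA lag in frames (half the stored trajectory of the
#: reference systems: 500 of 1000 frames).
DEFAULT_TICA_LAG = 500


@dataclass
class FeatureMatrix:
    """Frames x features matrix with a record of how it was built."""

    values: np.ndarray
    description: str = ""
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError(f"feature matrix must be 2-D, got {self.values.ndim}-D")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("feature matrix contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class Embedding:
    """Frames x k reduced coordinates with the spectrum that produced them."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    method: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


def featurize(
    traj: TrajectoryEnsemble, sel: AtomSelection, superpose: bool = True
) -> FeatureMatrix:
    """Flatten selected per-frame coordinates into a frames x (3*n_sel) matrix.

    With ``superpose=True`` each frame's selected atoms are Kabsch-aligned
    to frame 0 first, so rigid-body motion carries no signal.
    """
    if len(sel) == 0:
        raise SelectionError("empty selection")
    sub = traj.coords[:, sel.indices, :]
    if superpose:
        ref = sub[0]
        sub = np.stack(
            [apply_superposition(frame, kabsch_superpose(frame, ref)) for frame in sub]
        )
    n_frames = sub.shape[0]
    return FeatureMatrix(
        values=sub.reshape(n_frames, -1),
        description=f"xyz of selection {sel.expression!r} (superpose={superpose})",
        centered=False,
    )


# ---------------------------------------------------------------------------
# diffusion maps
# ---------------------------------------------------------------------------

def _pairwise_sq_dists(x: np.ndarray, block: int = 512) -> np.ndarray:
    """Dense squared Euclidean distance matrix, computed blockwise."""
    n = x.shape[0]
    sq = (x * x).sum(axis=1)
    out = np.empty((n, n))
    for start in range(0, n, block):
        stop = min(start + block, n)
        out[start:stop] = sq[start:stop, None] + sq[None, :] - 2.0 * (x[start:stop] @ x.T)
    np.maximum(out, 0.0, out=out)
    return out


def auto_bandwidth(x: np.ndarray, subsample: int = 1000, seed: int = 0) -> float:
    """Median of squared pairwise distances on a subsample — a scale-free
    default for the Gaussian kernel bandwidth epsilon."""
    n = x.shape[0]
    if n > subsample:
        rng = np.random.default_rng(seed)
        x = x[rng.choice(n, subsample, replace=False)]
    d2 = _pairwise_sq_dists(x)
    off = d2[~np.eye(d2.shape[0], dtype=bool)]
    eps = float(np.median(off))
    if eps <= 0:
        raise BandwidthError("all points coincide; bandwidth undefined")
    return eps


def diffusion_map(
    X: FeatureMatrix,
    epsilon: float | str = "auto",
    alpha: float = 1.0,
    k: int = 3,
) -> Embedding:
    """Diffusion-map embedding of a feature matrix.

    Builds ``K_ij = exp(-|x_i - x_j|^2 / eps)``, applies the density
    normalization ``K~ = D^-alpha K D^-alpha`` (``alpha=1`` is the
    Laplace–Beltrami normalization, removing sampling-density bias), row
    normalizes to a Markov matrix and eigendecomposes it via the
    symmetric conjugate. The trivial constant eigenvector (eigenvalue 1)
    is verified and excluded; coordinates are ``lambda_i * psi_i``.

    Raises
    ------
    BandwidthError
        If a kernel row sums to ~0 (numerically disconnected graph);
        advises a larger epsilon.
    """
    n = X.n_frames
    if n < k + 2:
        raise ConfigurationError(f"need n_frames >= k+2 = {k + 2}, got {n}")
    x = X.values
    if epsilon == "auto":
        eps = auto_bandwidth(x)
    else:
        eps = float(epsilon)
        if eps <= 0:
            raise ConfigurationError(f"epsilon must be positive, got {eps}")

    d2 = _pairwise_sq_dists(x)
    kernel = np.exp(-d2 / eps)

    deg = kernel.sum(axis=1)
    if np.any(deg < n * 1e-300) or np.any(deg - 1.0 < 1e-12):
        # a row whose only mass is its own diagonal entry is disconnected
        raise BandwidthError(
            "kernel graph numerically disconnected; increase epsilon "
            f"(current {eps:g})"
        )
    if alpha != 0.0:
        inv_d_alpha = deg**-alpha
        kernel = kernel * np.outer(inv_d_alpha, inv_d_alpha)
        deg = kernel.sum(axis=1)

    # symmetric conjugate S = D^-1/2 K~ D^-1/2 shares eigenvalues with the
    # Markov matrix M = D^-1 K~; eigenvectors map via D^-1/2
    inv_sqrt_d = 1.0 / np.sqrt(deg)
    sym = kernel * np.outer(inv_sqrt_d, inv_sqrt_d)
    sym = 0.5 * (sym + sym.T)
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals = evals[order][: k + 1]
    psi = (evecs[:, order][:, : k + 1]) * inv_sqrt_d[:, None]

    if abs(evals[0] - 1.0) > 1e-8:
        raise BandwidthError(
            f"leading eigenvalue {evals[0]:.12f} != 1; kernel graph ill-conditioned"
        )
    # normalize so the trivial eigenvector is constant +1, fix signs of the
    # rest by their largest-magnitude entry for determinism
    psi = psi / psi[0, 0]
    const_dev = np.abs(psi[:, 0] - 1.0).max()
    if const_dev > 1e-6:
        raise BandwidthError(f"trivial eigenvector not constant (max dev {const_dev:.2e})")
    coords = np.empty((n, k))
    eigs = np.empty(k)
    for i in range(k):
        v = psi[:, i + 1]
        v = v / np.linalg.norm(v)
        pivot = np.argmax(np.abs(v))
        if v[pivot] < 0:
            v = -v
        coords[:, i] = evals[i + 1] * v
        eigs[i] = evals[i + 1]
    return Embedding(
        coordinates=coords,
        eigenvalues=eigs,
        method="diffusion-map",
        parameters={"epsilon": eps, "alpha": alpha, "k": k},
    )


# ---------------------------------------------------------------------------
# TICA
# ---------------------------------------------------------------------------

def tica(
    X: FeatureMatrix,
    lag: int = DEFAULT_TICA_LAG,
    k: int = 3,
    var_cutoff: float = 0.999,
) -> Embedding:
    """Time-lagged independent component analysis.

    Solves ``C(tau) v = lambda C(0) v`` on mean-free features, with the
    time-lagged covariance symmetrized, ``C(tau) = (A + A^T)/2`` where
    ``A = X[:-tau]^T X[tau:] / (N - tau)``. Eigenvalues above 1 are
    clipped with a warning, so the reported spectrum lies in (0, 1]
    where defined.

    Regularization: the whitening basis is truncated to the leading
    principal components explaining ``var_cutoff`` of the total variance
    (at least ``k`` of them), and any retained ``C(0)`` eigenvalue below
    1e-10 of the largest is floored with a warning. Without the
    truncation, low-variance feature directions — rigid-body residuals
    of the superposition, per-atom jitter — are whitened up to unit
    variance and their sampling autocorrelation (of order
    ``2 sqrt(d/N)``) can bury the real slow modes.

    Components are ordered by eigenvalue (slowest first); the projection
    of the mean-free data onto them forms the embedding coordinates.
    """
    n, d = X.values.shape
    if lag < 1:
        raise ConfigurationError(f"lag must be >= 1, got {lag}")
    if lag >= n:
        raise ConfigurationError(f"lag {lag} >= n_frames {n}")
    if n <= lag + k:
        raise ConfigurationError(f"need n_frames > lag + k = {lag + k}, got {n}")
    if not (0.0 < var_cutoff <= 1.0):
        raise ConfigurationError(f"var_cutoff must be in (0, 1], got {var_cutoff}")
    x = X.values - X.values.mean(axis=0)

    m = n - lag
    c0 = (x.T @ x) / n
    a = (x[:-lag].T @ x[lag:]) / m
    ctau = 0.5 * (a + a.T)

    w0, u0 = np.linalg.eigh(0.5 * (c0 + c0.T))
    order0 = np.argsort(w0)[::-1]
    w0, u0 = w0[order0], u0[:, order0]
    # principal-component truncation of the whitening basis
    total = w0.sum()
    if total <= 0:
        raise ConfigurationError("feature matrix has zero variance")
    n_keep = int(np.searchsorted(np.cumsum(w0) / total, var_cutoff) + 1)
    n_keep = min(max(n_keep, k), d)
    w0, u0 = w0[:n_keep], u0[:, :n_keep]
    floor = 1e-10 * max(w0.max(), 1.0)
    if np.any(w0 < floor):
        warnings.warn(
            "rank-deficient instantaneous covariance; applying eigenvalue floor",
            RuntimeWarning,
            stacklevel=2,
        )
        w0 = np.maximum(w0, floor)
    # whiten and solve the symmetric problem
    whiten = u0 * (w0**-0.5)
    mat = whiten.T @ ctau @ whiten
    mat = 0.5 * (mat + mat.T)
    evals, evecs = sp_linalg.eigh(mat)
    order = np.argsort(evals)[::-1][:k]
    evals = evals[order]
    if np.any(evals > 1.0 + 1e-10):
        warnings.warn(
            f"TICA eigenvalues above 1 clipped (max {evals.max():.6f})",
            RuntimeWarning,
            stacklevel=2,
        )
    evals = np.clip(evals, None, 1.0)
    components = whiten @ evecs[:, order]  # generalized eigenvectors
    # deterministic sign convention
    for i in range(components.shape[1]):
        pivot = np.argmax(np.abs(components[:, i]))
        if components[pivot, i] < 0:
            components[:, i] *= -1.0
    coords = x @ components
    return Embedding(
        coordinates=coords,
        eigenvalues=evals,
        method="tica",
        parameters={"lag": lag, "k": k},
    )


# ---------------------------------------------------------------------------
# delegated 2-D manifold embedding
# ---------------------------------------------------------------------------

def embed_2d(X: FeatureMatrix, n_neighbors: int = 15, seed: int = 0) -> Embedding:
    """2-D manifold embedding for visualization, delegated to UMAP.

    Deterministic under a fixed seed. Use only for qualitative pictures
    of the landscape; distances in the embedded plane carry no
    quantitative meaning.
    """
    if n_neighbors >= X.n_frames:
        raise ConfigurationError(
            f"n_neighbors {n_neighbors} must be < n_frames {X.n_frames}"
        )
    if n_neighbors < 2:
        raise ConfigurationError("n_neighbors must be >= 2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced determinism
        from umap import UMAP

        reducer = UMAP(n_components=2, n_neighbors=n_neighbors, random_state=seed)
        coords = reducer.fit_transform(X.values)
    return Embedding(
        coordinates=np.asarray(coords, dtype=float),
        eigenvalues=np.array([]),
        method="manifold-2d",
        parameters={"n_neighbors": n_neighbors},
        seed=seed,
    )
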