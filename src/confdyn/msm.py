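"""Conformational-state discovery and Markov state models.

Two clustering routes label the frames: density-based OPTICS (extracts
clusters of varying density, labels sparse frames -1 = noise) and
Ward-linkage hierarchical clustering into a fixed number of microstates
(default 15). From the label sequence, transition counts at a lag tau
are accumulated, row-normalized into a transition matrix, and the
implied timescales ``t_i = -tau / ln lambda_i(tau)`` are read off the
eigenvalue spectrum. Lag-independence of the implied timescales is the
standard Markovianity diagnostic, scanned over a list of lags.

Clustering is delegated to scikit-learn; the MSM estimators are local.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConfigurationError, EstimationError, InsufficientDataError

__all__ = [
    "StateLabels",
    "CountMatrix",
    "TransitionMatrix",
    "TimescaleScan",
    "optics_cluster",
    "microstate_cluster",
    "count_matrix",
    "transition_matrix",
    "implied_timescales",
    "timescale_scan",
    "DEFAULT_N_MICROSTATES",
]

#: Default number of hierarchical microstates.
DEFAULT_N_MICROSTATES = 15


@dataclass
class StateLabels:
    """Per-frame integer state assignment; -1 is reserved for noise."""

    labels: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ConfigurationError("labels must be a 1-D sequence")
        if self.labels.size and self.labels.min() < -1:
            raise ConfigurationError("labels must be >= -1")

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)

    @property
    def n_states(self) -> int:
        valid = self.labels[self.labels >= 0]
        return int(np.unique(valid).size)

    @property
    def noise_fraction(self) -> float:
        return float((self.labels == -1).mean())


@dataclass
class CountMatrix:
    """n_states x n_states transition counts at lag tau (sliding window)."""

    counts: np.ndarray
    lag: int
    state_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ConfigurationError("counts must be non-negative")


@dataclass
class TransitionMatrix:
    """Row-stochastic transition probabilities at lag tau."""

    T: np.ndarray
    lag: int
    reversible: bool
    pi: np.ndarray
    state_ids: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        rows = self.T.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-10):
            raise EstimationError(f"rows not stochastic (max dev {np.abs(rows - 1).max():.2e})")
        if self.reversible:
            flux = self.pi[:, None] * self.T
            if np.abs(flux - flux.T).max() > 1e-8:
                raise EstimationError("detailed balance violated beyond 1e-8")


@dataclass
class TimescaleScan:
    """Implied timescales t_i(tau) across a list of lags.

    ``timescales[l, i]`` is the (i+2)-th process timescale in frames at
    ``lags[l]``; undefined entries (eigenvalue <= 0 or numerically 1) are
    NaN. ``converged`` flags whether t_2 varies by <10% over the top half
    of the lag range.
    """

    lags: np.ndarray
    timescales: np.ndarray
    converged: bool
    dt: float | None = None
    discarded_states: list = field(default_factory=list)

    @property
    def timescales_ns(self) -> np.ndarray | None:
        return self.timescales * self.dt if self.dt else None


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def optics_cluster(X: np.ndarray, min_samples: int = 20, xi: float = 0.05) -> StateLabels:
    """Density-based OPTICS clustering with xi cluster extraction.

    Points in sparse regions get label -1 (noise); clusters of differing
    density are extracted from the reachability ordering. Deterministic:
    points are processed in index order with ties broken by lower index.
    """
    from sklearn.cluster import OPTICS

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if min_samples < 2:
        raise ConfigurationError(f"min_samples must be >= 2, got {min_samples}")
    if X.shape[0] < min_samples:
        raise InsufficientDataError(
            f"{X.shape[0]} points < min_samples {min_samples}"
        )
    if np.allclose(X, X[0]):
        # all points identical: one cluster, no noise (OPTICS itself cannot
        # order zero-spread data meaningfully)
        return StateLabels(labels=np.zeros(X.shape[0], dtype=int), method="optics")
    model = OPTICS(min_samples=min_samples, xi=xi)
    labels = model.fit_predict(X)
    return StateLabels(labels=labels, method="optics")


def microstate_cluster(
    X: np.ndarray,
    n_clusters: int = DEFAULT_N_MICROSTATES,
    linkage: str = "ward",
    seed: int = 0,
) -> StateLabels:
    """Hierarchical microstate clustering (Ward linkage by default).

    Produces exactly ``n_clusters`` non-empty states and no noise label;
    the default of 15 matches standard MSM microstate practice for a
    1000-frame trajectory. ``seed`` is accepted for interface symmetry;
    agglomerative clustering is deterministic.
    """
    from sklearn.cluster import AgglomerativeClustering

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n_clusters < 1:
        raise ConfigurationError("n_clusters must be >= 1")
    if n_clusters > n:
        raise ConfigurationError(f"n_clusters {n_clusters} > n_frames {n}")
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage=linkage)
    labels = model.fit_predict(X)
    return StateLabels(labels=labels, method=f"hierarchical-{linkage}")


# ---------------------------------------------------------------------------
# MSM estimation
# ---------------------------------------------------------------------------

def count_matrix(
    labels: StateLabels | np.ndarray,
    lag: int,
    noise_policy: str = "ignore-transition",
) -> CountMatrix:
    """Sliding-window transition counts ``C_ij = #{t : s_t = i, s_{t+lag} = j}``.

    Noise frames (-1) either break the pairs they touch
    (``'ignore-transition'``, default — no transition is fabricated) or
    are dropped from the sequence before pairing (``'drop'``, which
    splices across noise gaps).
    """
    seq = labels.labels if isinstance(labels, StateLabels) else np.asarray(labels, int)
    if lag < 1:
        raise ConfigurationError(f"lag must be >= 1, got {lag}")
    if noise_policy not in ("ignore-transition", "drop"):
        raise ConfigurationError(f"unknown noise_policy {noise_policy!r}")
    if noise_policy == "drop":
        seq = seq[seq >= 0]
    if seq.size <= lag:
        raise InsufficientDataError(f"sequence of {seq.size} frames too short for lag {lag}")
    src, dst = seq[:-lag], seq[lag:]
    valid = (src >= 0) & (dst >= 0)
    if not valid.any():
        raise InsufficientDataError("no valid transition pairs (all involve noise)")
    src, dst = src[valid], dst[valid]
    state_ids = np.unique(np.concatenate([src, dst]))
    index = {s: i for i, s in enumerate(state_ids)}
    n = state_ids.size
    counts = np.zeros((n, n))
    np.add.at(counts, (np.array([index[s] for s in src]), np.array([index[s] for s in dst])), 1.0)
    return CountMatrix(counts=counts, lag=lag, state_ids=state_ids)


def _largest_scc(counts: np.ndarray) -> np.ndarray:
    """Indices of the largest strongly connected component of the count graph."""
    graph = csr_matrix(counts > 0)
    n_comp, assignment = connected_components(graph, directed=True, connection="strong")
    if n_comp == 1:
        return np.arange(counts.shape[0])
    sizes = np.bincount(assignment, weights=counts.sum(axis=1) + counts.sum(axis=0))
    return np.flatnonzero(assignment == np.argmax(sizes))


def transition_matrix(C: CountMatrix, reversible: bool = False) -> TransitionMatrix:
    """Maximum-likelihood transition matrix from a count matrix.

    Non-reversible (default): plain row normalization of the counts.
    Reversible: row normalization of the symmetrized counts
    ``(C + C^T)/2`` — an approximation to the reversible MLE that
    guarantees detailed balance exactly.

    Estimation is restricted to the largest strongly connected set of
    states; discarded states are reported in a warning. States with no
    outgoing counts are thereby pruned.
    """
    counts = C.counts
    if counts.size == 0 or counts.sum() == 0:
        raise EstimationError("empty count matrix")
    keep = _largest_scc(counts)
    if keep.size < counts.shape[0]:
        dropped = sorted(set(range(counts.shape[0])) - set(keep.tolist()))
        warnings.warn(
            f"restricting MSM to largest strongly connected set; "
            f"discarded states {[int(C.state_ids[i]) for i in dropped]}",
            RuntimeWarning,
            stacklevel=2,
        )
    sub = counts[np.ix_(keep, keep)]
    if sub.sum() == 0:
        raise EstimationError("no transitions within the connected set")
    if reversible:
        sub = 0.5 * (sub + sub.T)
    rows = sub.sum(axis=1)
    if np.any(rows == 0):
        raise EstimationError("state with no outgoing counts survived pruning")
    T = sub / rows[:, None]
    if reversible:
        pi = rows / rows.sum()  # symmetric counts: row sums are stationary
    else:
        evals, evecs = np.linalg.eig(T.T)
        i = np.argmin(np.abs(evals - 1.0))
        pi = np.real(evecs[:, i])
        pi = np.abs(pi) / np.abs(pi).sum()
    return TransitionMatrix(
        T=T, lag=C.lag, reversible=reversible, pi=pi, state_ids=C.state_ids[keep]
    )


def implied_timescales(T: TransitionMatrix) -> np.ndarray:
    """Implied timescales ``t_i = -tau / ln lambda_i`` in frames, sorted descending.

    The stationary eigenvalue (the single largest, = 1) is excluded.
    Eigenvalues <= 0 give no real timescale and are NaN (warning);
    further eigenvalues numerically >= 1 are unresolved at this lag and
    also NaN. For non-reversible matrices eigenvalues may be complex:
    the real part is used, with a warning if any imaginary magnitude
    exceeds 1e-8.
    """
    evals = np.linalg.eigvals(T.T)
    if np.abs(evals.imag).max() > 1e-8:
        warnings.warn(
            f"complex transition-matrix eigenvalues (max |imag| "
            f"{np.abs(evals.imag).max():.2e}); using real parts",
            RuntimeWarning,
            stacklevel=2,
        )
    lam = np.sort(evals.real)[::-1]
    lam = lam[1:]  # drop the stationary eigenvalue
    ts = np.full(lam.shape, np.nan)
    defined = (lam > 0) & (lam < 1.0 - 1e-12)
    ts[defined] = -T.lag / np.log(lam[defined])
    if np.any(lam <= 0):
        warnings.warn(
            f"{int((lam <= 0).sum())} eigenvalue(s) <= 0: timescale undefined at lag {T.lag}",
            RuntimeWarning,
            stacklevel=2,
        )
    if np.any(lam >= 1.0 - 1e-12):
        warnings.warn(
            f"{int((lam >= 1.0 - 1e-12).sum())} eigenvalue(s) at 1: process unresolved at "
            f"lag {T.lag}",
            RuntimeWarning,
            stacklevel=2,
        )
    return ts


def timescale_scan(
    labels: StateLabels | np.ndarray,
    lags: list[int],
    reversible: bool = False,
    noise_policy: str = "ignore-transition",
    dt: float | None = None,
) -> TimescaleScan:
    """Implied timescales as a function of lag — the Markovianity diagnostic.

    A flat t_2(tau) indicates the state decomposition is Markovian at
    these lags; ``converged`` is set when t_2 varies by <10% over the top
    half of the lag range. Lags beyond half the trajectory are allowed
    with a warning (few independent transition pairs).
    """
    seq = labels if isinstance(labels, StateLabels) else StateLabels(np.asarray(labels, int))
    if seq.n_states < 2:
        raise InsufficientDataError(
            f"{seq.n_states} state(s): no relaxation process to resolve at any lag"
        )
    lags_arr = np.asarray(sorted(lags), dtype=int)
    if lags_arr.size == 0 or lags_arr.min() < 1:
        raise ConfigurationError("lags must be positive integers")
    if lags_arr.max() >= seq.n_frames / 2:
        warnings.warn(
            f"max lag {lags_arr.max()} exceeds half the trajectory "
            f"({seq.n_frames} frames); estimates will be noisy",
            RuntimeWarning,
            stacklevel=2,
        )
    n_ts = max(seq.n_states - 1, 1)
    out = np.full((lags_arr.size, n_ts), np.nan)
    for li, lag in enumerate(lags_arr):
        C = count_matrix(seq, int(lag), noise_policy=noise_policy)
        T = transition_matrix(C, reversible=reversible)
        ts = implied_timescales(T)
        out[li, : min(ts.size, n_ts)] = ts[:n_ts]
    t2 = out[:, 0]
    top = t2[lags_arr >= lags_arr[0] + (lags_arr[-1] - lags_arr[0]) / 2]
    top = top[np.isfinite(top)]
    converged = bool(top.size >= 2 and (top.max() - top.min()) / top.max() < 0.10)
    return TimescaleScan(lags=lags_arr, timescales=out, converged=converged, dt=dt)
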