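"""Superposition-based deviation and fluctuation metrics.

RMSD quantifies the positional deviation of a frame from a reference
after optimal rigid-body superposition; RMSF quantifies each atom's
fluctuation about its mean position over the whole trajectory. Both use
the Kabsch algorithm — the closed-form least-squares rigid alignment via
singular value decomposition, with the sign correction that excludes
improper rotations (reflections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InsufficientDataError, SelectionError
from .trajectory import AtomSelection, TrajectoryEnsemble

__all__ = [
    "SuperpositionResult",
    "FluctuationProfile",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd_series",
    "rmsf",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid alignment of a mobile point set onto a reference.

    ``rotation`` is proper (det = +1); ``mobile @ rotation.T + translation``
    is the aligned point set; ``rmsd`` is the residual deviation in Å.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass(frozen=True)
class FluctuationProfile:
    """Per-atom RMSF (Å) over a stated selection."""

    rmsf: np.ndarray
    atom_indices: np.ndarray
    resids: np.ndarray


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Both inputs are (n, 3) with n >= 3 non-collinear points. The rotation
    is constrained to be proper by flipping the sign of the smallest
    singular direction when the raw SVD solution is a reflection.

    Raises
    ------
    ConfigurationError
        On mismatched shapes, fewer than 3 points, or collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ConfigurationError(
            f"point sets must share shape (n, 3); got {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise ConfigurationError(f"superposition needs >= 3 points, got {n}")

    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)

    # collinearity check: centered points must span at least a plane
    if np.linalg.matrix_rank(ref_c, tol=1e-10) < 2 or np.linalg.matrix_rank(mob_c, tol=1e-10) < 2:
        raise ConfigurationError("degenerate (collinear) point set; superposition is ill-posed")

    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    aligned = mob_c @ rotation.T
    rmsd = float(np.sqrt(((aligned - ref_c) ** 2).sum() / n))
    translation = reference.mean(axis=0) - rotation @ mobile.mean(axis=0)
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def apply_superposition(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    """Apply a fitted rotation/translation to an (n, 3) coordinate set."""
    return np.asarray(coords, float) @ result.rotation.T + result.translation


def rmsd_series(
    traj: TrajectoryEnsemble,
    sel: AtomSelection,
    reference_frame: int = 0,
    reference: str = "frame",
) -> np.ndarray:
    """Per-frame RMSD (Å) over a selection, after superposition.

    Each frame's selected atoms are Kabsch-aligned onto the reference
    before the deviation is measured, so rigid-body motion contributes
    nothing. The reference is frame ``reference_frame`` by default
    (``series[reference_frame] == 0``); pass ``reference='mean'`` to use
    the mean structure instead.
    """
    if len(sel) == 0:
        raise SelectionError("empty selection")
    if reference == "frame":
        if not (0 <= reference_frame < traj.n_frames):
            raise ConfigurationError(
                f"reference_frame {reference_frame} outside [0, {traj.n_frames})"
            )
        ref = traj.coords[reference_frame][sel.indices]
    elif reference == "mean":
        ref = _mean_structure(traj.coords[:, sel.indices, :])
    else:
        raise ConfigurationError(f"reference must be 'frame' or 'mean', got {reference!r}")

    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        out[t] = kabsch_superpose(traj.coords[t][sel.indices], ref).rmsd
    return out


def _mean_structure(coords: np.ndarray, passes: int = 2) -> np.ndarray:
    """Iteratively superposed mean structure of an (n_frames, n, 3) stack.

    Two passes: align everything to frame 0 and average, then re-align to
    that average and re-average. Removes drift contamination from the
    fluctuation estimate.
    """
    ref = coords[0]
    mean = ref
    for _ in range(passes):
        aligned = np.stack(
            [apply_superposition(frame, kabsch_superpose(frame, mean)) for frame in coords]
        )
        mean = aligned.mean(axis=0)
    return mean


def rmsf(traj: TrajectoryEnsemble, sel: AtomSelection) -> FluctuationProfile:
    """Per-atom root-mean-square fluctuation (Å) about the mean structure.

    ``RMSF_i = sqrt(mean_t |r_i(t) - rbar_i|^2)`` after superposing every
    frame onto the iteratively computed mean structure of the selection.
    """
    if len(sel) == 0:
        raise SelectionError("empty selection")
    if traj.n_frames < 2:
        raise InsufficientDataError("RMSF needs >= 2 frames")
    sub = traj.coords[:, sel.indices, :]
    mean = _mean_structure(sub)
    aligned = np.stack(
        [apply_superposition(frame, kabsch_superpose(frame, mean)) for frame in sub]
    )
    mean_final = aligned.mean(axis=0)
    fluct = np.sqrt(((aligned - mean_final) ** 2).sum(axis=2).mean(axis=0))
    resids = traj.atoms["resid"].to_numpy()[sel.indices]
    return FluctuationProfile(rmsf=fluct, atom_indices=sel.indices.copy(), resids=resids)
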