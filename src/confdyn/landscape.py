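"""Free-energy surfaces and binding-energy landscapes.

A free-energy surface (FES) over two embedding components is the
Boltzmann inversion of the occupancy histogram, ``F_b = -kT ln(n_b /
n_max)``, reported relative to the deepest bin (min F = 0). Empty bins
are masked rather than given a pseudo-count, so no barrier height is
fabricated. The energy map overlays a per-frame binding-energy series
(e.g. MM-GBSA dG) on the same grid as a per-bin mean with standard
error — the "energy-integrated" view of the landscape.

``kT`` defaults to 300 K, the simulations' thermostat temperature:
``kT = 1.9872e-3 kcal/mol/K * 300 K = 0.5962 kcal/mol``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .errors import AlignmentError, ConfigurationError
from .embeddings import Embedding
from .trajectory import EnergySeries

__all__ = [
    "KT_300K",
    "FreeEnergySurface",
    "EnergyMap",
    "binding_energy",
    "fes_from_density",
    "energy_surface",
    "per_state_energy",
]

#: Boltzmann constant in kcal/mol/K.
BOLTZMANN_KCAL = 1.9872e-3

#: kT at the 300 K thermostat temperature, kcal/mol.
KT_300K = BOLTZMANN_KCAL * 300.0


@dataclass
class FreeEnergySurface:
    """2-D free-energy surface on a histogram grid.

    ``F`` is in kcal/mol, shifted so the deepest unmasked bin is exactly
    0; masked entries (zero occupancy) are NaN with ``mask`` True.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    F: np.ndarray
    mask: np.ndarray
    counts: np.ndarray
    kT: float
    dims: tuple[int, int]

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_frame(self):
        """Long-format DataFrame of unmasked bins: bin_i,bin_j,center_x,center_y,count,F."""
        import pandas as pd

        ii, jj = np.where(~self.mask)
        return pd.DataFrame(
            {
                "bin_i": ii,
                "bin_j": jj,
                "center_x": self.x_centers[ii],
                "center_y": self.y_centers[jj],
                "count": self.counts[ii, jj].astype(int),
                "F": self.F[ii, jj],
            }
        )


@dataclass
class EnergyMap:
    """Per-bin mean/SE/count of a per-frame energy series on a FES grid."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    counts: np.ndarray
    dims: tuple[int, int]
    label: str = "energy"

    def to_frame(self):
        import pandas as pd

        occupied = self.counts > 0
        ii, jj = np.where(occupied)
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        return pd.DataFrame(
            {
                "bin_i": ii,
                "bin_j": jj,
                "center_x": xc[ii],
                "center_y": yc[jj],
                "count": self.counts[ii, jj].astype(int),
                "mean_dG": self.mean[ii, jj],
                "se_dG": self.se[ii, jj],
            }
        )


def binding_energy(e_complex, e_ligand, e_receptor):
    """Binding free energy: ``dG = E_complex - (E_ligand + E_receptor)``.

    The MM-GBSA combination rule, vectorized over aligned per-frame
    series; scalars in, scalar out. All inputs must be finite.
    """
    e_complex = np.asarray(e_complex, dtype=float)
    e_ligand = np.asarray(e_ligand, dtype=float)
    e_receptor = np.asarray(e_receptor, dtype=float)
    for name, arr in (("e_complex", e_complex), ("e_ligand", e_ligand), ("e_receptor", e_receptor)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite values")
    out = e_complex - (e_ligand + e_receptor)
    return float(out) if out.ndim == 0 else out


def _embedding_xy(emb: Embedding, dims: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    i, j = dims
    k = emb.coordinates.shape[1]
    if not (0 <= i < k and 0 <= j < k) or i == j:
        raise ConfigurationError(f"dims {dims} invalid for a {k}-component embedding")
    return emb.coordinates[:, i], emb.coordinates[:, j]


def fes_from_density(
    emb: Embedding,
    dims: tuple[int, int] = (0, 1),
    bins: int = 50,
    kT: float = KT_300K,
) -> FreeEnergySurface:
    """Free-energy surface from the occupancy histogram of two components.

    ``F_b = -kT ln(n_b / n_max)``: the modal bin sits at F = 0 and rarer
    bins lie higher by the Boltzmann population rule. Bins with zero
    occupancy are masked (NaN). With fewer than ~10 frames per bin on
    average the surface is noisy; a warning is emitted.
    """
    if kT <= 0:
        raise ConfigurationError(f"kT must be positive, got {kT}")
    if bins < 2:
        raise ConfigurationError("bins must be >= 2")
    x, y = _embedding_xy(emb, dims)
    if x.size < 10 * bins:
        warnings.warn(
            f"{x.size} frames over {bins}x{bins} bins is sparse; "
            "surface will be noisy",
            RuntimeWarning,
            stacklevel=2,
        )
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins)
    mask = counts == 0
    if mask.sum() == mask.size - 1:
        warnings.warn("all frames fall in a single bin; degenerate surface", RuntimeWarning,
                      stacklevel=2)
    F = np.full_like(counts, np.nan)
    n_max = counts.max()
    with np.errstate(divide="ignore"):
        F[~mask] = -kT * np.log(counts[~mask] / n_max)
    return FreeEnergySurface(
        x_edges=x_edges, y_edges=y_edges, F=F, mask=mask, counts=counts, kT=kT, dims=tuple(dims)
    )


def energy_surface(
    emb: Embedding,
    energies: EnergySeries,
    dims: tuple[int, int] = (0, 1),
    bins: int = 50,
) -> EnergyMap:
    """Per-bin mean and standard error of a per-frame energy series.

    Frames are binned by two embedding components; each occupied bin
    reports the mean energy of its frames, the SE (count >= 2 only; NaN
    for singleton bins) and the count. Counts sum to n_frames.
    """
    x, y = _embedding_xy(emb, dims)
    if len(energies) != x.size:
        raise AlignmentError(
            f"energy series has {len(energies)} values but embedding has {x.size} frames"
        )
    values = energies.values
    count_stat = sp_stats.binned_statistic_2d(x, y, values, statistic="count", bins=bins)
    mean_stat = sp_stats.binned_statistic_2d(
        x, y, values, statistic="mean", bins=(count_stat.x_edge, count_stat.y_edge)
    )
    std_stat = sp_stats.binned_statistic_2d(
        x, y, values, statistic="std", bins=(count_stat.x_edge, count_stat.y_edge)
    )
    counts = count_stat.statistic
    mean = np.where(counts > 0, mean_stat.statistic, np.nan)
    se = np.full_like(mean, np.nan)
    multi = counts >= 2
    # ddof-1 SE from the population std returned by binned_statistic
    se[multi] = std_stat.statistic[multi] * np.sqrt(
        counts[multi] / (counts[multi] - 1.0)
    ) / np.sqrt(counts[multi])
    return EnergyMap(
        x_edges=count_stat.x_edge,
        y_edges=count_stat.y_edge,
        mean=mean,
        se=se,
        counts=counts,
        dims=tuple(dims),
        label=energies.label,
    )


def per_state_energy(energies: EnergySeries, labels: np.ndarray):
    """Mean/SE/count of the energy series per state label (noise -1 excluded)."""
    import pandas as pd

    labels = np.asarray(labels, dtype=int)
    if len(energies) != labels.size:
        raise AlignmentError(
            f"energy series has {len(energies)} values but {labels.size} labels given"
        )
    df = pd.DataFrame({"state": labels, "value": energies.values})
    df = df[df["state"] >= 0]
    grouped = df.groupby("state")["value"]
    out = grouped.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_dG", "sem": "se_dG"})
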