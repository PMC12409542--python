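"""Trajectory data model and I/O.

Defines the in-memory containers every analysis stage consumes — a
coordinate ensemble, an atom selection, and a per-frame scalar energy
series — plus readers/writers for the standard formats (PDB topology,
DCD/XTC coordinates, ``frame,value`` CSV). File parsing is delegated to
MDAnalysis; this module only fixes units and conventions:

* coordinates are stored in Å (XTC's native nm are converted on read),
* the frame time step ``dt`` is in ns and constant,
* frame indexing is 0-based with half-open ranges.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, SelectionError, TrajectoryFormatError

__all__ = [
    "TrajectoryEnsemble",
    "AtomSelection",
    "EnergySeries",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
    "read_energy_series",
    "write_energy_series",
]

#: Atom names constituting the protein backbone, the convention used for
#: backbone RMSD.
BACKBONE_NAMES = ("N", "CA", "C", "O")

ATOM_COLUMNS = ("name", "resname", "resid", "chain", "element")


@dataclass
class TrajectoryEnsemble:
    """A frames x atoms x 3 coordinate ensemble with atom metadata.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    dt
        Time between stored frames in ns; must be positive.
    atoms
        DataFrame with one row per atom and columns
        ``name, resname, resid, chain, element``.
    metadata
        Free-form provenance (e.g. the lift matrix of a synthetic
        ensemble, source file paths).
    """

    coords: np.ndarray
    dt: float
    atoms: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryFormatError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryFormatError("coordinates contain non-finite values")
        if not self.dt > 0:
            raise TrajectoryFormatError(f"dt must be positive, got {self.dt}")
        if len(self.atoms) != self.coords.shape[1]:
            raise TrajectoryFormatError(
                f"atom table has {len(self.atoms)} rows but coordinates have "
                f"{self.coords.shape[1]} atoms"
            )
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise TrajectoryFormatError(f"atom table missing columns: {missing}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns, starting at 0."""
        return np.arange(self.n_frames) * self.dt

    def stride(self, step: int) -> "TrajectoryEnsemble":
        """Return every ``step``-th frame; ``dt`` scales accordingly."""
        if step < 1:
            raise TrajectoryFormatError(f"stride must be >= 1, got {step}")
        return TrajectoryEnsemble(
            coords=self.coords[::step].copy(),
            dt=self.dt * step,
            atoms=self.atoms,
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class AtomSelection:
    """A resolved atom selection: unique sorted indices into the atom table."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        idx = np.unique(idx)
        object.__setattr__(self, "indices", idx)
        if idx.size == 0:
            raise SelectionError(f"selection {self.expression!r} matched no atoms")
        if idx.min() < 0:
            raise SelectionError("selection indices must be non-negative")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class EnergySeries:
    """Per-frame scalar energy in kcal/mol, aligned to a trajectory."""

    values: np.ndarray
    label: str = "energy"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise AlignmentError(f"energy series {self.label!r} has non-finite values")

    def __len__(self) -> int:
        return int(self.values.size)


# ---------------------------------------------------------------------------
# selection mini-grammar
# ---------------------------------------------------------------------------

_RESID_RE = re.compile(r"^(\d+)(?:-(\d+))?$")


def _term_mask(traj: TrajectoryEnsemble, tokens: list[str]) -> np.ndarray:
    atoms = traj.atoms
    head = tokens[0].lower()
    if head == "all" and len(tokens) == 1:
        return np.ones(traj.n_atoms, dtype=bool)
    if head == "backbone" and len(tokens) == 1:
        return atoms["name"].str.upper().isin(BACKBONE_NAMES).to_numpy()
    if head == "calpha" and len(tokens) == 1:
        return (atoms["name"].str.upper() == "CA").to_numpy()
    if head == "resid" and len(tokens) >= 2:
        mask = np.zeros(traj.n_atoms, dtype=bool)
        for spec in tokens[1:]:
            m = _RESID_RE.match(spec)
            if m is None:
                raise SelectionError(f"bad resid range {spec!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            mask |= ((atoms["resid"] >= lo) & (atoms["resid"] <= hi)).to_numpy()
        return mask
    if head == "chain" and len(tokens) == 2:
        return (atoms["chain"].astype(str) == tokens[1]).to_numpy()
    raise SelectionError(f"cannot parse selection term {' '.join(tokens)!r}")


def select_atoms(traj: TrajectoryEnsemble, expr: str) -> AtomSelection:
    """Resolve a selection expression against a trajectory's atom table.

    Grammar: terms joined by ``and`` (intersection). Terms::

        all | backbone | calpha | resid N | resid N-M | chain X

    ``backbone`` matches atom names N, CA, C, O; ``calpha`` matches CA.
    Resolution is deterministic and independent of atom-record order.
    """
    expr = expr.strip()
    if not expr:
        raise SelectionError("empty selection expression")
    mask = np.ones(traj.n_atoms, dtype=bool)
    for term in re.split(r"\s+and\s+", expr):
        tokens = term.split()
        if not tokens:
            raise SelectionError(f"empty term in selection {expr!r}")
        mask &= _term_mask(traj, tokens)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {expr!r} matched no atoms")
    return AtomSelection(indices=idx, expression=expr)


# ---------------------------------------------------------------------------
# trajectory I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def read_trajectory(
    topology_path: str,
    coords_path: str,
    stride: int = 1,
    dt: float | None = None,
) -> TrajectoryEnsemble:
    """Read a PDB topology plus DCD/XTC coordinates into an ensemble.

    Parameters
    ----------
    stride
        Keep every ``stride``-th stored frame; ``dt`` is scaled by it.
    dt
        Time between *stored* frames in ns. If ``None``, taken from the
        coordinate file's metadata (converted from MDAnalysis' ps).

    Raises
    ------
    TrajectoryFormatError
        On atom-count mismatch between topology and coordinates, or an
        unreadable file.
    """
    import MDAnalysis as mda

    if stride < 1:
        raise TrajectoryFormatError(f"stride must be >= 1, got {stride}")
    try:
        top = mda.Universe(topology_path)
    except Exception as exc:  # MDAnalysis raises assorted types
        raise TrajectoryFormatError(f"cannot read topology {topology_path}: {exc}") from exc
    try:
        uni = mda.Universe(topology_path, coords_path)
    except ValueError as exc:
        # MDAnalysis reports atom-count mismatches as ValueError; recount
        # for a message naming both counts.
        try:
            coords_only = mda.Universe(coords_path, to_guess=())
            n_coord = coords_only.atoms.n_atoms
        except Exception:
            n_coord = "unknown"
        raise TrajectoryFormatError(
            f"topology has {top.atoms.n_atoms} atoms but coordinate file "
            f"has {n_coord}: {exc}"
        ) from exc
    except Exception as exc:
        raise TrajectoryFormatError(f"cannot read coordinates {coords_path}: {exc}") from exc

    ag = uni.atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # element/chain guessing chatter
        names = [a.name for a in ag]
        try:
            resnames = list(ag.resnames)
        except Exception:
            resnames = ["UNK"] * len(ag)
        resids = list(ag.resids)
        try:
            chains = [seg if seg and seg != "SYSTEM" else "A" for seg in ag.segids]
        except Exception:
            chains = ["A"] * len(ag)
        try:
            elements = list(ag.elements)
        except Exception:
            elements = [_guess_element(n) for n in names]
    atoms = pd.DataFrame(
        {
            "name": names,
            "resname": resnames,
            "resid": resids,
            "chain": chains,
            "element": elements,
        }
    )

    frames = []
    for i, _ts in enumerate(uni.trajectory):
        if i % stride == 0:
            frames.append(ag.positions.astype(float).copy())  # Å in MDAnalysis
    coords = np.stack(frames, axis=0)

    if dt is None:
        dt_stored_ns = float(uni.trajectory.dt) / 1000.0  # ps -> ns
    else:
        dt_stored_ns = float(dt)

    return TrajectoryEnsemble(
        coords=coords,
        dt=dt_stored_ns * stride,
        atoms=atoms,
        metadata={"topology": str(topology_path), "coordinates": str(coords_path), "stride": stride},
    )


def write_trajectory(traj: TrajectoryEnsemble, topology_path: str, coords_path: str) -> None:
    """Write an ensemble as a PDB topology plus a DCD/XTC coordinate file.

    The coordinate format is chosen by the extension of ``coords_path``.
    Round-tripping through :func:`read_trajectory` preserves coordinates
    to format precision (<= 1e-3 Å).
    """
    import MDAnalysis as mda

    n = traj.n_atoms
    uni = mda.Universe.empty(
        n,
        n_residues=int(traj.atoms["resid"].nunique()),
        atom_resindex=pd.factorize(traj.atoms["resid"])[0],
        trajectory=True,
    )
    uni.add_TopologyAttr("names", list(traj.atoms["name"]))
    res_order = traj.atoms.drop_duplicates("resid")
    uni.add_TopologyAttr("resnames", list(res_order["resname"]))
    uni.add_TopologyAttr("resids", list(res_order["resid"]))
    uni.add_TopologyAttr("elements", list(traj.atoms["element"]))
    uni.add_TopologyAttr("segid", ["A"])

    uni.atoms.positions = traj.coords[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        uni.atoms.write(topology_path)
        with mda.Writer(str(coords_path), n_atoms=n) as w:
            for frame in traj.coords:
                uni.atoms.positions = frame
                w.write(uni.atoms)


# ---------------------------------------------------------------------------
# energy series I/O
# ---------------------------------------------------------------------------

def read_energy_series(
    path: str, traj: TrajectoryEnsemble, label: str = "MM-GBSA dG_bind"
) -> EnergySeries:
    """Read a ``frame,value`` CSV aligned to a trajectory.

    Frames 0..n_frames-1 must each appear exactly once (any order); values
    are re-sorted by frame index. Raises :class:`AlignmentError` on any
    length or index mismatch.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise AlignmentError(f"cannot parse energy CSV {path}: {exc}") from exc
    for col in ("frame", "value"):
        if col not in df.columns:
            raise AlignmentError(f"energy CSV {path} lacks required column {col!r}")
    if len(df) != traj.n_frames:
        raise AlignmentError(
            f"energy CSV has {len(df)} rows but trajectory has {traj.n_frames} frames"
        )
    frames = pd.to_numeric(df["frame"], errors="coerce")
    values = pd.to_numeric(df["value"], errors="coerce")
    if frames.isna().any() or values.isna().any():
        raise AlignmentError(f"energy CSV {path} contains non-numeric entries")
    order = np.argsort(frames.to_numpy(), kind="stable")
    sorted_frames = frames.to_numpy()[order]
    if not np.array_equal(sorted_frames, np.arange(traj.n_frames)):
        raise AlignmentError(
            "energy CSV frame indices are not exactly 0..n_frames-1 each once"
        )
    return EnergySeries(values=values.to_numpy()[order], label=label)


def write_energy_series(series: EnergySeries, path: str) -> None:
    """Write a ``frame,value`` CSV (header row, '.' decimal)."""
    pd.DataFrame({"frame": np.arange(len(series)), "value": series.values}).to_csv(
        path, index=False
    )


def require_dynamic(traj: TrajectoryEnsemble, min_frames: int = 2) -> None:
    """Guard for analyses that need at least ``min_frames`` frames."""
    if traj.n_frames < min_frames:
        from .errors import InsufficientDataError

        raise InsufficientDataError(
            f"analysis needs >= {min_frames} frames, trajectory has {traj.n_frames}"
        )
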