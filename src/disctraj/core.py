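"""Core domain types and frame utilities.

The in-memory model is deliberately small: an :class:`AtomTable` backed by a
pandas DataFrame holds per-atom identity and van der Waals radii, a
:class:`Frame` is an ``(N, 3)`` coordinate array with a time stamp, and a
:class:`Trajectory` is an ordered list of frames sharing one atom table.
Species-level semantics (which atom is the per-lipid reference, which names
form the headgroup motifs, which species are occluders) live in a
:class:`SelectionConfig` so that analyses never hard-code atom names.

All lengths are in Angstrom, times in nanoseconds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default element -> van der Waals radius table (Angstrom), Bondi-style values.
#: Frozen so that surface areas are reproducible; override per element through
#: ``read_topology(..., radii=...)`` or a config file.
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "NA": 2.27,
    "MG": 1.73,
    "K": 2.75,
}

ATOM_COLUMNS = [
    "atom_id",
    "atom_name",
    "element",
    "residue_name",
    "residue_id",
    "segment",
    "vdw_radius",
]


class AtomTable:
    """Per-atom identity, residue membership and vdW radii.

    Atom ids are contiguous from 0. A molecule instance is identified by the
    ``(segment, residue_name, residue_id)`` triple; :meth:`residue_index`
    exposes a dense 0-based ordinal over those triples (file order), which the
    analyses use as the lipid id.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ATOM_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"AtomTable missing columns: {missing}")
        df = df[ATOM_COLUMNS].reset_index(drop=True)
        df["atom_id"] = np.arange(len(df))
        self.df = df
        # dense residue ordinal in order of first appearance
        key = (
            df["segment"].astype(str)
            + "|"
            + df["residue_name"].astype(str)
            + "|"
            + df["residue_id"].astype(str)
        )
        codes, _ = pd.factorize(key)
        self._resindex = codes.astype(np.intp)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_atoms(self) -> int:
        return len(self.df)

    @property
    def names(self) -> np.ndarray:
        return self.df["atom_name"].to_numpy()

    @property
    def elements(self) -> np.ndarray:
        return self.df["element"].to_numpy()

    @property
    def species(self) -> np.ndarray:
        """Residue names, used as species keys."""
        return self.df["residue_name"].to_numpy()

    @property
    def radii(self) -> np.ndarray:
        return self.df["vdw_radius"].to_numpy(dtype=float)

    @property
    def residue_index(self) -> np.ndarray:
        """Dense 0-based molecule ordinal per atom."""
        return self._resindex

    @property
    def n_residues(self) -> int:
        return int(self._resindex.max()) + 1 if len(self.df) else 0

    def residue_species(self) -> np.ndarray:
        """Species key of each residue, indexed by residue ordinal."""
        out = np.empty(self.n_residues, dtype=object)
        out[self._resindex] = self.df["residue_name"].to_numpy()
        return out

    def select(
        self,
        species: str | list[str] | None = None,
        names: str | list[str] | None = None,
        exclude_hydrogen: bool = False,
    ) -> np.ndarray:
        """Return sorted atom indices matching the given species/atom names."""
        mask = np.ones(len(self.df), dtype=bool)
        if species is not None:
            if isinstance(species, str):
                species = [species]
            mask &= np.isin(self.species, list(species))
        if names is not None:
            if isinstance(names, str):
                names = [names]
            mask &= np.isin(self.names, list(names))
        if exclude_hydrogen:
            mask &= self.elements != "H"
        return np.flatnonzero(mask)

    def validate(self) -> None:
        ids = self.df["atom_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("atom_ids must be contiguous from 0")


@dataclass
class Frame:
    """One trajectory frame: ``(N, 3)`` coordinates (A), time (ns), optional box."""

    coordinates: np.ndarray
    time: float = 0.0
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (N, 3)")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates contain non-finite values")

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), self.time,
                     None if self.box is None else self.box.copy())


@dataclass
class Trajectory:
    """An atom table plus ordered frames with strictly increasing times."""

    atoms: AtomTable
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self):
        n = self.atoms.n_atoms
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame has {f.coordinates.shape[0]} atoms, table has {n}"
                )
        t = self.times
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def coordinate_array(self) -> np.ndarray:
        """Stack all frames into an ``(n_frames, N, 3)`` array."""
        return np.stack([f.coordinates for f in self.frames])

    def copy(self) -> "Trajectory":
        return Trajectory(self.atoms, [f.copy() for f in self.frames])


# ---------------------------------------------------------------------------
# Selection configuration
# ---------------------------------------------------------------------------

ROLES = ("lipid", "detergent", "polymer", "scaffold")


@dataclass
class SpeciesEntry:
    """Selection metadata for one residue species."""

    role: str = "lipid"
    reference_atom: str = "C2"
    tail_atoms: tuple[str, ...] = ()
    motifs: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        seen: set[str] = set()
        for cls, atoms in self.motifs.items():
            atoms = tuple(atoms)
            if seen & set(atoms):
                raise ValueError(
                    f"motif classes overlap within species (class {cls!r})"
                )
            seen |= set(atoms)
            self.motifs[cls] = atoms
        self.tail_atoms = tuple(self.tail_atoms)


@dataclass
class SelectionConfig:
    """Species -> roles, reference atoms, tails and motif classes."""

    species: dict[str, SpeciesEntry] = field(default_factory=dict)

    def species_with_role(self, *roles: str) -> list[str]:
        return [k for k, v in self.species.items() if v.role in roles]

    def entry(self, species: str) -> SpeciesEntry:
        try:
            return self.species[species]
        except KeyError:
            raise KeyError(f"species {species!r} has no selection entry") from None

    def reference_indices(
        self,
        atoms: AtomTable,
        roles: tuple[str, ...] = ("lipid",),
    ) -> tuple[np.ndarray, np.ndarray]:
        """Indices of per-molecule reference atoms (e.g. the C2 glycerol carbon).

        Returns ``(atom_indices, residue_ordinals)`` sorted by residue ordinal,
        one entry per molecule of the requested roles.
        """
        idx_parts = []
        for sp in self.species_with_role(*roles):
            ref = self.entry(sp).reference_atom
            idx_parts.append(atoms.select(species=sp, names=ref))
        if not idx_parts:
            return np.array([], dtype=np.intp), np.array([], dtype=np.intp)
        idx = np.sort(np.concatenate(idx_parts))
        res = atoms.residue_index[idx]
        # one reference atom per molecule
        if len(np.unique(res)) != len(res):
            raise ValueError("a molecule carries more than one reference atom")
        return idx, res

    def motif_indices(
        self, atoms: AtomTable, species_role: str, motif_class: str,
        exclude_hydrogen: bool = True,
    ) -> np.ndarray:
        """All atoms of the given motif class across species of one role.

        ``motif_class`` may also be the pseudo-class ``"tail"``, resolved from
        ``tail_atoms``.
        """
        parts = []
        for sp in self.species_with_role(species_role):
            entry = self.entry(sp)
            if motif_class == "tail":
                names = entry.tail_atoms
            else:
                names = entry.motifs.get(motif_class, ())
            if names:
                parts.append(
                    atoms.select(species=sp, names=list(names),
                                 exclude_hydrogen=exclude_hydrogen)
                )
        if not parts:
            return np.array([], dtype=np.intp)
        return np.sort(np.concatenate(parts))


# ---------------------------------------------------------------------------
# Frame preprocessing
# ---------------------------------------------------------------------------


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Columns = principal axes of the point cloud, ordered by descending variance."""
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / len(c)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] < 1e-10 * max(evals[2], 1.0):
        raise ValueError("degenerate (collinear) reference configuration")
    if evals[0] > 0 and evals[1] / max(evals[0], 1e-300) < 1.2:
        warnings.warn(
            "smallest two principal variances are within 20%; the bilayer "
            "normal is ambiguous (patch narrower than it is thick?)",
            stacklevel=3,
        )
    return evecs[:, ::-1]  # descending variance: columns x, y, z


def _canonical_signs(axes: np.ndarray) -> np.ndarray:
    """Fix axis signs deterministically: largest-|component| entry positive."""
    x, z = axes[:, 0].copy(), axes[:, 2].copy()
    if x[np.argmax(np.abs(x))] < 0:
        x = -x
    if z[np.argmax(np.abs(z))] < 0:
        z = -z
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def preprocess_align(traj: Trajectory, sel: SelectionConfig) -> Trajectory:
    """Center and orient every frame on the bilayer reference atoms.

    Per frame the center of mass of the lipid reference atoms (C2 by default)
    is moved to the origin and their principal axes are rotated onto the
    Cartesian axes, with the smallest-extent axis (the bilayer normal) mapped
    to z. Axis signs are chosen for continuity with the previous frame; the
    first frame uses a deterministic sign convention with a right-handed
    (positive determinant) axis set.
    """
    ref_idx, _ = sel.reference_indices(traj.atoms, roles=("lipid",))
    if len(ref_idx) < 3:
        raise ValueError("need at least 3 reference atoms to align")
    out_frames: list[Frame] = []
    prev_axes: np.ndarray | None = None
    for fr in traj.frames:
        ref = fr.coordinates[ref_idx]
        com = ref.mean(axis=0)
        axes = _principal_axes(ref)
        if prev_axes is None:
            axes = _canonical_signs(axes)
        else:
            x, z = axes[:, 0].copy(), axes[:, 2].copy()
            if np.dot(x, prev_axes[:, 0]) < 0:
                x = -x
            if np.dot(z, prev_axes[:, 2]) < 0:
                z = -z
            axes = np.column_stack([x, np.cross(z, x), z])
        prev_axes = axes
        coords = (fr.coordinates - com) @ axes
        out_frames.append(Frame(coords, fr.time,
                                None if fr.box is None else fr.box.copy()))
    return Trajectory(traj.atoms, out_frames)


def validate_connectivity(traj: Trajectory, max_bond: float = 5.0) -> int:
    """Warn if consecutive atoms within a residue are farther apart than ``max_bond``.

    Coordinates are treated as unwrapped; a long apparent bond usually means the
    trajectory was wrapped across a periodic boundary. Returns the number of
    offending frames.
    """
    res = traj.atoms.residue_index
    same_res = res[1:] == res[:-1]
    bad_frames = 0
    for fr in traj.frames:
        d = np.linalg.norm(np.diff(fr.coordinates, axis=0), axis=1)
        if np.any(d[same_res] > max_bond):
            bad_frames += 1
    if bad_frames:
        warnings.warn(
            f"{bad_frames} frame(s) contain intra-residue neighbor distances "
            f"> {max_bond} A; coordinates may be wrapped", stacklevel=2,
        )
    return bad_frames


# ---------------------------------------------------------------------------
# Time-series utilities
# ---------------------------------------------------------------------------


def block_average(
    times: np.ndarray, values: np.ndarray, window: float = 15.0
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping block average of a scalar time series.

    Blocks of the given window (ns, default 15) start at the first sample time;
    each block reports its mean at the nominal block-center time. A trailing
    partial block is averaged over the samples it contains.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("empty series")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if window <= 0:
        raise ValueError("window must be positive")
    idx = np.floor((times - times[0]) / window).astype(int)
    # guard against float round-off putting t0+k*window into block k-1/k+1
    nblocks = idx.max() + 1
    sums = np.bincount(idx, weights=values, minlength=nblocks)
    counts = np.bincount(idx, minlength=nblocks)
    means = sums / counts
    centers = times[0] + (np.arange(nblocks) + 0.5) * window
    return centers, means
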