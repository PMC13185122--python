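"""Topology/trajectory readers and writers (PDB, multi-model PDB, CHARMM DCD).

File parsing is delegated to MDAnalysis; this module converts between its
universes and the package's :class:`~disctraj.core.AtomTable` /
:class:`~disctraj.core.Trajectory` types, assigns van der Waals radii from the
frozen element table, and attaches physical times (DCD files carry no absolute
time, so the frame interval is an explicit argument).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.PDB import PDBReader

import yaml

from .core import DEFAULT_VDW_RADII, AtomTable, Frame, SelectionConfig, SpeciesEntry, Trajectory

logger = logging.getLogger(__name__)

_TWO_LETTER = {"CL", "NA", "MG", "BR", "FE", "ZN", "CA"}

#: PDB fixed columns hold at most four characters of a residue name, so longer
#: species codes are truncated on write; known truncations are restored on
#: read. Extend via ``read_topology(..., resname_aliases=...)``.
DEFAULT_RESNAME_ALIASES: dict[str, str] = {"DMTA": "DMTAP"}


def guess_element(atom_name: str) -> str:
    """Guess the element symbol from a PDB-style atom name."""
    letters = "".join(ch for ch in atom_name if ch.isalpha()).upper()
    if not letters:
        raise ValueError(f"cannot guess element for atom name {atom_name!r}")
    if letters[:2] in _TWO_LETTER:
        return letters[:2]
    return letters[0]


def read_topology(
    path: str | Path,
    radii: dict[str, float] | None = None,
    resname_aliases: dict[str, str] | None = None,
) -> AtomTable:
    """Read a PDB file into an :class:`AtomTable`.

    ``radii`` overrides/extends the default element->vdW radius table. Atom ids
    are reassigned contiguously from 0 regardless of the file's serial numbers
    (a warning is logged when serials are duplicated). Residue names found in
    ``resname_aliases`` (default: the known four-character truncations) are
    mapped back to their canonical species keys.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    table = {**DEFAULT_VDW_RADII, **(radii or {})}
    names = u.atoms.names
    try:
        serials = u.atoms.ids
        if len(np.unique(serials)) != len(serials):
            logger.warning("duplicate atom serial numbers in %s; reindexing 0..N-1", path)
    except mda.exceptions.NoDataError:
        pass
    try:
        file_elements = [str(e).upper() for e in u.atoms.elements]
    except mda.exceptions.NoDataError:
        file_elements = [""] * len(names)
    elements = []
    vdw = []
    for nm, file_el in zip(names, file_elements):
        el = file_el if file_el else guess_element(str(nm))
        if el not in table:
            raise KeyError(
                f"no vdW radius for element {el!r} (atom {nm!r}); "
                "supply one via the radii override"
            )
        elements.append(el)
        vdw.append(table[el])
    try:
        segids = u.atoms.segids
    except mda.exceptions.NoDataError:
        segids = np.array([""] * len(names))
    aliases = (DEFAULT_RESNAME_ALIASES if resname_aliases is None
               else resname_aliases)
    df = pd.DataFrame(
        {
            "atom_id": np.arange(len(names)),
            "atom_name": [str(n) for n in names],
            "element": elements,
            "residue_name": [aliases.get(str(r), str(r)) for r in u.atoms.resnames],
            "residue_id": u.atoms.resids.astype(int),
            "segment": [str(s) for s in segids],
            "vdw_radius": vdw,
        }
    )
    return AtomTable(df)


def read_trajectory(
    path: str | Path, atoms: AtomTable, frame_interval: float
) -> Trajectory:
    """Read a multi-model PDB or DCD coordinate file.

    ``frame_interval`` (ns) supplies physical times ``0, dt, 2*dt, ...``; DCD
    headers carry only integrator steps, so the interval is always explicit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive (ns)")
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        reader = DCDReader(str(path))
    elif suffix in (".pdb", ".ent"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = PDBReader(str(path))
    else:
        raise ValueError(f"unsupported trajectory format {suffix!r}")
    frames: list[Frame] = []
    with reader:
        for i, ts in enumerate(reader):
            if ts.n_atoms != atoms.n_atoms:
                raise ValueError(
                    f"frame {i} has {ts.n_atoms} atoms, topology has {atoms.n_atoms}"
                )
            box = None
            if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
                box = np.array(ts.dimensions[:3], dtype=float)
            frames.append(Frame(ts.positions.astype(float), i * frame_interval, box))
    if not frames:
        raise ValueError(f"no frames read from {path}")
    return Trajectory(atoms, frames)


def _universe_from(atoms: AtomTable, n_frames: int = 1) -> "mda.Universe":
    long_names = {r for r in set(atoms.df["residue_name"]) if len(str(r)) > 4}
    if long_names:
        logger.warning(
            "residue names %s exceed the 4-character PDB column and will be "
            "truncated on write", sorted(long_names),
        )
    res = atoms.residue_index
    n_res = atoms.n_residues
    # per-residue attributes from the first atom of each residue
    first = np.zeros(n_res, dtype=np.intp)
    first[res[::-1]] = np.arange(len(res))[::-1]
    seg_names, seg_codes = np.unique(atoms.df["segment"].to_numpy(), return_inverse=True)
    res_seg = np.zeros(n_res, dtype=np.intp)
    res_seg[res] = seg_codes
    u = mda.Universe.empty(
        atoms.n_atoms,
        n_residues=n_res,
        n_segments=len(seg_names),
        atom_resindex=res,
        residue_segindex=res_seg,
        trajectory=True,
    )
    u.add_TopologyAttr("names", atoms.names)
    u.add_TopologyAttr("elements", atoms.elements)
    u.add_TopologyAttr("resnames", atoms.df["residue_name"].to_numpy()[first])
    u.add_TopologyAttr("resids", atoms.df["residue_id"].to_numpy()[first])
    u.add_TopologyAttr("segids", [str(s) for s in seg_names])
    u.add_TopologyAttr("occupancies", np.ones(atoms.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(atoms.n_atoms))
    return u


def write_pdb(atoms: AtomTable, frame: Frame, path: str | Path) -> None:
    """Write a single frame as a fixed-width PDB (occupancy 1.00, B 0.00)."""
    u = _universe_from(atoms)
    u.atoms.positions = frame.coordinates
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB (.pdb) or CHARMM DCD (.dcd)."""
    path = Path(path)
    u = _universe_from(traj.atoms)
    suffix = path.suffix.lower()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if suffix == ".pdb":
            with mda.Writer(str(path), multiframe=True, n_atoms=traj.atoms.n_atoms) as w:
                for fr in traj.frames:
                    u.atoms.positions = fr.coordinates
                    w.write(u.atoms)
        elif suffix == ".dcd":
            with mda.Writer(str(path), n_atoms=traj.atoms.n_atoms) as w:
                for fr in traj.frames:
                    u.atoms.positions = fr.coordinates
                    w.write(u.atoms)
        else:
            raise ValueError(f"unsupported trajectory format {suffix!r}")


# ---------------------------------------------------------------------------
# Selection / run configuration files
# ---------------------------------------------------------------------------


def selection_config_from_dict(d: dict) -> SelectionConfig:
    """Build a :class:`SelectionConfig` from a plain mapping (YAML layout)."""
    species = {}
    for name, entry in (d.get("species") or {}).items():
        species[name] = SpeciesEntry(
            role=entry.get("role", "lipid"),
            reference_atom=entry.get("reference_atom", "C2"),
            tail_atoms=tuple(entry.get("tail_atoms", ())),
            motifs={k: tuple(v) for k, v in (entry.get("motifs") or {}).items()},
        )
    return SelectionConfig(species=species)


def load_selection_config(path: str | Path) -> SelectionConfig:
    with open(path) as fh:
        return selection_config_from_dict(yaml.safe_load(fh) or {})
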