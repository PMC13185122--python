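"""Leaflet assignment, bilayer surface extraction, edge distances, regional
composition and lipid flip-flop counting.

A lipid belongs to the upper (lower) leaflet when its C2 reference atom lies
above (below) the plane bisecting the C2 center of mass. The bilayer footprint
is extracted as a Gaussian-smeared density on a voxel grid; collapsing a slab
of that mask along the normal yields a 2D inside/outside pixel map from which
each lipid's in-plane distance to the bilayer edge follows. Regions are the
four combinations of leaflet and edge proximity. A flip is a leaflet-label
change that persists for at least the debounce window (or to trajectory end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import AtomTable, Frame, SelectionConfig, Trajectory

REGIONS = ("upper-edge", "upper-interior", "lower-edge", "lower-interior")


@dataclass
class GridParams:
    voxel_edge: float = 6.0  # A ("resolution of 6" read as voxel edge length)
    density_isovalue: float = 0.01
    slab_thickness_projection: float = 20.0  # A, slab collapsed to the 2D pixel map
    slab_thickness_edge_count: float = 10.0  # A, slab for edge headgroup counts
    padding_voxels: int = 2

    def __post_init__(self):
        if self.voxel_edge <= 0 or self.density_isovalue <= 0:
            raise ValueError("voxel_edge and density_isovalue must be positive")


def assign_leaflets(
    frame: Frame, atoms: AtomTable, sel: SelectionConfig,
    include_detergent: bool = True,
) -> pd.DataFrame:
    """Label each lipid upper/lower by the sign of its C2 z minus the C2 midplane.

    The midplane is the center of mass of the *lipid* C2 atoms (detergent
    excluded), recomputed for every frame. Returns a DataFrame with columns
    lipid_id, species, z, leaflet.
    """
    lip_idx, lip_res = sel.reference_indices(atoms, roles=("lipid",))
    if len(lip_idx) == 0:
        raise ValueError("no lipid reference atoms found")
    z_mid = frame.coordinates[lip_idx, 2].mean()
    roles = ("lipid", "detergent") if include_detergent else ("lipid",)
    idx, res = sel.reference_indices(atoms, roles=roles)
    z = frame.coordinates[idx, 2]
    species = atoms.residue_species()[res]
    return pd.DataFrame(
        {
            "lipid_id": np.arange(len(idx)),
            "residue": res,
            "species": species,
            "z": z,
            "leaflet": np.where(z - z_mid >= 0, "upper", "lower"),
        }
    )


def extract_surface_mask(
    frame: Frame, atoms: AtomTable, sel: SelectionConfig,
    params: GridParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean inside-bilayer voxel mask from Gaussian-smeared lipid density.

    Lipid atoms (detergent and polymer excluded) each deposit a unit-amplitude
    Gaussian of width equal to their vdW radius; a voxel is inside when the
    summed density at its center reaches the isovalue. Returns ``(mask,
    origin)`` where ``origin`` is the center of voxel ``[0, 0, 0]`` and the
    grid covers the atom bounding box padded by ``padding_voxels``.
    """
    params = params or GridParams()
    lipid_species = sel.species_with_role("lipid")
    idx = atoms.select(species=lipid_species)
    if len(idx) == 0:
        raise ValueError("empty lipid selection")
    coords = frame.coordinates[idx]
    radii = atoms.radii[idx]
    h = params.voxel_edge
    pad = params.padding_voxels * h
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / h).astype(int), 1)
    origin = lo + h / 2.0
    density = np.zeros(shape, dtype=float)
    # deposit each atom's kernel on voxels within 3 sigma
    for (x, y, z), sigma in zip(coords, radii):
        reach = 3.0 * sigma
        i0 = np.maximum(np.floor((np.array([x, y, z]) - reach - origin) / h), 0).astype(int)
        i1 = np.minimum(
            np.ceil((np.array([x, y, z]) + reach - origin) / h), shape - 1
        ).astype(int)
        gx = origin[0] + h * np.arange(i0[0], i1[0] + 1)
        gy = origin[1] + h * np.arange(i0[1], i1[1] + 1)
        gz = origin[2] + h * np.arange(i0[2], i1[2] + 1)
        ex = np.exp(-((gx - x) ** 2) / (2 * sigma**2))
        ey = np.exp(-((gy - y) ** 2) / (2 * sigma**2))
        ez = np.exp(-((gz - z) ** 2) / (2 * sigma**2))
        density[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1] += \
            ex[:, None, None] * ey[None, :, None] * ez[None, None, :]
    return density >= params.density_isovalue, origin


def edge_distance(
    frame: Frame,
    atoms: AtomTable,
    sel: SelectionConfig,
    mask: np.ndarray | None = None,
    origin: np.ndarray | None = None,
    params: GridParams | None = None,
    include_detergent: bool = True,
) -> pd.DataFrame:
    """In-plane distance of each lipid's C2 atom to the nearest outside pixel.

    The voxel mask is averaged along z over the projection slab (|z| within
    half the slab thickness of the bilayer midplane); a pixel is outside when
    its inside-average is below 0.5. Distances are from the C2 xy position to
    outside pixel centers (deterministic; scipy's k-d tree breaks exact ties by
    index order). Raises if no outside pixel exists (grid padding too small).
    """
    params = params or GridParams()
    if mask is None or origin is None:
        mask, origin = extract_surface_mask(frame, atoms, sel, params)
    lip_idx, _ = sel.reference_indices(atoms, roles=("lipid",))
    z_mid = frame.coordinates[lip_idx, 2].mean()
    h = params.voxel_edge
    zs = origin[2] + h * np.arange(mask.shape[2])
    in_slab = np.abs(zs - z_mid) <= params.slab_thickness_projection / 2.0
    if not in_slab.any():
        raise ValueError("projection slab contains no voxel layer")
    pixel_inside_frac = mask[:, :, in_slab].mean(axis=2)
    outside = pixel_inside_frac < 0.5
    if not outside.any():
        raise ValueError("no outside pixel; increase grid padding")
    ii, jj = np.nonzero(outside)
    centers = np.column_stack([origin[0] + h * ii, origin[1] + h * jj])
    tree = cKDTree(centers)
    table = assign_leaflets(frame, atoms, sel, include_detergent=include_detergent)
    roles = ("lipid", "detergent") if include_detergent else ("lipid",)
    idx, _ = sel.reference_indices(atoms, roles=roles)
    d, _ = tree.query(frame.coordinates[idx, :2])
    table = table.copy()
    table["edge_distance"] = d
    return table


def region_assignment(
    frame: Frame, atoms: AtomTable, sel: SelectionConfig,
    edge_threshold: float = 10.0, params: GridParams | None = None,
    include_detergent: bool = True,
) -> pd.DataFrame:
    """Leaflet + edge-distance table with the four-region label attached."""
    table = edge_distance(frame, atoms, sel, params=params,
                          include_detergent=include_detergent)
    near = table["edge_distance"] < edge_threshold
    table["region"] = np.where(
        table["leaflet"] == "upper",
        np.where(near, "upper-edge", "upper-interior"),
        np.where(near, "lower-edge", "lower-interior"),
    )
    return table


def region_composition(
    traj: Trajectory,
    species: str,
    sel: SelectionConfig,
    edge_threshold: float = 10.0,
    params: GridParams | None = None,
) -> pd.DataFrame:
    """Fraction of a species among lipids in each of the four regions, per frame.

    The denominator counts all lipid C2 atoms in the region with detergent
    excluded; the ``system`` column is the frame-global species fraction (the
    reference level an unmixed patch converges to). Empty regions yield NaN.
    """
    rows = []
    for fr in traj.frames:
        table = region_assignment(fr, traj.atoms, sel, edge_threshold, params,
                                  include_detergent=False)
        is_sp = (table["species"] == species).to_numpy()
        row = {"time_ns": fr.time, "system": float(is_sp.mean())}
        for region in REGIONS:
            in_r = (table["region"] == region).to_numpy()
            row[region] = float(is_sp[in_r].mean()) if in_r.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["time_ns", *REGIONS, "system"])


# ---------------------------------------------------------------------------
# Flip counting
# ---------------------------------------------------------------------------


@dataclass
class FlipCounts:
    """Per-species directional flip tallies plus the underlying event list."""

    events: pd.DataFrame  # lipid_id, species, frame, time_ns, direction

    def per_species(self) -> pd.DataFrame:
        if self.events.empty:
            return pd.DataFrame(columns=["species", "lower_to_upper", "upper_to_lower"])
        tab = (
            self.events.groupby(["species", "direction"]).size().unstack(fill_value=0)
        )
        for col in ("lower_to_upper", "upper_to_lower"):
            if col not in tab:
                tab[col] = 0
        return tab[["lower_to_upper", "upper_to_lower"]].reset_index()


def count_flips(
    traj: Trajectory,
    sel: SelectionConfig,
    persistence: float = 15.0,
    include_detergent: bool = False,
) -> FlipCounts:
    """Debounced leaflet-flip events over a trajectory.

    A flip is recorded at the first frame of a leaflet-label change whose new
    label then persists for at least ``persistence`` ns or to the trajectory
    end; shorter midplane excursions are ignored. Each lipid's accepted label
    starts from its first frame.
    """
    times = traj.times
    labels = []
    for fr in traj.frames:
        t = assign_leaflets(fr, traj.atoms, sel, include_detergent=include_detergent)
        labels.append((t["leaflet"] == "upper").to_numpy())
    lab = np.asarray(labels)  # (n_frames, n_lipids) True = upper
    t0_table = assign_leaflets(traj.frames[0], traj.atoms, sel,
                               include_detergent=include_detergent)
    species = t0_table["species"].to_numpy()
    n_frames, n_lip = lab.shape
    rows = []
    for lip in range(n_lip):
        seq = lab[:, lip]
        # run-length encode
        change = np.flatnonzero(seq[1:] != seq[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [n_frames]])
        accepted = seq[0]
        for s, e in zip(starts[1:], ends[1:]):
            run_label = seq[s]
            if run_label == accepted:
                continue
            persists = (e == n_frames) or (times[e - 1] - times[s] >= persistence)
            if persists:
                direction = "lower_to_upper" if run_label else "upper_to_lower"
                rows.append((lip, species[lip], int(s), float(times[s]), direction))
                accepted = run_label
    events = pd.DataFrame(
        rows, columns=["lipid_id", "species", "frame", "time_ns", "direction"]
    )
    return FlipCounts(events=events)
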