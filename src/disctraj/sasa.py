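"""Solvent-accessible surface area and the occluded-fraction statistic.

SASA uses Shrake-Rupley point sampling on a Fibonacci sphere lattice with a
k-d tree for neighbor lookup. The occlusion statistic compares the lipid-tail
area computed with the occluders (rim polymers, detergent) removed — i.e.
treated as part of the solvent — against the area with them present; the
difference, normalised by the occluder-free area, is the occluded fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import AtomTable, Frame, SelectionConfig, Trajectory


@dataclass
class OcclusionParams:
    probe_radius: float = 2.0  # A
    n_sphere_points: int = 960
    exclude_hydrogen: bool = True

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 92:
            raise ValueError("n_sphere_points must be >= 92")


@dataclass
class OcclusionResult:
    """Per-frame tail areas (A^2) with and without occluders, and their ratio."""

    area_free: float
    area_in_context: float

    @property
    def occluded_area(self) -> float:
        return self.area_free - self.area_in_context

    @property
    def occluded_fraction(self) -> float:
        if self.area_free == 0:
            return 0.0
        return self.occluded_area / self.area_free


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (golden-angle lattice)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(
    frame: Frame,
    atoms: AtomTable,
    target: np.ndarray,
    context: np.ndarray,
    params: OcclusionParams | None = None,
) -> float:
    """Shrake-Rupley SASA (A^2) of ``target`` atoms amid ``context`` atoms.

    For each target atom, test points on the sphere of radius
    ``r_i + probe`` are kept when outside every other context atom's inflated
    sphere; the accessible fraction scales the sphere area
    ``4 pi (r_i + probe)^2``. ``target`` must be a subset of ``context``.
    """
    params = params or OcclusionParams()
    target = np.asarray(target, dtype=np.intp)
    context = np.asarray(context, dtype=np.intp)
    if len(target) == 0:
        raise ValueError("empty target selection")
    if not np.isin(target, context).all():
        raise ValueError("target must be a subset of context")
    radii = atoms.radii
    if np.any(radii[context] <= 0):
        raise ValueError("context atoms must have positive vdW radii")
    coords = frame.coordinates
    unit = fibonacci_sphere(params.n_sphere_points)
    ctx_coords = coords[context]
    ctx_radii = radii[context] + params.probe_radius
    r_max = ctx_radii.max()
    tree = cKDTree(ctx_coords)
    # map context row -> original index to exclude self
    area = 0.0
    for i in target:
        R = radii[i] + params.probe_radius
        center = coords[i]
        nbr_rows = tree.query_ball_point(center, R + r_max)
        nbr_rows = [j for j in nbr_rows if context[j] != i]
        pts = center + R * unit
        if nbr_rows:
            nc = ctx_coords[nbr_rows]
            nr = ctx_radii[nbr_rows]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 <= nr[None, :] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        area += frac * 4.0 * np.pi * R * R
    return float(area)


def resolve_occlusion_selections(
    atoms: AtomTable, sel: SelectionConfig, params: OcclusionParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (tail target, lipid-only context, lipid+occluder context) indices.

    Targets are the tail atoms of lipid-role species; occluders are all atoms
    of polymer- and detergent-role species (PEG and DTAB in the reference
    system). Hydrogens are excluded when configured (default).
    """
    params = params or OcclusionParams()
    xh = params.exclude_hydrogen
    lipid_species = sel.species_with_role("lipid")
    if not lipid_species:
        raise ValueError("no lipid species in selection config")
    target = sel.motif_indices(atoms, "lipid", "tail", exclude_hydrogen=xh)
    lipid_ctx = atoms.select(species=lipid_species, exclude_hydrogen=xh)
    occ_species = sel.species_with_role("polymer", "detergent")
    occ = (atoms.select(species=occ_species, exclude_hydrogen=xh)
           if occ_species else np.array([], dtype=np.intp))
    full_ctx = np.sort(np.concatenate([lipid_ctx, occ]))
    return target, lipid_ctx, full_ctx


def occluded_fraction(
    frame: Frame,
    atoms: AtomTable,
    sel: SelectionConfig,
    params: OcclusionParams | None = None,
) -> OcclusionResult:
    """Occluded fraction of lipid-tail SASA for one frame.

    ``area_free`` treats occluders as solvent (context = lipid atoms only);
    ``area_in_context`` includes them. With no occluder atoms present the two
    contexts coincide and the fraction is exactly 0.
    """
    params = params or OcclusionParams()
    target, lipid_ctx, full_ctx = resolve_occlusion_selections(atoms, sel, params)
    if len(target) == 0:
        raise ValueError("empty lipid-tail target selection")
    area_free = sasa(frame, atoms, target, lipid_ctx, params)
    if len(full_ctx) == len(lipid_ctx):
        return OcclusionResult(area_free, area_free)
    area_ctx = sasa(frame, atoms, target, full_ctx, params)
    return OcclusionResult(area_free, area_ctx)


def occlusion_series(
    traj: Trajectory,
    sel: SelectionConfig,
    params: OcclusionParams | None = None,
) -> pd.DataFrame:
    """Per-frame occlusion table: time_ns, area_free, area_in_context, fraction."""
    rows = []
    for fr in traj.frames:
        res = occluded_fraction(fr, traj.atoms, sel, params)
        rows.append((fr.time, res.area_free, res.area_in_context,
                     res.occluded_area, res.occluded_fraction))
    return pd.DataFrame(
        rows,
        columns=["time_ns", "area_free", "area_in_context",
                 "occluded_area", "occluded_fraction"],
    )
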