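"""Seeded synthetic bilayer-patch trajectories.

Generates a circular two-leaflet membrane patch of coarse pseudo-atom lipids
(a vertical stack per lipid: choline N, phosphate P, glycerol C2 reference,
ester O, and tail carbons) with per-species 2D Brownian lateral motion
reflecting at the patch rim, scripted leaflet flips, optional global
spherical-cap curvature, optional rigid tilt, and amphiphilic polymer chains
hugging the rim. The default patch emulates a 79 A radius disc of
90% DMPC / 9% DMTAP / 1% DMPE — 564 lipids at 69.5 A^2 per lipid — which is
the geometry all desk-scale analyses in this package are validated against.

Everything is deterministic given the PatchSpec/DynamicsSpec seed fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import DEFAULT_VDW_RADII, AtomTable, Frame, SelectionConfig, SpeciesEntry, Trajectory

# per-lipid pseudo-atom template: (name, element, offset along the outward
# leaflet direction relative to the C2 plane, A)
_HEAD_TEMPLATE = [("NC", "N", 4.0), ("P", "P", 2.5), ("C2", "C", 0.0), ("O2", "O", -1.5)]
_TAIL_SPACING = 3.0  # A between successive tail pseudo-carbons


def lipid_template(n_tail_atoms: int = 5) -> list[tuple[str, str, float]]:
    """Pseudo-atom stack of one lipid: head motifs plus ``n_tail_atoms`` tail carbons."""
    tails = [(f"T{k + 1}", "C", -_TAIL_SPACING * (k + 1) - 1.5)
             for k in range(n_tail_atoms)]
    return _HEAD_TEMPLATE + tails


def default_selection_config(n_tail_atoms: int = 5) -> SelectionConfig:
    """Selection config matching the synthetic generator's atom naming."""
    tails = tuple(f"T{k + 1}" for k in range(n_tail_atoms))
    head_motifs = {
        "choline": ("NC",),
        "phosphate": ("P",),
        "glycerol": ("C2",),
        "ester": ("O2",),
    }
    lipid = dict(role="lipid", reference_atom="C2", tail_atoms=tails,
                 motifs=dict(head_motifs))
    species = {
        "DMPC": SpeciesEntry(**lipid),
        "DMTAP": SpeciesEntry(**{**lipid, "motifs": dict(head_motifs)}),
        "DMPE": SpeciesEntry(**{**lipid, "motifs": dict(head_motifs)}),
        "DTAB": SpeciesEntry(
            role="detergent", reference_atom="C2", tail_atoms=tails,
            motifs={"choline": ("NC",), "glycerol": ("C2",)},
        ),
        "PEG": SpeciesEntry(
            role="polymer", reference_atom="LK",
            motifs={"methylene": ("CM",), "oxygen": ("OE",), "linker": ("LK",)},
        ),
    }
    return SelectionConfig(species=species)


@dataclass
class PatchSpec:
    """Static geometry of the circular bilayer patch."""

    radius: float = 79.0  # A
    area_per_lipid: float = 69.5  # A^2; 79 A disc -> 282 lipids per leaflet
    species_fractions: dict[str, float] = field(
        default_factory=lambda: {"DMPC": 0.90, "DMTAP": 0.09, "DMPE": 0.01}
    )
    leaflet_separation: float = 34.0  # A, C2 plane to C2 plane
    n_tail_atoms: int = 5
    lattice_jitter: float = 1.0  # A, in-plane jitter of lattice sites
    seed: int = 0

    def __post_init__(self):
        if self.radius <= 0 or self.area_per_lipid <= 0:
            raise ValueError("radius and area_per_lipid must be positive")
        total = sum(self.species_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species fractions sum to {total}, expected 1")

    @property
    def lipids_per_leaflet(self) -> int:
        return int(round(np.pi * self.radius**2 / self.area_per_lipid))


@dataclass
class DynamicsSpec:
    """Dynamics applied on top of a static patch."""

    D_per_species: dict[str, float] = field(default_factory=dict)  # A^2/ns
    frame_interval: float = 0.5  # ns
    n_frames: int = 100
    flip_schedule: tuple[tuple[int, int], ...] = ()  # (lipid_id, frame)
    curvature: float = 0.0  # 1/A, signed; positive bulges toward +z
    tilt_schedule: tuple[tuple[int, float, float], ...] = ()  # (frame, tilt deg, azimuth deg)
    z_sigma: float = 0.0  # A, per-lipid per-frame normal z jitter
    radius: float | None = None  # reflection radius; inferred from frame if None
    seed: int = 0

    def __post_init__(self):
        for sp, D in self.D_per_species.items():
            if D < 0:
                raise ValueError(f"negative diffusion coefficient for {sp}")
        if self.frame_interval <= 0 or self.n_frames < 1:
            raise ValueError("frame_interval must be > 0 and n_frames >= 1")
        for _, f in self.flip_schedule:
            if not (0 <= f < self.n_frames):
                raise ValueError("flip frame outside trajectory")
        if self.radius is not None and abs(self.curvature) * self.radius >= 1:
            raise ValueError("|curvature| * radius must be < 1")


def _triangular_disc_sites(n: int, area_per_site: float, rng: np.random.Generator,
                           jitter: float, phase: float = 0.0) -> np.ndarray:
    """``n`` jittered triangular-lattice sites filling a disc, closest-in first."""
    a = np.sqrt(2.0 * area_per_site / np.sqrt(3.0))  # lattice constant
    m = int(np.ceil(np.sqrt(n / np.pi) * 2.5)) + 3
    i, j = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
    x = a * (i + 0.5 * (j % 2)) + phase * a
    y = a * (np.sqrt(3.0) / 2.0) * j
    pts = np.column_stack([x.ravel(), y.ravel()])
    order = np.argsort(np.einsum("ij,ij->i", pts, pts), kind="stable")
    pts = pts[order[:n]]
    return pts + rng.normal(0.0, jitter, pts.shape)


def build_patch(spec: PatchSpec) -> tuple[AtomTable, Frame]:
    """Place lipids of a two-leaflet circular patch on jittered triangular lattices.

    Per leaflet ``round(pi r^2 / APL)`` lipids; species drawn per lipid from
    the configured fractions with the PatchSpec seed. Upper-leaflet C2 atoms sit at
    ``+leaflet_separation/2``, lower at the mirror plane.
    """
    n_leaf = spec.lipids_per_leaflet
    if n_leaf < 1:
        raise ValueError("area_per_lipid too large: fewer than one lipid per leaflet")
    rng = np.random.default_rng(spec.seed)
    template = lipid_template(spec.n_tail_atoms)
    species_names = list(spec.species_fractions)
    probs = np.array([spec.species_fractions[s] for s in species_names])

    rows = []
    coords = []
    resid = 0
    for leaflet_sign, phase in ((+1, 0.0), (-1, 0.5)):
        xy = _triangular_disc_sites(n_leaf, spec.area_per_lipid, rng,
                                    spec.lattice_jitter, phase)
        picks = rng.choice(len(species_names), size=n_leaf, p=probs)
        for k in range(n_leaf):
            resid += 1
            sp = species_names[picks[k]]
            for name, element, dz in template:
                rows.append((name, element, sp, resid, "MEMB",
                             DEFAULT_VDW_RADII[element]))
                z = leaflet_sign * (spec.leaflet_separation / 2.0 + dz)
                coords.append((xy[k, 0], xy[k, 1], z))
    df = pd.DataFrame(rows, columns=["atom_name", "element", "residue_name",
                                     "residue_id", "segment", "vdw_radius"])
    df.insert(0, "atom_id", np.arange(len(df)))
    return AtomTable(df), Frame(np.asarray(coords, dtype=float), time=0.0)


def add_edge_polymers(
    atoms: AtomTable, frame: Frame, n_chains: int, n_monomers: int, seed: int = 0,
    rim_offset: float = 2.0, monomer_spacing: float = 1.5,
) -> tuple[AtomTable, Frame]:
    """Append polymer chains hugging the patch rim between the leaflet planes.

    Chains are arcs of ``n_monomers`` pseudo-atoms on the rim cylinder
    (patch radius + ``rim_offset``) with small seeded radial/vertical jitter;
    atom 0 of each chain is a linker (LK), the rest alternate methylene (CM)
    and ether oxygen (OE). With ``n_chains = 0`` the input is returned unchanged.
    """
    if n_chains == 0:
        return atoms, frame
    rng = np.random.default_rng(seed)
    c2 = atoms.select(names="C2")
    if len(c2) == 0:
        raise ValueError("patch has no C2 reference atoms")
    rho_c2 = np.linalg.norm(frame.coordinates[c2, :2], axis=1)
    radius = float(rho_c2.max())
    half_sep = float(np.abs(frame.coordinates[c2, 2]).mean())
    a_rim = radius + rim_offset

    rows = []
    coords = []
    next_resid = int(atoms.df["residue_id"].max()) + 1
    for c in range(n_chains):
        phi0 = 2.0 * np.pi * c / n_chains
        phase = rng.uniform(0.0, 2.0 * np.pi)
        for m in range(n_monomers):
            phi = phi0 + m * monomer_spacing / a_rim
            rho = a_rim + np.clip(rng.normal(0.0, 0.8), -2.0, 2.0)
            z = 0.7 * half_sep * np.sin(2.0 * np.pi * m / 8.0 + phase) \
                + rng.normal(0.0, 0.5)
            z = float(np.clip(z, -half_sep, half_sep))
            if m == 0:
                name, element = "LK", "C"
            elif m % 2 == 1:
                name, element = "CM", "C"
            else:
                name, element = "OE", "O"
            rows.append((name, element, "PEG", next_resid + c, "PEG",
                         DEFAULT_VDW_RADII[element]))
            coords.append((rho * np.cos(phi), rho * np.sin(phi), z))
    df_new = pd.DataFrame(rows, columns=["atom_name", "element", "residue_name",
                                         "residue_id", "segment", "vdw_radius"])
    df = pd.concat([atoms.df.drop(columns="atom_id"),
                    df_new], ignore_index=True)
    df.insert(0, "atom_id", np.arange(len(df)))
    all_coords = np.vstack([frame.coordinates, np.asarray(coords, dtype=float)])
    return AtomTable(df), Frame(all_coords, frame.time)


def _sag(c: float, rho: np.ndarray) -> np.ndarray:
    """Spherical-cap height c*rho^2 / (1 + sqrt(1 - c^2 rho^2)); 0 when c = 0."""
    if c == 0.0:
        return np.zeros_like(rho)
    arg = np.clip(1.0 - (c * rho) ** 2, 0.0, None)
    return c * rho**2 / (1.0 + np.sqrt(arg))


def _tilt_rotation(frame_idx: int, schedule, n_frames: int) -> Rotation | None:
    if not schedule:
        return None
    ks = np.array([s[0] for s in schedule], dtype=float)
    tilts = np.array([s[1] for s in schedule], dtype=float)
    azis = np.array([s[2] for s in schedule], dtype=float)
    tilt = float(np.interp(frame_idx, ks, tilts))
    azi = float(np.interp(frame_idx, ks, azis))
    if tilt == 0.0:
        return None
    axis = np.array([np.cos(np.deg2rad(azi)), np.sin(np.deg2rad(azi)), 0.0])
    return Rotation.from_rotvec(np.deg2rad(tilt) * axis)


def simulate_dynamics(
    atoms: AtomTable,
    frame0: Frame,
    dyn: DynamicsSpec,
    sel: SelectionConfig | None = None,
) -> Trajectory:
    """Propagate a patch: 2D Brownian lipid motion, scripted flips, curvature, tilt.

    Frame 0 reproduces ``frame0``'s lateral placement; subsequent frames add
    per-axis Gaussian steps of variance ``2 D dt`` (species-wise D, reflecting
    at the patch radius). A scheduled flip teleports the whole lipid stack to
    the mirror leaflet at its frame. Curvature displaces each lipid vertically
    by the spherical-cap sag at its lateral radius; a tilt schedule applies a
    rigid rotation about an in-plane axis (linearly interpolated between
    scheduled knots). Non-lipid atoms (e.g. rim polymers) stay at their input
    positions apart from the rigid tilt.
    """
    sel = sel if sel is not None else default_selection_config()
    rng = np.random.default_rng(dyn.seed)
    mobile_roles = ("lipid", "detergent")
    ref_idx, ref_res = sel.reference_indices(atoms, roles=mobile_roles)
    if len(ref_idx) == 0:
        raise ValueError("no mobile lipids found")
    res_of_atom = atoms.residue_index
    mobile_res = np.zeros(atoms.n_residues, dtype=bool)
    mobile_res[ref_res] = True
    mobile_atoms = mobile_res[res_of_atom]
    # map residue ordinal -> row in the per-lipid arrays
    lip_row = -np.ones(atoms.n_residues, dtype=np.intp)
    lip_row[ref_res] = np.arange(len(ref_res))

    c2_xyz = frame0.coordinates[ref_idx]
    half_sep = float(np.abs(c2_xyz[:, 2]).mean())
    signs = np.where(c2_xyz[:, 2] >= 0, 1.0, -1.0)
    xy = c2_xyz[:, :2].copy()
    radius = dyn.radius if dyn.radius is not None else float(
        np.linalg.norm(xy, axis=1).max()
    )
    if abs(dyn.curvature) * radius >= 1:
        raise ValueError("|curvature| * radius must be < 1")

    # per-atom geometry relative to the owning lipid's C2
    arow = lip_row[res_of_atom[mobile_atoms]]
    axy_off = frame0.coordinates[mobile_atoms, :2] - xy[arow]
    a_dz = signs[arow] * frame0.coordinates[mobile_atoms, 2] - half_sep

    species = atoms.residue_species()[ref_res]
    D = np.array([dyn.D_per_species.get(sp, 0.0) for sp in species])
    step_sigma = np.sqrt(2.0 * D * dyn.frame_interval)

    flips_at: dict[int, list[int]] = {}
    for lipid_id, f in dyn.flip_schedule:
        if lipid_id < 0 or lipid_id >= len(ref_res):
            raise ValueError(f"flip lipid_id {lipid_id} out of range")
        flips_at.setdefault(int(f), []).append(int(lipid_id))

    static_coords = frame0.coordinates[~mobile_atoms]
    frames: list[Frame] = []
    for k in range(dyn.n_frames):
        if k > 0:
            moving = step_sigma > 0
            if moving.any():
                xy[moving] += rng.normal(
                    0.0, step_sigma[moving, None], (int(moving.sum()), 2)
                )
                rho = np.linalg.norm(xy, axis=1)
                out = rho > radius
                while out.any():
                    xy[out] *= ((2.0 * radius - rho[out]) / rho[out])[:, None]
                    rho = np.linalg.norm(xy, axis=1)
                    out = rho > radius
        for lipid_id in flips_at.get(k, ()):
            signs[lipid_id] *= -1.0
        z_noise = rng.normal(0.0, dyn.z_sigma, len(ref_res)) if dyn.z_sigma > 0 \
            else np.zeros(len(ref_res))
        rho_lip = np.linalg.norm(xy, axis=1)
        z_lip = signs * half_sep + _sag(dyn.curvature, rho_lip) + z_noise

        coords = np.empty((atoms.n_atoms, 3))
        coords[~mobile_atoms] = static_coords
        coords[mobile_atoms, 0] = xy[arow, 0] + axy_off[:, 0]
        coords[mobile_atoms, 1] = xy[arow, 1] + axy_off[:, 1]
        coords[mobile_atoms, 2] = z_lip[arow] + signs[arow] * a_dz
        rot = _tilt_rotation(k, dyn.tilt_schedule, dyn.n_frames)
        if rot is not None:
            coords = rot.apply(coords)
        frames.append(Frame(coords, k * dyn.frame_interval))
    return Trajectory(atoms, frames)


def generate(
    patch: PatchSpec,
    dyn: DynamicsSpec,
    n_chains: int = 0,
    n_monomers: int = 0,
    sel: SelectionConfig | None = None,
) -> Trajectory:
    """Convenience: build a patch, optionally add rim polymers, run the dynamics."""
    atoms, frame0 = build_patch(patch)
    if n_chains:
        atoms, frame0 = add_edge_polymers(atoms, frame0, n_chains, n_monomers,
                                          seed=patch.seed + 1)
    return simulate_dynamics(atoms, frame0, dyn, sel=sel)
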