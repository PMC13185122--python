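"""Thickness, area per lipid, curvature and edge headgroup counts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from disctraj.core import Frame, Trajectory
from disctraj.core import preprocess_align
from disctraj.geometry import (
    GeometryParams,
    area_per_lipid,
    density_profile,
    edge_headgroup_count,
    fit_curvature,
    thickness,
)
from disctraj.synthetic import DynamicsSpec, PatchSpec, build_patch, simulate_dynamics

PARAMS30 = GeometryParams(core_radius=30.0)


def _sag(c, rho):
    return c * rho**2 / (1.0 + np.sqrt(1.0 - (c * rho) ** 2))


class TestDensityProfile:
    def test_coplanar_atoms_single_bin(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        coords = frame0.coordinates.copy()
        idx, _ = sel.reference_indices(atoms)
        coords[idx, 2] = 0.123
        centers, dens = density_profile(Frame(coords), atoms, sel, PARAMS30)
        assert (dens > 0).sum() == 1

    def test_two_planes_symmetric_peaks(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        centers, dens = density_profile(frame0, atoms, sel, PARAMS30)
        occupied = centers[dens > 0]
        assert (occupied > 0).any() and (occupied < 0).any()
        assert np.isclose(occupied.max(), -occupied.min(), atol=0.5)

    def test_gaussian_sampling_recovered_within_poisson(self, sel):
        atoms, frame0 = build_patch(PatchSpec(radius=60.0, seed=14))
        dyn = DynamicsSpec(D_per_species={}, n_frames=1, z_sigma=2.0, seed=15)
        fr = simulate_dynamics(atoms, frame0, dyn).frames[0]
        params = GeometryParams(core_radius=70.0)
        centers, dens = density_profile(fr, atoms, sel, params)
        n_upper = dens[centers > 0].sum() * params.density_bin
        mu_upper = np.average(centers[centers > 0], weights=dens[centers > 0])
        n_leaf = atoms.n_residues // 2
        assert abs(n_upper - n_leaf) <= 3 * np.sqrt(n_leaf)
        assert abs(mu_upper - 17.0) < 3 * 2.0 / np.sqrt(n_leaf)


class TestThickness:
    def test_delta_planes_exact(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        prof = density_profile(frame0, atoms, sel, PARAMS30)
        assert thickness(prof) == pytest.approx(34.0, abs=0.5)

    def test_gaussian_leaflet_recovery(self, sel):
        atoms, frame0 = build_patch(PatchSpec(radius=105.2, seed=31))
        dyn = DynamicsSpec(D_per_species={}, n_frames=1, z_sigma=2.0, seed=32)
        fr = simulate_dynamics(atoms, frame0, dyn).frames[0]
        prof = density_profile(fr, atoms, sel, GeometryParams(core_radius=120.0))
        assert thickness(prof) == pytest.approx(34.0, abs=0.4)

    def test_invariant_after_alignment_of_shifted_frame(self, small_patch, sel):
        base = preprocess_align
        _, atoms, frame0 = small_patch
        aligned0 = base(Trajectory(atoms, [frame0]), sel).frames[0]
        shifted = Frame(frame0.coordinates + np.array([0.0, 0.0, 3.0]))
        aligned1 = base(Trajectory(atoms, [shifted]), sel).frames[0]
        t0 = thickness(density_profile(aligned0, atoms, sel, PARAMS30))
        t1 = thickness(density_profile(aligned1, atoms, sel, PARAMS30))
        assert t1 == pytest.approx(t0, abs=1e-6)

    def test_one_sided_profile_rejected(self):
        centers = np.arange(1.0, 10.0)
        with pytest.raises(ValueError, match="both sides"):
            thickness((centers, np.ones_like(centers)))


class TestAreaPerLipid:
    @pytest.mark.parametrize("apl", [50.0, 69.5, 80.0])
    def test_recovery_across_densities(self, sel, apl):
        """APL error stays within one lipid-equivalent (average of 3 seeds)."""
        errs = []
        n_expect = np.pi * 40.0**2 / apl
        for seed in (1, 2, 3):
            atoms, fr = build_patch(
                PatchSpec(radius=79.0, area_per_lipid=apl, seed=seed)
            )
            errs.append(area_per_lipid(fr, atoms, sel, GeometryParams()) - apl)
        one_lipid = apl / n_expect  # d(APL) per unit count
        assert abs(np.mean(errs)) <= one_lipid

    def test_halving_lipid_count_doubles_apl(self, small_patch, sel):
        import pandas as pd
        from disctraj.core import AtomTable

        _, atoms, frame0 = small_patch
        keep_res = np.unique(atoms.residue_index)[::2]
        keep = np.isin(atoms.residue_index, keep_res)
        thin_atoms = AtomTable(atoms.df[keep].reset_index(drop=True))
        thin_frame = Frame(frame0.coordinates[keep])
        full = area_per_lipid(frame0, atoms, sel, PARAMS30)
        half = area_per_lipid(thin_frame, thin_atoms, sel, PARAMS30)
        assert half == pytest.approx(2.0 * full, rel=0.15)

    def test_oversized_cylinder_flagged(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        with pytest.warns(UserWarning, match="lateral extent"):
            area_per_lipid(frame0, atoms, sel, GeometryParams(core_radius=60.0))


class TestCurvature:
    def test_exact_sphere_cap_recovered(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        coords = frame0.coordinates.copy()
        idx, _ = sel.reference_indices(atoms)
        rho = np.linalg.norm(coords[idx, :2], axis=1)
        coords[idx, 2] = np.sign(coords[idx, 2]) * 17.0 + _sag(0.01, rho)
        c = fit_curvature(Frame(coords), atoms, sel, PARAMS30)
        assert c == pytest.approx(0.01, abs=1e-4)

    def test_flat_patch_is_flat(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        assert abs(fit_curvature(frame0, atoms, sel, PARAMS30)) < 1e-5

    def test_mirror_symmetry(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        dyn = DynamicsSpec(D_per_species={}, n_frames=1, curvature=0.005,
                           z_sigma=1.0, seed=22)
        fr = simulate_dynamics(atoms, frame0, dyn).frames[0]
        mirror = Frame(fr.coordinates * np.array([1.0, 1.0, -1.0]))
        c = fit_curvature(fr, atoms, sel, PARAMS30)
        assert fit_curvature(mirror, atoms, sel, PARAMS30) == pytest.approx(-c)

    def test_inplane_rotation_invariance(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        dyn = DynamicsSpec(D_per_species={}, n_frames=1, curvature=0.004,
                           z_sigma=0.5, seed=23)
        fr = simulate_dynamics(atoms, frame0, dyn).frames[0]
        rot = Rotation.from_rotvec([0.0, 0.0, 1.1])
        rotated = Frame(rot.apply(fr.coordinates))
        c0 = fit_curvature(fr, atoms, sel, PARAMS30)
        c1 = fit_curvature(rotated, atoms, sel, PARAMS30)
        assert c1 == pytest.approx(c0, rel=1e-6)
        t0 = thickness(density_profile(fr, atoms, sel, PARAMS30))
        t1 = thickness(density_profile(rotated, atoms, sel, PARAMS30))
        assert t1 == pytest.approx(t0, abs=1e-9)


class TestEdgeHeadgroupCount:
    def test_ideal_patch_zero(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        assert edge_headgroup_count(frame0, atoms, sel) == 0

    def test_single_migrated_headgroup_counted(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        idx, _ = sel.reference_indices(atoms)
        coords = frame0.coordinates.copy()
        coords[idx[4], 2] = 0.0
        assert edge_headgroup_count(Frame(coords), atoms, sel) == 1

    def test_scripted_rim_migration_count(self, small_patch, sel):
        """Rim headgroups tilted into the midplane are counted exactly."""
        _, atoms, frame0 = small_patch
        idx, _ = sel.reference_indices(atoms)
        rho = np.linalg.norm(frame0.coordinates[idx, :2], axis=1)
        rim = np.argsort(rho)[-7:]
        coords = frame0.coordinates.copy()
        coords[idx[rim], 2] = np.linspace(-4.0, 4.0, 7)
        assert edge_headgroup_count(Frame(coords), atoms, sel) == 7
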