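"""Leaflet labels, surface mask, edge distances, regions and flip counting."""

import numpy as np
import pytest

from _oracles import debounced_flips_oracle
from disctraj.core import Frame, Trajectory
from disctraj.leaflet import (
    GridParams,
    assign_leaflets,
    count_flips,
    edge_distance,
    extract_surface_mask,
    region_assignment,
    region_composition,
)
from disctraj.synthetic import DynamicsSpec, PatchSpec, build_patch, simulate_dynamics


class TestAssignLeaflets:
    def test_symmetric_patch_splits_evenly(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        table = assign_leaflets(frame0, atoms, sel)
        counts = table["leaflet"].value_counts()
        assert counts["upper"] == counts["lower"]

    def test_single_outlier_goes_to_lower(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        idx, _ = sel.reference_indices(atoms)
        coords = frame0.coordinates.copy()
        coords[idx, 2] = 10.0
        coords[idx[5], 2] = -10.0
        table = assign_leaflets(Frame(coords), atoms, sel)
        assert (table["leaflet"] == "lower").sum() == 1
        assert table.loc[5, "leaflet"] == "lower"

    def test_scripted_flip_relabels_only_that_lipid(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        dyn = DynamicsSpec(D_per_species={}, n_frames=4, flip_schedule=((9, 2),))
        traj = simulate_dynamics(atoms, frame0, dyn)
        before = assign_leaflets(traj.frames[1], atoms, sel)["leaflet"]
        after = assign_leaflets(traj.frames[2], atoms, sel)["leaflet"]
        changed = np.flatnonzero((before != after).to_numpy())
        assert changed.tolist() == [9]


class TestSurfaceMask:
    def test_single_atom_blob_contains_atom_voxel(self, single_atom, sel):
        import pandas as pd
        from disctraj.core import AtomTable

        atoms, frame = single_atom
        df = atoms.df.copy()
        df["residue_name"] = "DMPC"
        mask, origin = extract_surface_mask(frame, AtomTable(df), sel,
                                            GridParams(voxel_edge=2.0))
        assert mask.any()
        vox = np.round((np.zeros(3) - origin) / 2.0).astype(int)
        assert mask[tuple(vox)]

    def test_disc_extent_matches_patch_radius(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        params = GridParams()
        mask, origin = extract_surface_mask(frame0, atoms, sel, params)
        ii, jj, _ = np.nonzero(mask)
        x = origin[0] + params.voxel_edge * ii
        y = origin[1] + params.voxel_edge * jj
        extent = np.hypot(x, y).max()
        assert 40.0 - params.voxel_edge <= extent <= 40.0 + params.voxel_edge

    def test_infinite_isovalue_empties_mask(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        mask, _ = extract_surface_mask(frame0, atoms, sel,
                                       GridParams(density_isovalue=1e12))
        assert not mask.any()


class TestEdgeDistance:
    def test_center_lipid_sees_patch_radius(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        params = GridParams()
        table = edge_distance(frame0, atoms, sel, params=params)
        c2, _ = sel.reference_indices(atoms)
        rho = np.linalg.norm(frame0.coordinates[c2, :2], axis=1)
        center = table.iloc[int(np.argmin(rho))]["edge_distance"]
        assert abs(center - 40.0) <= params.voxel_edge

    def test_rim_lipid_is_adjacent_to_outside(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        params = GridParams()
        table = edge_distance(frame0, atoms, sel, params=params)
        c2, _ = sel.reference_indices(atoms)
        rho = np.linalg.norm(frame0.coordinates[c2, :2], axis=1)
        rim = table.iloc[int(np.argmax(rho))]["edge_distance"]
        assert rim <= params.voxel_edge * np.sqrt(2.0)

    def test_padding_invariance(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        d2 = edge_distance(frame0, atoms, sel, params=GridParams(padding_voxels=2))
        d4 = edge_distance(frame0, atoms, sel, params=GridParams(padding_voxels=4))
        assert np.allclose(d2["edge_distance"], d4["edge_distance"])


class TestRegionComposition:
    def test_uniform_patch_matches_global_fraction(self, sel):
        atoms, frame0 = build_patch(PatchSpec(seed=51))
        traj = Trajectory(atoms, [frame0])
        comp = region_composition(traj, "DMTAP", sel)
        system = comp["system"].iloc[0]
        for region in ("upper-edge", "upper-interior", "lower-edge",
                       "lower-interior"):
            assert abs(comp[region].iloc[0] - system) < 0.1

    def test_absent_species_all_zero(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        comp = region_composition(Trajectory(atoms, [frame0]), "DTAB", sel)
        assert (comp.drop(columns="time_ns").iloc[0] == 0.0).all()

    def test_constructed_rim_enrichment(self, sel):
        """All charged lipids forced to the upper rim show up as upper-edge
        enrichment far above the system fraction, and vanish below."""
        atoms, frame0 = build_patch(
            PatchSpec(radius=40.0, species_fractions={"DMPC": 1.0}, seed=8)
        )
        c2, res = sel.reference_indices(atoms)
        rho = np.linalg.norm(frame0.coordinates[c2, :2], axis=1)
        upper = frame0.coordinates[c2, 2] > 0
        target_res = res[(rho > 30.0) & upper]
        names = atoms.df["residue_name"].to_numpy()
        names[np.isin(atoms.residue_index, target_res)] = "DMTAP"
        atoms.df["residue_name"] = names
        atoms2 = type(atoms)(atoms.df)
        comp = region_composition(Trajectory(atoms2, [frame0]), "DMTAP", sel,
                                  edge_threshold=10.0)
        row = comp.iloc[0]
        assert row["upper-edge"] > 2.0 * row["system"]
        assert row["lower-edge"] == 0.0 and row["lower-interior"] == 0.0

    def test_region_counts_partition_species(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        table = region_assignment(frame0, atoms, sel, include_detergent=False)
        total = (table["species"] == "DMTAP").sum()
        by_region = table[table["species"] == "DMTAP"].groupby("region").size()
        assert by_region.sum() == total


class TestCountFlips:
    def test_static_trajectory_has_no_flips(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        traj = simulate_dynamics(atoms, frame0,
                                 DynamicsSpec(D_per_species={}, n_frames=5))
        assert count_flips(traj, sel).events.empty

    def test_scripted_flip_recovered_exactly(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        dyn = DynamicsSpec(D_per_species={}, n_frames=40, frame_interval=1.0,
                           flip_schedule=((3, 7), (11, 20)))
        traj = simulate_dynamics(atoms, frame0, dyn)
        events = count_flips(traj, sel, persistence=15.0).events
        assert len(events) == 2
        assert events["lipid_id"].tolist() == [3, 11]
        assert events["frame"].tolist() == [7, 20]

    def test_brief_midplane_excursion_debounced(self, small_patch, sel):
        """A z-excursion shorter than the persistence window is not a flip."""
        _, atoms, frame0 = small_patch
        idx, _ = sel.reference_indices(atoms)
        res = atoms.residue_index
        frames = []
        for k in range(30):
            coords = frame0.coordinates.copy()
            if 10 <= k < 13:  # 3 ns blip, well under the 15 ns window
                coords[res == res[idx[2]]] *= np.array([1.0, 1.0, -1.0])
            frames.append(Frame(coords, time=float(k)))
        traj = Trajectory(atoms, frames)
        assert count_flips(traj, sel, persistence=15.0).events.empty

    def test_matches_debounce_oracle_on_noisy_labels(self, small_patch, sel):
        """Random label sequences: package events == brute-force oracle."""
        _, atoms, frame0 = small_patch
        idx, _ = sel.reference_indices(atoms)
        res = atoms.residue_index
        rng = np.random.default_rng(77)
        n_frames = 60
        lab = rng.random((n_frames, 6)) < 0.35  # True = flip target lipid down
        frames = []
        for k in range(n_frames):
            coords = frame0.coordinates.copy()
            for lip in range(6):
                if lab[k, lip]:
                    coords[res == res[idx[lip]]] *= np.array([1.0, 1.0, -1.0])
            frames.append(Frame(coords, time=float(k)))
        traj = Trajectory(atoms, frames)
        events = count_flips(traj, sel, persistence=10.0).events
        times = traj.times
        table0 = assign_leaflets(frames[0], atoms, sel)
        for lip in range(6):
            upper_seq = []
            for fr in frames:
                upper_seq.append(
                    assign_leaflets(fr, atoms, sel)["leaflet"].iloc[lip] == "upper"
                )
            expected = debounced_flips_oracle(np.array(upper_seq), times, 10.0)
            got = [
                (int(r["frame"]), r["direction"])
                for _, r in events[events["lipid_id"] == lip].iterrows()
            ]
            assert got == expected

    def test_per_species_tallies_match_events(self, small_patch, sel):
        _, atoms, frame0 = small_patch
        dyn = DynamicsSpec(D_per_species={}, n_frames=50, frame_interval=1.0,
                           flip_schedule=((1, 5), (2, 8), (1, 30)))
        traj = simulate_dynamics(atoms, frame0, dyn)
        fc = count_flips(traj, sel, persistence=15.0)
        tab = fc.per_species()
        assert int(tab["lower_to_upper"].sum() + tab["upper_to_lower"].sum()) == \
            len(fc.events)
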