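# disctraj

Analysis toolkit for molecular-dynamics trajectories of DNA-scaffolded lipid
nanodiscs (DLNs) — discoidal bilayer patches whose rim is stabilised by a
PEG-functionalised double-stranded DNA minicircle — and, more generally, for
finite bilayer patches.

It is written for simulators who have a topology (PDB) and a coordinate
trajectory (multi-model PDB or CHARMM DCD) of a membrane patch and want the
standard panel of nanodisc observables:

- **Surface occlusion** — Shrake–Rupley solvent-accessible surface area (SASA)
  of the lipid tails with a 2 Å probe, computed once with the occluders (PEG,
  detergent) treated as solvent and once with them present; the occluded
  fraction is `(A_free − A_context) / A_free`.
- **Contacts** — exact atom-pair counts within a 4 Å cutoff between lipid
  motifs (tails, choline, phosphate, glycerol, ester) and occluder motifs
  (PEG methylene/oxygen/linker), plus the fraction of possible pairs
  `⟨count⟩ / (N_A · N_B)`.
- **Leaflets, edges, flips** — upper/lower labels from the sign of each
  lipid's C2 glycerol carbon relative to the C2 midplane; a voxelised
  molecular surface collapsed to a 2D map gives each lipid its in-plane
  distance to the bilayer edge; species composition per (leaflet × edge)
  region; debounced flip-flop events.
- **Bilayer geometry** — thickness from per-leaflet Gaussian fits to the
  0.5 Å density profile, area per lipid in a 4 nm core cylinder, global
  curvature from per-leaflet sphere fits `z(ρ) = z₀ + cρ²/(1+√(1−c²ρ²))`,
  and the count of headgroups in the 1 nm midplane slab.
- **Lateral diffusion** — in-plane MSD of core-cylinder lipids at strides
  1–128 ns in powers of two; `D = slope/4` (2D Einstein relation) and the
  expected displacement `√(4Dt)`.
- **Tilt collective variable** — the least-RMSD rotation of (every fourth)
  C2 atom onto a reference frame, factored as `R = R_tilt · R_spin`
  (swing–twist about the bilayer normal); optional harmonic restraint energy
  `E = ½k(cos θ_tilt − target)²`.
- **Design arithmetic** — minicircle diameters from base-pair count
  (0.34 nm/bp rise), PEG modifications per 10.5-bp helical turn, and the
  lipid count filling the inner disc.

Because public nanodisc trajectories are scarce, the package ships a seeded
synthetic generator (`disctraj.synthetic`) that builds a circular two-leaflet
patch of coarse pseudo-atom lipids — by default a 79 Å disc of 90 % DMPC,
9 % DMTAP, 1 % DMPE (564 lipids) — with Brownian lateral motion, scripted
leaflet flips, optional curvature/tilt, and PEG chains hugging the rim. Every
analysis is validated against this generator's known ground truth.

## Worked example

```python
from disctraj import (PatchSpec, DynamicsSpec, build_patch,
                      add_edge_polymers, simulate_dynamics,
                      default_selection_config)
from disctraj.sasa import occluded_fraction
from disctraj.diffusion import (msd, diffusion_coefficient,
                                DiffusionParams, expected_displacement)

sel = default_selection_config()
atoms, frame0 = build_patch(PatchSpec(radius=79.0, seed=1))
atoms, frame0 = add_edge_polymers(atoms, frame0, n_chains=24, n_monomers=30,
                                  seed=2)

res = occluded_fraction(frame0, atoms, sel)
print(f"occluded fraction: {res.occluded_fraction:.3f}")

dyn = DynamicsSpec(D_per_species={"DMPC": 0.02, "DMTAP": 0.14, "DMPE": 1.14},
                   frame_interval=0.5, n_frames=400, seed=3)
traj = simulate_dynamics(atoms, frame0, dyn)
D, r2, _ = diffusion_coefficient(
    msd(traj, "DMPC", sel, DiffusionParams(strides=(1, 2, 4, 8, 16, 32, 64)))
)
print(f"DMPC D = {D:.3f} A^2/ns (R^2 = {r2:.3f}), "
      f"expect {expected_displacement(D, 880)} A over 880 ns")
```

prints

```
occluded fraction: 0.031
DMPC D = 0.019 A^2/ns (R^2 = 1.000), expect 8.1 A over 880 ns
```

The occluded fraction is small here because only 24 sparse 30-mer chains
decorate the rim of a 564-lipid patch; the recovered diffusion coefficient
sits within sampling error of the generator input 0.02 Ų/ns, and √(4Dt)
converts it to a physical displacement over a production-run horizon.

The command line mirrors the library:

```bash
disctraj design                      # minicircle geometry / PEG density table
disctraj synth --radius 79 --n-frames 100 --out patch
disctraj occlusion --topology patch.pdb --trajectory patch_traj.pdb \
    --frame-interval 0.5 --out occlusion.tsv
disctraj run --config run.yaml       # full report bundle (TSV + JSON)
```

`disctraj design` for the default 147-bp ring prints an outer diameter of
17.9 ≈ 18 nm, inner 13.9 ≈ 14 nm, and 1.5 PEG modifications per helical turn.

## Notes

- PDB fixed columns keep four characters of a residue name, so `DMTAP` is
  stored as `DMTA` on disk; the reader restores known truncations
  (`disctraj.io.DEFAULT_RESNAME_ALIASES`).
- Frames are aligned by principal axes of the lipid C2 atoms; the patch must
  be wider than it is thick for the bilayer normal to be identified (a
  warning is emitted otherwise). See `docs/methods.md` for the full model
  description, parameter defaults and limitations.
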