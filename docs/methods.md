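# Methods

This note describes the models and numerical procedures implemented in
`disctraj`, the defaults they use, and what the synthetic-data validation
does and does not establish. Lengths are in Å, times in ns, energies in the
units of the supplied spring constant.

## Coordinate model and preprocessing

A system is an `AtomTable` (atom name, element, residue/species, segment,
van der Waals radius) plus ordered frames of unwrapped Cartesian coordinates.
Radii come from a frozen Bondi-style element table
(`disctraj.core.DEFAULT_VDW_RADII`; H 1.20, C 1.70, N 1.55, O 1.52, P 1.80 …),
overridable per element; freezing the table makes surface areas reproducible
across installations. DCD files carry integrator steps, not physical time, so
the frame interval is an explicit reader argument.

Every analysis assumes aligned frames. `preprocess_align` moves the center of
mass of the lipid C2 reference atoms to the origin and rotates their
principal axes onto the Cartesian axes, mapping the smallest-variance axis to
z (the bilayer normal). Axis signs are canonicalised on the first frame
(largest-magnitude component positive, right-handed set) and chosen for
continuity with the previous frame afterwards, so leaflet labels cannot flip
between frames through an eigenvector sign change. The decomposition is only
meaningful when the patch's lateral variance exceeds its transverse variance
— a disc must be wider than it is thick (for C2 planes at ±17 Å this means a
patch radius ≳ 35 Å); a warning is raised when the two smallest variances are
within 20 %. Coordinates are assumed unwrapped; `validate_connectivity`
flags intra-residue neighbor distances above 5 Å as likely wrapping
artifacts. Periodic-boundary reassembly is out of scope.

Time series are summarised two ways: non-overlapping block averages (default
window 15 ns, each block reported at its nominal center; a trailing partial
block averages what it contains) and interval means that by default skip the
first 25 % of frames, the analogue of discarding the equilibration quarter of
a production run.

## Synthetic bilayer patches

The generator stands in for all-atom trajectories that are not publicly
deposited. Each lipid is a vertical pseudo-atom stack: choline N (+4.0 Å
from the C2 plane, pointing away from the midplane), phosphate P (+2.5),
glycerol C2 (the reference atom, at ±`leaflet_separation/2`), ester O
(−1.5), and five tail carbons at 3 Å spacing reaching the midplane. Lipids
occupy a jittered triangular lattice (jitter σ = 1 Å) truncated to the disc;
per leaflet `round(πr²/APL)` sites. Defaults — radius 79 Å, 69.5 Ų per
lipid (so 282 lipids per leaflet, 564 total), C2–C2 separation 34 Å,
90/9/1 DMPC/DMTAP/DMPE drawn per lipid from a seeded categorical — emulate
the reference nanodisc bilayer. Rim polymers are arcs of alternating
methylene/oxygen pseudo-atoms (first atom a linker) on the rim cylinder with
seeded radial/vertical jitter.

Dynamics: per-species 2D Brownian steps of per-axis variance `2DΔt`,
reflecting radially at the patch rim (the nanodisc bilayer is finite;
reflection keeps the MSD interpretable for strides ≪ r²/D); scripted flips
teleport a whole lipid stack to the mirror leaflet at a given frame (the
flip-counting contract concerns label changes, not pathways); optional
spherical-cap curvature displaces each lipid by the sag
`cρ²/(1+√(1−c²ρ²))`; an optional tilt schedule applies a rigid rotation
about an in-plane axis, linearly interpolated between knots; optional
per-lipid z-jitter (default 0) models headgroup roughness. Everything is
deterministic given the seeds.

What the generator does **not** emulate: molecular shape and packing
(lipids are rigid vertical stacks), tail disorder and interdigitation,
membrane undulations, correlated or anomalous diffusion, detergent
exchange, DNA/PEG conformational dynamics, solvent. Passing tests therefore
demonstrate that each analysis recovers the statistical structure it is
defined on — not that a specific all-atom result is reproduced.

## Surface occlusion

SASA uses Shrake–Rupley point sampling on a Fibonacci (golden-angle) sphere
lattice, 960 points per atom by default (≲1 % error at negligible cost;
doubling the count changes patch areas by <0.5 %), probe radius 2.0 Å, with
a k-d tree for neighbor culling. A test point on an atom's inflated sphere is
buried when it lies on or inside any other context atom's inflated sphere
(closed boundary, so exactly coincident occluders bury a surface completely).
The occluded fraction evaluates the tail SASA twice: `A_free` with context =
lipid atoms only (occluders treated as solvent) and `A_context` with the
occluders (polymer- and detergent-role species) included; the fraction is
`(A_free − A_context)/A_free`, zero exactly when no occluder atoms exist.
Hydrogens are excluded from targets and contexts by default. The test-suite
oracle is an independent equal-area latitude–longitude surface integration
with brute-force burial checks.

## Contacts

Two atoms are in contact at distance ≤ 4.0 Å (closed boundary; the boundary
has measure zero in practice and the convention is fixed for determinism).
Counts are exact — `cKDTree.count_neighbors` only accelerates enumeration —
and are verified against the all-pairs distance matrix. The
fraction-of-possible-pairs statistic divides the interval-mean count by
`N_A·N_B` computed over all atoms of each motif class in the system (the
per-system reading of pair normalisation; a per-molecule reading would scale
all fractions by a constant). Motif classes are heavy-atom chemical groups;
hydrogens are excluded by default. An empty motif is reported with zero
possible pairs and NaN fraction rather than raising, so partial systems
still produce a report.

## Leaflets, edge distance, regions, flips

The midplane is the mean z of all lipid C2 atoms, recomputed each frame;
a lipid is upper/lower by the sign of `z_C2 − z_mid`. The bilayer footprint
is a Gaussian density on a voxel grid (default edge 6 Å — the "resolution"
is interpreted as the voxel edge length and is configurable; kernel width =
each atom's vdW radius, unit amplitude; isovalue 0.01; grid padded by two
voxels), detergent and polymer excluded. Collapsing the mask over a 2 nm
slab around the midplane and thresholding the inside-average at 0.5 yields a
2D inside/outside pixel map; a lipid's edge distance is the in-plane
distance from its C2 to the nearest outside pixel center (ties broken by
pixel index order). Regions are leaflet × (edge distance < 10 Å); the 10 Å
threshold is a configurable default, as is the slab. Composition fractions
divide species C2 counts by all lipid C2 counts per region, detergent
excluded, with the frame-global fraction reported alongside.

A flip is recorded at the first frame of a leaflet-label change whose new
label persists ≥ 15 ns (the block-average window) or to the trajectory end;
without a persistence window, thermal z-jitter across the midplane would
inflate counts. The debounce window is configurable; note that permissive
(undebounced) counting can report several-fold more events on noisy data.

## Bilayer geometry

All geometry restricts to lipids whose C2 lies in a 4 nm-radius core
cylinder (configurable; the curvature fit's restriction can be disabled).
The density profile uses 0.5 Å bins. Thickness = `μ_upper − μ_lower` from
independent per-leaflet Gaussian fits initialised at each side's empirical
moments (max 2000 function evaluations; non-convergence raises with the
initialisation in the message; a near-delta profile with <4 occupied bins
falls back to the exact weighted mean). Area per lipid = `πR²/N_leaflet`
averaged over leaflets, with a warning when the cylinder overhangs the
patch. Curvature fits each leaflet's C2 set with the sag parameterisation
`z(ρ) = z₀ + cρ²/(1+√(1−c²ρ²))` — chosen over (center, radius) because the
flat limit c → 0 is an interior point, so planar patches fit stably —
bounded by `|c|ρ_max < 1`, and averages the two leaflets; positive c bulges
toward +z (the upper leaflet after alignment). The edge headgroup count is
the number of lipid C2 atoms within the 1 nm midplane slab with no radial
restriction.

## Lateral diffusion

Per species, the MSD at stride τ averages squared in-plane displacements
over all time origins and all lipids inside the core cylinder at the origin
frame (membership at the origin maximises statistics; a both-endpoints
criterion is available). Default strides are 1–128 ns in powers of two;
strides that exceed the span or do not divide the frame interval are skipped
with a warning. D is one quarter of the ordinary least-squares slope of MSD
vs τ over all available strides, unweighted; the intercept absorbs
stride-independent offsets and the fit R² is reported as a diagnostic
(ballistic or confined motion shows up there, not as an exception).
Expected displacement is `√(4Dt)`, reported to two significant figures.
Validation recovers D ∈ {0.02, 0.14, 1.14} Ų/ns within 10 % from ~200
probe lipids over 2000 frames of a 79 Å patch — with the core-membership
restriction this stays in the linear MSD regime; in smaller patches rim
reflection visibly depresses the long-stride MSD, which is why the
validation keeps the reference patch size.

## Tilt collective variable

The least-RMSD proper rotation (Kabsch/quaternion, via
`scipy.spatial.transform.Rotation.align_vectors`) maps the subsampled C2 set
(every fourth lipid by default) onto the designated reference frame. The
rotation is factored `R = R_tilt · R_spin` — twist about the normal
extracted as the normalised projection of the quaternion onto z, swing as
the remainder; this order is a convention (both orders give the same tilt
magnitude, which is the reported observable). At tilt → 0 the azimuth is 0
by convention; a 180° swing (vanishing twist projection) takes the
pure-swing branch. Identities maintained to 1e−9: recomposition reproduces
R; cos(tilt) equals the matrix element R₃₃; pre-composing any spin about z
leaves the tilt unchanged. The restraint energy is `½k(cosθ − target)²`
(default k = 10,000, matching a stiff production restraint); only the
colvar value and energy are computed — forces on atoms and restrained
integration are out of scope.

## Design arithmetic

A minicircle of `n` bp at 0.34 nm/bp rise has centerline diameter
`0.34n/π` nm; ±1 nm of helix width gives outer/inner diameters (reported at
full precision, with nearest-nm rounding in the report layer only).
Modification density is modifications per 10.5-bp turn. The lipid fill count
is `round(2π(d_inner/2)²/APL)` for two leaflets; the default APL of
0.684 nm² is back-solved from the reference design's 1:450 DNA:lipid
stoichiometry inside a 14 nm circle — it is an assembly-recipe constant, not
a measured bilayer property, and is configurable. A rough same-species
spacing estimate `√(leaflet area / count)` is provided but not asserted
against any reference.

## Pipeline and reproducibility

`disctraj run` executes align → regions/flips → geometry → occlusion →
contacts → diffusion → tilt from a YAML config, writing one TSV per analysis
(with a provenance header of version, inputs and seed) plus `summary.json`
of interval means. All randomness is seeded, so identical configs reproduce
outputs byte for byte, and disabling one analysis leaves the others'
outputs unchanged.

Validation problem sizes were chosen so the whole suite runs on a laptop
core in well under a minute apart from the diffusion scenarios (a few
seconds each): 564-lipid patches for composition/curvature, 1000 lipids for
thickness, ~500-atom patches for the SASA oracle, 10⁴ atoms for the contact
oracle.

## Known limitations

- No periodic-boundary handling, force fields, energies, or XTC/TRR input.
- PCA alignment fails on patches narrower than they are thick and on
  strongly non-discoidal geometries (vesicles, multilamellar stacks).
- Leaflet assignment uses a flat global midplane; strongly curved bilayers
  (|c|·r approaching 1) would need a curved-midplane assignment.
- The pair-count normalisation and the voxel "resolution" interpretation are
  documented conventions; results on external data should quote them.
- PDB files truncate residue names to four characters; known truncations are
  restored on read via `DEFAULT_RESNAME_ALIASES`.
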