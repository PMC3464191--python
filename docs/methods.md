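# Methods

This note defines the models and estimators the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices a user should know before trusting a
number. Units are ångström and nanoseconds throughout; conversions happen
only at the file I/O boundary.

## Data model and conventions

A topology is a flat atom table: chain, residue, atom name, element, van
der Waals radius and a species class (protein / water / ligand / lipid /
ion) assigned from residue-name rules; molecules are residue-level groups.
Radii are Bondi by element (H 1.10 Å, C 1.70, N 1.55, O 1.52, S 1.80, …),
overridable per call — the absolute pore radii and cavity volumes shift
systematically with the radius set, which is why validation is against
synthetic ground truth rather than published absolute values. Chain order
in the file defines subunit indices (A..E → 0..4). M2 prime notation maps
position p′ to residue 224 + p (9′ = 233, 14′ = 238, 16′ = 240).

Trajectories must have uniform frame spacing (1% tolerance). "Second
half" windows are t ≥ midpoint, inclusive; trailing windows default to
the last 10% of frames.

## Pore profile

Frames are first aligned: the pentamer's symmetry axis (the distinct
eigenvalue of the protein C-alpha inertia tensor — robust for a
C5-symmetric particle, where two eigenvalues coincide) goes to +z,
oriented so the 16′ marker lies above 9′, and the mean 9′ C-alpha z
defines the origin. If the markers are missing the geometric centre is
used with a warning and the axis sign is arbitrary.

At each z (default step 0.5 Å) the pore radius is the largest clearance
min_i(|c − x_i| − vdW_i) over probe centres c in the plane, maximised
within a 5 Å disc of the axis by nine deterministic starts (axis centre
plus eight points at 2.5 Å) refined with Nelder-Mead (xatol 1e-3 Å).
Protein heavy atoms within ±6 Å of the plane contribute, since spheres
protrude into the slab. Slabs with no atoms give NaN — missing, never
zero; negative clearances clamp to zero. The windowed constriction series
takes, per frame, the minimum of r(z, t) within ±2.5 Å (window 5 Å) of
the marker's mean z that frame.

On toy cylinders the optimiser agrees with a 0.05 Å brute-force grid
search to < 0.05 Å; on sloped wall sections the discrete wall rings
themselves perturb the realised radius by up to ~0.08 Å, which is a
property of the constructed geometry, not the search.

## Cavity detection and volumes

A voxel of the 1 Å analysis lattice is void in a frame when (i) its
centre keeps probe clearance (≥ vdW + 1.4 Å) from every protein heavy
atom, (ii) it lies in the transmembrane z-range (default −20..15 Å) and
outside the pore lumen (radial distance ≤ r(z) + 0.5 Å from the axis),
and (iii) it is buried: of 14 scan rays (6 axial, 8 diagonal) at least 9
hit a protein heavy atom within 8 Å (a hit = perpendicular distance to
the ray ≤ the atom's vdW radius). The burial rule (9 of 14 at 8 Å) and
the minimum component size (8 voxels) are package choices, configurable.

Consensus grids average the boolean void maps over frames sampled at a
stride (default 5 ns); voxels with frequency ≥ 0.20 form 26-connected
components. Components are classified by their lining atoms (protein
heavy atoms within 5 Å of a component voxel): ≥ 80% one chain →
intra-subunit; two chains ≥ 20% each → inter-subunit; otherwise flagged
ambiguous and reported. The largest component of each class is rotated by
k·72° about the pore axis onto the other four sites (C5 symmetrisation);
those copies are the per-site volume-integration regions.

Volumes are Monte-Carlo: n uniform points (default 10,000) in the
region's bounding box; hits fall inside a region voxel cube and keep
probe clearance from the protein; V = V_box·p with SE = V_box·√(p(1−p)/n).
Two consequences worth knowing:

- a bare, axis-aligned voxel cube fills its own bounding box, so its MC
  estimate is exact with SE = 0 — SE-sensitive checks need a region that
  does not tile its box or an atom-limited boundary;
- for a cavity not aligned with the lattice, integrating over the raw
  voxel cubes clips the sub-voxel boundary (≈ 11% for a rotated box,
  measured), so the pipeline dilates each symmetrised region by one voxel
  and lets the probe-clearance test resolve the true boundary. Per-frame
  volumes are computed inside these fixed regions and averaged over the
  second half of the run.

The cavity-facing polar surface fraction is a Shrake–Rupley-style
estimate: each lining atom carries sphere points at vdW + probe (default
240/atom), points buried by any neighbour's expanded sphere are removed,
and only accessible points within 1.5 Å of a cavity voxel centre count;
the fraction is the polar-atom (N/O/S) share of that area. Only atoms
whose expanded sphere can reach the facing zone contribute; beyond 800
such atoms a seeded uniform subsample is used (the ratio estimator is
insensitive to uniform atom subsampling, and the toy-lining tests compare
240-point against 5000-point sampling).

## Occupancy and densities

A molecule occupies a cavity when its heavy-atom geometric centre lies
within 1.0 Å of a cavity voxel centre — a simple rule, symmetric across
species and exactly testable; the threshold is configurable. Ligands and
waters count as molecules; lipids as individual acyl-chain heavy atoms
(headgroup/glycerol atoms excluded by name). Density maps add one count
per selected atom per frame to its containing 1 Å voxel and divide by the
number of averaged frames, so the map total equals the mean in-box atom
count exactly (number density, not mass-weighted). Occupancy counting
assumes the trajectory is expressed in the same frame as the cavity grid;
the synthetic generator builds aligned frames, and file-based inputs
should be aligned once before counting.

## Exchange kinetics

Binary traces b_m(t) mark molecule m occupying any cavity of a class;
molecules never bound are dropped from the trace set but remembered in
the pool size. The survival-style correlation

    C(Δt) = Σ_m Σ_t b_m(t) b_m(t+Δt) / Σ_m Σ_{t ≤ T−1−Δt} b_m(t)

starts at exactly 1. For an ergodic two-state (bound/bulk) process it
decays not to zero but to the stationary bound fraction π — and because
never-bound molecules contribute nothing to either sum, that plateau is
the *unconditional* π = Σb/(n_total·T), directly computable from the
data. The two-exponential model A_f·e^(−Δt/τ_f) + (1−A_f)·e^(−Δt/τ_s)
decays to zero, so fitting it to a plateaued curve is unidentifiable: the
slow component chases the plateau and τ_s diverges. The estimator
therefore (defaults, all exposed):

- rescales to (C − π̂)/(1 − π̂) before fitting (`plateau_corrected`);
  a classical mean-subtracted autocovariance mode also exists but is
  biased low when the trajectory is only a few dwell times long;
- weights residuals by √(pair count per lag), since long lags average
  far fewer pairs;
- bounds τ_s ≤ 2× the maximum lag (default maximum lag: half the
  trajectory) and multi-starts from τ_f ∈ {2, 10, 30}·Δt,
  τ_s ∈ {0.1, 0.3, 0.6}·max-lag;
- flags fits degenerate when the slow amplitude < 0.05 or τ_f/τ_s > 0.95,
  and reports the dominant component as the headline exchange time in
  that case (a pure single exponential is the textbook degenerate case).

Standard errors come from bootstrap over molecules (default 200
replicates, seeded), reported as a robust SD (1.4826·MAD) of the headline
time across replicates — a few replicates are plateau-dominated and hit
the τ_s bound, and a plain SD would measure only those outliers. With
fewer than 5 traces the bootstrap degrades to a jackknife with a warning.

Recovery, measured on the generator at the study-like per-ligand bound
fraction (~2.5%, bound dwell 150 frames, 100 ligands × 1000 frames):
single replicates carry only ~13–19 binding events and scatter ±30%;
pooling 10 replicates brings the fitted τ_s within 6–15% of truth. The
analysis drivers and the acceptance checks therefore pool replicates.

## Statistics

Occupancy correlations pair two per-cavity series averaged in aligned
time bins (default 10 frames) and pool the five sites of a class before
an ordinary least-squares fit; R² = 1 − SS_res/SS_tot equals the squared
Pearson correlation for simple OLS (asserted to 1e-12). Cavity tables
print mean±SD per site over the second-half window; the Average column is
the mean of per-site means with the SD of the site-averaged time series.

## The synthetic channel: what it emulates, what it does not

The generator emulates the *statistical* targets of the analysis, not
physics. It builds: a wall of carbon-like pseudo-atoms on rings of radius
r(z) + vdW following a piecewise-linear pore profile (default: 2.25 Å
constriction at z = 0, a secondary narrowing near +10 Å); five C-alpha
rods for the M2 helices (residues 221–245, 1.5 Å rise, 9′ at z = 0) with
optional per-subunit kinks applied as exact rotations at residue 238; a
body lattice (1.5 Å) between radii 7.5 and 18 Å; and ten cavities — five
intra-subunit boxes (6³ = 216 Å³, membrane-facing, z ≈ +7) and five
inter-subunit boxes (4.5³ ≈ 91 Å³ at the interfaces, z ≈ −5), each
realised as 72°-rotated copies of a template and each wrapped in a shell
of pseudo-atoms on its offset surface at per-atom vdW + probe distance,
so the probe-carved void is exactly the declared shape and the declared
volume is exact ground truth. Sphere cavities are supported; box sizes
were chosen so the inter volume sits near the low end of reported pLGIC
interface pockets. The two cavity classes are separated axially so each
shell keeps ≥ 2(vdW + probe) clearance from every other cavity — real
intra and inter pockets sit in roughly the same membrane plane, but the
toy pentagon is too crowded for independent exact shells.

Ligands are rigid 3-atom (C,C,O) ethanol-like bodies following
independent two-state continuous-time Markov chains with exponential
bound/bulk dwells (defaults 150/750 ns; the kinetics studies use 150/5850
ns to match a realistic ~2.5% per-ligand bound fraction), started from
the stationary distribution; bound ligands are placed uniformly at least
1.0 Å inside an assigned cavity (so membership by the 1 Å-centre rule is
exact), bulk ligands uniformly in a distant solvent shell. Waters fill
inter-subunit cavities toward a baseline reduced per resident ligand;
lipid chains (2 × 6 atoms per intra cavity) insert with probability
reduced per resident ligand — these are the anti-correlation knobs the
statistics stage must recover. Default pool: 30 ligands / 3000 bulk
waters (1 mol-%). Thermal noise (0.05 Å) is applied per residue as
pseudo-rigid group displacements: independent per-atom noise on a 0.5
Å-spaced shell would systematically shave the probe-accessible volume,
because clearance is a minimum over many atoms and the minimum of many
independently jittered distances is biased small — an extreme-value
artifact of dense pseudo-atom packing that real, sparsely packed atoms do
not show.

What the generator does **not** emulate — and what passing tests
therefore do not certify on real data: physical forces and realistic
dynamics (bulk solvent teleports between frames; there is no diffusion,
so the fast "rattling" exchange component of real trajectories is absent
and single-exponential dwells are the truth); protein conformational
change (the scaffold only jitters, so RMSD analyses are exercised on
constructed displacements in the tests); realistic lipid structure;
periodic imaging; and crystallographic disorder. Absolute agreement with
published pore radii or pocket volumes also depends on the vdW radius set
and the pocket-detection algorithm (alpha-sphere methods differ
systematically from this grid-probe rule), so the package validates
recovery of known synthetic truth, not literature values.

## Problem sizes and defaults

The shipped study conditions are desk-scale: 150 frames at 1 ns, cavity
consensus sampled every 5–10 ns, pore profiles every 10 frames at 1 Å
z-step, 10,000–40,000 MC iterations per volume, 50–200 bootstrap
replicates; the kinetics recovery pools 10 × (100 ligands × 1000 frames)
trace-level replicates. All of these are config fields
(`PipelineConfig`), and every stage accepts larger values unchanged.

## Known limitations

- The kink angle is defined on segment principal axes; for short segments
  (the 8-residue upper M2) the principal axis of an ideal helix is tilted
  a few degrees off the helix axis, so "bend the helix by α" and "the
  principal axes subtend α" differ — the tests construct the latter.
- detect_voids assumes an axis-aligned frame; it does not re-align.
- The burial rule can legitimately reject the centre of a very large
  cavity (> ~8 Å to the nearest wall along most rays).
- Occupancy counting does not re-align frames to the cavity grid.
- mc_volume integrates voxelised regions; without the one-voxel dilation
  the estimate of a lattice-misaligned cavity is biased low by the
  boundary clip.
- Bootstrap SEs assume molecules are exchangeable; they are, in the
  generator, but correlated binding in real systems would violate this.
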