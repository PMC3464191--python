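# chancav

Pore, cavity and ligand-occupancy analysis for pentameric ligand-gated
ion channel (pLGIC) trajectories — with a synthetic pentameric-channel
generator that provides exact ground truth for every stage.

## The problem

Allosteric modulators such as ethanol and anesthetics act on pLGICs (GLIC,
glycine and GABA-A receptors, nicotinic receptors) by occupying
transmembrane cavities: a membrane-facing *intra-subunit* pocket within
each subunit's helix bundle and an *inter-subunit* pocket at each subunit
interface. Quantifying this from molecular-dynamics trajectories requires
a chain of measurements, each with its own pitfalls:

- **Pore geometry** — the pore radius r(z) along the channel axis, where
  r(z) = max over probe centres c in the plane of min over atoms i of
  (|c − x_i| − vdW_i), and its windowed minimum at the hydrophobic gate
  (the 9′ position of the M2 helix, residue 233 in GLIC numbering);
- **Helix kink** — the angle between the first principal axes of the
  C-alpha inertia tensors of the lower (7′–14′, residues 221–238) and
  upper (14′–21′, 238–245) M2 segments, folded into [0°, 90°];
- **Cavity volumetrics** — frame-wise grid-probe void detection (1 Å
  lattice, 1.4 Å probe, burial by 14 scan rays), consensus grids over the
  trajectory (voxels void in ≥ 20% of frames sampled every 5 ns),
  intra/inter classification by lining-atom chains, five-fold (C5)
  symmetrisation, and Monte-Carlo volume integration (V = V_box · hits/n,
  SE = V_box · sqrt(p(1−p)/n));
- **Occupancy** — per-cavity counts of ligand and water molecules
  (heavy-atom centre within 1 Å of a cavity voxel centre) and lipid
  acyl-chain atoms, plus 1 Å number-density maps;
- **Exchange kinetics** — per-molecule binary occupancy traces b_m(t), the
  survival-style autocorrelation C(Δt) = Σ b_m(t)·b_m(t+Δt) / Σ b_m(t),
  and a bounded two-exponential fit A_f·e^(−Δt/τ_f) + (1−A_f)·e^(−Δt/τ_s)
  whose slow time constant τ_s is the bound-to-bulk exchange time;
- **Occupancy statistics** — time-binned per-cavity pairs (e.g. lipid
  atoms vs ligand count "at a given time") with OLS fits and R².

None of these headline numbers can be validated against a deposited
trajectory, so the package carries a first-class synthetic generator: a
C5-symmetric pseudo-atom channel with a prescribed pore profile, declared
box/sphere cavities of exactly known volume (each wrapped in a
probe-offset atom shell so the carved void *is* the declared shape),
markers at the 9′/14′/16′ positions, optional per-subunit kinks, and an
ethanol-like ligand pool following two-state Markov binding with
exponential dwell times. Every stage is tested against this ground truth
or against brute-force oracles.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
synthetic channel (36 283 atoms, 150 frames at 1 ns, 30 ligands over 3000
bulk waters ≈ 1 mol-%, bound/bulk dwells 150/750 ns, a 12° kink built
into subunit A):

```bash
cd analysis
python 01_simulate_channel.py && python 02_structure_deviation.py
python 03_pore_profile.py && python 04_cavity_volumes.py
python 05_occupancy_densities.py && python 06_exchange_kinetics.py
python 07_occupancy_correlations.py
```

Output from a run of the key steps:

```
kink angles: {'A': 11.98, 'B': 0.4, 'C': 0.41, 'D': 0.43, 'E': 0.41}
subunit A was built with a 12.0° kink; recovered 11.98°

pore constriction at 9' (z-window 5 Å, trailing half): 2.19 ± 0.03 Å  (designed 2.25 Å)

   site class  n_voxels  volume_A3  volume_se_A3  true_volume_A3  error_pct
intra_0 intra       234      219.1           2.8         216.000        1.4
inter_0 inter       100       94.8           1.4          91.125        4.0
...

exchange time: 145 ns (bootstrap SE 20), truth 150 ns, relative error 3.5%

intra: lipid vs ligand -> slope -3.04 (SE 0.42), R² = 0.58
inter: water vs ligand -> slope -0.98 (SE 0.05), R² = 0.91
```

The recovered kink is exact to 0.03°, the windowed 9′ constriction sits
2.7% under the designed 2.25 Å (lattice discretisation of the wall), all
ten cavity volumes land within ~5% of their declared values, the pooled
exchange-time fit recovers the 150 ns bound dwell within its bootstrap
error, and the anti-correlation knobs of the generator (lipids displaced
from intra cavities, waters from inter cavities) come back as negative
slopes with the expected R².

The same pipeline runs from a single YAML config:

```bash
chancav run --config config.yaml --out report/
chancav simulate --frames 100 --seed 1 --out traj.pdb --truth truth.json
chancav kink structure.pdb --bottom 221-238 --top 238-245
```

Real trajectories enter through `chancav.io.read_structure` /
`read_trajectory` (PDB/GRO; multi-model PDB, DCD, XTC, TRR) with
residue-name → species rules; grids are written as OpenDX.

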