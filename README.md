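# oximescreen

A screening toolkit for electron-donating-group (EDG) substituted
pyridinium-aldoxime reactivator candidates. It covers the computational
backbone of such a campaign end to end, with the expensive physics
(QM energies, all-atom MD, docking) replaced by ingested tables and a
calibrated toy simulator:

- **`chem_enum`** — enumerate para/ortho EDG-substituted analogs of the
  1-methylpyridinium-2-aldoxime scaffold from a configurable substituent
  registry, build their SMILES with RDKit, compute drug-likeness
  descriptors, and apply an inclusive-threshold CNS filter
  (MW ≤ 450, HBD ≤ 7, HBA ≤ 3, cLogP ≤ 5, PSA ≤ 70 Å², 12 ≤ heavy ≤ 30,
  BBB-permeant via a documented surrogate rule).
- **`pose_geometry`** — near-attack geometry from PDB poses: the
  oxime-O⋯P distance `d_OP` and the O–P–O angle `theta_OPO`, with apical
  classification (`d_OP < 8 Å`, `120° < theta ≤ 180°`).
- **`energy_rank`** — two-layer subtractive energy arithmetic
  (`E_high_model + E_low_real − E_low_model`), delta-vs-reference
  columns, threshold counting, ranking, and quartile-based candidate
  selection. Ships a transcription of the campaign's printed 18-analog
  energy table (`data/table1.csv`).
- **`pie_analysis`** — pair-interaction-energy totals from five-component
  decompositions, per-residue delta fingerprints, and ≥ 50 %
  interaction-residue consensus sets.
- **`dsmd_engine`** — distance-selection adaptive sampling: fixed-length
  cycles, each restarted from the previous cycle's minimum-distance
  frame, over any propagator satisfying a small contract.
- **`msm_fel`** — Markov state models at a configurable lag on a
  (d, theta) grid and 2D free-energy landscapes in kT, with global/local
  minima and minimax-path escape barriers.
- **`synthetic_data`** — every fixture with known ground truth: a
  calibrated two-basin/single-basin toy potential with an overdamped
  Langevin propagator, energy tables with exact pass counts, pose sets
  with exact apical fractions, and interaction matrices with exact
  consensus sets.

## CLI

```bash
oximescreen enumerate --r1 2,3,4,5,9 --r2 1,2,3,4,5,6,8,9 --mode combined
oximescreen rank --count "d_mp2<0" --count "d_mp2<=-15"
oximescreen quartile --scores scores.csv
oximescreen druglike --profiles descriptors.csv
oximescreen posegeom poses/*.pdb --dmax 8 --tmin 120
oximescreen pie --components pieda.csv --ligand 3-1 --ref 2-PAM
oximescreen consensus --matrix interactions.csv --fraction 0.5
oximescreen dsmd --scenario two_basin_side_GM --cycles 100 --steps 100 \
    --replicates 3 --seed 7 --out traj.csv
oximescreen fel --traj traj.csv --lag 25 --burn-in 30 --out-prefix fel
oximescreen synth energy-table --n 18 --n-negative-mp2 13 --n-below-b3lyp 3 --seed 1
```

## Notes

- The toy dynamics use kT = 1, one frame per time unit, so the default
  cycle length (100 frames) and MSM lag (25 frames) mirror the reference
  protocol's 100 ps cycles and 25 ps lag.
- Substituent registry ids 1–3 (methyl, 2-methyl-2-butene, phenyl) are
  authoritative; ids 4–9 are flagged placeholders — all counting logic
  is independent of fragment identity.
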