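# smdfan

Setup and analysis toolkit for **multidirectional steered molecular
dynamics** (SMD) of two-body complexes.

Single-direction SMD can miss mechanical anisotropy: the rupture force of a
protein–protein interface, or the exit pathway of a ligand, depends on the
direction of the applied force.  `smdfan` probes that anisotropy
systematically.  Given a complex in PDB format and two atom selections (the
immobilized and the pulled group), it:

1. computes the **principal axis** — the unit vector between the two
   groups' centers of mass — and generates a fan of unit pulling vectors
   v(θ, φ) = cosθ·axis + sinθ·(cosφ·e1 + sinφ·e2) over the hemisphere
   around it (default grid θ ∈ {0°, 45°, 90°}, φ ∈ {0°, 90°, 180°, 270°}:
   nine distinct directions);
2. scaffolds one run directory per direction with ready-to-run **NAMD** or
   **GROMACS** constant-velocity pulling inputs, replica-aware run scripts,
   and a VMD Tcl script drawing the direction arrows;
3. parses the engine output (NAMD SMD log lines, GROMACS pull `.xvg`) into
   force traces in pN and computes **rupture forces** F_max, force–COM
   distance curves, replica mean ± SD, and geometric **hydrogen-bond**
   counts per trajectory frame.

A bundled toy steered Brownian-dynamics engine (bead–spring complexes with
breakable interface bonds) runs the whole loop in minutes without an MD
engine, and doubles as the test fixture generator.

## Worked example

Run a toy campaign over the nine default directions (2 replicas each for
speed) and analyze it:

```sh
smdfan simulate --out campaign --replicas 2 --seed 1
smdfan analyze --root campaign
cat campaign/analysis/anisotropy.tsv
```

```
label	theta	phi	mean_f_max_pN	sd_f_max_pN	n_replicas
theta_0_phi_0	0.00	0.00	135.10	1.01	2
theta_45_phi_0	45.00	0.00	116.58	2.21	2
theta_45_phi_90	45.00	90.00	77.90	0.02	2
theta_45_phi_180	45.00	180.00	92.18	2.24	2
theta_45_phi_270	45.00	270.00	128.26	1.44	2
theta_90_phi_0	90.00	0.00	113.68	1.16	2
theta_90_phi_90	90.00	90.00	62.34	1.08	2
theta_90_phi_180	90.00	180.00	86.45	0.95	2
theta_90_phi_270	90.00	270.00	68.33	0.03	2
```

Each row is one pulling direction; `mean_f_max_pN` is the mean over
replicas of the maximum pulling force — the rupture force, i.e. the
mechanical stability of the interface along that direction — and the spread
across rows is the complex's mechanical anisotropy.  The built-in toy
complex is constructed with asymmetrically tilted breakable bonds, so
rupture is genuinely direction-dependent.

For a real system, replace `simulate` with `setup` and run the generated
inputs with your engine:

```sh
smdfan setup --pdb complex.pdb --fixed "chain A" --pulled "chain B" \
    --engine namd --spring-k 7 --velocity 0.00002 --replicas 5 --out runs
# ... run runs/*/run.sh on your cluster ...
smdfan analyze --root runs
```

Selections support `chain`, `resid a-b`, `name`, `segid` with
`and`/`or`/`not` and parentheses.

## Layout

- `smdfan.structure` — PDB I/O, selections, centers of mass, principal axis
- `smdfan.directions` — frames, direction fans, VMD arrow script
- `smdfan.enginegen` — NAMD/GROMACS input rendering and tree scaffolding
- `smdfan.smdparse` — NAMD log and `.xvg` parsers, COM distance series
- `smdfan.forceanalysis` — rupture forces, replica statistics, H-bonds
- `smdfan.toysim` — toy engine, built-in complex, quasi-static oracle
- `smdfan.cli` — `smdfan setup | simulate | analyze | visualize`
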