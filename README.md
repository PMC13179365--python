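# petkit

Analysis toolkit for PET-hydrolase engineering experiments. It implements,
as tested reusable code, the quantitative procedures used to characterize
engineered polyester hydrolases:

| module | what it does |
| --- | --- |
| `petkit.eis` | Randles-equivalent-circuit fitting of frequency-swept impedance spectra, parallel-plate capacitance-to-thickness inversion, and windowed film degradation rates (µm/h) |
| `petkit.kinetics` | TPA quantification via an A240 standard curve and inverse Michaelis–Menten fitting (`v = invVmax·[E]/(invKM+[E])`) with Jacobian-based standard errors |
| `petkit.titration` | pH-stat NaOH consumption → depolymerized PET mass (2 NaOH per TPA, 192.2 g/mol repeat unit), percent degradation, volumetric rates, time-to-X% |
| `petkit.thermal` | two-state van't Hoff melt-curve simulation (F350/F330 ratio, 20–95 °C ramp) and derivative-peak apparent-Tm extraction with detection-limit (">95 °C") reporting |
| `petkit.activity` | gravimetric weight-loss percentages, fold-activity vs wild type at matched conditions, residual-activity time courses and half-lives |
| `petkit.variants` | point-mutation parsing/validation, application to sequences, formal net-charge deltas at pH 8, and a packaged variant lineage table |
| `petkit.mdgeom` | trajectory geometry: catalytic-state classification (in-oxyanion / near-active-site / other), H-bond and out-of-plane angles, φ/ψ dihedrals, salt-bridge occupancy, water RDFs, Kabsch superposition and RMSD; multi-model PDB and CSV trajectory I/O |
| `petkit.synth` | seeded generators for every input above (spectra of a thinning film, duplicate kinetics datasets, melt curves, titration curves, trajectories with prescribed state occupancies, jittered structure pairs) |
| `petkit.cli` | `petkit` command wiring everything: `simulate`, `eis`, `kinetics`, `melt`, `reactor`, `activity`, `mdgeom`, `variants`, `demo` |

## CLI examples

```sh
# synthesize impedance sweeps of a film thinning at 21 µm/h, then analyze
petkit simulate eis --rate 21.0 --seed 1 --out spectra.csv
petkit eis fit --spectra spectra.csv --area-mm2 44.7 --eps-r 3.3 --window 3 8 --out fits.csv

# inverse Michaelis-Menten round trip
petkit simulate kinetics --inv-vmax 139 --inv-km 0.145 --seed 1 --out kin.csv
petkit kinetics fit --data kin.csv --out fit.json

# melting point from a ratio curve
petkit simulate melt --tm 79.1 --out melt.csv
petkit melt tm --data melt.csv

# bioreactor degradation profile from NaOH consumption
petkit simulate reactor --out titration.csv
petkit reactor profile --data titration.csv

# trajectory analyses
petkit simulate traj --occupancy 0.45 --n-frames 2000 --out traj.csv
petkit mdgeom saltbridge --traj traj.csv --basic 148 --acidic 233
petkit mdgeom rmsd --ref a.pdb --mob b.pdb --select CA

# net-charge accounting for a named variant
petkit variants charge --name R2M2

# regenerate the headline recovery table from one seed
petkit demo --seed 1 --out demo.json
```

Exit codes: 0 success, 2 usage error, 3 data error, 4 convergence failure.

## Notes on conventions

- Randles circuit: `Z(ω) = R_s + R_ct/(1 + iωR_ct·C)`; fits minimize
  1/|Z|-weighted stacked real/imaginary residuals in log-parameter space.
- Thickness: `d = ε₀·ε_r·A/C` with defaults ε_r 3.3, A 44.7 mm².
- Degradation rate: centered rolling linear smoothing (1 h) and central
  differences, averaged over a 3–8 h window by default; thinning positive.
- State classification bounds are strict on the upper end, inclusive on the
  lower (a tie at exactly 5.0 Å is near-active-site, not in-oxyanion).
- Apparent Tm is the derivative peak of the ratio signal, which for a
  van't Hoff two-state curve sits slightly below the thermodynamic
  midpoint; the extractor reports the peak, as instruments do.
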