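# ciukit

Collision-induced unfolding (CIU) analysis toolkit for traveling-wave
ion-mobility mass spectrometry, with gas-phase structure utilities:

- **`ciukit.synthetic`** — instrument-realistic synthetic CIU datasets
  (arrival-time-distribution matrices over a collision-voltage ramp,
  calibrant tables, toy 3-D structures) with known generative truth,
  including a voltage-dependent ligand-ejection channel coupled to the
  unfolding midpoint.
- **`ciukit.calibration`** — TWIMS drift-time → CCS calibration via the
  corrected power-law protocol (EDC flight-time correction, reduced-mass /
  charge correction, log–log least squares), plus the exact inverse.
- **`ciukit.analysis`** — CIU fingerprints (per-voltage max-normalized),
  centroid-CCS unfolding curves, ΔCCS, four-parameter logistic fits,
  closed-form CIU_χ extraction, replicate χ-profiles (mean ± sd), one-way
  ANOVA species comparisons, ligand-ejection logistic fits, and lab-frame
  collision energy (E_lab = z·V).
- **`ciukit.charge`** — stochastic proton placement on chargeable sites
  (Asp/Glu/Lys/Arg/His side chains + termini) minimizing unscreened Coulomb
  energy at fixed net charge, with an exhaustive-enumeration oracle and a
  convergence benchmark.
- **`ciukit.ccs`** — projection-approximation CCS by Monte Carlo over random
  orientations (CCS_CALC = 1.14 × CCS_PA, 1.4 Å probe), Kabsch-superposition
  RMSD, mass-weighted COM distances, and per-frame trajectory profiles.
- **`ciukit.io` / `ciukit.cli`** — raw-CSV ATD matrices (first column
  arrival time, header row of voltages), calibrant CSV tables, YAML
  configs/models, PDB structures (multi-model), and a subcommand CLI.

## CLI

Every subcommand writes its outputs plus a run record (seeds, parameters,
version) into the chosen output directory:

```sh
ciukit simulate -o out --seed 1            # synthetic ATDs + calibrants + truth
ciukit calibrate out/calibrants.csv -o out # fit the power-law calibration
ciukit fingerprint out/atd_apo_rep0.csv out/calibration.yaml -o out
ciukit fit out/atd_*_rep*.csv --model out/calibration.yaml -o out
ciukit chi out/fits_4pl.csv -o out         # per-species CIU_chi profiles
ciukit compare out/fits_4pl.csv -o out     # per-chi one-way ANOVA
ciukit eject ejection_series.csv -o out    # ligand-ejection logistic fit
ciukit chargeplace protein.pdb --target-charge 12 -o out
ciukit paccs protein.pdb -o out            # projection-approximation CCS
ciukit trajprofile trajectory.pdb -o out   # per-frame RMSD / COM / CCS table
```

`ciukit simulate` accepts a YAML config (`-c config.yaml`) overriding the
instrument settings, voltage ramp and species definitions; see
`ciukit.cli.DEFAULT_SPECIES` for the expected shape.

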