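# g4twist

Analysis of G-quadruplex (G4) folding inside negatively supercoiled
double-stranded DNA from magnetic-tweezers force ramps — for single-molecule
biophysicists who record bead-extension traces at fixed force and fixed
imposed turns and want to detect G4 formation and quantify its energetic
effect on duplex opening.

## The physics in brief

A torsionally constrained dsDNA tether under negative supercoiling relaxes
stress by plectonemes at low force and by a denaturation bubble above a
characteristic force F_C; at coexistence the extension variance σ²(L_e)
peaks, so F_C is read off as the maximum of the variance-versus-force
profile. A G4-forming promoter region adds a second relaxation channel —
partial melting plus G4 folding, absorbing ~7 turns — that produces a second
variance maximum at a lower force F_C1 < F_C2: the **double-peak
fingerprint** of G4 folding.

Quantities the package computes:

- **Worm-like chain** (Marko–Siggia) fits of untwisted curves:
  F = (k_BT/L_p)[1/(4(1−x/L_0)²) − 1/4 + x/L_0], giving L_0 and L_p.
- **Variance profiles and peak classification** (no/single/double) with
  explicit smoothing, prominence and separation thresholds, and the
  ensemble percentage of double peaks with binomial errors.
- **Logistic steepness** of supercoiled mean curves,
  L_e = a + b/(1 + e^{(F−F1)/S0}), the S0 statistic, Gaussian-mixture
  decomposition of S0 distributions (EM, 20 restarts, BIC model choice),
  and Wilcoxon rank-sum cohort comparison.
- **Energetics**: cost per relaxed turn α = π√(8·B·F_C) with B = L_p·k_BT;
  transition-energy ratio √(F_C1/F_C2); the duplex-vs-G4-path opening
  ledger; and the work difference between cohort mean curves,
  ∫ΔL_e dF (1 pN·nm = 0.14393 kcal/mol).
- **A synthetic-trace generator** (three-state occupancy, telegraph
  hopping, bead + tracking noise) that emulates the experiment so every
  stage is testable without proprietary raw data.

## Worked example

Simulate 100 wild-type force ramps in K⁺ at n_t = −40, classify their
variance profiles, and book the energetics from the detected forces:

```python
from g4twist import (TetherConfig, SimParams, simulate_ensemble,
                     variance_profile, classify_ensemble, build_ledger)

cfg = TetherConfig(construct="wt", ion="KCl")
prm = SimParams()
ramps = simulate_ensemble(100, -40, cfg, prm, seed=42)
profiles = [variance_profile(r, window=4.0) for r in ramps]
summary = classify_ensemble(profiles)
print(f"double peaks: {summary.n_double}/{summary.n} "
      f"({summary.pct_double:.1f} +- {summary.se_pct:.1f} %)")
print(f"F_C1 = {summary.F_C1_mean:.3f} +- {summary.F_C1_sd:.3f} pN")
print(f"F_C2 = {summary.F_C2_mean:.3f} +- {summary.F_C2_sd:.3f} pN")
ledger = build_ledger(F_C1=summary.F_C1_mean, F_C2=summary.F_C2_mean)
print(ledger.format())
```

prints

```
double peaks: 34/100 (34.0 +- 4.7 %)
F_C1 = 0.371 +- 0.004 pN
F_C2 = 0.690 +- 0.004 pN
Energy ledger (duplex opening vs G4-assisted opening)
  bending constant B          : 190.0 pN nm^2
  alpha(F_C1) per turn        : 74.0 pN nm = 11.0 kcal/mol
  alpha(F_C2) per turn        : 100.0 pN nm = 15.0 kcal/mol
  transition-energy ratio     : 0.73
  duplex opening cost         : 120.0 kcal/mol
  G4-path opening cost        : 88.0 kcal/mol
  net gain from G4 folding    : 32.0 kcal/mol
  reference 3 x 10.0 kcal/mol    : 30.0 kcal/mol
```

Read: 34% of ramps show the double-peak fingerprint (the generator's K⁺
folding probability is 0.35); the two characteristic forces are recovered
on the 0.01 pN grid; opening the G4-forming region via the G4 pathway
costs √(0.37/0.69) = 0.73 of the direct duplex route, i.e. 88 instead of
120 kcal/mol — a 32 kcal/mol gain, consistent with three G4s at
~10 kcal/mol each.

A command-line interface wraps the same library:

```
g4twist simulate --construct wt --ion KCl --turns -40 --n-ramps 10 --seed 7 --out traces/
g4twist analyze --in traces/ --turns -40 --window 4 --out report/
g4twist energetics --fc1 0.37 --fc2 0.69 --e-duplex 120
g4twist demo-paper
```

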