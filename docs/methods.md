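# Methods

## The measurement being modelled

A torsionally constrained double-stranded DNA tether (~6680 bp, contour
length L0 ≈ 2.0 μm, persistence length Lp ≈ 46 nm) is held in magnetic
tweezers at a fixed pulling force F and a fixed number of imposed turns
n_t, and the bead height — the tether end-to-end extension L_e — is
tracked at 300 Hz with ~10 nm axial resolution. A force ramp steps F in
0.01 pN increments, dwelling several seconds per force.

Under negative supercoiling the tether relaxes torsional stress either by
writhing into plectonemes (short extension) or, above a characteristic
force F_C, by opening a denaturation bubble (extended). At coexistence the
tether hops between the two arrangements and the extension variance
σ²(L_e) peaks; the force of the variance maximum is the operational
definition of F_C. A G-quadruplex-forming region inside the tether opens a
second relaxation channel: partial melting of that region followed by G4
folding, which absorbs ~7 turns at a lower force F_C1 < F_C2 and adds a
second variance maximum — the *double-peak fingerprint* of G4 folding.

## Synthetic-trace generator

No raw traces from this kind of experiment are publicly deposited, so
every analysis stage is exercised on a generator whose defaults encode the
study conditions quoted above.

**Occupancy.** Three states — plectonemic (P), G4 intermediate (G),
denatured bubble (D) — with sequential logistic weights

    s1(F) = 1/(1 + exp(−(F − F_C1)/w)),   s2(F) = 1/(1 + exp(−(F − F_C2)/w)),

and occupancies p_P = 1 − s1, p_G = s1(1 − s2), p_D = s1·s2 when the G4
pathway is available; p_P = 1 − s2, p_D = s2 otherwise. For n_t ≥ 0 the
duplex never opens (p_G = p_D = 0). Defaults F_C1 = 0.37 pN,
F_C2 = 0.69 pN.

**Mean extension.** L_e = p_P·Le_P + p_G·Le_G + p_D·Le_D with Le_D the
Marko–Siggia worm-like-chain extension at F, Le_P = max(0, Le_D − c·|n_t|)
for a plectoneme slope c (nm shortening per imposed turn), and
Le_G = Le_P + c·Δn_G4 where Δn_G4 = 72 bp / 10.4 bp·turn⁻¹ ≈ 6.9 turns is
the torsion absorbed when the whole G4-forming region opens as one event
(single- vs double-G4 substructures are not resolved by the measurement
and are not modelled separately).

**Fluctuations.** The trace is the mean plus two independent telegraph
processes, one per transition, each hopping by the extension quantum of a
single opening/closing event (amplitude c·Δn, with the turns quantum per
plectoneme↔bubble hop defaulting to the same 6.9 turns), plus a
mean-reverting AR(1) bead-relaxation term (SD 15 nm, time constant 50 ms)
and white tracking noise (SD 10 nm). The asymptotic variance is therefore

    σ² = s1(1−s1)·(c·Δn_G4)² + s2(1−s2)·(c·Δn_hop)² + σ_bead² + σ_track²,

maximal exactly at the characteristic forces. Modelling the fluctuation
amplitude as a per-hop quantum rather than the full P→D level separation
is deliberate: coexistence fluctuations exchange turns in nucleation-sized
quanta, and the full separation (>1 μm at n_t = −40) would produce a
single dominant variance maximum, contrary to what the double-peak
fingerprint looks like in this assay. With the per-quantum amplitudes the
two maxima are comparable in height, as observed.

**Kinetics.** Both telegraphs relax at 20 s⁻¹ (correlation time 50 ms,
scaled by `hop_rate_scale`). The sample variance of a correlated series
converges as 1 − 2τ/T in the window length T, so with τ = 50 ms the
estimate reaches ≥95% of its asymptote within ~3 s — matching the
empirical rule that acquisition windows longer than 4 s give stable
variances. (A slower choice, e.g. τ = 0.5–1 s, would need >20 s windows
and is inconsistent with that rule.)

**Transition width.** w = 0.04 pN. The width controls how far the two
mixing-variance bumps (separated by 0.32 pN) overlap: at w = 0.08 the
valley between them rises to ~83% of the peaks and the lower peak's
prominence falls below any reasonable detection threshold; at w = 0.04 the
bumps are cleanly resolved, giving variance-peak widths like those seen in
representative double-peak profiles. The value is a generator calibration,
exposed in `SimParams`.

**G4 availability.** Each ramp draws a Bernoulli flag with probability
p_fold, recorded as ground truth. Defaults per condition:
(wt, KCl) = 0.35, (wt, NaCl) = 0.18, (wt, LiCl) = 0.11,
(mut, KCl) = 0.12 — the measured double-peak rates at n_t = −40, which is
the calibration condition. Away from −40 turns a phenomenological
occlusion factor, gamma-shaped in |n_t| with its maximum near −30 turns
(the underwinding that opens a region about the size of the promoter),
scales the probability down: too little underwinding rarely opens the
region, too much buries it in plectonemes. For n_t ≥ 0 the probability is
zero. This n_t dependence is generator behaviour, not inference.

**Seeding.** A single master seed spawns per-ramp streams through numpy's
`SeedSequence`; traces within a ramp share one stream. Same seed, same
bits.

**What the generator does not emulate.** Camera image formation, bead
tracking, force calibration error, drift, torque, sequence-level melting
heterogeneity, hairpin/cruciform side reactions in the mutant, and
sub-structure (one vs two G4s) of the folding region. Passing tests
demonstrate that the analysis recovers what the generator programs under
realistic noise; they cannot certify instrument-specific artefacts.

## Analysis chain

**Variance profile.** Unbiased sample variance of the trailing analysis
window (default 4 s) of each trace, one value per grid force.
`variance_convergence` exposes the window dependence.

**Peak classification.** The profile is smoothed with a Gaussian kernel
(SD 0.03 pN); local maxima are kept if their prominence is at least 0.25 ×
the global maximum and they are at least 0.10 pN apart; 0/1/≥2 maxima map
to no-peak/single/double (the two most prominent define a double; ties
broken by height, then lower force). Characteristic forces are read at the
smoothed-profile maxima — the 0.01 pN grid makes sub-grid interpolation
unnecessary. All thresholds are explicit in `PeakDetectionOptions`; a
stability check in the test suite verifies that halving the smoothing
changes the ensemble double-peak rate by <5 percentage points.

**Ensemble summary.** Double-peak percentage with binomial standard error
100·√(p(1−p)/n), and mean ± SD of F_C per peak class.

**Worm-like chain.** Marko–Siggia interpolation, fitted in the
extension-versus-force direction (as plotted) by Levenberg–Marquardt,
weighted 1/sd where per-point SDs exist (a documented switch disables
weighting). The inverse L_e(F) is a safeguarded vectorised Newton solve,
matched to 1e-12 relative residual. Initialisation: L0 = 1.05 × maximum
observed extension, Lp = 50 nm; bounds L0 ∈ (0, 2×max], Lp ∈ [1, 200] nm.
Non-convergence raises; there are no silent defaults.

**Logistic steepness.** L_e = a + b/(1 + exp((F − F1)/S0)) fitted as
printed. With this exponent the curve increases with force only for
b < 0, so rising curves recover negative b; the sign is reported, not
flipped, and S0 (the steepness, pN) is invariant to the convention.
Initialisation a = min, b = range, F1 at half range, S0 = 0.5 pN.

**S0 mixture.** Gaussian mixture by expectation–maximisation
(scikit-learn), 20 restarts, best likelihood kept; degenerate zero-variance
solutions rejected and refit with a stronger covariance floor. k = 1 and
k = 2 are both fitted and compared by BIC; components are reported ordered
by mean and relative areas equal the weights. S0 enters untransformed.
Cohorts are compared with the two-sided Wilcoxon rank-sum test (normal
approximation, tie-corrected); the test suite cross-checks the statistic
against exhaustive enumeration at n = 4 + 4.

**Energetics.** Cost per relaxed turn α = π√(8·B·F_C) with B = Lp·k_B·T;
the transition-energy ratio √(F_C1/F_C2) (B cancels — asserted to machine
precision); the ledger multiplies the literature duplex-opening cost
(120 kcal/mol for the whole region) by the ratio and books the difference
as the net gain, to be compared with 3 × ~10 kcal/mol for three G4s. The
work difference between cohort mean curves is ∫(Le_hi − Le_lo) dF,
trapezoidal, converted at 1 pN·nm = 0.14393 kcal/mol; this equals the
pulling-work difference ∫F dLe when the curves coincide at the endpoints
(a warning fires if they do not, beyond 10% of the peak separation).
k_B·T is fixed at 4.11 pN·nm (298 K). Supercoiling density is
σ = n_t/(N_b/10.4); note that −40 turns gives −0.062 for N_b = 6680 but
−0.070 for N_b ≈ 5943 (the base-pair count implied by the fitted contour
length at 0.34 nm/bp); both usages appear in practice and both are
demonstrated in the tests, neither silently preferred.

## Validation experiments and problem sizes

The recovery experiments in `g4twist.experiments` (used by the test suite
and `scripts/acceptance.py`) run at desk scale on one CPU in under a
minute each:

- WLC recovery: 200 replicate untwisted curves, 25 log-spaced forces in
  0.03–3 pN, heteroscedastic noise from the equipartition estimate
  √(k_B T·dLe/dF) scaled as an average of 25 repeats (conservative —
  published average curves pool hundreds).
- Logistic recovery: 100 replicates, 60 forces in 0.05–3 pN, 40 nm
  Gaussian noise on the mean curve (transition-region per-measurement SDs
  of ~400 nm divided by ~100 averaged curves).
- Fingerprint rate: 400 ramps on the full 296-point grid, 5 s dwell, 4 s
  window; characteristic forces: 200 + 200 ramps; work area: 60 + 60
  ramps with the generator calibrated so its programmed stabilization,
  c·Δn_G4·(F_C2 − F_C1), equals 24 kcal/mol.

## Known limitations

- The occupancy model is phenomenological; it reproduces the analysed
  observables (mean curves, variance peaks, their statistics) without
  committing to a microscopic torque-balance model, and its plectoneme
  slope (55 nm/turn default) and hopping quanta are literature-order
  placeholders, configurable but not fitted.
- Fitted S0 values of generator mean curves are smaller than those of the
  real averaged curves (the generator's transitions are sharper than the
  molecule-to-molecule spread that broadens published averages); the
  steepness pipeline is therefore validated on curves synthesised from
  the logistic truth itself, and on the generator only for orderings and
  mixture concordance.
- The classifier thresholds are tuned for the default generator geometry;
  on real data with different peak-height ratios the prominence fraction
  may need revisiting (it is a single explicit parameter).
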