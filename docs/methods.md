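# Methods

This note documents the models implemented in `allokin`, the conventions and
defaults behind them, what the synthetic generators do and do not emulate,
and the numerical choices a user fitting real data should know about.

## Units and conventions

Concentrations are in nM, kinetic time in minutes, rates in min⁻¹, uptake
velocities in fmol/min. Trajectory durations are in µs, frame intervals in
ns (1 µs = 1000 ns), transition rates per µs, coordinates and distances in
Å, angles in degrees wrapped to (−180, 180]. Frames are 0-indexed with
time = frame × frame_interval. All tabular I/O is UTF-8 comma-delimited
text with dot decimals and units embedded in column names (`conc_nM`,
`time_min`, `k_per_min`, `time_ns`, `angle_deg`, `distance_A`).

Randomness is always explicit: simulators take a seed, and the dissociation
simulator derives per-curve substreams from (seed, condition index,
replicate index), so adding a condition never changes the noise of existing
curves.

## Occupancy-gated dissociation model

A radioligand pre-bound at the central S1 site dissociates first-order with
rate `k_buffer`. A vestibule (S2) ligand at concentration c occupies its
site in rapid equilibrium and suppresses the observed rate:

    k_obs(c) = k_buffer · (1 − emax · cʰ / (cʰ + IC50ʰ))

- `k_buffer` — control rate; the assay is run at a temperature where the
  control half-life is ~15 min, so the simulator default is ln2/15 ≈ 0.0462
  min⁻¹.
- `allo_ic50` — the allosteric potency: the concentration halving the rate
  (exactly, when emax = 1 and h = 1). This is the model's definitional
  anchor.
- `emax` (default 1) — fraction of the rate suppressed at saturation. The
  dissociation data the model emulates are plotted as ratios without
  visible lower plateaus, so whether saturation fully arrests dissociation
  is not observable; full impedance is the default and `emax` is exposed.
- `hill` (default 1) — occupancy cooperativity; single-site occupancy has
  slope 1 and no published slopes suggest otherwise.

Simulated signals are `ns + B₀·e^(−k_obs(c)·t)` at the standard seven
sampling times (5, 10, 15, 20, 30, 50, 70 min) with multiplicative Gaussian
noise of relative sd `noise_rel` (default 0.02). Proportional noise is the
right first-order description of scintillation counts at these levels;
the generator does not emulate plate-position effects, pipetting error
correlated within a replicate, or filter-washing losses — so passing
recovery tests demonstrate estimator correctness under the stated noise
model, not robustness to systematic artifacts. Rebinding after the dilution
step is assumed fully blocked (as the chase design intends); there is no
two-ligand competition for S1.

## Rate fitting

`fit_monoexponential` is two-stage: a log-linear regression of log(signal)
on time supplies starting values, then bounded nonlinear least squares
refines `ns + B₀·e^(−kt)` (plateau fixed at 0 by default — the assay
subtracts nonspecific binding — with `with_plateau=True` exposed).
Convergence tolerance is 1e−10 on the relative parameter change, max 500
iterations; non-convergence is flagged on the result, never silent.

The default objective minimizes **relative** residuals (`weighting=
"relative"`), matching the proportional error structure of counting data.
This matters for uncertainty: with 7 points and 2 parameters the standard
error of k from the weighted fit is calibrated — in Monte-Carlo, the
t(0.975, df=5) ≈ 2.57 interval covers ~95%, while a plain unweighted fit
under proportional noise covers only ~81% at ±1.96·SE. Note the normal
1.96 multiplier itself covers only ~89% at df = 5 regardless of weighting;
use the t quantile for honest 95% intervals at this design size.

Rates are fit per replicate and aggregated downstream (averaging of
normalized ratios per concentration), rather than pooling points across
replicates into one fit.

## Allosteric potency

Ratios `k_[drug]/k_buffer` (buffer = mean rate of the c = 0 control rows)
are fit with

    ratio(c) = bottom + (top − bottom) / (1 + 10^(h·(log₁₀c − log₁₀IC50)))

with top fixed at 1, bottom fixed at 0 and h fixed at 1 by default (all
three can be freed; competition binding frees top and bottom). The location
parameter is optimized as pIC50, so the SE lives on the log scale and the
reported concentration interval `10^(9−(pIC50±SE))` nM is asymmetric, with
the IC50 as its geometric mean. Flat curves (span < 0.1) and fits drifting
more than two decades outside the tested concentration range are returned
flagged, not as numbers.

When ≥3 replicates exist per concentration, points are weighted 1/SD²;
because a 3-replicate SD is itself very noisy, weights are clipped to one
decade around their median so a chance near-zero SD cannot dominate the
fit.

ΔAP (fold change in potency, mutant/WT) is stored as the exact ratio with a
`rounded` accessor applying report precision (integer at ≥10, one decimal
below). A censored mutant IC50 (a lower bound, potency ablated beyond the
tested range) propagates to a censored, lower-bound fold change.

## Equilibrium binding and uptake

Competition curves use the same logistic machinery with free span;
monotone-increasing (wrong-direction) data are flagged. Cheng–Prusoff
`Ki = IC50/(1+L/K_D)` converts competition IC50s to inhibition constants;
for uptake inhibition the package applies it with L = substrate
concentration and K_D = K_M — the conventional choice, recorded here
because the source assays do not specify the transformation (fit outputs
carry this note in their metadata).

Michaelis–Menten fits are least squares on `v = V_max·S/(K_M+S)`,
initialized from a double-reciprocal regression; a K_M collapsing below
10⁻⁶ of the largest substrate level (velocity flat in S) raises instead of
returning a degenerate estimate. The mixed-inhibition model

    v = V_max·S / (K_M·(1 + I/K_ic) + S·(1 + I/K_iu))

is fit globally over all inhibitor levels; internally the optimizer works
with the inverse constants 1/K_ic, 1/K_iu bounded at ≥0, so the pure
competitive limit K_iu = ∞ is exactly representable at the boundary rather
than an escape to infinity. Apparent per-level parameters obey
`K_M,app = K_M(1+I/K_ic)/(1+I/K_iu)` and `V_max,app = V_max/(1+I/K_iu)`;
the mechanism classifier compares the highest level to control with a 10%
relative tolerance (matching typical reported SE magnitudes): K_M up &
V_max flat → competitive; V_max down & K_M flat → noncompetitive; both →
mixed; anything else → indeterminate.

## Synergy and microdialysis

Bliss independence: expected remaining activity under two independent
inhibitors is `f_a·f_b`; `synergy_excess = f_expected − f_observed` is
positive under synergy. Dialysate fraction series (20-min bins) are
normalized to the mean of the first `n_basal` pre-perfusion fractions
(default 3, matching the plotted normalization; the sampling protocol
collects four basal fractions, so `n_basal=4` is equally supported —
the discrepancy between the two conventions is inherent to the source
design, not resolvable here). AUC over the perfusion window (default
20–160 min) is the trapezoidal integral of (percent − 100), i.e. release
above baseline; the 100% subtraction is a flag (`baseline`) since an
unsubtracted area is equally defensible. Probe-recovery correction is the
plain product perfusate × recovery fraction.

## Synthetic trajectories and conformational statistics

Rotamer dynamics are a continuous-time Markov chain over
(gauche+, gauche−, trans) with generator Q (µs⁻¹). Simulation is an exact
jump process (exponential holding times, embedded-chain jumps — chosen over
matrix-exponential sampling because it is exact, simple, and yields the
true jump count for convergence checks), discretized at the frame interval.
The stationary distribution solves πQ = 0 with a strong-connectivity check.
Dihedral emissions are state mean + wrapped Gaussian (default sd 15°) —
wrapping, not truncation, is what keeps the trans mode at ±180° honest;
distance emissions are state-conditional Gaussians floored at 0 Å.

What the CTMC generator emulates is the *statistical* structure the
conformational analyses assume — Markovian state switching with
state-conditional emissions and stationarity. Real MD trajectories have
non-Markovian memory, within-state anharmonicity, and slow drift that the
generator deliberately omits; tests passing on CTMC data validate the
estimators, not any specific molecular system.

Analysis conventions:

- χ1 is the N–CA–CB–X dihedral with X from a built-in per-residue table
  (Thr → OG1, Phe → CG, …); the signed angle uses the standard atan2
  construction (verified against an independent MD-toolkit oracle in the
  tests).
- Rotamer bins are fixed 120° sectors as half-open intervals:
  gauche+ = (0, 120], gauche− = (−120, 0], trans otherwise. Angles are
  wrapped first; the sign convention is declared in output metadata rather
  than assumed to match any particular plotting convention.
- Bootstrap histograms pool all trajectories of one condition first, then
  draw (by default) 500 samples of 5000 frames with replacement, reporting
  per-bin mean and sd of the relative frequency. With n_boot = 1 and a
  full-pool sample without replacement this reduces exactly to the plain
  histogram.
- Transition rates count raw consecutive-frame label changes (optionally
  restricted to direct changes between a named state pair), summed over
  trajectories and divided by total observed time. Frame discretization can
  only miss jumps, so the estimate is a lower bound on the jump rate and
  rises toward it as the frame interval shrinks; no dwell-time debouncing
  is applied by default.
- Pairwise RMSD matrices superpose every frame pair with the Kabsch
  algorithm (SVD with reflection correction by the sign of the smallest
  singular value; rank-deficient/collinear configurations raise). By
  default pairs are aligned on the RMSD selection itself — a pure
  pose-shape comparison in which rigidly related poses are identical; pass
  a separate `align_selection` (e.g. the binding-site atoms) to measure
  ligand displacement within a common reference frame, which is what the
  two-pose examples and tests do. All pairs are computed with one batched
  SVD; the default bootstrap is 10 samplings of 500 frames (a 500×500
  matrix each).
- Frame filtering by distance uses strict inequality at the threshold
  (default 4.5 Å), so boundary values are excluded.

## Problem sizes in tests and the acceptance script

The Monte-Carlo checks use sizes chosen to make their statistical
tolerances meaningful at interactive runtimes: 200 end-to-end pipeline
runs (11 concentrations × 3 replicates each) for median-IC50 recovery,
500 curves for SE calibration, 10 replicate 50-µs CTMC trajectories
(~250k frames) for occupancy/rate validation, 1000 random pairs for the
superposition oracle, and the full published bootstrap sizes (500 × 5000
for histograms, 10 × 500² for RMSD matrices). The whole suite runs in a
few minutes on one CPU.

## Known limitations

- The logistic potency fit assumes a single S2 site and no cooperative
  ternary-complex coupling; no Schild-style affinity decomposition is
  attempted.
- Bi-exponential or dispersed-rate dissociation is out of scope; data with
  genuine rate heterogeneity will show it as lack of fit, not as a second
  component.
- The uptake Ki convention (L = S, K_D = K_M) is a documented choice, not a
  derivation.
- CTMC-based validation bounds what the trajectory statistics can promise
  on real MD data (see above).
- The mechanism classifier is a two-point trend test, deliberately simple;
  intermediate-level curvature is ignored.
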