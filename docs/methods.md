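# Methods

## Signal model

WEPCAST MRI labels arterial water at the neck with a pCASL train (duration
τ, default 4000 ms) and reads out a flow-encoded phase-contrast image of the
superior sagittal sinus at `t_acq = τ + PLD` (PLD default 3000 ms), with
t = 0 at the start of labeling. Magnetizations are normalized so equilibrium
venous/arterial blood is 1 per 100 mL and equilibrium tissue is λ per 100 g.

The venous signal mixes two populations weighted by the water extraction
fraction E:

- **Tissue-routed path.** An extracted spin obeys the ASL-type tissue
  equation `dMt/dt′ = (λ − Mt)/T1,t + f·(Ma(t′) − Mt/λ)` from t′ = 0 to its
  capillary-exit instant `t_acq − δv` (CBF f converted to mL·g⁻¹·ms⁻¹ as
  f/6·10⁶), where `Ma(t′)` is the arterial inflow magnetization. At exit the
  magnetization is divided by λ (partition coefficient) and relaxes with
  blood T1 toward 1 for the remaining δv.
- **Vessel-only path.** An unextracted spin crosses the labeling plane
  `δa + δv` before acquisition and relaxes with blood T1 the whole way. The
  arterial transit time is tied to the venous transit time per dispersion
  bin: `δa = 0.555·δv`.

Transit-time dispersion: δv ~ N(δ̄v, σ²) with σ = 1161.7 ms, represented as
a 300-bin histogram with centers evenly spaced on [0, 9000] ms, truncated
and renormalized. Bins with `δv ≥ t_acq` have a zero-length tissue phase
(the tissue value is equilibrium λ, so the tissue-path signal reduces to
blood relaxation from 1 over the full window); vessel-only spins whose
crossing predates the labeling window are unlabeled.

**Background suppression** is modeled as instantaneous global inversions
m → (1 − 2ε)m at the scheduled instants (ε = efficiency, default 1),
applied to tissue, venous and in-transit arterial spins alike. Labeling is
multiplicative: at its plane-crossing a labeled spin's magnetization — the
control-condition value it would otherwise have — is scaled by (1 − 2α),
α = 0.86. This convention reduces to the familiar bolus amplitude
`1 − 2α·e^(−δa/T1,b)` when no pulse precedes the crossing and guarantees
exactly that α = 0 makes control and label identical, a conservation
property the test suite asserts to machine precision.

All trajectories are solved **piecewise in closed form**. Between events
(bs pulses, bolus edges, pulse-echo points u + δa where a pulse enters or
leaves a labeled spin's transit history) the arterial inflow has the exact
form `c + b·e^(−t′/T1,b)`, and the tissue equation is linear with an
exponential forcing, so each segment propagates analytically. A fine-step
(0.1 ms) Runge-Kutta integrator exists only in the test suite as an
independent oracle; closed form and oracle agree to ~1e−15 relative.

### Why background suppression is load-bearing

Without bs pulses every compartment starts at equilibrium and the control
signal is identically 1 — it carries no transit-time information and the
two-parameter inversion is singular. Mid-sequence inversions create
transient tissue/blood contrast (T1,t = 1056 ms vs T1,b ≈ 1700 ms) that
makes the control signal δv-sensitive. The default schedule (1600, 2900) ms
is chosen on that basis; it does **not** null tissue at acquisition (a
schedule that does, e.g. pulses at 3000/6313 ms, drives the venous signal
negative and conditions the inversion far worse). One consequence of ideal
inversions is parity: the sign of a spin's label–control difference flips
with each pulse it experiences after labeling, so path-wise differences can
be negative even though the dispersion-averaged difference is positive.

## Estimation

A per-subject dictionary evaluates the forward model on the grid E =
0.400…0.999 (step 0.001, 600 values) × δv = 2000…4500 ms (step 25 ms, 101
values) for the subject's CBF and blood T1. Because the transit histogram is
fixed, the 300 per-bin path values per condition are computed once and every
grid entry is a weighted combination — a full build takes ~20 ms. Measured
control/label ROI means are divided by the M0 scan and corrected for the M0
scan's finite repetition time (the scan *underestimates* M0 by
`1 − e^(−TR/T1,b)`, ≈0.3% at TR = 10 s, so the normalized signal is
multiplied by that factor; the correction is a documented toggle, default
on). Lookup is unweighted Euclidean nearest neighbor in the 2-D
(control, label) space; exact ties break to smaller δv then smaller E, and
matches on any grid edge are flagged.

### Precision of the discrete inversion

The two grid axes are strongly anisotropic in signal space: one 25 ms δv
step moves the signal pair ~30× more than one 0.001 E step (per-step
Jacobian singular values ≈ 6.6e−4 and 1.4e−5 at the default operating
point). Discrete nearest neighbor therefore aliases δv quantization into E:
over 1000 noiseless off-grid truths the E error is 0.003 median / 0.009
p95 / 0.05 max, while δv lands within one grid step 99.3% of the time
(median 7 ms). This is a property of the grid geometry, not of the signal
model — on-grid inputs self-match exactly. ROI- or subject-level averaging
reduces the E aliasing to ~0.003. Sub-grid refinement (local interpolation)
would remove it but is deliberately not applied: the estimator is the
discrete dictionary lookup.

## Quantification

`PS = −ln(1 − E)·f` (Renkin–Crone single-capillary exchange), with E < 1
enforced. Global CBF is total arterial inflow (mL/min) divided by brain
mass, `f = flow / (volume × ρ) × 100` in mL/100 g/min with brain density
ρ = 1.06 g/mL (configurable; the density conversion affects only the
absolute scale).

## Blood T1

The Look-Locker saturation-recovery series (first sample 150 ms after
saturation, 150 ms spacing, 30 samples, 10 averages) is fitted with
unweighted nonlinear least squares to `S(t) = St + S0·(1 − e^(−t/T1,b))`
— the physically meaningful sign of the exponent — with St absorbing
partial-volume tissue signal. Initialization: St = min(S), S0 = max − min,
T1 = 1700 ms; T1 bounded to [500, 4000] ms; standard errors from the
Gauss-Newton curvature. Averages are pooled before fitting by default
(per-average fitting is available for empirical variance). With ideal 90°
excitations and full inter-pulse blood replenishment no Look-Locker
correction applies. A flat series raises; non-convergence returns a flagged
result. Noiseless round-trips recover all three coefficients to ≤0.1%;
with 3%-of-S0 noise and 10 averages the median |T1 error| is <40 ms.

## Legacy peak-detection comparator

The prior estimator finds the ROI with the maximal normalized difference
signal, assumes its venous bolus arrival time is τ/2 + PLD, and inverts the
peak for E alone. Here the inversion reuses this package's forward model
with the total label-plane→vein transit *fixed* at τ/2 + PLD (so
δv = BAT/(1 + 0.555)); the dispersion kernel is kept, because under ideal
bs pulses the parity effect above makes a dispersion-free single-transit
difference disagree in sign with dispersed data, leaving no consistent
inversion. What defines the method — and biases it by ~±0.025 in E when the
true arrival deviates by ±0.5 s — is the fixed-arrival assumption, which is
preserved. Equal peak ties break to the anterior-most ROI with a warning;
flat or all-negative profiles raise; peaks outside the attainable model
range clamp with the bias sign reported.

## Synthetic data

Generators are pure functions of (parameters, seed) and emulate:

- **ROI tables**: 8 ROIs anterior→posterior, spatially constant E (default
  0.9) and a linear δv profile (default 3000→3600 ms — illustrative of the
  qualitative in-vivo range, not a measured profile); signals are forward
  simulations scaled by a nominal M0 with additive Gaussian noise on the
  ROI means (complex-difference ROI means are effectively Gaussian at these
  SNRs; a Rician option exists for low SNR). The M0 channel emulates the M0
  *scan*, i.e. M0·(1 − e^(−TR/T1,b)), so the pipeline's recovery correction
  is exercised rather than bypassed.
- **Cohorts**: per-subject truths drawn from normal distributions — E
  (0.9, 0.03), δv (3300, 300) ms, f (55, 6) mL/100 g/min, T1,b (1742, 100)
  ms — clipped to physiological ranges.
- **Saturation-recovery series** on the default Look-Locker schedule.

Measurement-noise default: σ = 1.5e−4 of M0 on ROI-mean signals, calibrated
once so that noise alone propagates to an inter-subject PS CoV of ~5%, the
scale of the reported in-vivo inter-visit reproducibility of this class of
measurement (measured gain: 2.8% PS CoV at σ = 1e−4, 8.7% at 2.5e−4). The
generators do not model the spatial shape of the bolus along the vessel
(each ROI is an independent forward simulation at its own δv; the ROI
difference then falls monotonically with δv, so "peak" experiments place
the bolus-center transit at the anterior ROI), nor motion, physiological
noise, partial volume in the WEPCAST ROIs, or k-space/reconstruction
effects. Passing tests therefore validate the estimator chain under the
stated statistical structure, not those acquisition-level confounds.

## Monte-Carlo experiments

- **Blood-T1 heterogeneity**: 200 replications of 12-subject cohorts with
  T1,b SD 100 ms; each subject estimated once with the sex-default T1 and
  once with the subject's true T1 (an idealized measurement). Using true T1
  lowers the inter-subject PS CoV (means ~39% → ~19% under the default
  cohort spread) in ≥95% of replications.
- **Bolus-arrival mismatch**: trials perturb the true venous BAT by exactly
  ±500 ms (random sign) around τ/2 + PLD, the reported in-vivo spread. The
  joint inversion (subject-level E = mean over 8 ROIs, as the method is
  used) errs no more than the single-peak fixed-arrival estimate in
  ≥~95% of trials (median |E error| ~0.003 vs ~0.024).

## Numerical choices and edge cases

- Pulse windows are half-open `(t_start, t_end]`; a pulse exactly at a
  compartment-transition instant belongs to the earlier phase.
- The tissue ODE's degenerate resonance (decay rate equal to 1/T1,b) is
  handled by a series branch when |B − 1/T1,b| < 1e−12·B.
- The 300-bin histogram's quantization error is ~1e−4 relative for
  dispersion means well inside the transit range, rising to ~1e−3 when
  substantial mass sits on the labeled-bolus edge kink (δv ≈ 1930 ms for
  the default protocol).
- Initial condition: all compartments at equilibrium at t = 0 (no
  pre-saturation is modeled; if the real sequence pre-saturates, control
  and label signals would both shift).
- Experiment problem sizes (200 replications × 12 subjects; 100 trials;
  100 recovery draws) keep a full run in tens of seconds while holding
  Monte-Carlo fractions stable to a few percent across seeds.

## Known limitations

- Transverse magnetization, flow-encoding phase, slice profiles and B1 are
  out of scope; bs pulses are ideal instantaneous inversions by default.
- The actual bs schedule of the in-vivo sequence is not public; results
  that depend on the schedule (notably inversion conditioning) are stated
  for the package default (1600, 2900) ms.
- The E precision of the discrete dictionary inversion is bounded by the
  aliasing analysis above (~±0.01 single-ROI); applications needing finer E
  should average ROIs or enable a sub-grid refinement extension.
- δa/δv = 0.555, σ = 1161.7 ms and T1,t = 1056 ms are literature constants
  shared across subjects; the sensitivity harness quantifies their ±10%
  influence (PS shifts < 10% on default synthetic data).
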