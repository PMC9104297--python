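# Methods

## Signal model and preprocessing

A skin-conductance channel is modelled as the sum of a slowly varying
tonic level (SCL), a phasic component made of discrete skin conductance
responses (SCRs), stage-specific motion artifacts, and white measurement
noise.  Analysis runs at 8 Hz (resampled from the 100 Hz acquisition
rate); sudomotor dynamics live below ~0.4 Hz, so nothing physiological is
lost.  Resampling is polyphase with a Kaiser(β = 14) anti-alias window —
the long window keeps passband ripple below 10⁻⁸ so constant and slow
content pass through unchanged.

The analysis low-pass (order 6, 0.6 Hz) is applied as the *exact squared
analytic Butterworth magnitude* in the frequency domain on an
odd-reflected (value- and slope-continuous) padded copy of the signal.
This is the response of an ideal forward–backward pass: exactly zero
phase, DC gain exactly 1, and the magnitude `1/(1+(f/f_c)^{12})` at every
frequency.  A bilinear-transform discrete design would deviate
substantially from that magnitude near and above the cutoff at so low a
working rate (frequency warping), which matters because SCR morphology —
and therefore event-time recovery — depends on the filter's true shape.
Stage segmentation uses half-open `[start, end)` windows; a sample on a
shared boundary belongs to the later stage.

The low-pass is applied only on the decomposition/index path.  The
spectral quality metric consumes the resampled-but-unfiltered signal: its
noise band (f > 0.4 Hz) would be emptied by construction by a 0.6 Hz
filter.

## Decomposition

Each segment solves the strictly convex program

    min ½‖Kp + Bℓ + Cd − x‖² + α·1ᵀp + ½γ‖ℓ‖²,   p ≥ 0,

with `K` the convolution by a unit-peak biexponential kernel
(τ_rise = 0.7 s, τ_decay = 2.0 s — standard sudomotor constants), `B` a
cubic B-spline basis with knots every 10 s, `C` offset + linear drift
(unpenalized, so absolute µS levels are preserved), α = 8·10⁻⁴,
γ = 10⁻².  Since `p ≥ 0`, the L1 term is linear on the feasible set and
the problem is a bound-constrained QP.

**Kernel/preprocessing consistency.**  When invoked from the pipeline the
kernel is passed through the same zero-phase low-pass as the data
(including ~4 s of acausal pre-ringing taps).  Without this the filter's
ringing around each SCR is unrepresentable by the causal kernel and the
optimizer compensates with dense spurious driver activity; with it, a
clean SCR collapses to a few driver taps at the true event time.
`decompose()` called directly uses the raw biexponential.

**Solver.**  Block principal pivoting on the KKT system (the optimal
driver is sparse, so only small dense solves on the working set are
needed), with the Kim–Park backup rule for finite termination and dense
Gram blocks cached per segment geometry.  Near-collinear neighbouring
kernel columns make exact pivoting stall on noisy segments over phasic
changes of order 10⁻² µS — far below measurement noise — so the relative
KKT tolerance starts at 10⁻⁷ and escalates stepwise (×10, ×100, ×500)
if iteration counts pass 15/25/35.  Clean segments converge at the base
tolerance; typical 120 s segments solve in 30–150 ms.  A bound-constrained
L-BFGS route over the same objective (FFT operators, analytic gradients)
serves as fallback and as an independent cross-check in the tests,
together with a dense trust-region QP reference.  A ridge of 10⁻⁹ on the
driver block keeps the QP strictly convex (the kernel's first tap is
zero, so trailing convolution columns are otherwise rank-deficient).
The residual is defined as `x − phasic − tonic`, making the additive
reconstruction identity exact by construction.

Decomposition is per stage (indices are reported per stage); the
correlation analysis concatenates per-stage components over the
contiguous baseline + stress window rather than re-decomposing the joint
window, trading a possible tonic seam at the boundary for halved compute.

## Indices

SCR detection: local maxima of the segment's phasic trace with amplitude
at least 5 % of that segment's largest peak amplitude, separated by at
least 1 s (jitter suppression).  The relative threshold makes counts
invariant to channel gain, which differs strongly across body sites.  Its
flip side is honest and kept: segments with no strong SCRs (unresponsive
sites) get a low absolute threshold and count noise ripples, producing
elevated but stage-insensitive counts — the same signature visible in
published index tables for poorly responsive sites.  Phasic/tonic means
and variances use the unbiased (n−1) estimator.

## Quality

`Pn = P(f > 0.4 Hz)/P(f > 0)` from a Welch periodogram: Hann window, 32 s
segments (≥ 7 averages on a 120 s stage), 50 % overlap, per-window linear
detrend.  Detrending is essential: with the conductance mean retained the
DC bin dominates total power and Pn of every channel collapses toward
zero.  Band powers are trapezoid integrals with the 0.4 Hz edge
interpolated onto the grid, so below-band and above-band fractions sum to
1 exactly.  The band's upper edge is the working Nyquist (4 Hz).

## Statistics

* Within-subject Pearson correlation of each site against the reference
  (finger), per component (raw/phasic/tonic), over baseline + stress.
* Baseline-vs-stress per index: each group standardized and gated by a
  one-sample Kolmogorov–Smirnov test against the standard normal
  (pass = p ≥ 0.05, both groups must pass); then a two-sided paired
  t-test, else the two-sided Wilcoxon rank-sum test.  The rank-sum
  fallback is deliberately unpaired (a signed-rank option exists behind
  `PipelineConfig.paired_fallback`).  No multiple-testing correction —
  raw p-values are reported per index and site.
* ROC: thresholds sweep +∞ and all distinct observed values; predicted
  stressed when value ≥ threshold; AUC by trapezoid.  Indices that
  decrease under stress give AUC < 0.5 and are reported as-is.
* Hydration-style progression: per stage, the count of subjects whose
  site correlation exceeds a cut (default 0.5, strict inequality);
  subjects missing any stage are excluded from all.

## Synthetic cohorts

The generator is the generative mirror of the decomposition model.  Per
subject: a central homogeneous Poisson event stream (3 events/min,
doubled during the Stroop stage); each site keeps an event with its
`responsiveness` probability and scales truncated-normal amplitudes
(0.3 ± 0.15 µS) by its gain; phasic = events ⊛ unit-peak biexponential;
tonic = site level plus a random-walk drift smoothed over 20 s (the
smoothing scale keeps generated drift inside what the 10 s-knot tonic
model can express — a 4-site recording whose "tonic" wiggles at 0.2 Hz
would contradict the model the generator mirrors); walking adds 0.45–3.5
Hz band-limited noise scaled per site; weightlifting adds Poisson-timed
~1 s smoothed square pulses of random sign; white measurement noise
(0.02 µS) tops it off.  Everything is reproducible from a master seed via
per-subject seed spawning, and the ground truth stores every component
and event list.

Default site profiles: responsive finger (0.9) and foot (0.95) with small
drift (0.01 µS/√s, calibrated so the finger–foot raw correlation lands in
the high range reported for real palmar/plantar pairs), poorly responsive
forehead and neck (0.2 — partially hydration-limited but not stress-blind)
with larger drift, foot-dominant walking noise, finger/neck-dominant
lifting artifacts, site-typical tonic levels.  An optional
`responsiveness_end` ramps responsiveness linearly over the session to
emulate slow electrode-site hydration.

What the generator does **not** emulate: shared tonic trends across sites
(thermoregulation), so synthetic tonic correlations hover near zero where
real ones can be substantial; subject-level heterogeneity in rates and
amplitudes; non-stationary artifact spectra; electrode drying.  Passing
tests therefore validate the machinery and its qualitative site
contrasts, not quantitative agreement with any particular human dataset.

## Problem sizes in the test suite

The qualitative multi-site check runs 20 cohorts of 10 subjects
(baseline + stress decomposed per site; four-stage quality), chosen to
keep the full suite around three minutes on one CPU.  In that check the
head/neck-like sites are configured fully stress-blind (responsiveness
0), encoding the contrast between responsive and non-responsive sites;
at weak-but-nonzero responsiveness those sites acquire a genuine small
stress effect (and a systematic threshold-shift effect on noise-dominated
SCR counts), which is a different scientific scenario from the one the
contrast tests.  Monte-Carlo calibration tests use 1000 null replicates
(type-I error), 500 (AUC properties), and 100–200 (spectral limits).
The acceptance script analyses the full default cohort of 23 subjects.

## Known limitations

* SCR counts on noisy segments depend mildly on the solver's working
  tolerance, because the relative threshold picks up optimizer-level
  phasic ripples; the tolerance staircase bounds this far below the
  between-subject variability that the statistics operate on.
* The rank-sum fallback tests distributional equality, not a paired
  location shift; it is kept for fidelity to the gated procedure it
  implements.
* Whole-recording (rather than per-stage) decomposition is not exposed
  as a pipeline mode; `decompose()` accepts arbitrary-length inputs if
  needed.
* Pn compares sites fairly only at a common working rate; it is a ratio,
  so a site with little EDA content can show high Pn from modest noise.
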