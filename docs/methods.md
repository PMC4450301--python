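# Methods

This note records the model conventions, estimator choices and numerical
decisions behind `fdeeg`, in the spirit of a statistical package's model
documentation.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model overview and assumptions

The EEG record `V(t)` is treated as a fractal (not merely stochastic) time
series generated by a random-walk-like transport process in an abstract
"informational" space.  Its governing equation is a fractional diffusion
equation of temporal order `2H`, which interpolates between a Poisson
equation (`H = 0`), classical diffusion (`H = 1/2`) and a wave equation
(`H = 1`).  Three consequences shape the implementation:

- the response to an external flux `φ(t)` is the Riemann–Liouville
  fractional integral of order `H` of the flux, scaled by
  `τ^{1/2−H} D_eff^{−1/2}` (obtained by substituting the relaxation-time
  relation `C = (D_eff/τ)^{1/2}` into the solution prefactor
  `C^{2H−1} D_eff^{−H}`; an alternative "literal" `1/D_eff` prefactor is
  kept behind a flag for comparison);
- under constant flux the response grows as `t^H`, the classical `√t`
  random-walk growth at `H = 1/2` and linear growth at `H = 1` — both are
  asserted to 1e-6 by the growth-exponent tests;
- the effective diffusivity is time-dependent,
  `D_eff/D = [2^{1−H} Γ(H) z^{1−H} I₀(z) e^{−z}]²` with `z = t/2τ`.  The
  squared-bracket reading is fixed by internal consistency: substituting
  the large-`z` Bessel asymptote `I₀(z) ≈ e^z/√(2πz)` must reproduce the
  power law `2^{1−2H} Γ(H)²/π · z^{1−2H}`, whose limits are 1 at
  `H = 1/2` and 0 for `H > 1/2`.  The unsquared bracket fails this and is
  provided only as a non-default comparison flag.

The spatial coordinate (the informational distance `η` between neurons)
never enters the computed solution: the flux formulation absorbs the
spatial gradient through Fick's law.  `η` is carried as a metadata label
only.

One point where this package's account deviates from a naive reading of
the diffusivity figures: the exact `H = 1/2` curve is *not* monotone
toward 1.  It rises to an interior maximum of ≈1.381 near `z ≈ 1.06` and
then decays to 1 *from above* with a `1/(4z)` correction (this follows
directly from `√(2πz)·I₀(z)e^{−z} = 1 + 1/(8z) + …`).  Likewise the
`H = 1` endpoint has no interior maximum: `z^{1−H}` is constant there and
the curve is `I₀(z)²e^{−2z}`, monotone decay from 1.  Shape tests assert
these exact behaviours; they were verified against a 50-digit
arbitrary-precision evaluation of the closed form.

## Hurst estimation (R/S)

`rs_hurst` implements classical rescaled-range analysis: for each segment
length `w` (geometrically spaced, 10 scales by default, from
`min_window = 16` to half the record), the record is cut into
non-overlapping segments; each segment is mean-adjusted, cumulatively
summed, and its range divided by the segment standard deviation;
zero-variance segments are skipped.  Detrending is mean-adjustment only
(no linear detrend), per the classical procedure.

The raw log–log slope of R/S against `w` is biased upward for short
segments (measurably ≈0.54 on long white-noise records).  The default
estimator therefore applies the Anis–Lloyd expected-R/S correction with
the finite-sample `(w − 1/2)/w` factor: `Ĥ = 0.5 +` slope of
`log₂(R/S) − log₂(E[R/S])` against `log₂ w`.  This centres the white-noise
case on 0.5 and recovers fGn exponents 0.6–0.9 within ±0.1 in the mean
(the recovery is still biased low at high `H` on short windows — roughly
0.77 for true 0.9 at 512 samples — which is an intrinsic finite-size
property of R/S, not an implementation artifact).  The uncorrected OLS
slope is available with `corrected=False`; the raw slope is always
retained in the estimate, with `H` clamped to [0, 1] because the
downstream formulas (`Γ(H)`, `z^{1−H}`) require it.

`sliding_hurst` timestamps each window at its trailing edge; the default
window is one second of samples so the first estimate matches the
convention that the initial `H` comes from the full pre-stimulus second.
Constant windows inside an otherwise valid record carry the previous
estimate forward; an entirely constant record raises a degenerate-input
error.

The reflection rule `H' = 1 − H` folds antipersistent exponents into the
reference span [0.5, 1]: both sides carry the same fluctuation magnitude,
so magnitude computations always run on the persistent side, while the
*unreflected* exponent decides the trend (persistent keeps the previous
deflection direction, antipersistent reverses it, and an exact 0.5 — no
correlation — is resolved by a seeded fair coin so neither direction is
structurally favoured).

## Fractional integral (product integration)

`frac_integral` evaluates `(1/Γ(H)) ∫₀ᵗ φ(ξ)(t−ξ)^{H−1} dξ` by product
integration: the flux is piecewise linear between its samples and the
kernel moments `∫(t−ξ)^{H−1}dξ` and `∫ξ(t−ξ)^{H−1}dξ` are integrated in
closed form on every sub-interval, so the integrable singularity at
`ξ → t` never meets a quadrature node.  Constant flux is reproduced
exactly (`t^H/Γ(H+1)`); against an adaptive-quadrature oracle with an
algebraic endpoint weight the scheme agrees to 1e-6 relative on the
reference Gaussian pulse and converges at better than first order in the
step.  The flux grid must resolve the pulse: the prediction loop samples
the flux at `min(dt, σ/8)` regardless of the output step, since the
reference pulse (σ = 1 ms) is narrower than a 256 Hz sample interval.

## Per-moment prediction loop

`predict_signal` steps `t_k = k·dt` from the stimulus (model clock `t = 0`
at stimulus application, mapped to the recording's onset time).  At each
step it: obtains `H_k` per the `H_policy` (`fixed`, `prestim`, or the
default free-running `trailing`, which re-runs R/S over the trailing
window of the concatenated pre-stimulus + predicted record; the first
estimate always comes from the full pre-stimulus second); reflects `H_k`
for magnitude; refreshes `D_eff,k` from the diffusivity law at `t_k`; and
evaluates the frozen-coefficient magnitude model
`M_k = M(t_k; H_k, D_eff,k)` with the current coefficients applied to the
whole flux history.  Time-varying coefficients inside a convolution are
mathematically under-defined; this quasi-static convention is the
simplest one consistent with a per-moment update, and the alternatives
(per-step kernel freezing, history-dependent coefficients) would change
the result only where `H_k` moves quickly.

Sign and magnitude are composed as
`V_k = V_{k−1} + trend(H_k, sign(ΔM_k)) · |ΔM_k|` with
`ΔM_k = M_k − M_{k−1}`: the magnitude model proposes both the step size
and a direction, and the trend rule keeps or reverses that direction.
Under persistent `H` the increments telescope, so the prediction equals
the direct model evaluation exactly — the loop-vs-direct consistency test
asserts agreement at the peak to 1e-9.  This composition was chosen over
feeding back the realized trend `sign(V_{k−1} − V_{k−2})` because a
persistently `H > 0.5` record would then lock its direction forever,
which contradicts the non-monotone evoked morphology the model is meant
to produce.

Units: the flux is V·m/s, the output is microvolts; a single configured
conversion constant (default 1 μV per model voltage unit) bridges them.
The relaxation time τ has no published value; the default 0.001 s is the
same order as the stimulus width, is required-configurable, and is logged
on every CLI run.

## Synthetic trials

`simulate_fgn` generates exact-covariance fractional Gaussian noise by
Davies–Harte circulant embedding (covariance-matrix factorization
fallback for records up to 4096 samples in the rare non-positive-embedding
case), deterministic under seed.  A trial is 1 s of background before and
1 s after the stimulus at 256 Hz; the background defaults to `H = 0.9`
(strongly persistent, as occipital records are) at 2 μV RMS, so the
±5 μV response bands separate signal from background.  The evoked
template is two Gaussian bumps (defaults: P at 118 ms, +9 μV; N at
170 ms, −4.97 μV; width 15 ms) — real evoked shapes are not Gaussian, and
the generator makes no attempt at multichannel structure, artifacts, or
non-stationary background, so passing tests demonstrate estimator and
pipeline correctness on the model's own assumptions, not fidelity to any
particular recording.  Session seeds are spawned per trial from the
master seed via `SeedSequence`.

## Feature extraction

`detect_response` screens strict local extrema of the post-stimulus
segment against the response bands: a deflection qualifies when its
magnitude reaches 5 μV (values beyond the 10 μV band edge also qualify —
observed peak-to-peak values exceed the band, so the band cannot be
exclusive).  Initiation is the latency of the first qualifying peak;
the response terminates at the last qualifying peak or, when no negative
extremum reaches the band, at the deepest local minimum after it (the
negative rebound at which the record returns to rest); peak-to-peak is
max − min over that span.  Bands are absolute voltages by default — the
reading is deliberately *not* offset-invariant — with baseline
correction available as a flag.  Latencies are reported on the sample
grid (1000/256 ≈ 3.9 ms resolution at the default rate).  Feature tables
average per-subject rows arithmetically; features are measured on grand
averages by default (per-trial-then-average is the caller's choice by
passing single-trial sets).

## Preprocessing

Bandpass: 4th-order Butterworth, zero-phase (forward–backward) with
reflect padding; a zero low edge degrades to a pure lowpass.  Wavelet
denoising: db4, 4 levels, soft universal threshold
`σ√(2 ln n)` with `σ` from the MAD of the finest detail level, on an
orthogonal (periodization) transform so shrinkage cannot increase energy.
All settings are exposed; none have published values.

## Problem sizes and determinism

Statistical tests use 8192-sample records and 20 seeds for full-length
estimator calibration, 512–2048 samples for sliding-window behaviour, and
40-trial sessions for the averaging pipeline — sizes at which the
estimator's sampling spread is small against the asserted tolerances while
the whole suite stays fast.  Every stochastic path takes an explicit seed;
`scripts/acceptance.py` derives all of its streams from the single
`--seed` argument.

## Known limitations

- R/S has intrinsic finite-size bias at high `H` and short windows; the
  sliding trajectory on strongly persistent data reads low (≈0.77 for
  true 0.9 at 512 samples).  Interpret trajectories comparatively.
- The free-running prediction's initiation latency depends on the model's
  early transient, which the published parameterization leaves
  under-determined (τ and the flux-to-μV conversion are unpublished);
  absolute latencies should not be compared against recordings without
  calibrating both.
- The per-moment coefficient update is a quasi-static convention, not a
  derived discretization of a time-varying-order equation.
- Single channel only; no artifact model; no statistical testing of
  real-vs-predicted feature differences.
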