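# fdeeg

Fractional-diffusion modelling of the human EEG response to an external
stimulus.

Evoked potentials — the stereotyped positive peak (P) and negative rebound
(N) that follow, e.g., a checker-reversal visual stimulus — ride on a
background EEG that behaves as a fractal time series with a Hurst exponent
`H` well above 0.5.  `fdeeg` implements a model in which the record `V(t)`
obeys a fractional diffusion equation of temporal order `2H`, so the
response to a stimulus flux `φ(t)` is a Riemann–Liouville fractional
integral with the weakly singular kernel `(t − ξ)^{H−1}`:

    V(t) = V0 + τ^{1/2−H} D_eff^{−1/2} · (1/Γ(H)) ∫₀ᵗ φ(ξ) (t − ξ)^{H−1} dξ

with `V0` the voltage at stimulus onset, `τ` the relaxation time, and
`D_eff(t)` a time-dependent effective diffusivity of the neural tissue
obtained by matching the fractional model against the phase-lagging model
of the action potential:

    D_eff / D = [ 2^{1−H} Γ(H) z^{1−H} I₀(z) e^{−z} ]²,   z = t / 2τ

where `I₀` is the zero-order modified Bessel function.  The ratio tends to
1 as `z → ∞` for `H = 1/2` (classical diffusion) and to 0 for
`1/2 < H ≤ 1`, following the power law `2^{1−2H} Γ(H)²/π · z^{1−2H}`.

The stimulus is a Gaussian flux pulse `φ(t) = φ₀ exp(−(t − t*)²/σ²)`.  A
per-moment prediction loop re-estimates `H` by rescaled-range (R/S)
analysis as the record grows, refreshes `D_eff`, and uses the trend rule
(persistent `H > 0.5` continues the previous deflection, antipersistent
`H < 0.5` reverses it) to assign the sign of each predicted increment.

The package is aimed at researchers exploring fractal/fractional models of
evoked responses and at anyone needing a well-tested R/S Hurst estimator,
exact-covariance fractional-Gaussian-noise simulation, or product
integration of weakly singular Volterra kernels.

## Worked example

```python
import numpy as np
from fdeeg import (ModelConfig, TissueParams, TrialSpec, detect_response,
                   grand_average, make_session, predict_signal, rs_hurst,
                   simulate_fgn, effective_diffusivity)

# one second of persistent fractal background at 256 Hz
prestim = simulate_fgn(256, H=0.9, scale=2.0, seed=42)
est = rs_hurst(prestim)

params = TissueParams(D=6.5e-4, tau=1e-3)
d = effective_diffusivity(0.118, est.H, params)

# free-running prediction of the post-stimulus second
cfg = ModelConfig(params=params, H_policy="trailing", seed=1)
pred = predict_signal(prestim, cfg, duration=1.0)
feats = detect_response(pred.series)

# synthetic session: 40 evoked trials, grand-averaged
session = make_session(TrialSpec(seed=7), n_trials=40)
feats_avg = detect_response(grand_average(session))
```

prints (via the obvious `print` statements):

```
pre-stimulus Hurst estimate: H = 0.860 (stderr 0.049, 10 scales)
effective diffusivity at t = 118 ms: D_eff = 8.160e-06 m^2/s (D_eff/D = 0.0126)
predicted 1 s post-stimulus record: 257 samples, range [0.00, 68.72] uV
predicted response: initiation 20 ms, duration 0.977 s, peak-to-peak 63.04 uV
grand average of 40 synthetic trials: initiation 121 ms, duration 0.047 s, peak-to-peak 13.83 uV
```

The pre-stimulus record is strongly persistent (`H ≈ 0.86`), so the
effective diffusivity has already decayed to ~1% of the tissue value by
118 ms — the tissue "remembers" the stimulus and transports it
super-diffusively.  The grand average of 40 noisy synthetic trials
recovers the injected evoked template (P at 118 ms, peak-to-peak
13.97 μV) to within the sampling grid and the residual background noise,
while the free-running model prediction shows the same qualitative
morphology (an early positive deflection climbing past the 5 μV response
band, then a rebound).

A command-line interface mirrors the library:

```sh
fdeeg simulate --seed 7 --n-trials 40 --out session.csv
fdeeg predict pre.txt --tau 0.001 --out pred
fdeeg hurst signal.txt --window 256 --out hurst.csv
fdeeg diffusivity --h 0.7 --out curve.csv
fdeeg compare real.csv predicted.csv --out table.csv
```

Every run logs its fully resolved configuration (including the defaulted
relaxation time τ, which no published value pins down) and the seed.

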