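# fractalgaze

Fractal analysis of eye-tracking gaze dynamics: from raw 300 Hz binocular
samples to detrended-fluctuation-analysis (DFA) scaling exponents and
multi-level models of how they change with age, stimulus content, and
face-looking.

## The scientific problem

Where an infant looks from millisecond to millisecond is not a sequence of
independent choices: gaze is produced by many interacting neural, motor,
and sensory processes operating on nested timescales. A signature of such
interaction-dominant dynamics is *scale invariance* — fluctuations whose
statistical structure looks the same whether you examine 100 ms or 10 s of
behavior. This package quantifies that structure in gaze recordings and
models how it varies across a developmental cohort, with a fully synthetic
data generator so that every stage (and every claim about recovery of
known parameters) is testable without access to any infant data.

## The statistic at its core

The raw recording is reduced to a one-dimensional *amplitude series*: for
each consecutive sample pair, the Euclidean displacement of the gaze point

&nbsp;&nbsp;&nbsp;&nbsp;D = √((X₂−X₁)² + (Y₂−Y₁)²),&nbsp;&nbsp; T = t₂−t₁,

and the series of D/T values is analyzed by DFA: mean-center, integrate to
a profile, detrend the profile with order-2 polynomials in non-overlapping
windows of size *n*, pool the RMS residual F(n), and estimate the scaling
exponent **α** as the slope of log F(n) against log n over window sizes
from 4 samples to a quarter of the series.

* α ≈ 0.5 — white noise, uncorrelated gaze variation
* α ≈ 1.0 — pink (1/f) noise, scale-invariant "optimally flexible" dynamics
* α ≈ 1.5 — brown noise, an over-rigid integrated random walk

Upstream of DFA sits a strict quality-control chain (precision screening on
attention-cue trials at 1.21° of visual angle, sub-200 ms blink
interpolation with an interpolation-proportion cut at 0.115, longest
contiguous run extraction, and a 1000-sample minimum). Downstream, α is
modeled with 4-level mixed-effects models (segments within movies within
visits within persons) with multi-level centered covariates, and
face-looking is tallied against per-frame face rectangles and modeled with
a binomial-logit mixed model.

## Worked example

```python
import numpy as np
from fractalgaze import (
    NoiseSpec, SessionSpec, generate_colored_noise, generate_gaze_session,
    apply_qc, dfa_alpha, classify_noise,
)

# 1. a pure 1/f series has scaling exponent ~1
x = generate_colored_noise(NoiseSpec(n=5000, beta=1.0, seed=42))
res = dfa_alpha(x)
print(f"1/f noise: alpha = {res.alpha:.3f} (R^2 = {res.r2:.3f}) -> {classify_noise(res.alpha)}")

# 2. a full synthetic visit, through QC, to per-segment exponents
session, truth, tracks = generate_gaze_session(SessionSpec(target_alpha=0.85, seed=7))
series, meta, report = apply_qc([session])
alphas = [dfa_alpha(s.values, allow_short=True).alpha for s in series]
print(f"retained {len(series)}/{len(session.segments)} segments after QC "
      f"(precision {meta['precision_deg'][0]:.2f} deg)")
print(f"mean recovered alpha = {np.mean(alphas):.3f} (target 0.85)")
```

prints

```
1/f noise: alpha = 0.969 (R^2 = 0.997) -> pink
retained 18/31 segments after QC (precision 0.21 deg)
mean recovered alpha = 0.884 (target 0.85)
```

The first line shows the estimator on a noise series with a known
exponent; the log–log fit is nearly perfectly linear (R² = 0.997). The
second part simulates one lab visit (eight ~20 s movies plus five
attention cues, with blinks, dropout, and recording jitter), runs the full
QC chain — 13 of 31 segments lose too much contiguous data, as real infant
segments do — and recovers the injected exponent from the surviving
amplitude series to within sampling error.

A command-line interface wraps the same stages
(`fractalgaze simulate | preprocess | dfa | aoi | model | all`); see
`fractalgaze --help`.

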