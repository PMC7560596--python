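# Methods

This note documents the models, algorithms, defaults, and design choices
behind `fractalgaze`, in the spirit of a statistical software appendix. It
describes what the code computes and why; every quantitative claim here is
one the test suite or `scripts/acceptance.py` computes itself.

## 1. The amplitude series

The analyzed quantity is the per-interval magnitude of gaze displacement.
For a contiguous run of valid samples, the binocular recording is reduced
to a cyclopean gaze point (average of the two eyes when both are valid,
the valid eye otherwise), and for each consecutive pair of samples

    D = sqrt((X2 - X1)^2 + (Y2 - Y1)^2),    T = t2 - t1,

the series value is D/T. T is expressed in nominal sample intervals (one
interval = 1/300 s at the default rate), so values are pixels per
interval. Because DFA's exponent is invariant under affine transforms of
its input (centering removes offsets; a global scale cancels in the
log–log slope — asserted to 1e-12 in the tests), the unit choice (pixels
vs degrees, per-interval vs per-ms) does not affect α. This also resolves
the question of whether the analysis should run in pixels or degrees of
visual angle: for the central screen region the two are related nearly
linearly, and the exponent is unchanged either way.

## 2. Detrended fluctuation analysis

Given a series x of length N:

1. profile: P(k) = Σ_{i≤k} (x_i − mean(x));
2. for each window size n, partition P into ⌊N/n⌋ non-overlapping windows
   from the start (trailing remainder discarded; a both-ends variant that
   also windows from the end is available behind `remainder="both_ends"`),
   fit an order-m polynomial in each window by least squares, and pool
   F(n) = sqrt(mean over windows of the mean squared residual);
3. α = OLS slope of log F(n) on log n (base 2 for reporting; the slope is
   base-invariant), with the fit's R² retained as a linearity diagnostic.

Defaults: m = 2, window sizes log-uniformly spaced in [4, N/4], rounded to
integers and deduplicated; series below 1000 samples are refused unless
explicitly overridden (DFA is not validated below that length).

**Number of scales.** The estimator supports any number of scales ≥ 2;
the default is 19, with the sparse historical 4-scale variant available.
The choice is deliberate: at the minimum admissible window (n = 4 for an
order-2 trend) each window retains a single residual degree of freedom,
so F(4) is systematically suppressed relative to the asymptotic power
law. With only four scale points that suppressed point carries enough
regression leverage to bias the slope visibly upward for weakly
correlated series; with 19 points its leverage is diluted. The acceptance
anchors (below) verify that the default protocol lands the three
canonical noises on their textbook exponents, and a dedicated test checks
that the sparse and dense schemes correlate above 0.8 across synthetic
1/f series, so results from either parameterization are comparable.

**Degenerate inputs.** A constant (or exactly polynomial) series yields
F(n) = 0 at some scale and raises a degenerate-series error rather than
returning −∞ slopes. Non-finite inputs are rejected.

**Noise classification.** α is labeled by bands: white [0.4, 0.7), pink
[0.7, 1.0] (closed — a value of exactly 1.0 is pink), brown (1.0, 1.6],
with `sub_white`/`super_brown` outside. Published descriptions of the
pink band vary between "α ~ 0.8" and "α ~ 1"; the bands here follow the
[0.7, 1.0] convention and are configurable.

**Surrogate null.** `shuffle_null` permutes the series values, which
preserves the amplitude distribution but destroys temporal order; any
genuine long-range correlation collapses to α ≈ 0.5. This is the standard
check that an observed exponent reflects temporal structure rather than
the marginal distribution.

## 3. Quality control

The chain runs in a fixed order, mirroring stringent infant eye-tracking
practice:

1. **Precision screen (session level).** Precision is the RMS of
   successive-sample angular displacement during attention-cue trials
   (the longest contiguous raw run per trial), computed per axis and per
   eye, averaged across axes, eyes, and trials. Sessions above 1.21° are
   dropped whole; a `mean+2sd` mode derives the cut from the dataset
   itself. The per-axis average is the default reading of "averaged
   across X and Y axes for both eyes"; a Euclidean-displacement variant
   is implemented as an alternative (`mode="euclidean"`).
2. **Blink interpolation (segment level).** Maximal invalid runs whose
   flank-to-flank duration is under 200 ms, with valid samples on both
   sides, are filled linearly per coordinate per eye. Longer gaps and
   edge gaps remain missing. The blink definition is the observable one
   (short validity gaps with valid flanks) with the duration cap
   configurable.
3. **Interpolation-proportion filter.** Segments whose interpolated
   fraction exceeds 0.115 are dropped; an 80th-percentile mode computes
   the threshold from the data and records it. (With a data-derived
   threshold the filter is by construction not idempotent — re-running it
   on its own output would recompute a lower quantile — so idempotence is
   guaranteed, and tested, for the fixed-threshold mode.)
4. **Longest contiguous run.** Residual missing data split a segment; the
   longest valid run wins, earliest on ties.
5. **Amplitude series and minimum length.** Series shorter than 1000
   values are dropped.

The QC report tallies every exclusion with its reason and level, and a
visit (person) counts as excluded when it retains no series at all.

## 4. Face areas of interest

Face AOIs are per-frame axis-aligned rectangles (0–3 per frame, at a
nominal 30 fps). Samples are assigned to the frame at or before their
timestamp; the point-in-rectangle test is half-open (closed on the min
edges, open on the max edges) so abutting rectangles never double-count a
point. Missing frames inside a track are filled by linear interpolation
of each rectangle coordinate for faces present on both flanks; a face
absent on either flank (obscured) is not invented, and edge gaps are not
extrapolated. Pixelated movies reuse their social counterpart's track
unchanged. Tallies count valid on-screen samples into face/non-face;
off-screen samples are excluded from both. Aggregation to movie, visit,
and person level sums the counts and recomputes the summary — never
averages of ratios. Both the bounded proportion n_face/(n_face+n_nonface)
and the literal ratio n_face/n_nonface are reported; the models consume
the proportion (bounded and numerically well-behaved), with the ratio
available for comparability.

## 5. Mixed-effects models

The design is 4-level nested: segments in movies in visits in persons.
Covariates are decomposed by multi-level centering (person mean at the
grand mean, visit mean at the person mean, movie mean at the visit mean,
segment value at the movie mean), so each coefficient isolates variation
at a single level; face-looking enters as the four centered terms.
Condition enters as Pixelated/AttentionCue dummies with Social the
reference.

* **α models** — linear mixed models, ML by default (fixed-effect
  likelihood-ratio tests require ML; REML is available behind a flag).
  Random structure: person intercept and age slope, visit and movie
  intercept variance components, optionally a visit-level Pixelated
  slope. Backend: statsmodels MixedLM with a Powell warm start before
  L-BFGS (variance components near their zero boundary defeat a cold
  gradient start), or lme4's `lmer` through Rscript — several-fold faster
  and used for batched replicate studies. A test asserts the two backends
  agree in log-likelihood and estimates on the same data.
* **Face-looking model** — binomial-logit GLMM on per-segment
  (n_face, n_nonface) counts with person-level random effects only
  (richer structures are deliberately not offered at this outcome's
  scale). Backend: lme4 `glmer`, the reference frequentist GLMM
  implementation; no equivalent exists in the installed Python stack.
  lme4's "very large eigenvalue / rescale" diagnostic — triggered by the
  sheer magnitude of binomial counts, with estimates stable across
  optimizers — is not treated as non-convergence; genuine "failed to
  converge" messages are, and are reported via the `converged` flag, never
  silently repaired.
* **Comparison** — likelihood-ratio tests use Δ(−2LL) against a χ² with
  Δdf degrees of freedom (no boundary correction, matching common
  reporting practice); AIC = −2LL + 2k and BIC = −2LL + k·log(n) are
  derived from the same likelihood. Variance explained is the squared
  correlation of fitted and observed values.

## 6. The synthetic-data generator

The generator is first-class, tested code; it is how every downstream
claim is validated.

**Colored noise.** Fourier spectral synthesis: complex Gaussian
coefficients scaled by f^(−β/2), inverse-transformed, standardized. The
target spectrum is exact in expectation and the series is seeded and
bit-reproducible. The monofractal correspondence α = (β+1)/2 links the
spectral exponent to the DFA exponent; tests verify the periodogram slope
(±0.1), the α↔β map across β ∈ [0, 2] (±0.1), and that integration raises
α by 1.0 (±0.15).

**Sessions.** A visit comprises four ~20 s "social" movies cut into 3–4
segments at movement events, their pixelated counterparts sharing the
cuts, and five 6 s attention cues. Within a segment the D/T magnitude
series is an affine transform of a colored-noise series at the target α
(default 12 ± 4 px/interval, clipped at zero; the clip engages for well
under 1% of samples and affine maps leave α untouched) — the exponent is
injected directly into the quantity DFA consumes. Positions follow a
random-direction walk with those step magnitudes, mirror-reflected at the
screen edges. Blinks arrive as a Poisson process (default 8/min, 60–180
ms, always under the 200 ms cap and flanked by valid samples); longer
dropout (300–1000 ms gaps) removes a target fraction (default 5%) of
samples; per-eye Gaussian jitter (default 0.02°) emulates finite
precision. The face track is constructed per frame: with probability
`face_look_prob` the (moving) face rectangle covers that frame's gaze
samples, otherwise it is displaced to the far side of the screen — so the
realized face-look fraction tracks the target without distorting the walk.

What the generator does **not** emulate: saccade kinematics (main
sequence), fixation/saccade alternation, smooth pursuit, pupil dynamics,
head movement, or calibration drift. Its jitter is white, whereas real
recording noise is partly structured. Passing recovery tests therefore
show that the pipeline measures what it claims on data with known
ground truth — not that real infant gaze has any particular exponent.
One consequence the generator does reproduce faithfully: additive white
jitter dilutes temporal correlation and drags measured α toward 0.5,
which is precisely why poor-precision sessions must be excluded rather
than analyzed.

**Cohorts.** Segment-level exponents follow a generative mixed model:
α = 0.85 + 0.001·(age − 15 mo) − 0.023·Pixelated − 0.030·AttentionCue
(+ optional age×condition interactions and face-looking effects) +
person intercept (var 0.001) + person age slope (negligible var) + visit
intercept (var 0.0015) + movie intercept (near zero) + residual
(var 0.008), clipped to (0, 2) — variances mirror the magnitudes
estimated in observational data of this design. Cohort scale defaults:
190 persons, 1–3 visits each, ages 3–35 months, ~22 retained segments
per visit (70% retention of the full battery). Face-looking counts are
binomial with logit probability −0.5 + 0.02·(age−15) − 1.71·Pixelated +
person intercept (SD 0.5); the α face-looking effects act on the
multi-level centered observed proportions, matching the model
decomposition exactly, so recovery tests are tests of the estimator and
not of an attenuation correction. The binomial assumption ignores the
serial correlation of real gaze samples within a segment; recovery tests
should be read accordingly.

## 7. Calibration anchors and problem sizes

`scripts/acceptance.py` recomputes, from scratch at every run: the mean
DFA exponent of 200 seeded white-noise series (expected ≈ 0.5), of their
cumulative sums (≈ 1.5), and of 200 spectrally synthesized 1/f series
(≈ 1.0), each of length 5000. The test suite additionally checks oracle
equivalence of the vectorized estimator against an independently coded
naive double-loop DFA (agreement to 1e-10 on 50 series), shuffle
surrogates, strict monotonicity of mean α in β, QC rule attribution on
constructed single-violation datasets, and mixed-model coverage (100
replicate cohorts at the scale above; each fixed effect inside its 95%
CI in ≥ 90 replicates, for the linear and the logistic model). Replicate
counts and series lengths were chosen to keep the full suite comfortably
within a desk-scale run while leaving the coverage assertions
well-powered.

## 8. Known limitations

* Wald confidence intervals from ML variance estimates can be slightly
  anti-conservative at a few hundred groups; the coverage tests bound
  this (≥ 90% at nominal 95%) rather than assuming it away.
* The blink detector is definitional (short validity gaps with valid
  flanks), not a reimplementation of any proprietary noise-based
  event detector; on real recordings the two may disagree at gap edges.
* The exact window-size schedule used by any particular historical
  analysis is a free parameter here (`n_scales`); the schemes are
  cross-checked for agreement but not identical.
* The pipeline treats segment boundaries and AOI rectangles as inputs;
  it does not segment movies or detect faces.
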