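# Methods

## The data model

A *session* is one person's pair of 1 Hz streams over roughly twenty minutes:
behavior codes in {1, 2, 3} (proself / neutral / prosocial) and emotional
valence in integer screen pixels 0..1123 (most negative to most positive,
neutral mid-scale). Sessions come in dyads (two persons who talked to each
other), and dyads carry a group label, *intractable* or *tractable*, derived
from the quality of the joint statement the pair produced. Either stream of
a person may be absent (the emulated study lost two person-records "for
technical reasons"); absence is represented as absence, never as zeros.

The analyses treat every stream marginally. Nothing couples a person's
behavior to their emotion, or the two persons of a dyad; accordingly the
synthetic generator draws all streams independently.

## Behavior: dwell-time densities

**Extraction.** Run-length encoding assigns every second to exactly one run;
the first and last runs of a session are kept as complete durations even
though the session boundary censors them (no censoring rule is imposed; with
~60 runs per session the two boundary runs are a ~3% contamination). Because
single persons yield too few durations per state for a stable density,
durations are pooled across persons within a group — per state, and across
all three states ("123").

**Multi-bin PDF.** For each bin width Δt in a doubling schedule
{1, 2, 4, …} (up to the maximum duration), histogram bins [t, t+Δt) are
anchored at the minimum observed duration; each bin with count ≥ 5
contributes the density point (t, count/(N·Δt)) at its left edge, and where
two widths collide at the same t the smaller width wins. Fine bins resolve
the short-dwell region while wide bins rescue the sparse tail — the reason
for using several bin sizes at once.

**Fitting.** Three forms are fitted to the density points:
single exponential A·e^(−a·t), power law A·t^(−α), stretched exponential
A·exp(−(a·t)^b). Linear/log-linear forms reduce to weighted linear least
squares; the stretched form is a bounded multi-start Levenberg–Marquardt
(trust-region) fit with an analytic Jacobian, always seeded with the
single-exponential solution (b = 1) so the nested model can never beat it by
more than solver tolerance. Fits minimize squared error in **log density**
with weights √count: the variance of log of a histogram count is
approximately 1/count, so this is the standard weighting for logged Poisson
counts. An unweighted log-space fit was tried first and recovered b = 0.45
from data generated at b = 0.5 (20-seed mean, n = 5000) — the many sparse
tail bins dominate the unweighted objective; with √count weights recovery is
0.32/0.46/0.98 for generating b = 0.3/0.5/1.0. R² is reported as the
weighted coefficient of determination about the weighted mean log density,
and model ranking is by descending R² with ties to fewer parameters.

**Effective switching rate.** k(t) = PDF(t)/S(t) with S(t) the upper tail
integral of the *fitted* form, evaluated by adaptive quadrature. For b = 1,
k ≡ a (memoryless); for b < 1, k(t) decreases — the operational meaning of
behavioral memory. k(t) equals −d ln S/dt, which the tests verify by finite
differences to 10⁻⁴ relative error.

## Emotion: fluctuation analysis

**Rescaled range.** For each segment size n (powers of two, 16 … N/4) the
series is cut into ⌊N/n⌋ non-overlapping segments (remainder dropped).
Within a segment, R is the range of the cumulative sum of mean-adjusted
values and S the population (divide-by-n) standard deviation; R/S is
averaged over segments, and H is the least-squares slope of ln(mean R/S) vs
ln(n). The estimator is applied to the **increments** of the valence trace.
Known small-sample behavior: R/S reads slightly above 0.5 on uncorrelated
data (≈0.55 at N = 4096) and compresses toward the center at extreme H; the
minimum segment size of 16 (rather than 8) trims the worst of that bias
while keeping six points on the regression at N = 4096. Zero-variance
segments are skipped; a constant series is a degenerate-input error.

**Shuffle surrogates.** Uniform random permutations destroy temporal order
while preserving the value distribution; surrogate H collapsing to ~0.5
confirms that an elevated H (or curvature in the R/S plot) reflected genuine
temporal structure.

**Power spectra.** One-sided spectra at 1 Hz sampling, zero frequency
excluded: raw FFT modulus squared; periodogram with rectangular window,
no detrending, no zero-padding; Welch with 8 segments at 50% overlap,
rectangular window; Thomson multitaper built on DPSS tapers (time-bandwidth
4, 7 tapers, eigenspectrum average). The tail slope is the least-squares
line on (ln f, ln power) over f ∈ [0.01, 0.25] Hz. The upper limit stops one
octave below Nyquist deliberately: a discrete-time random walk has PSD
σ²/(4 sin²(πf)), which only follows 1/f² while 4 sin²(πf) ≈ (2πf)² — within
~25% below 0.25 Hz. Fitting to 0.5 Hz flattens the Brownian slope to ≈ −1.74
and breaks the slope↔Hurst consistency check; over [0.01, 0.25] the slope is
≈ −1.93.

**Slope ↔ Hurst.** With the slope s measured on the raw trace and H
describing its increments, H = (|s| − 1)/2; with both on the increments,
H = (|s| + 1)/2. The pipeline uses the first convention (slope from the
trace, R/S from the increments). Results outside [0, 1] are clamped with a
warning.

**Dichotomization.** Each second is labeled below/above the session-mean
valence (exact ties go above — integer pixels make ties possible, and the
choice is arbitrary but deterministic); the run lengths of the binary
sequence are the crossing intervals. A single session yields too few
intervals for a density fit, so only diagnostics are derived: for a
memoryless random walk the intervals follow the t^(−3/2) first-return law,
which the tests confirm on simulated walks (slope −1.5 ± 0.25 over
t ∈ [1, 64], 100 paths of 4096 steps).

## Group comparison

Mann-Whitney U (U counts pairs where the first sample exceeds the second;
ties count ½). Exact enumeration of the null when n + m ≤ 16 without ties —
small synthetic checks need exactness — otherwise the normal approximation
with tie and continuity corrections, which is what the study-sized samples
(~21 vs ~23 persons) use. The one-sided direction must be stated by the
caller; no default direction is assumed at the function level. Summary
tables carry one row per person plus an AVERAGES row per group; rows with
missing metrics are kept, excluded from the averages, and footnoted.

The bootstrap CI for the between-group difference of pooled stretched
exponents is an **extension**: the original pooled design cannot attach a
variance to b. Each resample redraws durations with replacement and refits
the entire multi-bin + stretched pipeline. The interval is the *basic*
(reverse-percentile) bootstrap, 2·θ̂ − quantiles: resampling perturbs which
histogram bins pass the count threshold and shifts the refitted exponent
systematically, a first-order bias the basic interval corrects and the raw
percentile interval would absorb. More than 20% refit failures raises an
unstable-estimate error.

## Synthetic generator

The generator exists so that every estimator can be validated against known
ground truth; its defaults emulate the study conditions.

- **Study shape:** 11 intractable + 12 tractable dyads × 2 persons,
  1200 s sessions, missing-person probability 2/46 (the study lost 2 of 46
  records). Per-person streams get seeds derived from
  (master_seed, dyad index, person, stream) so adding dyads never perturbs
  existing ones.
- **Behavior:** a semi-Markov chain — uniform initial state, dwell times
  from the configured family, next state among the other two with
  configurable weights (uniform by default; no transition matrix is imposed
  by the emulated design). Dwell sampling inverts the exact CDF of
  f(t) ∝ exp(−(t/τ)^b) on t ≥ 1 via the regularized incomplete gamma
  function, then rounds up to whole seconds (1 Hz coding resolution).
  Defaults b = 0.3 (the pooled estimate the analysis recovers; group-specific
  values are configurable but default equal, since no distinct published
  values survive) and τ = 0.1 s, chosen so integer dwells have median ~8 s
  and mean ~19 s — about sixty runs per 20-minute session, the order of
  switching plausible for per-second-coded conversation. Note τ is not the
  mean dwell: for b < 1 the mean is τ·Γ(2/b)/Γ(1/b), ~190τ at b = 0.3.
- **Emotion:** increments of sd 5 px/√s accumulated from pixel 561
  (mid-scale), saturating at the screen edges 0/1123 (a mouse sticks at the
  edge rather than reflecting), rounded to the integer pixel grid. For
  hurst_target ≠ 0.5 the increments are exact-covariance fractional Gaussian
  noise via Davies–Harte circulant embedding (Cholesky fallback if an
  eigenvalue is numerically negative) — needed chiefly as a test fixture for
  the Hurst estimator.

What the generator does **not** emulate: any behavior↔emotion coupling,
any within-dyad interaction, topic content, coder disagreement, or the
s-shaped curvature the real R/S plots showed. Passing tests therefore
demonstrate estimator correctness under the stated stochastic models, not
fidelity of those models to real conversations.

## Numerical conventions and degenerate inputs

Natural logarithms throughout. Dwell times are integer seconds ≥ 1.
Histogram anchor at the minimum observed duration. Stretched-fit exponent
bounded to [0.02, 1.5] (the upper slack lets sampling noise around b = 1
express itself rather than piling on the boundary). Constant series, empty
samples, out-of-domain codes and non-contiguous time indices raise typed
errors (`DegenerateInputError`, `ParameterError`, `FormatError`, …);
validation violations are returned as data, not raised, by
`validate_session`. Pipeline stages log every skip (unfittable pools,
missing streams); nothing is auto-excluded.

## Known limitations

- The multi-bin estimator with left-edge representative points and ceil
  discretization carries a small upward bias in the recovered exponent at
  b = 0.3 (≈ +0.02 at n = 5000, τ = 4); it is within the tested tolerance
  band and documented rather than corrected, matching the method as used.
- R/S bias is not Anis–Lloyd-corrected; the raised minimum segment size is
  the only mitigation, and estimates at H = 0.3 read ≈ +0.08 high.
- Exact Mann-Whitney is limited to n + m ≤ 16 tie-free samples; integer
  metrics with ties always take the corrected normal approximation.
- Fits assess relative goodness of fit among three fixed forms; no absolute
  goodness-of-fit test or maximum-likelihood alternative is provided.
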