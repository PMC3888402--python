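# conflictdyn

Statistical-physics style analysis of dyadic "difficult conversations":
per-second **behavior** codes (1 = proself, 2 = neutral, 3 = prosocial) and
per-second **emotional valence** traces (mouse-position pixels, 0 = most
negative to 1123 = most positive), recorded for two-person dyads labeled
*intractable* or *tractable* by the quality of the joint statement they
produced.

The package asks whether these streams carry a *memory* of their own past,
and whether that memory differs between the two groups:

- **Behavior.** The dwell time *t* a person spends in one behavioral state is
  pooled across persons and its probability density is estimated with
  multi-bin-size histograms. Three candidate forms are fitted by least squares
  on log density and ranked by R²:

  | form | PDF(t) | switching hazard |
  |---|---|---|
  | single exponential | A·exp(−a·t) | constant (Markov, memoryless) |
  | power law | A·t^(−α) | ∝ 1/t (scale-free) |
  | stretched exponential | A·exp(−(a·t)^b), 0 < b ≤ 1 | falls with time in state when b < 1 |

  The effective kinetic rate constant k(t) = PDF(t)/S(t), with survival
  S(t) = ∫ₜ^∞ PDF(u) du, makes the memory explicit: for the stretched form
  with b < 1, k(t) decreases — the longer a behavior has persisted, the less
  likely it is to change this second.

- **Emotion.** The valence trace is analyzed as a continuous signal: Hurst
  rescaled-range (R/S) analysis on its increments, power spectral density on
  the raw trace (FFT, periodogram, Welch, Thomson multitaper) with the
  log-log tail slope *s*, and the consistency relation H = (|s| − 1)/2.
  H ≈ 0.5 and s ≈ −2 mean the valence moves as ordinary Brownian motion —
  steps with no memory. Shuffle surrogates and a mean-split dichotomization
  (whose crossing intervals follow the t^(−3/2) first-return law for a
  random walk) complete the picture.

- **Groups.** Per-person metrics are compared between intractable and
  tractable dyads with the Mann-Whitney U test (exact when n+m ≤ 16 and
  tie-free, tie/continuity-corrected normal approximation otherwise). A
  bootstrap CI for the between-group difference of the pooled stretched
  exponent is provided as an extension beyond the pooled analysis.

Because the original recordings are not public, a first-class synthetic
generator reproduces the study's shape — 11 + 12 dyads of two persons,
~20-minute 1 Hz sessions, heavy-tailed behavioral dwell times
(semi-Markov, stretched-exponential with b = 0.3 by default), bounded
random-walk valence traces, and occasional missing persons — so every
estimator can be validated against known ground truth.

## Worked example

```sh
python analysis/01_simulate_study.py --seed 0 --out results
python analysis/02_behavior_dwell_analysis.py --out results
python analysis/03_emotion_fluctuation_analysis.py --out results
python analysis/04_group_comparison.py --out results
```

The simulation writes 44 person-records (21 intractable, 23 tractable; two
persons dropped by the missingness model). The behavior step prints, among
others:

```
      group state                  form  r_squared
intractable   123 stretched_exponential   0.953771
  tractable   123 stretched_exponential   0.975207
intractable: pooled b = 0.317; k(1 s) = 0.150/s falls to k(60 s) = 0.0215/s
```

— the stretched exponential wins every pooled duration set, the fitted
exponent recovers the generating b = 0.3, and the switching rate falls
roughly sevenfold over a minute in state: behavioral memory. The emotion
step prints

```
      group  tail_slope  hurst_H
intractable   -1.967730 0.547788
  tractable   -1.912096 0.552862
```

— tail slopes near −2 and Hurst exponents near 0.5 (R/S runs slightly high
on uncorrelated data): valence behaves as a memoryless random walk. The
group comparison accepts both null hypotheses (one-sided Mann-Whitney
p = 0.46 on H, p = 0.97 on the R/S line-fit R²): no group difference in the
emotion fluctuations.

The same pipeline runs as a single command over a YAML config:

```sh
conflictdyn all --seed 0 --out results
conflictdyn validate results/study_data.csv results/study_metadata.csv
```

## Layout

- `src/conflictdyn/` — the library: `synthetic` (study generator),
  `io` (CSV dialect), `durations` (dwell-time PDFs, fits, k(t)),
  `fluctuation` (R/S, PSD, dichotomization), `groups` (tests, summaries),
  `pipeline` + `cli` (orchestration).
- `analysis/` — numbered narrative drivers reproducing the full analysis.
- `tests/` — unit, property (hypothesis), and statistical acceptance tests.
- `docs/methods.md` — models, estimator conventions, defaults, limitations.
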