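# Methods

This note documents the models, numerical choices and known limitations of
`gate50`. Nothing here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Paired-click protocol and signal model

A session consists of `n_pairs` (default 120) click pairs: S1 and S2
separated by `isi_ms` = 500 ms, with pair onsets spaced uniformly in
8–12 s. Sampling is 1 kHz; two channels are modelled, Cz and one EOG.

The simulator represents each evoked P50-band component as a
Gaussian-windowed cosine burst,

    g(t) = exp(−(t−L)² / 2σ²) · cos(2π f₀ (t−L)),

with carrier f₀ = 35 Hz and envelope σ = 8 ms, centred at the subject's
true latency L ∈ [45, 75] ms after each click. This template survives the
10–50 Hz bandpass nearly unchanged, and its scale is **calibrated
numerically**: a unit burst is placed in a standard epoch, filtered, and
scored by the same peak rules the pipeline uses; the injected burst is then
scaled so the post-filter peak-to-trough amplitude equals the subject's true
amplitude. This makes ground-truth recovery a well-posed end-to-end test
(latency within ±2 ms on the 1 ms grid, amplitude within a few tenths of a
percent in the noise-free case).

On top of the evoked responses the simulator adds: white Gaussian background
noise (`noise_sd`, default 5 µV) independently on Cz and EOG; blink events
(Poisson, `blink_rate`/min) as 150 µV Gaussian pulses (σ = 60 ms) on EOG,
bleeding into Cz with coefficient `eog_bleed` = 0.2; and optional
high-amplitude artifact segments (150 µV, 200 ms) anchored inside randomly
chosen trials' screening windows, with the chosen trial indices recorded in
the recording metadata so rejection logic can be checked against the
injection log.

What the simulator does **not** emulate: real EEG's 1/f background and alpha
rhythm, the N100/P200 components, stimulus (click) artifacts, electrode
drift, or latency jitter across trials. Passing recovery tests therefore
demonstrates correctness of the measurement chain under its stated
assumptions, not robustness to every property of clinical recordings.

## Preprocessing chain

1. **Online screen.** A trial is flagged when any Cz or EOG sample in
   −100…500 ms around its pair onset exceeds ±100 µV; trials whose window
   leaves the recording are flagged `out_of_bounds`.
2. **Ocular correction.** Cz ← Cz − b·EOG, with b the least-squares slope
   of Cz on the EOG channel(s) over the whole recording. A pattern-based
   vendor algorithm fills this role in the original acquisition software; a
   whole-record regression is used here because it is fully specifiable and
   satisfies the same contract (removal of ocular variance). Zero-variance
   EOG leaves Cz untouched with a warning. Any DC shift introduced is
   removed later by the bandpass.
3. **Epoching.** One epoch per pair, −100…923 ms inclusive at 1 kHz →
   1024 samples, time 0 at the first click. Other sampling rates are
   linearly resampled to 1 kHz first. An optional exclusion list mimics
   manual rejection.
4. **Offline rejection.** Epochs containing any |sample| > 50 µV are
   dropped (separately logged from the online screen).
5. **Average + filter.** Point-wise mean of retained epochs, then a
   zero-phase frequency-domain bandpass: DFT, bins outside 10–50 Hz zeroed
   with raised-cosine transitions of 2 Hz outside each edge
   (gain ½(1−cos π(f−8)/2) on 8–10 Hz, mirrored on 50–52 Hz), inverse DFT.
   The transition shape is a package choice — only the 10–50 Hz band is
   prescribed — chosen to avoid the ringing of a brick-wall mask while
   keeping the operation bit-reproducible (pure `numpy.fft` on fixed bins).
   No baseline subtraction and no notch filter are applied.

## Peak scoring

S1 latency is the time of the maximum sample in 45–75 ms post-stimulus
(earliest sample on ties); amplitude is that peak minus the minimum in
[30 ms, latency). The trough is taken regardless of sign, since filtering
does not guarantee a negative value. If the window maximum is ≤ 0 the
response is scored absent (amplitude 0) — a "positive deflection" that is
non-positive is contradictory, and absence is the conservative reading.
S2 uses the same window relative to the second click, followed by the
consistency rule: if the S2 latency differs from the S1 latency by more
than 10 ms, S2 is scored 0. Subjects with S1 < 0.5 µV are invalid. The
ratio S2/S1 is capped at 2 (`truncated` flag set when the cap binds);
impaired gating means ratio strictly greater than 0.4.

## Cohort generator

Each group's covariates are drawn from truncated-normal marginals whose
**post-truncation** mean and SD are numerically matched (least squares on
the analytic truncated moments) to the published group summaries. Bounds:
gating ratio [0, 2], S1 latency [45, 75] ms, amplitudes and WAIS scores
(0, ∞), z-scored indices unbounded, age [18, 65]. Moment matching keeps the
printed summaries reproducible despite the bounds; marginals whose targets
lie outside the truncated-normal family — the control gating ratio
(CV = 1.0, above the attainable limit on [0, 2]) and the patient Digit
Symbol score (SD 12.06 at mean 9.96, above the half-normal CV limit) — are
flagged by `calibration_flags`; for those the mean is held exact and the SD
takes the family's closest attainable value. The patient gating ratio
(CV 0.885) is near the boundary and matches to within 2 %.

Dependence is a Gaussian copula with a block correlation structure: 0.6
among the nine WAIS indices, 0.3 between the two CPT indices and the WAIS
block, 0 elsewhere (the matrix is verified positive semidefinite). The
published study reports only marginals; joint behaviour of any model fitted
to simulated cohorts depends on these explicit, tunable values. Smoking is
Bernoulli at the group prevalence; packs-per-day is 0 for non-smokers and,
among smokers, a positive truncated normal whose conditional moments
reproduce the overall (zeros included) mean/SD. Note that the five P50
columns are drawn marginally, so `diff_uv` is calibrated to its own summary
rather than computed as `s1_uv − s2_uv`; the model never uses it.

The calibration test asserts the analytic targets to 2 % and the empirical
moments of a 10,000-per-group draw within 2 % plus a four-standard-error
Monte-Carlo allowance (with 88 marginal checks, ~1 %-of-SD sampling noise
alone would otherwise produce spurious failures).

For parameter-recovery and bootstrap studies, `simulate_model_cohort` draws
covariates from simple documented distributions (gating and smoking
Bernoulli(½); d′ standard normal; Arithmetic and Block Design N(10, 3²);
PIQ N(58, 10²)) chosen so the published coefficients' linear predictor is
centred near zero — both outcome classes are then well populated and
maximum-likelihood estimates are informative. The PIQ location is a
simulation design choice, not a clinical claim.

## Diagnostic model

Fitting is binomial maximum likelihood via iteratively reweighted least
squares (statsmodels GLM; convergence tolerance 1e−8, 100 iterations),
standard errors from the inverse observed information. Rank-deficient
designs raise an error naming the collinear terms; separation is detected
from the fitter's own diagnostics plus a standardized-coefficient bound.

Stepwise selection enters the candidate with the smallest 1-df **score
test** p-value when below `sle` and removes the included term with the
largest **Wald** p-value when above `sls` (defaults 0.15/0.15, mirroring
the common default of the statistical system the procedure originates
from). Iteration stops when nothing changes or a visited model recurs;
every step is recorded in an audit trail. Boundary behaviour: `sle = 0`
yields intercept-only, `sle = sls = 1` the full candidate set.

The gating-ratio cutoff is explored by a locally weighted linear (LOESS)
smooth of the binary outcome on the ratio (span 0.75, no robustness
iterations), converted to log-odds; the reported cutoff is the smallest
ratio at which the smooth crosses the cohort-prevalence log-odds (linear
interpolation between curve points). The original analysis read the 0.4
cutoff off a smoothed-risk display without stating a rule; the
prevalence-crossing rule is this package's explicit operationalization, and
the full curve is always returned (also attached to the `no_cutoff_found`
error when no crossing exists, e.g. a flat curve).

Odds ratios are e^β with 95 % Wald intervals (z = 1.96).

### The published coefficient set

The shipped JSON stores the printed coefficients verbatim: Intercept
10.20 (2.05), Gating 1.00 (0.48), d′ −0.37 (0.22), Arithmetic −0.32 (0.10),
Block Design 0.28 (0.14), Performance IQ −0.19 (0.03), Smoke 1.58 (0.80).
Two published inconsistencies are carried as machine-readable notes rather
than silently corrected: e^−0.19 = 0.83 does not equal the printed PIQ odds
ratio 0.90 (which corresponds to ≈ −0.105), and scoring group-mean
covariates with −0.19 yields near-zero probabilities — so calibration
statistics computed with the printed value against realistic cohorts are
expected to be extreme even though discrimination remains good; and
e^1.58 = 4.85 vs the printed smoking odds ratio 4.87 (presumed rounding).
The printed education and packs-per-day t statistics are likewise not
reproducible from the printed summaries under either pooled or Welch forms
and are not used as targets; the gender and smoking chi-squares and the age
t statistic are reproduced exactly.

## Validation statistics

The c statistic counts concordant/discordant/tied case–control pairs
(sort + binary search, O(n log n)); it equals the Mann–Whitney AUC, which
the tests verify against scipy as an independent oracle. Hosmer–Lemeshow
uses deciles of risk (ties kept in one bin), statistic
Σ (O−E)²/(E(1−E/n_g)), df = bins − 2 (df = 8 for 10 bins); degenerate bins
are merged into a neighbour with the df reduced, and the event is logged.
The two-group t test defaults to the pooled-variance form — it reproduces
the printed age statistic from summary data, which Welch does not — with
Welch available by flag; the chi-square applies no continuity correction,
matching the printed values.

Bootstrap internal validation draws B resamples with replacement at the
original n, refits, and records each refit's c **on its own resample**
(matching the original description); an optimism-corrected mode (evaluate
on the original data) is available but off by default. Single-class or
non-convergent resamples are redrawn and counted; more than ~10 % redraws
raises an error.

## Problem sizes and determinism

Default study conditions follow the source protocol: 120 pairs per session,
500 ms ISI, 8–12 s between pairs, 1 kHz sampling, 106 patients / 74
controls per simulated cohort. Test-suite studies use 10,000-subject
cohorts for coefficient recovery, 200 replicates at n = 1,000 for the
stepwise false-entry rate, 100 replicates at n = 2,000 for cutoff
estimation, and B ∈ [100, 200] bootstrap resamples in unit tests (B = 1000
remains the default of the public API). All generators take explicit seeds
and are bit-reproducible; the pipeline writes byte-identical artifacts for
identical configs.

## Known limitations

* The EEG forward model is a single-component template; it validates the
  measurement chain, not source-level physiology.
* EDF support is read-only and requires the optional `mne` dependency;
  writing uses the TSV+JSON fixture format. EDF ingestion is not exercised
  by the test suite.
* Cross-covariate correlations in simulated cohorts are assumptions (0.6 /
  0.3 / 0), not estimates; any joint-model result on simulated data is
  conditional on them.
* The published model's PIQ coefficient issue (above) means absolute risk
  from `score_probability` with the shipped coefficients should not be
  interpreted clinically; ranking (discrimination) is unaffected.
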