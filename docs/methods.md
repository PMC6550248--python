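# Methods

## Coverage estimation for on/off-cycle sampling

A sensor's design is a `SamplingSchedule` (f, d, r, threshold): pings at
frequency *f* during on-cycles of length *d* seconds, separated by rest
periods of *r* seconds. With *S* = 86,400 s, the design expectations are
*b* = *S*/(*d*+*r*) bursts/day and *p* = *f·d·b* pings/day. Neither need
be an integer: the GPS regime (1 Hz, 60 s on, 600 s off) has
*b* = 130.909… and *p* = 7,854.54…, because the 660 s cycle does not
divide the day. Defaults: accelerometer (10, 60, 60), GPS (1, 60, 600),
threshold 30 s for both.

**Burst segmentation.** Within each day, a burst is a maximal run of
pings whose consecutive gaps are *no greater than* the threshold; the
tie (gap exactly equal to the threshold) stays inside the burst.
Implementation is a single vectorised pass over the sorted gap sequence;
its contract is pinned by an independent brute-force reference that
evaluates every consecutive-gap comparison separately and rebuilds
segments in plain Python. Single-ping bursts are allowed (duration 0,
counted in *b̂ᵢ*); duplicate timestamps are retained with gap 0;
unsorted input is an error, not silently reordered, because upstream
readers already sort.

**Daily estimators.** *p̂ᵢ* = Σⱼ *p̂ᵢⱼ*; *d̂ᵢ* = mean duration;
*f̂ᵢ* = *p̂ᵢ*/(*b̂ᵢ·d̂ᵢ*); *Ĉᵢ* = *p̂ᵢ/p*; mean inter-burst gap =
mean over j of (start of burst j+1 − end of burst j). The form of *f̂ᵢ*
is the unique one under which the decomposition
*Ĉᵢ* = (*b̂ᵢ/b*)(*d̂ᵢ/d*)(*f̂ᵢ/f*) is an algebraic identity; the test
suite verifies it to 1e−9 on every non-degenerate day of a cohort-scale
simulation (in practice the error is at the 1e−16 floating-point floor).
Degenerate conventions: a day with no bursts has *p̂ᵢ* = 0, *Ĉᵢ* = 0 and
missing *d̂ᵢ*, *f̂ᵢ*, gap; a day whose bursts are all single pings has
*d̂ᵢ* = 0 and missing *f̂ᵢ*; the gap is missing with fewer than two
bursts. *b̂ᵢ* > *b* and *Ĉᵢ* > 1 are reported as-is — the segmentation
rule can legitimately find more bursts than designed, and we do not cap.

**Day windows.** Days are half-open 86,400 s windows anchored at each
subject's start (their enrollment time when a manifest provides it,
otherwise their first observed ping), so day indexing is deterministic
and timezone-free; pings are assigned to exactly one day and a burst
never spans a boundary. Clock-calendar days and midnight-spanning bursts
were the main open design point; enrollment-anchored windows were chosen
because they make "day 1" comparable across subjects. The same anchor
defines 7-day weeks, so daily and weekly indexing always agree.

## Survey metrics

Each prompted survey records delivery, first-view and submit
timestamps. View latency = first-view − delivery (missing if never
viewed); completion latency = submit − first-view (missing if never
submitted); both validated non-negative, with violations raised as
data-integrity errors naming the survey. Item responses are integers on
the 0–3 Likert scale; a domain score is the mean of the *answered*
items of that domain (item non-response tolerated), missing if none
answered. A viewed-but-unsubmitted survey contributes to view latency
but not to completion latency, completion counts or scores. The default
`DomainMap` is a synthetic 23-item instrument over mood, anxiety,
sleep, psychosis and medication adherence (5/5/4/5/4 items); it is a
stand-in, not a reconstruction of any particular instrument, and is
overridable in configuration.

## Weekly features and lagging

Subject-week rows carry A and G (mean daily coverage over the week's
days, counting zero-coverage days), V and C (means over surveys
*delivered* that week that were viewed / completed), T (count of
surveys *submitted* that week) and per-domain Y (mean score over
surveys submitted that week). Delivery-week attribution keeps latency
units interpretable; submission-week attribution makes T a completion
count. `lag_table` pairs Y at week j with covariates at week j−l
strictly within subject; rows with any missing value are dropped
(complete case — no imputation) and counted in the table's metadata.
Covariate standardisation (z-scoring within the analysis set) is
available behind a flag and off by default.

## The association model

`SymptomLagModel` fits the Gaussian random-intercept regression
Y = β₀ + μᵢ + β·X + ε per domain × lag by REML (statsmodels `MixedLM`)
with Wald z tests on fixed effects; the estimator and test are recorded
in the output metadata since other choices (ML, likelihood-ratio,
Satterthwaite) are defensible. Numerical choices: covariates are
rescaled to unit variance *internally* for conditioning (latencies are
in seconds, coverages in [0, 1]; the reparameterisation is exact and all
reported quantities are back on the original scale); optimizers are
tried in the order lbfgs → bfgs → powell until one converges (gradient
tolerance 1e−8, 200 iterations, statsmodels' deterministic
variance-component initialisation); constant covariates are dropped
with a warning and reported as missing cells; fewer than two subjects
or fewer rows than fixed effects is an estimation error. At the
σ_μ = 0 boundary the fit collapses to OLS, which the tests verify to
1e−6.

Multiple testing uses the Benjamini–Hochberg–Yekutieli step-up rule
with harmonic correction c(m) = Σ 1/k, rejecting the i* smallest
p-values where i* is the largest i with p₍ᵢ₎ ≤ i·q/(m·c(m)), at
q = 0.05. The family is the full covariate × domain × lag grid by
default (`per-lag` is available), the conservative reading of
"corrected across the grid". BY's validity under arbitrary dependence
matters here because cells at neighbouring lags share data. Wald
p-values can underflow to exactly 0 for extreme z statistics; grid
assembly clips them to the smallest positive double so −log₁₀ p and the
step-up rule stay defined.

## The synthetic cohort

The simulator is the package's test bed and defines its study
conditions: 16 subjects, 13 weeks, the two sensor schedules above,
prompts at 10:00 on Monday/Wednesday/Friday (any enrollment-anchored
7-day window therefore contains exactly three prompts).

*Sensors.* On-cycles run continuously from enrollment (the device does
not re-anchor at midnight). Missingness has three independent levers
per sensor: burst dropout π_b, burst truncation (realised duration
d·U, U ~ Uniform(t_low, 1)), and ping retention π_p, giving expected
coverage ≈ (1−π_b)·π_p·(1+t_low)/2. The defaults — accelerometer
(0.25, 0.56, 0.80), GPS (0.30, 0.70, 0.85) — put expected first-month
coverages near 0.47 and 0.51 respectively, a realism preset chosen once
to mirror the roughly-half coverage reported for cohorts of this kind.
With all three levers off, the accelerometer reaches daily coverage
exactly 1.0; GPS cannot on any single day, because its fractional
*p* = 7,854.54… can never equal an integer ping count — the scheduled
stream alternates 7,860/7,800 pings per day and attains exact unit
coverage over the schedule's natural 11-day period (11 days = 1,440
cycles exactly). Calibration is therefore asserted per-day for the
accelerometer and per-period for GPS.

*Surveys and outcomes.* View latency is a two-component log-normal
mixture (medians 30 s and 3,600 s, σ = 0.8/1.0, equal weights) —
immediate versus delayed responders, verified bimodal by a
two-component GMM BIC + Ashman-D check; completion is Bernoulli with a
logistic link to the subject-week latent symptom level; completion
latency is log-normal (median 180 s). Latencies are capped at 48 h
(the survey expires before the next prompt window), which also keeps
every submission inside its delivery week so full-adherence calibration
(T = 3/week) is exact. Weekly domain outcomes are generated
*continuously* from the random-intercept regression on the realised
covariates of the week lagged by a configurable true lag (default 1;
weeks before the lag is reachable use population baseline covariates),
then mapped to integer items by largest-remainder apportionment, so the
observed weekly domain mean equals the generated outcome within
1/(2k) for a k-item domain and the regression holds exactly in the
exported ground truth. The default truth coefficients are a realism
preset (signs: worse scores with lower accelerometer coverage, higher
GPS coverage, faster viewing, slower completion, fewer completions)
scaled to keep scores interior to [0, 3]; calibration studies pass
their own coefficients.

A fixed seed makes the whole study byte-identical (per-subject,
per-stream generators spawned from one `SeedSequence`); the manifest
records per-file SHA-256 digests. A table-level generator
(`simulate_weekly_table`) draws covariates i.i.d. from
pipeline-shaped distributions and applies the outcome equation without
measurement rounding; recovery/type-I/FDR studies use it so the model
being fitted is exactly the model that generated the data.

*What the simulator does not emulate* — and hence what passing tests do
not establish about real cohorts: informative missingness beyond the
latency/completion links (real sensor gaps correlate with behaviour and
device state), device/OS heterogeneity, accelerometer waveform or GPS
spatial structure (payloads are white noise), survey content validity,
and drift in schedule parameters over time. The calibration results are
statements about the estimators and the fitting machinery, not about
clinical effect sizes.

## Problem sizes in the calibration suite

Chosen as the package's own defaults: segmentation and BY oracles use
1,000 random instances each; the coverage identity runs on the full
16-subject × 90-day cohort; zero-missingness calibration uses 22 days
(two full GPS periods); dropout calibration 200 days at π_b = 0.5
(asserted within 3 Monte-Carlo SEs of 0.5); CI coverage 200 replicates
and type-I error 500 replicates of a 50-subject × 12-week study; FDR
control 500 replicates of a 30-subject × 10-week, 2-domain × 2-lag null
grid; CLI reproducibility two complete 3-subject × 6-week runs compared
by file hash.

## Known limitations

Weeks are enrollment-anchored blocks, not calendar weeks; surveys are
attributed to weeks by delivery (V, C) and submission (T, Y), so a
survey submitted after its delivery week moves mass between adjacent
weeks in real (uncapped) data. Wald z tests are mildly anticonservative
in very small cohorts relative to Satterthwaite-type corrections. The
complete-case lag table discards information when covariate missingness
is structured. The estimators quantify how much data arrived, not why
it is missing; coverage is not a missingness mechanism.
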