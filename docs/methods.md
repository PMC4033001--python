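# Methods

This note documents the models, estimators and numerical conventions
implemented in `rehabtap`, the choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Signal chain

**Preprocessing order.** Recordings are processed trim → calibrate →
smooth: the first and last 0.5 s are discarded (start-up and
hand-withdrawal artifacts), raw sensor readings are mapped to Newtons
by piecewise-linear interpolation over a monotone calibration table
(readings outside the table range clamp to the end forces), and the
force channel is convolved with a unit-sum triangular window
(`scipy.signal.windows.triang`), 160 samples by default — ≈53 ms at the
nominal 3 kHz rate. The window length and sample rate are independent
parameters; the 53 ms correspondence is emergent, not hard-coded. The
kernel is centred with reflected edges so output length equals input
length, constant signals are fixed points, and landmark times are not
systematically delayed. The triangular form (nonzero endpoints) is
used rather than the zero-endpoint variant, whose 3-sample window would
degenerate to the identity. After trimming, the trace carries its time
origin (`t0_ms`) so all landmark times remain in original-recording
coordinates.

**Landmark detection.** Scanning forward, an onset fires at the first
sample whose force strictly exceeds the 0.05 N threshold, provided at
least 75 ms have elapsed since the previous tap's offset; the matching
offset fires at the first sample strictly below threshold at least
40 ms after that onset. Ties exactly at threshold fire nothing. A
trailing onset with no qualifying offset is discarded. Landmark time is
the time of the first qualifying sample — no sub-sample interpolation,
which could change times by at most one sample at 3 kHz. The threshold
is a per-recording parameter: a manual override (for patients tapping
too softly or off the sensor) is an explicit config field recorded in
the output provenance, not an interactive step. The same threshold is
used for onsets and offsets (no hysteresis). No slope criterion is
applied: the threshold rule alone defines a "sudden impact".

A known, intended consequence of smoothing before detection: the 53 ms
kernel spreads each pulse's foot backwards in time, so the 0.05 N
crossing on the smoothed trace occurs up to ~25 ms earlier than on the
raw trace. This shift is common to all taps in a recording — it cancels
exactly in inter-tap intervals, in the resultant length R, and in any
between-session contrast — but it biases *absolute* asynchrony
estimates; analyses that need unbiased absolute landmark times (e.g.
mean tap-to-click asynchrony in physical ms) should detect on the
unsmoothed trace, as the parameter-recovery tests do.

**Interval filtering.** ITIs are onset-to-onset differences. Intervals
strictly longer than 2000 ms are pauses, strictly shorter than 120 ms
are double-tap artifacts; both are flagged and excluded from metrics
but retained for audit. The boundary values 120 and 2000 ms are kept
(closed interval), following the wording "larger than"/"shorter than".
Double-tap re-contacts with legal refractory spacing are *detected* as
taps — physiology is enforced by the interval filter, not the detector.

## Tapping outcomes

Speed is the sample median of the kept intervals (even counts: mean of
the central pair); variability is the coefficient of variation in
percent after a single-pass 3-SD trim: the block mean and sample SD
(n−1 denominator throughout — the clinical-statistics convention)
define the band mean ± 3·SD, intervals outside it are discarded once
(no iteration), and CV = 100 × SD/mean of the survivors. The
denominator is the post-trim mean, so numerator and denominator
describe the same sample; a switch (`post_trim_mean=False`) restores
the pre-trim block mean for sensitivity analyses, since the defining
sentence admits either reading. Blocks recorded before and after a
therapy session are pooled by concatenating kept intervals — the
boundary between blocks never forms an interval. Analysis windows are
measured from the first tap: ~14 s for speed tapping, 60 s paced.
Metrics on empty input propagate as missing (NaN), never as zero.

Note the trimmed CV estimates the *trimmed-distribution* CV: under a
log-normal interval distribution with cv = 0.10 the single 3-SD trim
removes ≈0.4% of intervals, giving an estimand of ≈0.0980 rather than
0.100. The parameter-recovery tests compare against this estimand
(frozen from a 4-million-sample oracle simulation), not the raw
generator parameter.

## Circular synchronization

Each onset is referenced to its *nearest* click (symmetric, no
directional assumption): phase = 2π(onset − click)/T ∈ (−π, π], with
the half-cycle tie mapped to +π, T = 60000/tempo ms. Summaries: mean
resultant length R = |n⁻¹ Σ e^{iθ}|, circular mean phase (argument of
the mean vector), angular SD √(−2 ln R), and the Rayleigh uniformity
test with Z = nR² and the standard series approximation
p ≈ e^{−Z}[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],
clamped into (0, 1]. R is the synchronization outcome fed to the ANOVA
(higher = more synchronized); the angular SD is exported as an
alternative, since the choice of circular dependent variable is a
convention. R and the Rayleigh p are invariant under common time
shifts and under joint rescaling of onsets and schedule; the mean phase
rotates equivariantly.

## Clinical scores

9HPT improvement is POST − PRE completion time in seconds (negative =
faster = better). POMS: 35 items rated 1–5, subscale scores are item
*sums*; the item→subscale mapping is an editable configuration whose
default follows the 35-item short-form convention (14 depression/
anxiety, 7 fatigue, 7 vigor, 7 hostility) — a scoring convention, not a
fixed property of the instrument. Validation rejects out-of-range
ratings and mapping gaps/overlaps. The faces scale is an ordered list
of letter codes (default 7 faces, configurable) mapped to 0-based
ordinals with higher = happier. The Barthel index arrives pre-scored
and is carried as a covariate only.

## Statistical battery

**Mixed ANOVA.** One between-subject factor (group) × one
within-subject factor (session), complete design required (no silent
imputation), group sizes may differ. The decomposition splits the
between-subject stratum into group and subject-within-group error, and
the within-subject stratum into session, group × session, and
session × subject error, via sequential projections that coincide with
the classical formulas for balanced designs and with R's `aov` for
unequal groups. For k ≥ 3 within levels, Mauchly's W is computed on
the *pooled within-group* covariance (error df N − G) projected onto
k − 1 orthonormal contrasts, with the standard χ² approximation;
Greenhouse–Geisser ε̂ = (Σλ)²/((k−1)Σλ²) from the contrast-covariance
eigenvalues, clamped into (1/(k−1), 1]. Both the uncorrected and the
ε-corrected p are always reported; the headline p is the GG p whenever
Mauchly is significant at α = 0.05. With k = 2, ε = 1 exactly and the
two p values coincide. Effect sizes are generalized eta squared:
η²_G = SS_effect/(SS_effect + SS_subject + SS_within-error), the
design-robust definition appropriate for mixed designs. The
implementation was verified against R's `car::Anova` (type III,
sum-to-zero contrasts): SS, F, Mauchly W and p, ε and corrected p agree
to printed precision; pingouin agrees on SS/F/p (its sphericity helper
pools across groups without removing group means, which is not the
mixed-design convention). A zero error stratum (noiseless data)
reports an infinite F with p = 0 rather than failing.

**Post-hoc contrasts.** Tukey HSD from fitted cell means:
q = |mᵢ − mⱼ|/√(MS_error/n), p from the studentized-range distribution;
with two cells this reduces exactly to the pooled two-sided t test via
q = t√2.

**Nonparametric/exact battery.** Fisher's exact test (two-sided by the
"probability at most that of the observed table" rule, the convention
of R's `fisher.test`); Mann–Whitney reporting both the rank-sum-form W
(U of the first sample) and the signed normal deviate Z with mid-rank
tie correction and 0.5 continuity correction; Welch's t with
Satterthwaite fractional df; Friedman's rank χ² with tie correction,
df = k − 1. The asymptotic Friedman and Mann–Whitney p values were
checked against exhaustive within-row permutation (6⁸ tables) and
C(10,5) enumeration oracles on small samples.

**Outcome transforms.** Positively supported outcomes (median ITI, CV,
pegboard times) are natural-log transformed before parametric group
analysis; the transform is recorded in a provenance column and
non-positive values are rejected by name. Printed group summaries
remain on the raw scale; tests operate on the log scale.

**Minimization randomization.** Small accrual batches (1–3 patients)
are assigned by enumerating every labelling that keeps |n_A − n_B| ≤ 1,
scoring each candidate roster by a standardized imbalance — for each
numeric covariate (age, Barthel, pegboard baseline)
|mean_A − mean_B| / pooled SD, plus the absolute difference in female
proportion, equally weighted — and choosing the minimum, with ties
broken uniformly at random by the supplied seed. Batches of 2–3 are
the design's normal case; a batch of 1 (a trailing accrual) is allowed
and is then dominated by the size rule. The metric's equal weighting
and pooled-SD standardization are this package's choices; simulation
shows the final imbalance is roughly a third of the random-allocation
median at n = 28 while never violating the size constraint.

## Synthetic data

**What it emulates.** Unpaced traces: log-normal ITIs parameterized by
(mean, CV) — strictly positive and right-skewed like real inter-tap
intervals; piecewise-linear rise/plateau/fall force pulses (~1 N peak,
80 ms dwell, 5/10 ms rise/fall) on a 3 kHz grid; additive Gaussian
sensor noise clipped at 0 N (a resistive sensor cannot read negative
force); soft taps with peak drawn uniformly below the 0.05 N detection
threshold; double-tap re-contacts 117–119 ms after their host onset
(the host dwell shortens to 42 ms so the artifact respects the
75/40 ms refractory geometry while staying under the 120 ms filter
bound); and pauses of 2.2–4 s. Paced traces: clicks spaced exactly
60000/tempo ms (default 69 BPM), tap onsets offset by normal
asynchronies wrapped onto (−T/2, T/2]. Drawn intervals are clipped
from below so consecutive pulses always respect the detector's
refractory geometry. Cohorts: log-normal pegboard PRE times
(~57 ± 35 s) with normal per-group improvements, latent-normal POMS
items rounded into 1–5 with a shared per-subject effect (paired
structure), and linearly drifting faces ratings on a 7-point ordinal
scale over twelve time points. All generators are bit-reproducible
from (params, seed).

**Ground truth.** Each generated contact is recorded with the exact
sample indices at which the *clean* (noise-free, unsmoothed) signal
crosses the detection threshold, making landmark-level oracle
comparisons well defined at ±1 sample. Soft taps never cross; their
nominal pulse extent is recorded and they are flagged `soft`.

**What it does not emulate, and what passing tests show.** No
accelerometer kinematics, no amplitude drift, fatigue, tremor,
sensor-surface misses, or burst noise; pulse shapes are stylized and
noise is white. Passing recovery tests therefore demonstrate that the
chain is *correct and calibrated under its stated assumptions* — they
do not certify performance on pathological real recordings, which is
what the per-recording threshold override and audit trail exist for.

**Problem sizes.** The suite's standing simulations use ~1 200
landmarks over 100 zero-noise traces for oracle equivalence, ~20 000
taps for interval-metric recovery (Monte-Carlo error ≈0.5%, well below
the 2% assertion), ~140 paced taps for synchronization recovery, 1 000
null cohorts (n = 10/group) for type-I calibration, and 1 000
simulated 28-patient accruals for the randomizer — sizes chosen so
Monte-Carlo error is small relative to each assertion's tolerance.

## Known limitations

* The calibration mechanism is implemented, but real calibration-table
  values are hardware-specific; synthetic tables exercise the path.
* Mauchly's χ² approximation is poor for very small samples (as is
  standard); ε-corrected p values are reported regardless of the gate.
* The sequential SS decomposition is the `aov` convention; strongly
  unbalanced groups would make type-II/III distinctions relevant for
  the between-subject effect.
* The Friedman and Rayleigh p values are asymptotic; exact versions are
  used only as test oracles at small n.
* Exactly one between and one within factor are supported — the
  design's shape — not general factorial layouts.
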