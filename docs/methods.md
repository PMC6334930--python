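# Methods

This note documents the models, conventions and numerical choices behind
ethokit, in the spirit of a statistical appendix: what each procedure
assumes, which parameters matter, and where the design was genuinely
open.

## Linked tables

A `LinkedBehaviourTable` pairs a long data table (one row per read:
`id`, `t` in seconds, behavioural variables) with a metadata table (one
row per individual). Construction is permissive towards metadata-only
individuals — an animal that produced no reads is a legitimate
experimental outcome — but strict the other way: a data row whose id is
absent from the metadata is an error naming the orphans, because it can
no longer be interpreted. Every data-filtering operation restricts the
visible metadata to exactly the ids still present in the data, so
group-by-metavariable summaries can never silently include individuals
whose reads were all removed.

Duplicate `(id, t)` rows are kept at ingestion (hardware can emit ties);
operations that need a regular series deduplicate explicitly through
resampling. Time binning (`bin_time`, resampling) is half-open
`[k·w, (k+1)·w)` and left-anchored at `t = 0`, so negative times (after a
baseline shift) fall into negative-index bins; the convention is
arbitrary but applied uniformly.

## DAM2 import

Monitor files are parsed as 42 tab-separated fields per line: reading
index, date (`19 Nov 13`), time, a status code, five unused fields, a
light-sensor flag, and 32 channel counts. Each metadata row is resolved
to a file and channel, and its id minted as
`"<start_datetime>|<file>|<NN>"` — an identifier that is unique across
experiments, unlike any user-facing label. Reads are kept when their
timestamp lies in the closed window `[start_datetime, stop_datetime]`,
and `t` is seconds since the row's own start, which self-aligns replicate
experiments; a subsequent baseline shift
(`t := t − days(xmv("baseline_days"))`) can re-anchor all animals to a
shared experimental event such as a lighting transition. Readings with a
status code other than 1 are kept and counted in a warning rather than
dropped — silent data loss is worse than a noisy record. Timestamps are
naive local time; devices log local time and no timezone arithmetic is
attempted.

## Dead-animal curation

The detector scans windows of `time_window` seconds (default 2 days; 1.5
days is a common choice for fly experiments) on a grid with
`time_window / resolution` stride (resolution default 24, i.e. windows
every 2 h for the default length). An animal is scored dead from the
first window in which the mean of the boolean target (`moving`) over the
reads actually present is strictly below `prop_immobile` (default 0.01:
immobile more than 99% of the time); all reads from that window start
onward are discarded. Choices worth noting:

* The scan grid is anchored at each animal's first read; animals
  spanning less than one `time_window` are never scored.
* Windows are evaluated on available reads only, with no gap imputation,
  and trailing windows that extend past the end of the record still
  count — an animal dying shortly before the recording stops is caught.
* Truncation is permanent: an animal that "revives" after a qualifying
  dead window stays truncated, which is the desired behaviour for
  escapes and tracking failures as well as deaths.
* The operation is idempotent (re-curation removes nothing further) and
  only ever removes a suffix in `t` of each series: removing trailing
  all-immobile reads can only raise the moving fraction of the windows
  that remain.

With 60 s reads and the default 1% threshold, the truncation point lands
within one grid stride of a simulated death time in ≥ 99% of cases (the
acceptance suite measures this over 200 simulations).

## Periodograms and rhythmicity

All four estimators consume a per-individual series resampled to a
regular grid (default 10-minute bins of the mean; empty bins are
missing) and return a common table of period, power and significance
threshold.

**Chi-square (Sokolove–Bushell).** Candidate periods are integer
multiples of the sampling interval — phase folding requires whole bins —
inside the search range (default 16–32 h). At a period of `r` bins the
statistic is `Q_P = K · Σ_h (M_h − M̄)² / s²` with `M_h` the phase-class
means, `M̄` the grand mean, `s²` the (population) variance and
`K = N/r`; under the no-rhythm null `Q_P ~ χ²(r−1)`. Missing bins are
dropped from every mean and `N` is the available count. `Q_P` is
invariant to affine rescaling of the series, and a series with zero
within-phase variance at `P` attains `Q_P = N` exactly.

**Significance and multiplicity.** The default threshold applies a Šidák
correction across the M candidate periods (per-period level
`1 − (1−α)^(1/M)`), so a whole periodogram of a non-rhythmic series
crosses its threshold anywhere with probability ≈ α. This is a
deliberate calibration choice: simulation shows the per-period χ²
quantile is correctly calibrated (≈ 5% exceedance at any single period)
but, with ~97 correlated candidate periods, an uncorrected scan flags
essentially *every* arrhythmic individual somewhere in the range —
a useless classifier at the population level. `correction="none"`
restores the raw per-period quantile (appropriate for one pre-specified
period, and for textbook worked examples), and `"bonferroni"` is
available; Šidák under positive dependence is mildly conservative, which
is the acceptable direction for claiming rhythmicity.

**Lomb–Scargle.** Classical normalised periodogram (power divided by the
sample variance, unit-mean exponential under white noise) on a frequency
grid spanning the period range with 4× oversampling of the natural
resolution `1/T`. The threshold is the standard M-independent-frequencies
level `z* = −ln(1 − (1−α)^(1/M))`; sharper extreme-value bounds are out
of scope. A constant series is defined to have zero power everywhere.

**Autocorrelation.** Power at lag `L` is the sample ACF; the white-noise
band is `Φ⁻¹(1−α/2)/√N`, uncorrected (the conventional correlogram
band). **Fourier.** Discrete Fourier power of the mean-subtracted series
normalised by `N·s²` (unit-mean under white noise) at the Fourier
frequencies in range, with the same M-frequency threshold as
Lomb–Scargle.

**Peak detection.** A candidate peak is a local maximum of power that
exceeds its significance threshold and is maximal within ±5% of its own
period; candidates are ranked (up to 3) by descending relative power
(power − threshold), and lower-ranked candidates within 5% of a kept
peak's period are suppressed. The ±5% exclusion window is a documented
choice — wide enough to merge one rhythm's grid-level shoulder, narrow
enough to keep genuinely distinct ultradian/circadian pairs apart. An
individual is *rhythmic* iff it has a rank-1 peak; its first-peak period
and relative power feed the population summaries.

**Population statistics.** `group_summary` reports, per group, the mean
and SD (in hours) of the first-peak period over rhythmic individuals,
the percentage rhythmic, and raw counts, rounded to two digits
(round-half-even; the reference percentages are insensitive to the tie
rule). `two_group_logit_fit` is the binomial GLM with logit link for a
two-group design in closed form: `β₀ = ln(k₁/(n₁−k₁))`,
`β₁ = ln(k₂/(n₂−k₂)) − β₀`, with expected-information Wald standard
errors `√(1/k + 1/(n−k))` summed over the groups involved. The closed
form is the exact MLE (the model is saturated), so it matches an IRLS
fit to the solver's tolerance; complete separation (k = 0 or k = n) has
no finite MLE and raises rather than returning pseudo-estimates.

## Wavelet spectrograms

The continuous wavelet transform uses the Morlet wavelet with centre
frequency ω₀ = 6 and dj = 1/20 suboctaves — the conventional defaults
for time–frequency analysis of geophysical and behavioural series —
implemented as the standard zero-padded FFT transform with the
`√(2πs/δt)` frequency-domain normalisation. Scale and Fourier period are
related by `λ = 4π/(ω₀ + √(2+ω₀²)) ≈ 1.033`, so the period axis is
essentially the scale axis. The series mean is removed first; NaN gaps
are linearly interpolated (the transform needs regular input) and
interpolated spans longer than 10 samples are masked. A cone-of-influence
mask flags cells within one e-folding time `√2·s` of either record edge;
masked cells are excluded from every downstream average. Daily folding
averages power over `t mod 24 h` into 144 ten-minute phase bins;
light/dark marginals average the folded power over phase windows
(default L = [0, 12 h), D = [12 h, 24 h)); population averages are
element-wise means over individuals sharing a grid. Exact reproduction
of any particular tool's colour scaling is not claimed — the tested
quantities are ridge locations and folded/marginal power tables.

## Synthetic data

The generators define the conditions under which the statistical claims
are tested:

* **Activity**: counts per 60 s reading are Poisson with rate
  `λ₀ · (1 + a·sin(2πt/P))`, optionally multiplied by a light–dark
  square wave, with λ₀ = 2 counts/min as a typical healthy-fly baseline,
  periods in the 16–32 h band of interest (25 h for the
  lengthened-period scenarios), and recordings of 6–10 days. Death is a
  hard truncation of the rate to zero — exactly the signature the
  curation step must detect. Poisson is the minimal count process with
  the right support for beam crossings; real fly activity is
  overdispersed and bursty, so passing recovery tests here demonstrates
  correctness of the estimators, not their power on the hardest real
  data.
* **Position**: 0.1 Hz samples in [0, 1] composed of a circadian mean
  drift, a fast pacing oscillation whose instantaneous period follows a
  schedule integrated through the phase (`dφ/dt = 1/p(t)`), and Gaussian
  noise, clipped to the tube. A period schedule drifting across the day
  reproduces the frequency-modulation structure that the folded
  spectrogram is designed to reveal.

Both are pure functions of their spec including its seed, and activity
series round-trip bit-exactly through the DAM2 writer and parser.

## Problem sizes and determinism

The test and acceptance workloads use 6–10-day recordings at 60 s reads
(activity) or 10 s samples (position), populations of up to ~50
individuals, 100–200 simulation replicates for recovery rates, and 500
trials for bootstrap coverage — sizes at which every statistical check
runs in seconds while leaving the Monte-Carlo error well inside the
asserted margins. All randomness flows through explicitly seeded numpy
generators; the pipeline writes byte-identical summary CSVs when re-run
with the same config and seed.

## Known limitations

* Single-beam DAM2 text files only; multi-beam monitors, environmental
  sensor channels and video-tracking databases are out of scope.
* The chi-square periodogram's null assumes exchangeable bins; strong
  within-day autocorrelation (activity bouts) inflates per-period
  exceedance beyond the nominal level even with the Šidák family
  correction. This is the main statistical caveat when interpreting
  percent-rhythmic tables.
* Lomb–Scargle significance uses the classical independent-frequency
  approximation rather than modern extreme-value bounds.
* No phase estimation, rhythm-strength indices, cosinor regression,
  sleep-bout scoring, or wavelet significance testing against red-noise
  nulls.
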