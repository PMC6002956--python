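# Methods

This note documents the conventions, models and numerical choices behind
`damkit`. Where the DAM ecosystem has no single fixed convention, the
choice made here is stated explicitly; the test suite asserts exactly
these behaviors.

## Monitor-file dialect and validation

DAMSystem3 monitor files are read as 42 tab-separated fields per row:
reading index; date `D Mon YY` (English month abbreviations, two-digit
years mapped to 2000–2099); time `HH:MM:SS`; status code; five device
extras (parsed and ignored; written back as zeros); a 0/1 light-sensor
flag; and 32 channel counts. ASCII/UTF-8 with LF or CRLF endings.

Validation is total: every file yields either a `MonitorData` (possibly
with warnings) or a rejection carrying the complete issue list.

- **Status codes.** 0 and 1 are valid; any other value marks a hardware
  error — the row is dropped with a warning. The accepted set is a
  module constant, since vendor firmware is not fully documented.
- **Timestamp grid.** Timestamps must be strictly increasing on an exact
  grid of the declared acquisition interval. Dropouts of up to 6 missing
  intervals are repaired by inserting zero-count records (one warning per
  gap); longer gaps, duplicate timestamps, and off-grid spacings are
  fatal, because they invalidate binning. Holes left by rows dropped for
  bad status codes are exempt from gap handling — they have already been
  warned about once, and inventing zero counts there would fabricate
  inactivity. Days containing such holes are simply incomplete.
- **Accounting invariant.** rows in = rows retained + rows dropped with a
  `bad_status_code` warning; no silent drops.
- Daylight-saving shifts are not modeled; timestamps are taken as
  written.

Legacy DAMSystem2 channel files (`index, date, time, status, count`) are
merged column-wise; missing channels are zero-filled with warnings, and
any disagreement between channel-file time grids is fatal.

## Experimental days, regimes and phases

Experimental days run **light onset to light onset**, not midnight to
midnight, so every complete day contains one full day phase followed by
one full night phase; day/night totals are then well defined. In DD the
same onset-anchored boundary is kept as the subjective day, since the
free-running phase is unknown. The regime (LD/DD/excluded) of a reading
comes from the calendar-date membership of its timestamp in the
configured LD and DD date ranges; within LD, the phase is *day* iff the
time of day lies in `[light_onset, light_onset + day_length_hours)`.
`day_length_hours` defaults to 12 (the usual 12:12 paradigm) and is
configurable. A consequence of date-based filtering plus onset anchoring
is that the first and last experimental days of a date range are
partial; all per-day statistics flag and, where stated, exclude them.

Binning aligns bin boundaries to the light onset and keeps only complete
bins, so a sum-binned series conserves the raw total minus the dropped
partial bins.

## Dead-fly exclusion

A fly is dead iff its total counts on **any complete** experimental day
fall below the threshold (strictly `total < threshold`, so threshold 0
never kills); the first such day is reported. Partial first/last days
never drive death calls — their totals are biased low. The default
threshold is 50 counts/day, a conventional lab choice, and is exposed in
the config. Default handling excludes the whole fly from all downstream
statistics (`dead_mode: exclude`); `dead_mode: truncate` instead keeps
the days strictly before the first sub-threshold day. The dead set is
monotone non-decreasing in the threshold, and on synthetic flies with
programmed post-death silence the first dead day is recovered exactly
for any positive threshold; both properties are asserted in the tests.

## Activity statistics

Condition summaries aggregate **fly-level first**: each fly contributes
the mean of its daily totals over complete days in scope, and the
condition mean and SEM (sd/√n, ddof 1) are taken across flies. This
keeps flies with unequal numbers of observed days equally weighted and
makes the SEM a between-individual quantity. A single-fly condition
reports SEM 0 with n = 1; an empty condition reports n = 0 and an
undefined mean rather than failing.

An **activity bout** is a maximal run of consecutive readings with
count > 0; its length is the run length times the acquisition interval.
Bouts are assigned whole to the day containing their first reading (no
splitting), which preserves bout-length statistics at day boundaries.
Per day, Σ bout lengths = interval × number of active readings, except
that a boundary-crossing bout moves its tail minutes into its onset day.

Activity profiles come in two modes: `full_experiment` (mean ± SEM of
per-bin counts across flies over the whole span) and `ld_average` (each
fly's complete LD days are folded onto a 24 h time-of-day axis anchored
at light onset before averaging across flies).

## Sleep

Sleep uses the standard fly convention: a continuous period of zero
counts lasting at least `window_minutes` (default 5 min). Scoring marks
every minute inside a maximal zero-count run whose duration reaches the
window; this is mathematically identical to marking all minutes covered
by any all-zero sliding window of that length, and the test suite
asserts the equivalence on random traces. Consequences asserted as
properties: no sleep bout shorter than the window exists, and the sleep
set shrinks monotonically as the window grows.

Acquisition intervals finer than 1 min are first summed to 1-min bins;
intervals between 1 min and the window that divide it evenly are scored
at native resolution with a window of `window / interval` readings;
coarser intervals are rejected as unable to resolve the definition.
Runs touching the series boundary count by their observed length (no
censoring correction). Runs crossing the LD/DD boundary are scored once
on the full series and their minutes attributed to regimes by timestamp.

Day/night sleep totals, sleep profiles (mean sleep fraction per bin,
fly-means first) and sleep bouts (maximal runs of sleep minutes,
onset-day assignment) follow the activity conventions above.

## Chi-square periodogram

Counts are pre-binned to the widest bin Δ that divides every tested
period and is a multiple of the acquisition interval (Δ = gcd of the
minimum period and the resolution, in minutes: 6 min for the default
18–30 h × 0.1 h grid; 30 min at 0.5 h resolution). A resolution not
representable on the reading grid is rejected with a suggested
alternative. For each tested period of *p* bins, the series is truncated
to *K* = ⌊N/p⌋ complete cycles (the ragged last cycle is discarded, for
determinism and the textbook form) and

Q(p) = K · N′ · Σ_h (M_h − M)² / Σ_i (x_i − M)²,  N′ = K·p,

with column means M_h and grand mean M over the folded points. Under the
null Q(p) ≈ χ²(p − 1).

**Significance line.** A periodogram scan tests many periods at once
(121 on the default grid), so an uncorrected per-period quantile would
flag noise as rhythmic in nearly every fly — empirically ~99 % of
simulated Poisson-noise flies exceed an uncorrected 0.05 line somewhere
on the default grid. The significance line therefore treats `alpha` as
the family-wise level of the scan and Šidák-corrects the per-period
quantile, `1 − (1 − α)^(1/m)` over m tested periods, by default;
`correction` may be set to `bonferroni` or to `none` for the raw
per-period line when comparing against software that uses it. With the
default line, ≥ 95 % of rhythm-free flies are called arrhythmic at
strength threshold 1 while strongly rhythmic fixtures score strengths
of 4 and above.

**Peak and rhythm strength.** The peak is the tested period maximizing
Q − S (the significance-referenced excess), ties broken toward the
shorter period for determinism. Rhythm strength is Q(peak)/S(peak);
flies with strength below the threshold (default 1, boundary inclusive)
are arrhythmic and excluded from mean periodograms and period box
plots. A zero-variance series yields strength 0, an undefined peak, and
an arrhythmic call rather than an error. Q is scale-invariant
(a ratio statistic), and the implementation matches an explicit-loop
fold to 1e-9 relative error in the tests.

Period analysis runs on DD (free-run) days; the pipeline requires at
least 3 cycles of the longest tested period of DD data and skips the
analysis (with a log note) otherwise.

## Actograms

Actogram matrices have one experimental day per row and onset-anchored
time-of-day bins per column, for a single fly or a per-(day, bin)
mean/median across the flies of a condition. Double plotting
concatenates day d with day d+1 in row d; the last row's right half is
absent markers (NaN). The redundancy invariant — right half of row d
equals left half of row d+1 wherever both exist — is asserted in tests.

## Synthetic data generator

Beam crossings are event counts, so each simulated fly is an
inhomogeneous **Poisson** process: counts per reading are
Poisson(λ(t) · interval) with λ(t) = max(0, baseline + amplitude·w(t)),
where w is a sinusoid, a square wave (active first half-cycle — the
default, because it gives crisp periodogram and sleep fixtures), or a
crepuscular double-Gaussian with dawn/dusk peaks. LD masking scales the
day-phase rate by 2f and the night-phase rate by 2(1−f) for
`day_active_fraction` f (0.5 = no masking, 1.0 = fully diurnal; the
scaling preserves the daily mean under 12:12). Death silences the
channel from the programmed day's light onset. Monitors cover whole
calendar dates midnight-to-midnight, so — as in a real recording — the
first and last onset-anchored days are partial.

Randomness comes exclusively from `numpy.random.default_rng(seed)`,
drawn channel by channel in channel order, so identical (specs,
calendar, seed) reproduce byte-identical files; fixtures in the test
suite rely on this. Ground truth (true period, death day, expected
daily counts, programmed zero-rate blocks) is emitted alongside.

What the generator does **not** emulate: startle responses at light
transitions, masking dynamics, position-dependent beam sensitivity,
inter-fly correlation, or overdispersed counts. Passing tests on this
data therefore validate the pipeline's arithmetic and inference rules,
not its robustness to every artifact of real recordings.

## Problem sizes and runtime choices

The test fixtures use one simulated monitor over 3 LD + 7 DD days at
1-min acquisition; parameter-recovery checks use 16 flies per programmed
period (22/24/26 h, 7 DD days, 0.1 h resolution), 200 noise flies for
the specificity check, and 50 random 6-day series at 0.5 h resolution
for the brute-force periodogram comparison — sizes at which each check
is both statistically informative and quick to run.

## Known limitations

- Light-sensor data are parsed but unused; LD/DD ranges come from the
  config, not from the sensor.
- No statistical tests between conditions are computed; the CSVs are
  exported for external statistics.
- Whether the original GUI tool anchors experimental days at light onset
  or midnight, scores boundary-touching inactivity runs, or breaks
  strength ties at the threshold is not publicly specified; this
  package's choices (onset anchoring, observed-length scoring, inclusive
  threshold) are documented here as its own definitions.
- Sub-minute acquisition intervals are aggregated before sleep scoring,
  so sub-minute wake blips are invisible to the sleep detector at native
  resolution.
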