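# Methods

## Data model

A recording is an ordered collection of 2-minute epochs, each carrying a
bradykinesia score (BKS), a dyskinesia score (DKS ≥ 0) and worn / tremor /
walking flags, plus a list of medication-reminder events.  Timestamps are
local wall-clock times; all windows in the pipeline (daytime, dose anchors)
are defined on the clock, so no timezone arithmetic is performed.  Missing
epochs are represented by absence: readers never interpolate gaps, and every
denominator counts only present ("available") epochs.  Recordings span 1–10
days (6 days is typical).

## Masks and availability

* **worn** — the logger's wear flag.
* **sleep** — BKS ≥ 80.  Sustained scores at this level correspond to
  absent movement, usually sleep.
* **inactive** — the 30-minute centred moving-median BKS is strictly
  greater than 40.  Inactivity means too little movement for bradykinesia
  to be clinically assessable; the median is taken over 15 epochs on the
  2-minute grid, skipping absent and not-worn epochs, with truncated
  windows at recording edges (dropping the first/last 14 minutes of every
  block would waste data for no benefit).
* **daytime** — clock time in the half-open window [09:00, 18:00), i.e.
  exactly 270 2-minute epochs per full day.  The half-open convention is
  what makes the 9-hour day come out to a round epoch count.

"Centre weighted moving median" is implemented as a centred, unweighted
moving median; no weighting scheme is published, and the centring is the
operative property.  The window (15 epochs) is configurable.

The boundary case BKS = 80 belongs to the sleep mask (≥ 80) but the median
BKS sample is defined as BKS ≤ 80; the two definitions overlap on a set of
measure zero and both are kept as written.

## Summary scores

All medians are 50th percentiles with linear interpolation between order
statistics (continuous at small n).  Samples, pooled over all days:

| score | sample |
|---|---|
| mBKS | worn ∧ daytime ∧ BKS ≤ 80 |
| active mBKS | as mBKS, ∧ ¬inactive |
| mDKS | worn ∧ daytime |
| adjusted mDKS | worn ∧ daytime ∧ ¬walking; epochs with tremor ∧ DKS ≥ 10 contribute 0 |
| PTD | numerator DKS ≥ 10 ∧ ¬walking ∧ ¬tremor; denominator worn ∧ daytime |
| PTB | numerator severity level ∈ {3,4,5}; denominator worn ∧ daytime ∧ ¬sleep ∧ ¬inactive |

The PTD denominator excludes not-worn epochs by default: counting epochs
the device cannot score would deflate PTD by an amount that depends only on
compliance.  `ptd_denominator: all` restores the literal all-epochs
reading.  The DKS ≥ 10 threshold (75th percentile of a control population)
is a configurable constant, since no control cohort ships with the package.

An empty sample after masking yields NaN ("not estimable"), never an
exception or a sentinel value.

## Severity calibration

The continuous severity level s ∈ [0, 5.5] is tied to MDS-UPDRS III by
mapping half-integer severity boundaries onto the interval edges
(0.5 → 10, 1.5 → 22.5, 2.5 → 35, 3.5 → 47.5, 4.5 → 60), linear between and
extended at 12.5 points/level beyond.  Integer levels bin the
UPDRS-equivalent value lower-closed ([35, 47.5) → level 3), which makes
"s ≥ 2.5" and "level ∈ {3,4,5}" coincide exactly.

BKS → s is piecewise linear through the anchor table

```
(bks 0 → 0), (23 → 2.26), (26 → 2.5), (40 → 4.0), (80 → 5.5)
```

clipped to [0, 5.5].  Only (26 → 2.5) is fixed by the target definition
(BKS 26 ≙ severity 2.5 ≙ UPDRS III 35); the other anchors are package
defaults placed so that the published score landmarks fall where the scale
expects them — BKS 23 just below the elevated-PTB onset, BKS 80 at the
sleep boundary.  The original epoch→level model is not published, so the
calibration is a user-replaceable table and every downstream result is
defined relative to it.

Derived conversions: `ptb_to_minutes(p) = max(0, p − 30) × 7.714`
(continuous, piecewise linear, zero on the control range, 540 min at
p = 100); PTB categories < 30% / 30–75% / ≥ 75%; referenced improvement
`100·(before − after)/(before − reference)`.

## First-dose levodopa response

1. **First dose time (DT)** — the earliest reminder clock time at or after
   05:00, snapped to the 2-minute grid.  "After 05:00" is read as
   at-or-after.  No qualifying reminder ⇒ the whole assessment is not
   estimable.
2. **Early-morning bradykinesia (EMB)** — mean severity over the 5-epoch
   (10-min) window centred on DT across all recorded days (≤ 30 slots for
   6 days).  A slot is unavailable when absent, not worn, asleep or
   inactive (the daytime mask does not apply — the window falls in the
   early morning).  EMB is not estimated when more than 50% of the slots
   are unavailable; the mean (rather than median) is used over the ≤ 30
   slots because the sample is small and the SD of the same values feeds
   the QC rule.
3. **Response curve** — severities at matching 2-minute offsets from DT
   are pooled across days into a mean-by-offset curve; an offset needs at
   least 3 contributing days (capped at the number of recorded days) so a
   single aberrant morning cannot define the curve.  The curve is smoothed
   over a centred 15-epoch (30-min) window.  The default kernel is a
   moving **average**: a moving median flattens any symmetric trough into
   a plateau half a window wide, and combined with the earliest-offset
   tie-break this biases the peak-effect time early by up to 8 minutes; the
   mean keeps a unique minimum for convex troughs.  A median kernel is
   available via `pte_smoothing: median`.
4. **Peak levodopa effect (PTE)** — the minimum of the smoothed curve over
   offsets 46–90 min post-dose ("peak" effect = least bradykinesia; the
   severity axis increases toward worse mobility).  Ties break to the
   earliest offset.  The across-day SD at the chosen offset is the PTE
   variability.
5. **Levodopa response** — Δ₁ = EMB − PTE severity; significant when
   ≥ 1.15 levels (≈ 14 UPDRS-III points ≈ 30% improvement).
6. **Wearing-off** — Δ₂ = maximal rise of the smoothed curve above the PTE
   severity within the 2 h after PTE, truncated at the next distinct
   reminder clock time; wearing-off when Δ₂ ≥ 1 level.  Anchoring the
   window to PTE reproduces the nominal 165–210 min post-dose band when
   PTE is 46–90 min post-dose.
7. **QC** — excess variability when the severity SD exceeds 1 level at
   *both* anchor times (conjunction; `variability_rule: or` switches to
   either).  QC-excluded recordings are classed `excluded_variability`.
8. **Classification** — Δ₁ < 1.15 ⇒ NFC/NFU by EMB side of 2.5;
   Δ₁ ≥ 1.15 ⇒ FC/FU by PTE-severity side of 2.5, suffixed _WO/_P by
   wearing-off.  The map is a total partition of QC-passing, estimable
   recordings; anything missing an input is `not_estimable`.  Exclusion is
   applied per recording.

## Synthetic cohort

The generator emulates exactly the features the pipeline consumes: a
6-day, 2-minute epoch grid; diurnal sleep (BKS ≥ 80 outside the wake
window); a dose-locked severity trace
`clip(baseline − amplitude·R(t − dose) + ε, 0, 5.5)` with R rising
linearly from `response_onset_min` (default 15) to `response_peak_min`
(default 60, constrained to the 46–90 min window), holding at full effect
for `plateau_min` (default 30) and then either persisting or decaying
exponentially (half-time default 30 min) for wearing-off subjects;
Gaussian noise (default SD 0.15 levels); severity mapped to BKS through
the inverse calibration; dose-locked dyskinesia (DKS ≈ `dysk_amplitude`
while the response is within 0.3 levels of peak, near zero otherwise — an
independence mode is a matter of setting `dysk_amplitude` with
`response_amplitude` 0); independent per-epoch walking/tremor flags
(default 2%); optional not-worn epochs and daily BKS ≈ 45 inactivity
bouts.  All randomness comes from numpy's seeded PCG64 generator on an
integer epoch grid, so cohorts are byte-identical across runs and
platforms.

The plateau before decay reflects the clinical geometry in which a
wearing-off decline is detected roughly 2–3 hours after the dose rather
than at the peak itself; it also means the generative trough is flat where
the estimator reads it, so the simulator does not manufacture a smoothing
bias that real responses would not show.

Canonical scenarios (noise SD 0.15 unless overridden):

| class | baseline | amplitude | wearing-off |
|---|---|---|---|
| NFC | 1.5 | 0.0 | – |
| NFU | 3.5 | 0.3 | – |
| FC_P | 3.6 | 2.2 | no |
| FC_WO | 3.6 | 2.2 | yes |
| FU_P | 3.9 | 1.3 | no |
| FU_WO | 3.9 | 1.3 | yes |

Baselines stay below severity 4.0 because BKS(4.0) = 40 under the default
calibration: a sustained awake score above 40 is, by definition, swallowed
by the inactivity mask — a genuine confound of severe bradykinesia that
the scenarios deliberately avoid so that class membership, not mask
interaction, is what they test.  FU amplitudes leave a 0.1-level margin on
the PTE-severity boundary and 0.15 on the significance boundary; FU_WO's
implied Δ₂ is 1.3·(1 − 2^(−90/30)) ≈ 1.14.

What the generator does **not** emulate: raw accelerometry, realistic
score autocorrelation within epochs, pharmacokinetic variability between
days, dose-to-dose differences, or correlated missingness.  Passing the
recovery suites therefore shows the pipeline inverts its own generative
model under realistic noise — not that it is robust to every artefact of
real recordings.

## Cohort statistics

Welch's t, Mann-Whitney, chi-square, one-way ANOVA and Pearson's r are
thin wrappers over scipy.stats; the Fisher-z 95% CI and the Šídák
adjustment (1 − (1 − p)^m) are computed in closed form.  The effect size
defaults to the pooled-SD standardized mean difference
`(m₁ − m₂)/√((s₁² + s₂²)/2)`; published before/after tables rarely state
their convention (and are not always reproducible from printed summaries),
so baseline-SD and paired variants are selectable.  Percent change with a
zero baseline is reported as NaN.

## Numerical choices and degenerate inputs

* Percentiles: linear interpolation between order statistics.
* Moving medians/means: centred, truncated at edges, NaN-skipping; an
  all-NaN window yields NaN; even windows are configuration errors.
* Not-estimable results are NaN (floats) or `not_estimable` (classes);
  they propagate, never raise.
* SDs use ddof = 1; a single observation has SD 0 (it cannot trigger the
  variability rule on its own).
* Tie-breaks: earliest offset for equal smoothed minima; `nanargmin`'s
  first-occurrence semantics implement this directly.
* Dose clock times are snapped to the nearest 2-minute grid point.

## Problem sizes

The test suite and the acceptance script run the simulation study at 100
seeds per canonical scenario (600 six-day recordings, ~4 300 epochs each),
which estimates per-scenario class recovery to within a few percent and
completes in well under a minute on one CPU; the remaining checks are
closed-form arithmetic on fixed inputs.

## Known limitations

* The severity calibration beyond the fixed (26 → 2.5) anchor is a
  package default, not a published model; absolute PTB values depend on it
  (PTB-vs-PTB comparisons under a common calibration do not).
* Only the first morning dose is analysed; responses to later doses are
  out of scope.
* Walking and tremor arrive as input flags; no detection is performed.
* The 34% excess-variability exclusion rate reported for real cohorts is a
  property of real data; the simulator's defaults produce far cleaner
  mornings.
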