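# Methods

This note documents the models behind `sleepcoach`, the calibration of the
synthetic cohort, the numerical choices, and what the simulator does and
does not emulate.

## Instruments

The ISI total is the plain sum of seven 0–4 items. Band boundaries are
none 0–7, subthreshold 8–14, moderate 15–21, severe 22–28; eligibility for
the intervention is strict (total > 14), as is referral (total > 21), which
makes the severe band and the referral rule coincide (severe ⇔ referral at
the final interview). The AES and ETQ item lists vary between deployments,
so the package only fixes the scoring *shape*: per-item mean subscales with
configurable item indices and scales. Defaults (6 AES items rated 1–5 in
two subscales of 3; 2 ETQ benevolence items on a 5-level agreement scale
and 2 credibility items on 0–3) are chosen so the conventional positivity
thresholds — satisfaction strictly above 3 of 5, credibility strictly above
1 of 3, benevolence in the top-two agreement levels — are expressible;
every threshold and layout is overridable in configuration. Subscores are
means rather than sums so thresholds read naturally "out of 5" / "out of 3".

## Sleep diary

Clock times carry no date. The noon-anchored convention resolves them:
times ≥ 12:00 belong to the evening of the entry's `night_date`, times
< 12:00 to the next morning. This parses early-evening (21:30) and
post-midnight (01:30) bedtimes uniformly, with no flags, and is covered by
a metamorphic test (shifting all clock times one hour across midnight
changes no duration).

SOL and WASO are taken as reported minutes; TIB and TWAK are derived from
clock times; TST = TIB − SOL − WASO − TWAK and SE = 100·TST/TIB are always
derived. Entries with SOL + WASO + TWAK > TIB are **rejected**, not
clamped: clamping would silently break the identity that every downstream
aggregate relies on. Durations are real minutes internally; hh:mm
formatting (half-up rounding) exists only at the presentation layer.
Window aggregates ("first 2 nights", "last 2 nights", "all") are
componentwise arithmetic means over *completed* entries in chronological
order; missing days do not shift the window. A diary week counts as
complete at ≥ 7 validated entries; consecutiveness is not required.

## Protocol state machine

The flow is a table-driven pure transition function, so a recorded event
log replays to the identical state. Guards encode the program's dosing:
Interview 2 becomes due exactly when the 7th diary entry validates; Step 2
runs 10 elapsed recommendation days before Interview 3; the final branch
is referral (total > 21) versus autonomous use. Interviews are modeled as
*due-states* with no time-out, since users may delay and the program
defines none. Diary entries remain accepted while an interview is due and
during Step 2 (users keep their diary up; the entries feed the pre/post
windows). Screened-low users are terminal after the three-item hygiene
bundle — the program offers them nothing further. Dropout is an explicit
event, legal from every non-terminal stage; terminal stages absorb. At
most three ISI occasions can ever enter the history, in interview order.

## Recommendation rules

The personalized-recommendation conditions of deployed apps are typically
proprietary configuration; here they are a declarative rule table loaded
from YAML/JSON. A condition is a pure predicate over the weekly indicator
aggregate (sol, nwak, twak, waso, tib, tst, se) and the ISI answers,
written in a deliberately small expression grammar (names, numeric
literals, comparisons, and/or/not, +−×÷) compiled through an AST whitelist
— rule files cannot execute code. Fired rules order by (priority, id), so
output is invariant to file order; with no firing rule the generic hygiene
bundle is returned, marked as personalized output. The shipped default
rules are standard behavioral sleep-medicine heuristics — time-in-bed
restriction when efficiency is low and time in bed exceeds 9 h, stimulus
control when SOL > 30 min, a fixed rise time when TWAK > 30 min, a
wind-down routine for fragmented nights, a specialist note at severe ISI —
and are a package default, not a claim about any deployed system's rules.

## Statistics

Chi-square, pooled t, paired t and Pearson r are implemented from their
formulas; scipy supplies only the distribution tails. No Yates continuity
correction is applied: the uncorrected Pearson statistic is the dialect
that reproduces published group comparisons of this kind. The two-sample t
is pooled-variance with df = n₁ + n₂ − 2 (not Welch), matching the printed
df pattern of such reports. p-values are computed exactly and formatted
("<.001") only at the report layer.

## Synthetic cohort

The generator's defaults *are* the study conditions; they are not tuning
knobs.

**Funnel.** n = 2069 downloaders; screening is Bernoulli(0.76) with a
logistic tilt on centered age and gender (slopes 0.08 per decade and 0.30;
non-screeners come out older and more male, directionally). Eligibility is
a latent severity stratum, Bernoulli(0.491) among screened; Step-1
completion is Bernoulli(0.215) among eligible.

**Baseline ISI.** Truncated normals per stratum — subclinical (10.02,
3.42) on [0, 14], clinical (18.2, 2.74) on [15, 28] — rounded to integers
*after* truncation so eligibility is exact by construction. The (mean, sd)
pairs are read as the pre-truncation parameters; the clinical stratum's
realized mean is then ≈ 18.8, consistent with the slightly higher baseline
observed among intervention completers.

**Effects.** Post-Step-1 ISI = baseline + N(−2.57, 4.20), rounded and
clamped to [0, 28]; post-Step-2 adds N(−0.96, 4.63). The means are the
printed pre/post differences; the sds invert the paired-t relation
sd = |Δ|·√n / t from the reported statistics (t = 7.88 at n = 166;
t = 1.42 at n = 47). Clamping bias is negligible at these effect sizes
(< 0.05 points). With a zero sd the shift is applied exactly — the
closed-form limit used in tests (stated with an integer mean shift, since
totals are integers).

**Step-2 self-selection.** Continuation into Step 2 is Bernoulli around
0.283 with a logistic tilt of −0.0215 per interview-2 ISI point (centered
at the model-implied interview-2 mean). The slope is calibrated
analytically — shift ≈ β·σ²·(1−p) — so continuers' interview-2 mean sits
≈ 0.35 points below the Step-1-completer mean, reproducing the observed
milder scores of those who continue. Setting the slope to zero recovers a
plain Bernoulli stage.

**Diaries.** For each night, time in bed is truncated-normal (per-night
means and sds drifting linearly so that the first-2-night and last-2-night
averages hit their calibrated values: TIB 536.8 → 520.5 min over the
Step-1 week). The total nocturnal wake time is drawn as a Beta-distributed
*fraction* of that night's TIB, moment-matched to the calibrated sleep
efficiency (67.60 ± 20.25 % first two nights → 73.82 ± 17.33 % last two),
then split into SOL : WASO : TWAK by a Dirichlet in the calibrated
component proportions (≈ 91.6 : 49.0 : 58.2 first nights). NWAK is
negative-binomial (Poisson when not overdispersed) at 1.89 → 1.67. Step-2
nights use the post-recommendation calibration (SE 72.36 ± 16.76, TIB
517.8 min) flat across 10 nights.

This fraction-then-split construction was chosen over independent
per-component draws deliberately: the calibrated component dispersions
exceed their means (SOL cv ≈ 1.7), so independent heavy-tailed draws
frequently violate wake ≤ TIB, and any rejection or clamping step then
biases the realized means well outside Monte-Carlo error. Drawing the
wake *fraction* makes every night feasible by construction and recovers
the calibrated SE mean exactly in expectation, at the cost of not
reproducing the printed per-component dispersions (the realized component
sds are smaller; between-user heterogeneity is not separately modeled).
The calibrated component means are also mutually inconsistent as printed
(TIB − SOL − WASO − TWAK ≠ the printed TST by ~26 min on the first
nights); since TST and SE are derived quantities in this engine, the
calibration resolves the conflict in favor of the printed sleep
efficiency and uses the components only as proportions.

Nights are anchored to a fixed calendar date, bedtimes are normal around
23:00 (sd 45 min), and all times round to whole minutes with the identity
re-imposed after rounding. The whole night is kept strictly inside one
noon-to-noon window; the resulting upper truncation of very long nights
biases the realized TIB mean about 1 % low — documented, not corrected,
since no downstream quantity depends on absolute TIB at that precision.

**What the simulator does not emulate.** Acceptance/trust questionnaire
responses (no calibration targets use them), dialogue text, app-open
timestamps, nap or within-night awakening structure, non-random attrition
*within* a phase (dropout between diary days), and any covariance between
demographics and sleep outcomes beyond the screening tilt. Passing
calibration tests therefore says the engine reproduces the *marginal*
funnel and outcome profile of such a deployment, not individual-level
joint structure of real data.

## Verification design

Each statistic is checked against an independent oracle (brute-force
double loops, closed forms, scipy's implementations) on random inputs;
diary arithmetic and instrument scoring carry property tests (hypothesis,
derandomized); protocol safety is model-checked with 10⁴ random event
sequences (no path reaches Step 2 without 7 validated diary days, no
fourth ISI occasion, terminals absorb). Calibration recovery runs 20
seeds at the full cohort size (n = 2069), a few seconds of CPU;
problem sizes in the remaining suites (hundreds of users, hundreds of
random tables) are chosen to keep the whole suite under half a minute
while leaving Monte-Carlo error far below the tested tolerances.

## Known limitations

* The rule table ships plausible defaults, not any deployed system's
  actual conditions; conclusions about recommendation *content* should
  treat it as a placeholder.
* ISI change scores are additive-normal; regression to the mean,
  floor effects near 0 and response heterogeneity are only crudely
  captured by the clamp.
* Diary noise is independent across nights given the drift line; real
  diaries show strong within-user autocorrelation.
* The printed dispersions of wake components are not reproduced (see
  above); SE dispersion is.
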