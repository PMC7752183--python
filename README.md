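# sleepcoach

A desk-scale Python engine for autonomous insomnia screening and a two-step
behavioral sleep intervention, of the kind delivered by smartphone apps with
an embodied conversational agent. It is aimed at researchers in digital
behavioral sleep medicine who want to prototype, audit or power-analyze such
a program without any real user data: every part of the pipeline — the
instruments, the electronic sleep diary, the interaction-flow state machine,
the recommendation rules, the adherence funnel and the outcome statistics —
is implemented as testable, seedable code, and a calibrated synthetic-cohort
simulator reproduces the feasibility profile of a population-scale
deployment.

## What it models

**Screening.** The Insomnia Severity Index (ISI): 7 items scored 0–4, total
T ∈ [0, 28], banded as none (0–7), subthreshold (8–14), moderate (15–21) and
severe (22–28). T > 14 admits a user to the intervention; T > 21 at the
final interview indicates referral to a sleep specialist. Acceptance (AES:
usability, satisfaction) and trust (ETQ: benevolence, credibility)
instruments are scored as configurable per-item-mean subscales.

**The sleep diary.** Each night records bedtime, reported sleep-onset
latency (SOL), awakening count (NWAK), reported wake after sleep onset
(WASO), final wake time and rise time. The engine derives, with
midnight-safe (noon-anchored) time arithmetic,

```
TIB  = arise − try_sleep           TWAK = arise − final_wake
TST  = TIB − SOL − WASO − TWAK     SE   = 100 · TST / TIB
```

TST and SE are always derived, never entered, so the identity is exact for
every accepted night; entries over-reporting wakefulness are rejected with a
diagnostic.

**The program.** A deterministic state machine: screening interview →
(hygiene advice and exit, if T ≤ 14) → Step 1, a 7-day diary with morning
feedback → Interview 2 → Step 2, 10 days of personalized recommendations
driven by a declarative, sandboxed rule table over the weekly indicators and
ISI answers → Interview 3 → autonomous use or referral. Dropout is an
explicit event; terminal stages absorb.

**The synthetic cohort.** 2069 simulated downloaders pass a calibrated
adherence funnel (76% screen; 49.1% of screened are eligible; 21.5% of
eligible complete Step 1; 28.3% of those complete Step 2), with baseline ISI
drawn from a two-component truncated normal (subclinical 10.02 ± 3.42 on
0–14; clinical 18.2 ± 2.74 on 15–28), additive normal intervention effects
(Step 1: −2.57 ± 4.20; Step 2: −0.96 ± 4.63), and nightly diaries whose
wake structure is drawn as a Beta fraction of time in bed split by a
Dirichlet — see `docs/methods.md` for the full model and its assumptions.

**Statistics.** Pearson chi-square (no continuity correction), pooled
two-sample t, paired t and Pearson correlation, implemented from the
formulas with scipy supplying only distribution tails, plus funnel
percentage reports.

## Worked example

```python
from sleepcoach import ISIResponse, score_isi
from sleepcoach.diary import read_diary_csv, derive_night, window_mean
from sleepcoach.recommend import personalize

r = score_isi(ISIResponse(items=(3, 3, 3, 2, 2, 2, 3)))
print(r.total, r.band.value, r.eligible_for_intervention)
# 18 moderate True      -> moderate insomnia, enters the intervention

entries, errors = read_diary_csv("diary_week.csv")   # one row per night
week = window_mean([derive_night(e) for e in entries], "all")
print(round(week.se, 1), round(week.sol, 1))
# 71.9 94.7             -> weekly sleep efficiency 71.9%, mean SOL ~95 min

print([item.advice_id for item in personalize(week).items])
# ['stimulus_control', 'fixed_rise_time', 'wind_down', 'morning_light']
```

With that week (sleep efficiency 71.9%, sleep-onset latency above 30 min,
terminal wakefulness above 30 min), the rule table fires stimulus control,
a fixed rise time, a wind-down routine and morning-light advice, in priority
order. The same flows are available on the command line:

```bash
sleepcoach score-isi --items 3,3,3,2,2,2,3
sleepcoach simulate --n-users 2069 --seed 42 --out cohort/
sleepcoach report --cohort cohort/ --out report/
sleepcoach recommend --diary week.csv --isi isi.json
```

Every command honoring `--seed` writes a `manifest.json` with the seed and
SHA-256 of each output, so reruns are byte-auditable.

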