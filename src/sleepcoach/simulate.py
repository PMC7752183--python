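"""Synthetic cohort simulator: population, adherence funnel, outcomes.

Generates a cohort of app users through the whole program with no external
data: demographics, the monotone adherence funnel (downloaded -> screened
-> eligible -> Step 1 -> Step 2), baseline and follow-up ISI totals, and
nightly sleep diaries for intervention users.

Model
-----
* Screening is Bernoulli around a base rate, with an optional logistic
  tilt on age and gender (non-responders skew older and more male).
* Baseline ISI is a two-component truncated normal: a subclinical stratum
  on 0..14 and a clinical stratum on 15..28, rounded to integers after
  truncation so eligibility (total > 14) is exact by construction.
* Step-1 and Step-2 effects are additive normal changes on the previous
  ISI total, rounded and clamped to [0, 28].  With a zero sd the change
  is applied exactly (closed-form limit).
* Step-2 uptake carries a logistic tilt on the interview-2 total (milder
  complaints after Step 1 -> more likely to continue), reproducing the
  self-selection of continuers; the base rate stays the configured one.
* Diary nights: time in bed is truncated-normal; sleep onset latency,
  wake after sleep onset and terminal wakefulness are moment-matched
  lognormals (their dispersions exceed their means, which a zero-truncated
  normal cannot represent without inflating the mean).  Per-night means
  drift linearly between the calibrated first-2-night and last-2-night
  values.  The three wake components are jointly rescaled so their
  expected sum equals expected TIB minus the calibrated TST, and TST / SE
  are always *derived* through the diary identity, never drawn.

Identical (config, seed) pairs produce identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .diary import DiaryEntry, NightIndicators, derive_night, window_mean
from .instruments import ISIResult, Occasion, classify_isi
from .protocol import EventKind, ProtocolEvent

__all__ = [
    "Normal",
    "TruncNormal",
    "EffectModel",
    "IndicatorDrift",
    "DiaryPhaseModel",
    "DiaryModel",
    "Demographics",
    "ScreeningTilt",
    "Step2Selection",
    "CohortConfig",
    "UserProfile",
    "SyntheticUser",
    "default_config",
    "generate_cohort",
    "cohort_metrics",
    "emit_study_tables",
    "cohort_to_frames",
    "cohort_from_frames",
    "user_events",
    "DIARY_ANCHOR_DATE",
]

#: calendar anchor for simulated diaries (first night of Step 1)
DIARY_ANCHOR_DATE = date(2020, 4, 23)


def _hms(h: int, m: int, s: int = 0) -> float:
    """hh:mm:ss to minutes (used to state calibration constants legibly)."""
    return h * 60.0 + m + s / 60.0


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class TruncNormal:
    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (self.lo < self.hi):
            raise ValueError("truncation range must satisfy lo < hi")

    def expected(self) -> float:
        """Analytic mean of the truncated distribution."""
        if self.sd == 0:
            return min(max(self.mean, self.lo), self.hi)
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return float(sps.truncnorm.mean(a, b, loc=self.mean, scale=self.sd))


@dataclass(frozen=True)
class EffectModel:
    """Additive change applied to the previous ISI total."""

    mean_delta: float
    sd_delta: float

    def __post_init__(self) -> None:
        if self.sd_delta < 0:
            raise ValueError("sd_delta must be >= 0")


@dataclass(frozen=True)
class IndicatorDrift:
    """Linear drift of a nightly indicator between the calibrated mean/sd
    of the first two and the last two nights of a phase."""

    first: Normal
    last: Normal

    def at(self, night: int, n_nights: int) -> Normal:
        """Per-night parameters; nights 1-based.  The drift line is chosen
        so the average over nights (1, 2) equals ``first`` and over the last
        two nights equals ``last``."""
        if n_nights <= 2:
            return self.first
        # solve a + b*1.5 = first, a + b*(n-0.5) = last
        span = (n_nights - 0.5) - 1.5
        b_m = (self.last.mean - self.first.mean) / span
        b_s = (self.last.sd - self.first.sd) / span
        return Normal(
            mean=self.first.mean + b_m * (night - 1.5),
            sd=max(self.first.sd + b_s * (night - 1.5), 0.0),
        )


@dataclass(frozen=True)
class DiaryPhaseModel:
    """Night-generation model for one program phase.

    Time in bed is drawn directly; the total nocturnal wake time is drawn
    as a Beta-distributed *fraction* of that night's TIB whose mean and
    dispersion come from the calibrated sleep-efficiency drift
    (fraction = 1 - SE/100), and is then split into SOL / WASO / TWAK by a
    Dirichlet in the calibrated component proportions.  This keeps the
    diary identity feasible for every draw and recovers the calibrated SE
    mean exactly in expectation; TST and SE are derived, never drawn.
    """

    n_nights: int
    tib: IndicatorDrift
    #: sleep-efficiency calibration (percent); drives the wake fraction
    se: IndicatorDrift
    #: component calibrations; their *relative* means set the SOL:WASO:TWAK
    #: split of the nightly wake time
    sol: IndicatorDrift
    waso: IndicatorDrift
    twak: IndicatorDrift
    nwak: IndicatorDrift

    def wake_fraction_at(self, night: int) -> Normal:
        se = self.se.at(night, self.n_nights)
        return Normal(mean=1.0 - se.mean / 100.0, sd=se.sd / 100.0)

    def wake_split_at(self, night: int) -> Tuple[float, float, float]:
        parts = [
            max(d.at(night, self.n_nights).mean, 0.0)
            for d in (self.sol, self.waso, self.twak)
        ]
        total = sum(parts)
        if total <= 0:
            return (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
        return tuple(p / total for p in parts)


@dataclass(frozen=True)
class DiaryModel:
    step1: DiaryPhaseModel
    step2: DiaryPhaseModel
    bedtime_mean_hour: float = 23.0  # clock hours, noon-based arithmetic
    bedtime_sd_hour: float = 0.75
    tib_bounds: Tuple[float, float] = (120.0, 900.0)
    #: Dirichlet concentration of the SOL/WASO/TWAK split (lower = the
    #: night-to-night split varies more)
    wake_split_concentration: float = 2.0


@dataclass(frozen=True)
class Demographics:
    age_bands: Tuple[Tuple[int, int], ...] = ((18, 30), (31, 50), (51, 65), (66, 85))
    age_band_probs: Tuple[float, ...] = (0.211, 0.475, 0.240, 0.074)
    p_female: float = 0.651
    education_levels: Tuple[str, ...] = ("middle_school", "high_school", "university")
    education_probs: Tuple[float, ...] = (0.194, 0.206, 0.600)
    p_hcp: float = 0.057
    p_confined: float = 0.759
    familiarity_probs: Tuple[float, float, float] = (0.10, 0.30, 0.60)
    # substance measures per severity stratum (subclinical, clinical)
    cds5: Tuple[Normal, Normal] = (Normal(4.53, 6.93), Normal(6.45, 8.30))
    cigarettes: Tuple[Normal, Normal] = (Normal(3.09, 6.40), Normal(5.33, 8.68))
    cage: Tuple[Normal, Normal] = (Normal(0.65, 0.97), Normal(0.78, 1.12))
    drinks: Tuple[Normal, Normal] = (Normal(1.34, 2.09), Normal(1.66, 3.18))


@dataclass(frozen=True)
class ScreeningTilt:
    """Logistic tilt of the screening probability on centered covariates,
    giving non-responders the observed older / more-male skew.  Magnitudes
    are qualitative defaults; zero betas disable the tilt."""

    beta_age_per_decade: float = 0.08
    beta_male: float = 0.30
    age_center: float = 43.5
    male_rate_center: float = 0.349


@dataclass(frozen=True)
class Step2Selection:
    """Logistic tilt of Step-2 uptake on the interview-2 ISI total
    (centered at its expected value), calibrated so continuers carry the
    observed milder post-Step-1 scores.  Zero slope disables selection."""

    beta_per_isi_point: float = -0.0215


@dataclass(frozen=True)
class CohortConfig:
    n_users: int = 2069
    seed: int = 0
    p_screen: float = 0.76
    p_eligible_given_screen: float = 0.491
    p_step1_given_eligible: float = 0.215
    p_step2_given_step1: float = 0.283
    isi_baseline_subclinical: TruncNormal = TruncNormal(10.02, 3.42, 0.0, 14.0)
    isi_baseline_clinical: TruncNormal = TruncNormal(18.2, 2.74, 15.0, 28.0)
    step1_effect: EffectModel = EffectModel(-2.57, 4.20)
    step2_effect: EffectModel = EffectModel(-0.96, 4.63)
    demographics: Demographics = field(default_factory=Demographics)
    diary_model: Optional[DiaryModel] = None
    screening_tilt: ScreeningTilt = field(default_factory=ScreeningTilt)
    step2_selection: Step2Selection = field(default_factory=Step2Selection)

    def __post_init__(self) -> None:
        if self.n_users < 0:
            raise ValueError("n_users must be >= 0")
        for name in (
            "p_screen",
            "p_eligible_given_screen",
            "p_step1_given_eligible",
            "p_step2_given_step1",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} = {p} outside [0, 1]")
        if self.diary_model is None:
            object.__setattr__(self, "diary_model", _default_diary_model())


def _default_diary_model() -> DiaryModel:
    """Diary calibration: first-2 / last-2 night means and SDs of the
    Step-1 week, and the post-recommendation week for Step 2."""
    step1 = DiaryPhaseModel(
        n_nights=7,
        tib=IndicatorDrift(
            Normal(_hms(8, 56, 45), _hms(1, 34, 22)),
            Normal(_hms(8, 40, 27), _hms(1, 29, 27)),
        ),
        se=IndicatorDrift(Normal(67.60, 20.25), Normal(73.82, 17.33)),
        sol=IndicatorDrift(
            Normal(_hms(1, 31, 38), _hms(2, 39, 11)),
            Normal(_hms(0, 58, 37), _hms(1, 26, 0)),
        ),
        waso=IndicatorDrift(
            Normal(_hms(0, 48, 57), _hms(0, 55, 48)),
            Normal(_hms(0, 42, 1), _hms(0, 52, 58)),
        ),
        twak=IndicatorDrift(
            Normal(_hms(0, 58, 11), _hms(1, 9, 42)),
            Normal(_hms(0, 39, 43), _hms(0, 39, 57)),
        ),
        nwak=IndicatorDrift(Normal(1.89, 1.57), Normal(1.67, 1.32)),
    )
    after = {
        "tib": Normal(_hms(8, 37, 45), _hms(0, 50, 21)),
        "se": Normal(72.36, 16.76),
        "sol": Normal(_hms(1, 8, 50), _hms(1, 25, 2)),
        "waso": Normal(_hms(0, 35, 58), _hms(0, 32, 57)),
        "twak": Normal(_hms(0, 41, 17), _hms(0, 32, 22)),
        "nwak": Normal(1.35, 0.97),
    }
    step2 = DiaryPhaseModel(
        n_nights=10,
        tib=IndicatorDrift(after["tib"], after["tib"]),
        se=IndicatorDrift(after["se"], after["se"]),
        sol=IndicatorDrift(after["sol"], after["sol"]),
        waso=IndicatorDrift(after["waso"], after["waso"]),
        twak=IndicatorDrift(after["twak"], after["twak"]),
        nwak=IndicatorDrift(after["nwak"], after["nwak"]),
    )
    return DiaryModel(step1=step1, step2=step2)


def default_config(n_users: int = 2069, seed: int = 0) -> CohortConfig:
    """The default calibration reproducing the study conditions.

    Funnel: 76% of downloaders screen; 49.1% of screened are eligible
    (total > 14); 21.5% of eligible complete Step 1; 28.3% of Step-1
    completers complete Step 2.  Baseline strata: truncated normals
    (10.02, 3.42) on 0..14 and (18.2, 2.74) on 15..28.  Step-1 change:
    mean -2.57 (18.56 -> 15.99); its sd, 4.20, inverts the paired
    t = |d| sqrt(n) / sd with t = 7.88 at n = 166.  Step-2 change: mean
    -0.96 (15.64 -> 14.68), sd 4.63 from t = 1.42 at n = 47.
    """
    return CohortConfig(n_users=n_users, seed=seed)


# ---------------------------------------------------------------------------
# Synthetic users
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UserProfile:
    age: int
    gender: str  # "female" | "male"
    education: str
    health_care_professional: bool
    confined: bool
    familiarity: int  # 0/1/2
    cds5: float
    cage: float
    cigarettes: float
    drinks: float


@dataclass(frozen=True)
class SyntheticUser:
    user_id: str
    profile: UserProfile
    screened: bool
    eligible: bool
    step1_completed: bool
    step2_completed: bool
    isi_series: Tuple[ISIResult, ...]
    diaries_step1: Tuple[DiaryEntry, ...] = ()
    diaries_step2: Tuple[DiaryEntry, ...] = ()

    @property
    def diaries(self) -> Tuple[DiaryEntry, ...]:
        return self.diaries_step1 + self.diaries_step2


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _draw_trunc_normal(rng: np.random.Generator, dist: TruncNormal) -> float:
    if dist.sd == 0:
        return min(max(dist.mean, dist.lo), dist.hi)
    for _ in range(1000):
        x = rng.normal(dist.mean, dist.sd)
        if dist.lo <= x <= dist.hi:
            return x
    return min(max(dist.mean, dist.lo), dist.hi)  # pathological config


def _draw_beta(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Beta draw moment-matched to (mean, sd); degenerate sd returns mean.

    The variance is capped just below the feasible maximum mean*(1-mean)
    so extreme calibrations still yield a proper distribution.
    """
    mean = min(max(mean, 1e-6), 1.0 - 1e-6)
    if sd <= 0:
        return mean
    var = min(sd * sd, 0.95 * mean * (1.0 - mean))
    nu = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _draw_count(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Awakening count: negative binomial when overdispersed, else Poisson."""
    if mean <= 0:
        return 0
    var = sd * sd
    if var > mean:
        r = mean * mean / (var - mean)
        p = r / (r + mean)
        return int(rng.negative_binomial(r, p))
    return int(rng.poisson(mean))


def _round_isi(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else 0


def _apply_effect(
    rng: np.random.Generator, total: int, effect: EffectModel
) -> int:
    delta = effect.mean_delta if effect.sd_delta == 0 else rng.normal(
        effect.mean_delta, effect.sd_delta
    )
    return max(0, min(28, _round_isi(total + delta)))


def _simulate_phase_nights(
    rng: np.random.Generator,
    model: DiaryModel,
    phase: DiaryPhaseModel,
    start: date,
) -> List[DiaryEntry]:
    entries: List[DiaryEntry] = []
    lo_tib, hi_tib = model.tib_bounds
    for night in range(1, phase.n_nights + 1):
        tib_par = phase.tib.at(night, phase.n_nights)
        frac_par = phase.wake_fraction_at(night)
        split = phase.wake_split_at(night)
        nwak_par = phase.nwak.at(night, phase.n_nights)

        # bedtime clock, minutes after noon; keep the whole night strictly
        # inside one noon-to-noon window so timeline resolution is exact
        bed_off = rng.normal(model.bedtime_mean_hour, model.bedtime_sd_hour) * 60.0 - 720.0
        bed_off = min(max(bed_off, 60.0), 1200.0)
        tib = _draw_trunc_normal(
            rng,
            TruncNormal(tib_par.mean, tib_par.sd, lo_tib, min(hi_tib, 1430.0 - bed_off)),
        )
        # total wake time as a Beta fraction of tonight's TIB, split into
        # SOL / WASO / TWAK by a Dirichlet in the calibrated proportions:
        # feasible (wake < TIB) for every draw, so no truncation bias
        frac = _draw_beta(rng, frac_par.mean, frac_par.sd)
        wake = frac * tib
        conc = model.wake_split_concentration
        shares = rng.dirichlet([max(p, 1e-3) * 3.0 * conc for p in split])
        sol, waso, twak = (wake * sh for sh in shares)
        nwak = _draw_count(rng, nwak_par.mean, nwak_par.sd)

        # minute-resolution clock times; re-derive integers so the diary
        # identity survives rounding
        bed_off_i = int(round(bed_off))
        tib_i = int(round(tib))
        twak_i = min(int(round(twak)), tib_i)
        sol_i = int(round(sol))
        waso_i = int(round(waso))
        over = sol_i + waso_i + twak_i - tib_i
        if over > 0:
            waso_i = max(0, waso_i - over)
            over = sol_i + waso_i + twak_i - tib_i
            if over > 0:
                sol_i = max(0, sol_i - over)
        night_date = start + timedelta(days=night - 1)
        noon = datetime.combine(night_date, time(12, 0))
        bed_dt = noon + timedelta(minutes=bed_off_i)
        arise_dt = bed_dt + timedelta(minutes=tib_i)
        wake_dt = arise_dt - timedelta(minutes=twak_i)
        entries.append(
            DiaryEntry(
                night_date=night_date,
                try_sleep_time=bed_dt.time(),
                reported_sol_min=float(sol_i),
                nwak=nwak,
                reported_waso_min=float(waso_i),
                final_wake_time=wake_dt.time(),
                arise_time=arise_dt.time(),
            )
        )
    return entries


def generate_cohort(
    config: CohortConfig, seed: Optional[int] = None
) -> List[SyntheticUser]:
    """Generate the full synthetic cohort; deterministic in (config, seed).

    ``seed`` overrides ``config.seed`` when given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    demo = config.demographics
    tilt = config.screening_tilt
    sel = config.step2_selection
    # centering constant for the step-2 selection tilt: the model-implied
    # mean interview-2 total among Step-1 completers
    i2_center = config.isi_baseline_clinical.expected() + config.step1_effect.mean_delta
    screen_base = _logit(config.p_screen) if 0 < config.p_screen < 1 else None
    step2_base = (
        _logit(config.p_step2_given_step1)
        if 0 < config.p_step2_given_step1 < 1
        else None
    )

    users: List[SyntheticUser] = []
    for i in range(config.n_users):
        band = demo.age_bands[rng.choice(len(demo.age_bands), p=demo.age_band_probs)]
        age = int(rng.integers(band[0], band[1] + 1))
        female = rng.random() < demo.p_female
        education = demo.education_levels[
            rng.choice(len(demo.education_levels), p=demo.education_probs)
        ]
        hcp = rng.random() < demo.p_hcp
        confined = rng.random() < demo.p_confined
        familiarity = int(rng.choice(3, p=demo.familiarity_probs))
        clinical = rng.random() < config.p_eligible_given_screen
        stratum = 1 if clinical else 0
        profile = UserProfile(
            age=age,
            gender="female" if female else "male",
            education=education,
            health_care_professional=hcp,
            confined=confined,
            familiarity=familiarity,
            cds5=max(0.0, rng.normal(demo.cds5[stratum].mean, demo.cds5[stratum].sd)),
            cage=max(0.0, rng.normal(demo.cage[stratum].mean, demo.cage[stratum].sd)),
            cigarettes=max(
                0.0, rng.normal(demo.cigarettes[stratum].mean, demo.cigarettes[stratum].sd)
            ),
            drinks=max(0.0, rng.normal(demo.drinks[stratum].mean, demo.drinks[stratum].sd)),
        )

        if screen_base is None:
            p_screen = config.p_screen
        else:
            z = (
                screen_base
                - tilt.beta_age_per_decade * (age - tilt.age_center) / 10.0
                - tilt.beta_male * ((0.0 if female else 1.0) - tilt.male_rate_center)
            )
            p_screen = _logistic(z)
        screened = rng.random() < p_screen
        uid = f"u{i:05d}"
        if not screened:
            users.append(
                SyntheticUser(uid, profile, False, False, False, False, ())
            )
            continue

        base_dist = (
            config.isi_baseline_clinical if clinical else config.isi_baseline_subclinical
        )
        total1 = _round_isi(_draw_trunc_normal(rng, base_dist))
        total1 = int(min(max(total1, base_dist.lo), base_dist.hi))
        isi1 = classify_isi(total1, occasion=Occasion.INTERVIEW1)
        eligible = isi1.eligible_for_intervention

        step1 = bool(eligible and rng.random() < config.p_step1_given_eligible)
        isi_series: Tuple[ISIResult, ...] = (isi1,)
        diaries1: Tuple[DiaryEntry, ...] = ()
        diaries2: Tuple[DiaryEntry, ...] = ()
        step2 = False
        if step1:
            diaries1 = tuple(
                _simulate_phase_nights(
                    rng, config.diary_model, config.diary_model.step1, DIARY_ANCHOR_DATE
                )
            )
            total2 = _apply_effect(rng, total1, config.step1_effect)
            isi2 = classify_isi(total2, occasion=Occasion.INTERVIEW2)
            isi_series += (isi2,)
            if step2_base is None:
                p_step2 = config.p_step2_given_step1
            else:
                p_step2 = _logistic(
                    step2_base + sel.beta_per_isi_point * (total2 - i2_center)
                )
            step2 = rng.random() < p_step2
            if step2:
                start2 = DIARY_ANCHOR_DATE + timedelta(
                    days=config.diary_model.step1.n_nights
                )
                diaries2 = tuple(
                    _simulate_phase_nights(
                        rng, config.diary_model, config.diary_model.step2, start2
                    )
                )
                total3 = _apply_effect(rng, total2, config.step2_effect)
                isi_series += (classify_isi(total3, occasion=Occasion.INTERVIEW3),)
        users.append(
            SyntheticUser(
                uid,
                profile,
                screened=True,
                eligible=eligible,
                step1_completed=step1,
                step2_completed=step2,
                isi_series=isi_series,
                diaries_step1=diaries1,
                diaries_step2=diaries2,
            )
        )
    return users


# ---------------------------------------------------------------------------
# Cohort-level measurements
# ---------------------------------------------------------------------------


def cohort_metrics(cohort: Sequence[SyntheticUser]) -> Dict[str, float]:
    """The funnel and outcome quantities of one generated cohort.

    Percentages are on the 0..100 scale; ISI means in scale points; sleep
    efficiency of the first two diary nights in percent, derived through
    the diary identity per user.
    """
    n = len(cohort)
    screened = [u for u in cohort if u.screened]
    eligible = [u for u in screened if u.eligible]
    step1 = [u for u in eligible if u.step1_completed]
    step2 = [u for u in step1 if u.step2_completed]

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else float("nan")

    metrics: Dict[str, float] = {
        "n_users": float(n),
        "n_screened": float(len(screened)),
        "n_eligible": float(len(eligible)),
        "n_step1": float(len(step1)),
        "n_step2": float(len(step2)),
        "screened_pct": pct(len(screened), n),
        "eligible_pct": pct(len(eligible), len(screened)),
        "step1_pct": pct(len(step1), len(eligible)),
        "step2_pct": pct(len(step2), len(step1)),
    }
    if step1:
        base = [u.isi_series[0].total for u in step1]
        post1 = [u.isi_series[1].total for u in step1]
        metrics["step1_baseline_isi"] = float(np.mean(base))
        metrics["step1_post_isi"] = float(np.mean(post1))
        metrics["post_step1_remission_pct"] = pct(
            sum(1 for t in post1 if t <= 14), len(post1)
        )
        se_vals = [
            window_mean([derive_night(e) for e in u.diaries_step1], "first2").se
            for u in step1
        ]
        metrics["se_first2"] = float(np.mean(se_vals))
        se_last = [
            window_mean([derive_night(e) for e in u.diaries_step1], "last2").se
            for u in step1
        ]
        metrics["se_last2"] = float(np.mean(se_last))
    if step2:
        metrics["step2_post_isi"] = float(
            np.mean([u.isi_series[2].total for u in step2])
        )
        metrics["post_step2_remission_pct"] = pct(
            sum(1 for u in step2 if u.isi_series[2].total <= 14), len(step2)
        )
    return metrics


def cohort_to_frames(cohort: Sequence[SyntheticUser]):
    """Export a cohort as (users, diaries) DataFrames (CSV-ready)."""
    import pandas as pd

    urows, drows = [], []
    for u in cohort:
        totals = [r.total for r in u.isi_series]
        urows.append(
            {
                "user_id": u.user_id,
                "age": u.profile.age,
                "gender": u.profile.gender,
                "education": u.profile.education,
                "health_care_professional": u.profile.health_care_professional,
                "confined": u.profile.confined,
                "familiarity": u.profile.familiarity,
                "cds5": round(u.profile.cds5, 3),
                "cage": round(u.profile.cage, 3),
                "cigarettes": round(u.profile.cigarettes, 3),
                "drinks": round(u.profile.drinks, 3),
                "screened": u.screened,
                "eligible": u.eligible,
                "step1_completed": u.step1_completed,
                "step2_completed": u.step2_completed,
                "isi_baseline": totals[0] if len(totals) > 0 else None,
                "isi_post_step1": totals[1] if len(totals) > 1 else None,
                "isi_post_step2": totals[2] if len(totals) > 2 else None,
            }
        )
        for phase, entries in (("step1", u.diaries_step1), ("step2", u.diaries_step2)):
            for e in entries:
                drows.append(
                    {
                        "user_id": u.user_id,
                        "phase": phase,
                        "night_date": e.night_date.isoformat(),
                        "try_sleep_time": e.try_sleep_time.strftime("%H:%M"),
                        "reported_sol_min": e.reported_sol_min,
                        "nwak": e.nwak,
                        "reported_waso_min": e.reported_waso_min,
                        "final_wake_time": e.final_wake_time.strftime("%H:%M"),
                        "arise_time": e.arise_time.strftime("%H:%M"),
                    }
                )
    return pd.DataFrame(urows), pd.DataFrame(drows)


def cohort_from_frames(users_df, diaries_df) -> List[SyntheticUser]:
    """Rebuild synthetic users from exported frames (funnel flags, ISI
    series and diaries round-trip exactly; profiles round to 3 decimals)."""
    from .diary import parse_diary_row

    by_user: Dict[str, Dict[str, List[DiaryEntry]]] = {}
    if len(diaries_df):
        for _, row in diaries_df.iterrows():
            rec = {k: str(row[k]) for k in DiaryEntryColumns}
            entry = parse_diary_row(rec)
            by_user.setdefault(str(row["user_id"]), {}).setdefault(
                str(row["phase"]), []
            ).append(entry)
    users: List[SyntheticUser] = []
    occasions = (Occasion.INTERVIEW1, Occasion.INTERVIEW2, Occasion.INTERVIEW3)
    for _, row in users_df.iterrows():
        totals = [
            int(row[k])
            for k in ("isi_baseline", "isi_post_step1", "isi_post_step2")
            if not _isna(row[k])
        ]
        series = tuple(
            classify_isi(t, occasion=occasions[j]) for j, t in enumerate(totals)
        )
        phases = by_user.get(str(row["user_id"]), {})
        users.append(
            SyntheticUser(
                user_id=str(row["user_id"]),
                profile=UserProfile(
                    age=int(row["age"]),
                    gender=str(row["gender"]),
                    education=str(row["education"]),
                    health_care_professional=bool(row["health_care_professional"]),
                    confined=bool(row["confined"]),
                    familiarity=int(row["familiarity"]),
                    cds5=float(row["cds5"]),
                    cage=float(row["cage"]),
                    cigarettes=float(row["cigarettes"]),
                    drinks=float(row["drinks"]),
                ),
                screened=bool(row["screened"]),
                eligible=bool(row["eligible"]),
                step1_completed=bool(row["step1_completed"]),
                step2_completed=bool(row["step2_completed"]),
                isi_series=series,
                diaries_step1=tuple(phases.get("step1", ())),
                diaries_step2=tuple(phases.get("step2", ())),
            )
        )
    return users


DiaryEntryColumns = (
    "night_date",
    "try_sleep_time",
    "reported_sol_min",
    "nwak",
    "reported_waso_min",
    "final_wake_time",
    "arise_time",
)


def _isna(v) -> bool:
    try:
        return v is None or (isinstance(v, float) and math.isnan(v)) or v != v
    except TypeError:
        return False


def _safe_paired_t(before: Sequence[float], after: Sequence[float]):
    """Paired t that degenerates to a zero statistic on constant data
    (an all-identical cohort yields zero-valued test statistics)."""
    from .stats import TestResult, paired_t

    d = np.asarray(after, dtype=float) - np.asarray(before, dtype=float)
    try:
        return paired_t(d)
    except ValueError:
        return TestResult(0.0, float(max(d.size - 1, 1)), 1.0, "paired_t")


def _safe_chi_square(counts):
    from .stats import TestResult, chi_square

    try:
        return chi_square(counts)
    except ValueError:
        return TestResult(0.0, 1.0, 1.0, "chi_square")


def emit_study_tables(cohort: Sequence[SyntheticUser]) -> Dict[str, "pd.DataFrame"]:
    """Feasibility-report bundle for a generated cohort.

    Regenerates every statistic class the study design uses: the adherence
    funnel with conditional percentages, demographic comparisons of
    screeners vs non-screeners (pooled t / chi-square), baseline severity
    strata, severity-band distributions along the program, pre/post ISI
    paired tests and the nightly-indicator comparisons.
    """
    import pandas as pd

    from .protocol import FUNNEL_STAGES
    from .stats import funnel_percentages, two_sample_t_pooled

    screened = [u for u in cohort if u.screened]
    not_screened = [u for u in cohort if not u.screened]
    eligible = [u for u in screened if u.eligible]
    step1 = [u for u in eligible if u.step1_completed]
    step2 = [u for u in step1 if u.step2_completed]

    counts = [len(cohort), len(screened), len(eligible), len(step1), len(step2)]
    funnel = pd.DataFrame(funnel_percentages(counts), index=list(FUNNEL_STAGES))

    # demographics: screened vs not screened
    rows = []
    if len(screened) >= 2 and len(not_screened) >= 2:
        a_age = np.array([u.profile.age for u in screened], dtype=float)
        b_age = np.array([u.profile.age for u in not_screened], dtype=float)
        try:
            t = two_sample_t_pooled(
                a_age.mean(), a_age.std(ddof=1), a_age.size,
                b_age.mean(), b_age.std(ddof=1), b_age.size,
            )
        except ValueError:
            from .stats import TestResult

            t = TestResult(0.0, float(a_age.size + b_age.size - 2), 1.0, "two_sample_t_pooled")
        rows.append(("age", "t", t.statistic, t.df, t.p_value))
        for name, pick in (
            ("gender_female", lambda u: u.profile.gender == "female"),
            ("health_care_professional", lambda u: u.profile.health_care_professional),
            ("confined", lambda u: u.profile.confined),
        ):
            tab = [
                [sum(pick(u) for u in g), sum(not pick(u) for u in g)]
                for g in (screened, not_screened)
            ]
            r = _safe_chi_square(tab)
            rows.append((name, "chi_square", r.statistic, r.df, r.p_value))
    demographics = pd.DataFrame(
        rows, columns=["characteristic", "method", "statistic", "df", "p_value"]
    )

    # severity-band distributions along the program
    def band_counts(results: Sequence[ISIResult]) -> Dict[str, int]:
        out = {"none": 0, "subthreshold": 0, "moderate": 0, "severe": 0}
        for r in results:
            out[r.band.value] += 1
        return out

    severity = pd.DataFrame(
        {
            "baseline_screened": band_counts([u.isi_series[0] for u in screened]),
            "baseline_step1": band_counts([u.isi_series[0] for u in step1]),
            "post_step1": band_counts([u.isi_series[1] for u in step1]),
            "post_step2": band_counts([u.isi_series[2] for u in step2]),
        }
    )

    # ISI evolution (paired tests)
    evo_rows = []
    if step1:
        base = [u.isi_series[0].total for u in step1]
        post1 = [u.isi_series[1].total for u in step1]
        r = _safe_paired_t(post1, base)  # positive t for a decrease
        evo_rows.append(
            ("step1_baseline_vs_post", np.mean(base), np.mean(post1), len(step1), r.statistic, r.df, r.p_value)
        )
    if step2:
        i2 = [u.isi_series[1].total for u in step2]
        i3 = [u.isi_series[2].total for u in step2]
        b = [u.isi_series[0].total for u in step2]
        r = _safe_paired_t(i3, i2)
        evo_rows.append(
            ("step2_post1_vs_post2", np.mean(i2), np.mean(i3), len(step2), r.statistic, r.df, r.p_value)
        )
        r = _safe_paired_t(i3, b)
        evo_rows.append(
            ("step2_baseline_vs_post2", np.mean(b), np.mean(i3), len(step2), r.statistic, r.df, r.p_value)
        )
    isi_evolution = pd.DataFrame(
        evo_rows,
        columns=["comparison", "mean_before", "mean_after", "n", "t", "df", "p_value"],
    )

    # nightly indicators, Step-1 week: first 2 vs last 2 completed nights
    def indicator_frame(users, first_sel, last_sel, diaries_of):
        recs = []
        for attr in ("tib", "tst", "se", "sol", "nwak", "waso", "twak"):
            firsts, lasts = [], []
            for u in users:
                nights = [derive_night(e) for e in diaries_of(u)]
                firsts.append(getattr(window_mean(nights, first_sel), attr))
                lasts.append(getattr(window_mean(nights, last_sel), attr))
            r = _safe_paired_t(lasts, firsts)
            recs.append(
                (
                    attr,
                    np.mean(firsts),
                    np.std(firsts, ddof=1) if len(firsts) > 1 else 0.0,
                    np.mean(lasts),
                    np.std(lasts, ddof=1) if len(lasts) > 1 else 0.0,
                    r.statistic,
                    r.df,
                    r.p_value,
                )
            )
        return pd.DataFrame(
            recs,
            columns=["indicator", "mean_before", "sd_before", "mean_after", "sd_after", "t", "df", "p_value"],
        )

    indicators_step1 = (
        indicator_frame(step1, "first2", "last2", lambda u: u.diaries_step1)
        if step1
        else pd.DataFrame()
    )
    indicators_step2 = (
        indicator_frame(
            step2,
            "all",
            "all",
            lambda u: u.diaries_step1,
        )
        if step2
        else pd.DataFrame()
    )
    if step2:
        # before = the Step-1 week, after = the Step-2 nights
        after = indicator_frame(step2, "all", "all", lambda u: u.diaries_step2)
        indicators_step2 = indicators_step2.assign(
            mean_after=after["mean_after"],
            sd_after=after["sd_after"],
        )
        stats_rows = []
        for attr in ("tib", "tst", "se", "sol", "nwak", "waso", "twak"):
            befores = [
                getattr(window_mean([derive_night(e) for e in u.diaries_step1], "all"), attr)
                for u in step2
            ]
            afters = [
                getattr(window_mean([derive_night(e) for e in u.diaries_step2], "all"), attr)
                for u in step2
            ]
            r = _safe_paired_t(afters, befores)
            stats_rows.append((r.statistic, r.df, r.p_value))
        indicators_step2 = indicators_step2.assign(
            t=[s[0] for s in stats_rows],
            df=[s[1] for s in stats_rows],
            p_value=[s[2] for s in stats_rows],
        )

    return {
        "funnel": funnel,
        "demographics": demographics,
        "severity_bands": severity,
        "isi_evolution": isi_evolution,
        "sleep_indicators_step1": indicators_step1,
        "sleep_indicators_step2": indicators_step2,
    }


def user_events(user: SyntheticUser) -> List[ProtocolEvent]:
    """The protocol event log implied by a synthetic user's trajectory.

    Replaying the returned events through :func:`sleepcoach.protocol.replay`
    reconstructs the user's final stage; non-completers end with an
    explicit dropout event.
    """
    events: List[ProtocolEvent] = []
    if not user.screened:
        events.append(ProtocolEvent(EventKind.USER_DROPOUT))
        return events
    events.append(ProtocolEvent(EventKind.ISI_COMPLETED, user.isi_series[0]))
    if not user.eligible:
        return events  # screened-low: terminal after hygiene advice
    if not user.step1_completed:
        events.append(ProtocolEvent(EventKind.USER_DROPOUT))
        return events
    for entry in user.diaries_step1:
        events.append(ProtocolEvent(EventKind.DIARY_ENTRY_VALIDATED, entry))
    events.append(ProtocolEvent(EventKind.ISI_COMPLETED, user.isi_series[1]))
    if not user.step2_completed:
        events.append(ProtocolEvent(EventKind.USER_DROPOUT))
        return events
    for entry in user.diaries_step2:
        events.append(ProtocolEvent(EventKind.DIARY_ENTRY_VALIDATED, entry))
        events.append(ProtocolEvent(EventKind.STEP2_DAY_ELAPSED))
    events.append(ProtocolEvent(EventKind.ISI_COMPLETED, user.isi_series[2]))
    return events
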