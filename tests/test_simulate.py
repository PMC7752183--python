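"""Cohort simulator: determinism, validity, calibration structure."""

import dataclasses

import numpy as np
import pytest

from sleepcoach.diary import derive_night
from sleepcoach.instruments import Occasion
from sleepcoach.protocol import ProtocolState, Stage, funnel_counts, replay
from sleepcoach.simulate import (
    CohortConfig,
    EffectModel,
    Step2Selection,
    TruncNormal,
    cohort_from_frames,
    cohort_metrics,
    cohort_to_frames,
    default_config,
    emit_study_tables,
    generate_cohort,
    user_events,
)


class TestConfig:
    def test_default_calibration_constants(self):
        cfg = default_config()
        assert cfg.n_users == 2069
        assert cfg.p_screen == 0.76
        assert cfg.p_eligible_given_screen == 0.491
        assert cfg.p_step1_given_eligible == 0.215
        assert cfg.p_step2_given_step1 == 0.283
        assert cfg.step1_effect == EffectModel(-2.57, 4.20)
        assert cfg.step2_effect == EffectModel(-0.96, 4.63)
        assert cfg.isi_baseline_subclinical == TruncNormal(10.02, 3.42, 0.0, 14.0)
        assert cfg.isi_baseline_clinical == TruncNormal(18.2, 2.74, 15.0, 28.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(default_config(), p_screen=1.2)

    def test_truncnorm_expected_mean(self):
        d = TruncNormal(0.0, 1.0, -10.0, 10.0)
        assert d.expected() == pytest.approx(0.0, abs=1e-9)
        clinical = default_config().isi_baseline_clinical
        assert clinical.expected() == pytest.approx(18.83, abs=0.01)


class TestGeneration:
    def test_empty_cohort(self):
        assert generate_cohort(default_config(n_users=0)) == []

    def test_same_seed_identical_cohorts(self):
        cfg = default_config(n_users=150, seed=5)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_different_seeds_differ(self):
        cfg = default_config(n_users=150)
        assert generate_cohort(cfg, seed=1) != generate_cohort(cfg, seed=2)

    def test_funnel_flags_monotone_and_series_consistent(self, small_cohort):
        for u in small_cohort:
            assert (not u.step2_completed) or u.step1_completed
            assert (not u.step1_completed) or u.eligible
            assert (not u.eligible) or u.screened
            expected_len = (
                0 if not u.screened else 1 + u.step1_completed + u.step2_completed
            )
            assert len(u.isi_series) == expected_len
            occ = [r.occasion for r in u.isi_series]
            assert occ == [Occasion.INTERVIEW1, Occasion.INTERVIEW2, Occasion.INTERVIEW3][: len(occ)]

    def test_isi_totals_within_scale_and_strata(self, small_cohort):
        for u in small_cohort:
            for r in u.isi_series:
                assert 0 <= r.total <= 28
            if u.screened:
                assert u.eligible == (u.isi_series[0].total > 14)

    def test_all_diaries_pass_validation(self, small_cohort):
        n_nights = 0
        for u in small_cohort:
            if u.step1_completed:
                assert len(u.diaries_step1) == 7
            if u.step2_completed:
                assert len(u.diaries_step2) == 10
            for entry in u.diaries:
                ind = derive_night(entry)  # raises on any invalid entry
                assert 0.0 <= ind.se <= 100.0
                n_nights += 1
        assert n_nights > 0


class TestClosedFormLimit:
    def test_zero_sd_effects_shift_exactly(self):
        cfg = dataclasses.replace(
            default_config(n_users=400, seed=3),
            step1_effect=EffectModel(-3.0, 0.0),
            step2_effect=EffectModel(-1.0, 0.0),
        )
        cohort = generate_cohort(cfg)
        step1 = [u for u in cohort if u.step1_completed]
        assert step1
        for u in step1:
            assert u.isi_series[1].total == max(0, min(28, u.isi_series[0].total - 3))
            if u.step2_completed:
                assert u.isi_series[2].total == max(
                    0, min(28, u.isi_series[1].total - 1)
                )

    def test_degenerate_deltas_break_paired_t(self):
        from sleepcoach.stats import paired_t

        cfg = dataclasses.replace(
            default_config(n_users=300, seed=3), step1_effect=EffectModel(-3.0, 0.0)
        )
        step1 = [u for u in generate_cohort(cfg) if u.step1_completed]
        deltas = [u.isi_series[1].total - u.isi_series[0].total for u in step1]
        with pytest.raises(ValueError, match="constant"):
            paired_t(deltas)


class TestSelectionTilt:
    def test_zero_slope_recovers_plain_bernoulli(self):
        cfg = dataclasses.replace(
            default_config(n_users=2069),
            step2_selection=Step2Selection(beta_per_isi_point=0.0),
        )
        rates = []
        for s in range(6):
            m = cohort_metrics(generate_cohort(cfg, seed=s))
            rates.append(m["step2_pct"])
        assert np.mean(rates) == pytest.approx(28.3, abs=5.0)

    def test_continuers_have_milder_interview2_scores(self):
        cfg = default_config(n_users=2069)
        cont, stop = [], []
        for s in range(8):
            for u in generate_cohort(cfg, seed=s):
                if u.step1_completed:
                    (cont if u.step2_completed else stop).append(u.isi_series[1].total)
        assert np.mean(cont) < np.mean(stop)


class TestRoundTripAndReplay:
    def test_frame_round_trip(self, small_cohort):
        users_df, diaries_df = cohort_to_frames(small_cohort)
        back = cohort_from_frames(users_df, diaries_df)
        assert len(back) == len(small_cohort)
        for a, b in zip(small_cohort, back):
            assert a.user_id == b.user_id
            assert (a.screened, a.eligible, a.step1_completed, a.step2_completed) == (
                b.screened,
                b.eligible,
                b.step1_completed,
                b.step2_completed,
            )
            assert [r.total for r in a.isi_series] == [r.total for r in b.isi_series]
            assert a.diaries == b.diaries

    def test_event_replay_matches_funnel_flags(self, small_cohort):
        states = []
        for u in small_cohort[:300]:
            state, _ = replay(user_events(u), ProtocolState(user_id=u.user_id))
            states.append(state)
            if u.step2_completed:
                assert state.stage in (Stage.AUTONOMOUS_USE, Stage.REFERRED)
                assert (state.stage == Stage.REFERRED) == u.isi_series[2].referral_indicated
            elif u.screened and not u.eligible:
                assert state.stage == Stage.SCREENED_LOW
            else:
                assert state.stage == Stage.DROPPED_OUT
        counts = funnel_counts(states)
        sub = small_cohort[:300]
        assert counts["screened"] == sum(u.screened for u in sub)
        assert counts["eligible"] == sum(u.eligible for u in sub)
        assert counts["step1_completed"] == sum(u.step1_completed for u in sub)
        assert counts["step2_completed"] == sum(u.step2_completed for u in sub)


class TestStudyTables:
    def test_report_bundle_structure(self, small_cohort):
        tables = emit_study_tables(small_cohort)
        assert set(tables) == {
            "funnel",
            "demographics",
            "severity_bands",
            "isi_evolution",
            "sleep_indicators_step1",
            "sleep_indicators_step2",
        }
        funnel = tables["funnel"]
        counts = funnel["count"].tolist()
        assert counts == sorted(counts, reverse=True)
        sev = tables["severity_bands"]
        assert sev["baseline_screened"].sum() == sum(u.screened for u in small_cohort)
        # eligible users can only start moderate or severe
        assert sev.loc["none", "baseline_step1"] == 0
        assert sev.loc["subthreshold", "baseline_step1"] == 0

    def test_identical_users_give_zero_statistics(self, small_cohort):
        template = next(u for u in small_cohort if u.step2_completed)
        clones = [dataclasses.replace(template, user_id=f"c{i}") for i in range(5)]
        tables = emit_study_tables(clones)
        assert (tables["isi_evolution"]["t"] == 0.0).all()
        assert (tables["sleep_indicators_step1"]["t"] == 0.0).all()


class TestCalibrationSmoke:
    """One-seed sanity check; the full 20-seed recovery suite lives in the
    acceptance tests."""

    def test_single_seed_metrics_in_broad_bands(self):
        m = cohort_metrics(generate_cohort(default_config(), seed=2))
        assert m["screened_pct"] == pytest.approx(76.0, abs=4.0)
        assert m["step1_pct"] == pytest.approx(21.5, abs=8.0)
        assert m["step1_baseline_isi"] == pytest.approx(18.8, abs=1.0)
        assert m["se_first2"] == pytest.approx(67.6, abs=6.0)
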