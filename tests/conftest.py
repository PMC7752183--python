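"""Shared fixtures and deterministic hypothesis configuration."""

from __future__ import annotations

from datetime import date, datetime, time, timedelta

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from sleepcoach.diary import DiaryEntry

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


NIGHT = date(2020, 4, 23)


def build_entry(
    bed_off_min: int,
    tib_min: int,
    sol: float,
    waso: float,
    twak: int,
    nwak: int = 1,
    night: date = NIGHT,
) -> DiaryEntry:
    """Construct a diary entry from durations (bed offset is minutes past
    noon), guaranteeing clock-time consistency."""
    noon = datetime.combine(night, time(12, 0))
    bed = noon + timedelta(minutes=bed_off_min)
    arise = bed + timedelta(minutes=tib_min)
    wake = arise - timedelta(minutes=twak)
    return DiaryEntry(
        night_date=night,
        try_sleep_time=bed.time(),
        reported_sol_min=sol,
        nwak=nwak,
        reported_waso_min=waso,
        final_wake_time=wake.time(),
        arise_time=arise.time(),
    )


@st.composite
def valid_diary_entries(draw) -> DiaryEntry:
    """Random internally-consistent diary entries.

    Bed offsets span 13:00-22:00 and nights are at most ~11.7 h so the
    whole night sits strictly inside one noon-to-noon window even after a
    +1 h metamorphic shift.
    """
    bed_off = draw(st.integers(60, 600))
    tib = draw(st.integers(30, 700))
    twak = draw(st.integers(0, tib))
    sol = draw(st.integers(0, tib - twak))
    waso = draw(st.integers(0, tib - twak - sol))
    nwak = draw(st.integers(0, 6))
    return build_entry(bed_off, tib, sol, waso, twak, nwak)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest default-calibration cohort shared across tests."""
    from sleepcoach.simulate import default_config, generate_cohort

    return generate_cohort(default_config(n_users=600, seed=11))
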