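"""Detection rules: single inpatient claim, 30-day outpatient pair,
window independence, and a subset-enumeration brute-force oracle."""

from __future__ import annotations

import datetime as dt
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claims_lookback import Claim, Interval, detect, presence_profile

D0 = dt.date(2001, 1, 1)
WINDOW = Interval(D0, D0 + dt.timedelta(days=180))
CODE = "25000"  # Diabetes
COND = "Diabetes"


def claim(day: int, setting: str, code: str = CODE) -> Claim:
    return Claim("p1", D0 + dt.timedelta(days=day), setting, code)


def test_interval_rejects_empty():
    with pytest.raises(ValueError):
        Interval(D0, D0)


@pytest.mark.parametrize(
    "claims, present, onset_day, basis",
    [
        # one inpatient claim suffices, counted at first occurrence
        ([claim(10, "inpatient")], True, 10, "inpatient_single"),
        # two physician claims 15 days apart never qualify
        ([claim(0, "physician"), claim(15, "physician")], False, None, None),
        # exactly 30 days apart qualifies (inclusive), onset at first claim
        ([claim(0, "physician"), claim(30, "physician")], True, 0, "outpatient_pair"),
        # a single outpatient claim never qualifies; inpatient rule wins
        (
            [claim(5, "outpatient_facility"), claim(40, "inpatient")],
            True,
            40,
            "inpatient_single",
        ),
        # pair may mix outpatient-facility and physician settings
        (
            [claim(3, "outpatient_facility"), claim(50, "physician")],
            True,
            3,
            "outpatient_pair",
        ),
        # earliest onset across rules wins
        (
            [claim(2, "physician"), claim(60, "physician"), claim(90, "inpatient")],
            True,
            2,
            "outpatient_pair",
        ),
        # non-matching codes are invisible
        ([claim(10, "inpatient", "79902")], False, None, None),
        ([], False, None, None),
    ],
)
def test_detect_rules(codebook, claims, present, onset_day, basis):
    res = detect(claims, COND, codebook, WINDOW)
    assert res.present is present
    if present:
        assert res.onset_date == D0 + dt.timedelta(days=onset_day)
        assert res.basis == basis
    else:
        assert res.onset_date is None


def test_inpatient_wins_onset_tie(codebook):
    claims = [
        claim(7, "inpatient"),
        claim(7, "physician"),
        claim(45, "physician"),
    ]
    res = detect(claims, COND, codebook, WINDOW)
    assert res.onset_date == D0 + dt.timedelta(days=7)
    assert res.basis == "inpatient_single"


def test_claims_outside_window_invisible(codebook):
    claims = [claim(-5, "inpatient"), claim(200, "inpatient")]
    assert detect(claims, COND, codebook, WINDOW).present is False


def test_per_setting_pairing_switch(codebook):
    mixed = [claim(3, "outpatient_facility"), claim(50, "physician")]
    assert detect(mixed, COND, codebook, WINDOW).present is True
    assert (
        detect(mixed, COND, codebook, WINDOW, pair_pooling="per_setting").present
        is False
    )
    same = [claim(3, "physician"), claim(50, "physician")]
    assert (
        detect(same, COND, codebook, WINDOW, pair_pooling="per_setting").present is True
    )
    with pytest.raises(ValueError):
        detect(mixed, COND, codebook, WINDOW, pair_pooling="bogus")


def test_mixed_rule_lets_inpatient_join_pair(codebook):
    claims = [claim(0, "physician"), claim(40, "inpatient")]
    off = detect(claims, COND, codebook, WINDOW)
    assert off.onset_date == D0 + dt.timedelta(days=40)  # rule A only
    on = detect(claims, COND, codebook, WINDOW, mixed_rule=True)
    assert on.onset_date == D0  # pair (0, 40) now qualifies
    assert on.basis == "outpatient_pair"


# -- presence_profile -------------------------------------------------------

PREV = Interval(D0 - dt.timedelta(days=365), D0)
INC = Interval(D0, D0 + dt.timedelta(days=91))


def test_profile_prevalence_only(codebook):
    claims = [claim(-100, "inpatient")]
    assert presence_profile(claims, COND, codebook, PREV, INC) == (True, False)


def test_profile_both(codebook):
    claims = [
        claim(-100, "physician"),
        claim(-60, "physician"),
        claim(5, "inpatient"),
    ]
    assert presence_profile(claims, COND, codebook, PREV, INC) == (True, True)


def test_profile_pair_straddling_index_counts_nowhere(codebook):
    claims = [claim(-20, "physician"), claim(20, "physician")]
    assert presence_profile(claims, COND, codebook, PREV, INC) == (False, False)


def test_profile_requires_abutting_windows(codebook):
    gap = Interval(D0 + dt.timedelta(days=1), D0 + dt.timedelta(days=91))
    with pytest.raises(ValueError, match="abut"):
        presence_profile([], COND, codebook, PREV, gap)


# -- oracle and properties --------------------------------------------------


def oracle_detect(claims, condition, codebook, window):
    """Enumerate all subsets of size <= 2 and check the rules directly."""
    visible = [
        c
        for c in claims
        if window.start <= c.service_date < window.end
        and codebook.matches(c.code, condition)
    ]
    onsets = []
    for c in visible:  # rule A singletons
        if c.setting == "inpatient":
            onsets.append((c.service_date, "inpatient_single"))
    for a, b in combinations(visible, 2):  # rule B pairs
        if a.setting != "inpatient" and b.setting != "inpatient":
            if abs((a.service_date - b.service_date).days) >= 30:
                onsets.append((min(a.service_date, b.service_date), "outpatient_pair"))
    if not onsets:
        return False, None, None
    date, basis = min(onsets)
    return True, date, basis


def _random_claims(rng: np.random.Generator, n: int) -> list[Claim]:
    settings_ = ["inpatient", "outpatient_facility", "physician"]
    codes = [CODE, "2500", "79902"]  # two diabetes codes + one non-matching
    return [
        Claim(
            "p1",
            D0 + dt.timedelta(days=int(rng.integers(-40, 220))),
            settings_[int(rng.integers(0, 3))],
            codes[int(rng.integers(0, 3))],
        )
        for _ in range(n)
    ]


def test_detect_agrees_with_subset_oracle(codebook):
    rng = np.random.default_rng(42)
    for _ in range(600):
        claims = _random_claims(rng, int(rng.integers(0, 9)))
        res = detect(claims, COND, codebook, WINDOW)
        exp_present, exp_onset, exp_basis = oracle_detect(claims, COND, codebook, WINDOW)
        assert res.present == exp_present
        assert res.onset_date == exp_onset
        assert res.basis == exp_basis


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    days=st.lists(st.integers(min_value=-40, max_value=220), max_size=8),
    settings_=st.lists(st.integers(min_value=0, max_value=2), max_size=8),
    grow=st.integers(min_value=1, max_value=120),
)
def test_window_monotonicity_and_order_independence(codebook, days, settings_, grow):
    """Enlarging a window never turns presence off; claim order is
    irrelevant; onset stays within the matching claims' date span."""
    names = ["inpatient", "outpatient_facility", "physician"]
    claims = [
        Claim("p1", D0 + dt.timedelta(days=d), names[s % 3], CODE)
        for d, s in zip(days, settings_ + [0] * len(days))
    ]
    small = detect(claims, COND, codebook, WINDOW)
    bigger = Interval(
        WINDOW.start - dt.timedelta(days=grow), WINDOW.end + dt.timedelta(days=grow)
    )
    big = detect(claims, COND, codebook, bigger)
    if small.present:
        assert big.present
    shuffled = detect(list(reversed(claims)), COND, codebook, WINDOW)
    assert shuffled == small
    if small.present:
        dates = [
            c.service_date
            for c in claims
            if c.service_date in WINDOW and codebook.matches(c.code, COND)
        ]
        assert min(dates) <= small.onset_date <= max(dates)
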