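"""Four-group classification, incidence/prevalence proportions, and
misclassification metrics against the gold-standard lookback."""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from claims_lookback import (
    GROUPS,
    SimulationConfig,
    WindowSpec,
    classify,
    incidence_proportion,
    misclassification,
    prevalence_proportion,
    run_grid,
    simulate,
)
from claims_lookback.classify import METRIC_COLUMNS

from conftest import INDEX, make_dataset, make_patients


def records(groups: dict[str, str], condition="Diabetes", L=6) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "patient_id": list(groups),
            "condition": condition,
            "lookback_months": L,
            "group": pd.Categorical(list(groups.values()), categories=GROUPS),
        }
    )
    return df


def test_window_spec_intervals():
    spec = WindowSpec(dt.date(2001, 7, 1), lookback_months=6)
    assert spec.prevalence_interval.start == dt.date(2001, 1, 1)
    assert spec.prevalence_interval.end == dt.date(2001, 7, 1)
    assert spec.incidence_interval.end == dt.date(2001, 10, 1)
    with pytest.raises(ValueError):
        WindowSpec(dt.date(2001, 7, 1), lookback_months=0)


def test_claim_near_index_is_prevalence_only_at_every_L(codebook):
    ds = make_dataset(
        make_patients(1), [("p001", "2001-05-10", "inpatient", "25000")]
    )  # two months before index
    for L in (6, 12, 18, 24, 30, 36):
        rec = classify(ds, codebook, L)
        row = rec[(rec.patient_id == "p001") & (rec.condition == "Diabetes")]
        assert row["group"].iat[0] == "prevalence_only"


def test_reclassification_both_to_incidence_only(codebook):
    # qualifying pair ~20 months before index + pair just after index
    ds = make_dataset(
        make_patients(1),
        [
            ("p001", "1999-11-05", "physician", "25000"),
            ("p001", "1999-12-20", "physician", "25000"),
            ("p001", "2001-07-10", "physician", "25001"),
            ("p001", "2001-08-20", "outpatient_facility", "25000"),
        ],
    )
    g36 = classify(ds, codebook, 36)
    g12 = classify(ds, codebook, 12)
    pick = lambda rec: rec[(rec.condition == "Diabetes")]["group"].iat[0]
    assert pick(g36) == "both"
    assert pick(g12) == "incidence_only"


def test_no_claims_all_neither_and_complete(codebook):
    ds = make_dataset(make_patients(3), [])
    rec = classify(ds, codebook, 12)
    assert len(rec) == 3 * 12
    assert (rec["group"] == "neither").all()


def test_incidence_proportion_arithmetic():
    base = {f"p{i}": "neither" for i in range(8)}
    base.update({"a": "incidence_only", "b": "incidence_only"})
    base.update({"x": "both", "y": "prevalence_only"})
    assert incidence_proportion(records(base)) == pytest.approx(200.0)
    only_inc = {f"p{i}": "incidence_only" for i in range(5)}
    assert incidence_proportion(records(only_inc)) == pytest.approx(1000.0)
    none = {"a": "both", "b": "prevalence_only"}
    assert math.isnan(incidence_proportion(records(none)))  # I+D == 0 undefined
    zero = {"a": "neither", "b": "prevalence_only"}
    assert incidence_proportion(records(zero)) == 0.0
    with pytest.raises(ValueError, match="incomplete"):
        incidence_proportion(records(base), n_patients=99)


def test_prevalence_proportion_arithmetic():
    mix = {f"p{i}": "neither" for i in range(92)}
    mix.update({f"b{i}": "both" for i in range(3)})
    mix.update({f"q{i}": "prevalence_only" for i in range(5)})
    assert prevalence_proportion(records(mix)) == pytest.approx(80.0)
    assert prevalence_proportion(records({"a": "neither"})) == 0.0
    assert prevalence_proportion(records({"a": "both", "b": "both"})) == 1000.0


def test_misclassification_hand_example():
    """Three incident patients at L=6 of whom one is truly incident at the
    gold standard and two were prevalent (group 'both' at 36)."""
    base36 = {f"n{i}": "neither" for i in range(6)}
    base36.update({f"q{i}": "prevalence_only" for i in range(8)})
    base36.update({"p2": "both", "p3": "both", "p1": "incidence_only"})
    at36 = records(base36, L=36)  # prevalent@36 = 8 + 2 = 10

    base6 = {f"n{i}": "neither" for i in range(6)}
    base6.update({f"q{i}": "prevalence_only" for i in range(4)})
    base6.update({f"q{i}": "neither" for i in range(4, 8)})
    base6.update({"p1": "incidence_only", "p2": "incidence_only", "p3": "incidence_only"})
    at6 = records(base6, L=6)

    m = misclassification(at6, at36)
    assert m["n_false_positive"] == 2
    assert m["false_positive_fraction"] == pytest.approx(0.2)
    assert m["pct_incident_false_positive"] == pytest.approx(2 / 3)
    assert m["sensitivity"] == 1.0
    assert m["ppv"] == pytest.approx(1 / 3)


def test_misclassification_self_comparison_is_perfect():
    groups = {"a": "incidence_only", "b": "both", "c": "neither", "d": "prevalence_only"}
    rec = records(groups, L=36)
    m = misclassification(rec, rec)
    assert m["n_false_positive"] == 0
    assert m["false_positive_fraction"] == 0.0
    assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0 and m["ppv"] == 1.0


def test_misclassification_cohort_mismatch_rejected():
    a = records({"a": "neither"}, L=6)
    b = records({"b": "neither"}, L=36)
    with pytest.raises(ValueError, match="cohort mismatch"):
        misclassification(a, b)


def test_run_grid_cardinality_and_determinism(codebook):
    ds, _ = simulate(SimulationConfig(n_patients=60, seed=9))
    grid = run_grid(ds, codebook)
    assert list(grid.columns) == METRIC_COLUMNS
    assert len(grid) == 12 * 6
    # shuffled patient order -> identical grid
    shuffled = ds.patients.sample(frac=1.0, random_state=1).reset_index(drop=True)
    ds2 = type(ds)(patients=shuffled, claims=ds.claims, meta=ds.meta)
    grid2 = run_grid(ds2, codebook)
    pd.testing.assert_frame_equal(
        grid.sort_values(["condition", "lookback_months"]).reset_index(drop=True),
        grid2.sort_values(["condition", "lookback_months"]).reset_index(drop=True),
    )


def test_run_grid_empty_cohort(codebook):
    ds = make_dataset(make_patients(4), [])
    grid = run_grid(ds, codebook)
    assert (grid["incidence_per_1000"] == 0.0).all()
    assert (grid["n_false_positive"] == 0).all()
    # nothing identified in the gold window -> FPF is 0/0, undefined
    assert grid["false_positive_fraction"].isna().all()


def test_run_grid_requires_gold_in_grid(codebook):
    ds = make_dataset(make_patients(2), [])
    with pytest.raises(ValueError, match="gold"):
        run_grid(ds, codebook, L_values=[6, 12], gold_L=36)


def test_incidence_proportion_ratio_not_monotone_counterexample(codebook):
    """The incident COUNT is monotone in L (set inclusion) but the ratio
    I/(I+D) need not be: one truly incident patient plus a patient whose
    only claims lie >6 months before index makes the proportion RISE with
    the longer lookback (denominator shrinks, numerator constant)."""
    ds = make_dataset(
        make_patients(3),
        [
            ("p001", "2001-07-10", "inpatient", "25000"),  # truly incident
            ("p002", "2000-01-15", "inpatient", "25000"),  # detected only at long L
        ],
    )
    grid = run_grid(ds, codebook, L_values=[6, 36])
    sub = grid[grid.condition == "Diabetes"].set_index("lookback_months")
    assert sub.at[6, "n_incident"] == 1 and sub.at[36, "n_incident"] == 1
    assert sub.at[6, "incidence_per_1000"] == pytest.approx(1000 / 3)
    assert sub.at[36, "incidence_per_1000"] == pytest.approx(500.0)
    assert sub.at[36, "incidence_per_1000"] > sub.at[6, "incidence_per_1000"]


def test_grid_matches_scalar_reclassifier_on_random_cohorts(
    codebook, all_sample_codes
):
    from conftest import brute_force_classify, random_cohort, sorted_records

    rng = np.random.default_rng(123)
    for _ in range(25):
        ds = random_cohort(rng, codebook, all_sample_codes, int(rng.integers(1, 12)))
        for L in (6, 24):
            fast = sorted_records(classify(ds, codebook, L))
            slow = sorted_records(brute_force_classify(ds, codebook, L))
            pd.testing.assert_frame_equal(fast, slow)
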