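"""Four-group classification and lookback-misclassification metrics.

For each patient and condition, presence is evaluated independently in a
prevalence window ``[index - L months, index)`` and an incidence window
``[index, index + incidence_months)``, yielding one of four mutually
exclusive groups: ``both``, ``prevalence_only``, ``incidence_only``,
``neither``.  The incidence proportion is ``I/(I + D)`` (incidence-only
count over incidence-only plus condition-free patients; prevalent patients
are excluded from the risk set), reported per 1,000.

Shortening the lookback L moves patients from ``prevalence_only`` to
``neither`` and from ``both`` to ``incidence_only``.  Patients who are
incident at a short L but prevalent at the gold-standard L* (36 months by
default) are false positives; the false positive fraction divides them by
the number of patients with the condition identified in the gold-standard
prevalence period.  Because the short-L incident set always contains the
gold-standard incident set, sensitivity is 1 by construction while
specificity and positive predictive value decay as L shrinks.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .codebook import ConditionCodebook
from .cohort import CohortDataset, add_months
from .detection import Interval

__all__ = [
    "GROUPS",
    "DEFAULT_L_GRID",
    "WindowSpec",
    "classify",
    "incidence_proportion",
    "prevalence_proportion",
    "misclassification",
    "run_grid",
    "METRIC_COLUMNS",
]

GROUPS = ("both", "prevalence_only", "incidence_only", "neither")
DEFAULT_L_GRID = (6, 12, 18, 24, 30, 36)

METRIC_COLUMNS = [
    "condition",
    "lookback_months",
    "n_both",
    "n_prev_only",
    "n_incident",
    "n_neither",
    "incidence_per_1000",
    "prevalence_per_1000",
    "n_false_positive",
    "false_positive_fraction",
    "pct_incident_false_positive",
    "sensitivity",
    "specificity",
    "ppv",
]


@dataclass(frozen=True)
class WindowSpec:
    """Index date + lookback length L (months) + incidence length (months)."""

    index_date: dt.date
    lookback_months: int
    incidence_months: int = 3

    def __post_init__(self) -> None:
        if self.lookback_months <= 0:
            raise ValueError("lookback_months must be positive")
        if self.incidence_months <= 0:
            raise ValueError("incidence_months must be positive")

    @property
    def prevalence_interval(self) -> Interval:
        return Interval(
            add_months(self.index_date, -self.lookback_months), self.index_date
        )

    @property
    def incidence_interval(self) -> Interval:
        return Interval(
            self.index_date, add_months(self.index_date, self.incidence_months)
        )


# ---------------------------------------------------------------------------
# vectorized presence engine
# ---------------------------------------------------------------------------


def _matched_claims(dataset: CohortDataset, codebook: ConditionCodebook) -> pd.DataFrame:
    """Claims joined to the conditions their codes identify and to the
    patient's index date.  One row per claim x matched condition."""
    claims = dataset.claims
    if claims.empty:
        return pd.DataFrame(
            columns=["patient_id", "service_date", "setting", "condition", "index_month"]
        )
    match = codebook.match_table(claims["code"].unique())
    m = claims.merge(match, on="code")
    patients = dataset.patients[["patient_id", "index_date"]].copy()
    patients["index_month"] = patients["index_date"].values.astype("datetime64[M]")
    m = m.merge(patients[["patient_id", "index_month"]], on="patient_id")
    return m[["patient_id", "service_date", "setting", "condition", "index_month"]]


def _present_pairs(
    matched: pd.DataFrame,
    start_months: int,
    end_months: int,
    pair_pooling: str,
    mixed_rule: bool,
) -> pd.DataFrame:
    """(patient_id, condition) pairs detected within the window
    ``[index + start_months, index + end_months)`` (calendar months)."""
    if matched.empty:
        return pd.DataFrame(columns=["patient_id", "condition"])
    # month-resolution arithmetic: index dates are first-of-month, so
    # datetime64[M] offsets land exactly on calendar window boundaries
    index_month = matched["index_month"].values.astype("datetime64[M]")
    start = (index_month + np.int64(start_months)).astype("datetime64[ns]")
    end = (index_month + np.int64(end_months)).astype("datetime64[ns]")
    sd = matched["service_date"].values.astype("datetime64[ns]")
    sub = matched.loc[(sd >= start) & (sd < end)]

    keys = ["patient_id", "condition"]
    hits = [sub.loc[sub["setting"] == "inpatient", keys]]  # rule A

    inpatient = sub["setting"] == "inpatient"
    if pair_pooling == "pooled":
        pools = [sub if mixed_rule else sub.loc[~inpatient]]
    elif pair_pooling == "per_setting":
        pools = []
        for setting in ("outpatient_facility", "physician"):
            mask = sub["setting"] == setting
            if mixed_rule:
                mask = mask | inpatient
            pools.append(sub.loc[mask])
    else:
        raise ValueError(f"pair_pooling must be 'pooled' or 'per_setting', got {pair_pooling!r}")

    for pool in pools:  # rule B: earliest and latest >= 30 days apart
        if pool.empty:
            continue
        span = pool.groupby(keys, sort=False)["service_date"].agg(["min", "max"])
        qual = span[(span["max"] - span["min"]).dt.days >= 30]
        hits.append(qual.reset_index()[keys])

    return pd.concat(hits, ignore_index=True).drop_duplicates()


def _records_from_pairs(
    patient_ids: Sequence[str],
    conditions: Sequence[str],
    prev_pairs: pd.DataFrame,
    inc_pairs: pd.DataFrame,
    lookback_months: int,
) -> pd.DataFrame:
    idx = pd.MultiIndex.from_product(
        [patient_ids, conditions], names=["patient_id", "condition"]
    )
    rec = idx.to_frame(index=False)
    prev = prev_pairs.copy()
    prev["in_prev"] = True
    inc = inc_pairs.copy()
    inc["in_inc"] = True
    rec = rec.merge(prev, on=["patient_id", "condition"], how="left")
    rec = rec.merge(inc, on=["patient_id", "condition"], how="left")
    in_prev = rec["in_prev"].notna().to_numpy()
    in_inc = rec["in_inc"].notna().to_numpy()
    group = np.select(
        [in_prev & in_inc, in_prev, in_inc],
        ["both", "prevalence_only", "incidence_only"],
        default="neither",
    )
    out = rec[["patient_id", "condition"]].copy()
    out["lookback_months"] = lookback_months
    out["group"] = pd.Categorical(group, categories=GROUPS)
    return out


def classify(
    dataset: CohortDataset,
    codebook: ConditionCodebook,
    lookback_months: int,
    incidence_months: int = 3,
    *,
    pair_pooling: str = "pooled",
    mixed_rule: bool = False,
) -> pd.DataFrame:
    """Four-group classification records for every patient x condition.

    Returns a complete DataFrame (``n_patients x n_conditions`` rows) with
    columns ``patient_id, condition, lookback_months, group``.
    """
    if lookback_months <= 0:
        raise ValueError("lookback_months must be positive")
    matched = _matched_claims(dataset, codebook)
    prev = _present_pairs(matched, -lookback_months, 0, pair_pooling, mixed_rule)
    inc = _present_pairs(matched, 0, incidence_months, pair_pooling, mixed_rule)
    return _records_from_pairs(
        dataset.patients["patient_id"].tolist(),
        list(codebook.conditions),
        prev,
        inc,
        lookback_months,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _group_counts(records: pd.DataFrame) -> dict[str, int]:
    counts = records["group"].value_counts()
    return {g: int(counts.get(g, 0)) for g in GROUPS}


def _check_single_cell(records: pd.DataFrame) -> None:
    if records["condition"].nunique() > 1 or records["lookback_months"].nunique() > 1:
        raise ValueError("records must cover a single condition and lookback length")
    if records["patient_id"].duplicated().any():
        raise ValueError("duplicate patient in classification records")


def _ratio(num: int, den: int) -> float:
    """Undefined ratios propagate as NaN, never coerced to 0."""
    return num / den if den else math.nan


def incidence_proportion(records: pd.DataFrame, n_patients: Optional[int] = None) -> float:
    """Incidence per 1,000 = 1000 * I / (I + D) for one condition and L."""
    _check_single_cell(records)
    if n_patients is not None and len(records) != n_patients:
        raise ValueError(
            f"incomplete record set: {len(records)} records for {n_patients} patients"
        )
    c = _group_counts(records)
    return 1000.0 * _ratio(c["incidence_only"], c["incidence_only"] + c["neither"])


def prevalence_proportion(records: pd.DataFrame, n_patients: Optional[int] = None) -> float:
    """Prevalence per 1,000 = 1000 * (both + prevalence_only) / N."""
    _check_single_cell(records)
    if n_patients is not None and len(records) != n_patients:
        raise ValueError(
            f"incomplete record set: {len(records)} records for {n_patients} patients"
        )
    c = _group_counts(records)
    return 1000.0 * _ratio(c["both"] + c["prevalence_only"], len(records))


def misclassification(
    records_at_L: pd.DataFrame, records_at_gold: pd.DataFrame
) -> dict:
    """Misclassification statistics of lookback L against the gold standard.

    False positives are patients incident-only at L but not at the gold
    lookback (they are prevalent — group ``both`` — under the gold
    standard).  Returns one metrics row as a dict (see ``METRIC_COLUMNS``).
    """
    _check_single_cell(records_at_L)
    _check_single_cell(records_at_gold)
    if records_at_L["condition"].iat[0] != records_at_gold["condition"].iat[0]:
        raise ValueError("condition mismatch between record sets")
    ids_L = set(records_at_L["patient_id"])
    ids_G = set(records_at_gold["patient_id"])
    if ids_L != ids_G:
        raise ValueError("cohort mismatch between record sets")

    n = len(ids_L)
    c = _group_counts(records_at_L)

    def _ids(records: pd.DataFrame, group: str) -> set:
        return set(records.loc[records["group"] == group, "patient_id"])

    inc_L = _ids(records_at_L, "incidence_only")
    inc_G = _ids(records_at_gold, "incidence_only")
    prev_G = _ids(records_at_gold, "both") | _ids(records_at_gold, "prevalence_only")

    fp = inc_L - inc_G
    tp = inc_L & inc_G
    not_inc_L = ids_L - inc_L
    not_inc_G = ids_G - inc_G

    return {
        "condition": records_at_L["condition"].iat[0],
        "lookback_months": int(records_at_L["lookback_months"].iat[0]),
        "n_both": c["both"],
        "n_prev_only": c["prevalence_only"],
        "n_incident": c["incidence_only"],
        "n_neither": c["neither"],
        "incidence_per_1000": 1000.0
        * _ratio(c["incidence_only"], c["incidence_only"] + c["neither"]),
        "prevalence_per_1000": 1000.0 * _ratio(c["both"] + c["prevalence_only"], n),
        "n_false_positive": len(fp),
        "false_positive_fraction": _ratio(len(fp), len(prev_G)),
        "pct_incident_false_positive": _ratio(len(fp), len(inc_L)),
        "sensitivity": _ratio(len(tp), len(inc_G)),
        "specificity": _ratio(len(not_inc_L & not_inc_G), len(not_inc_G)),
        "ppv": _ratio(len(tp), len(inc_L)),
    }


def run_grid(
    dataset: CohortDataset,
    codebook: ConditionCodebook,
    L_values: Iterable[int] = DEFAULT_L_GRID,
    incidence_months: int = 3,
    gold_L: Optional[int] = None,
    *,
    pair_pooling: str = "pooled",
    mixed_rule: bool = False,
    return_records: bool = False,
):
    """Misclassification metrics for every condition x lookback length.

    ``gold_L`` defaults to ``max(L_values)`` and must be in the grid.
    Deterministic for fixed input; one row per condition per L, columns
    ``METRIC_COLUMNS``.  With ``return_records=True`` also returns the
    concatenated classification records for every L.
    """
    L_values = sorted(set(int(L) for L in L_values))
    if not L_values or any(L <= 0 for L in L_values):
        raise ValueError("L_values must be positive lookback lengths in months")
    if gold_L is None:
        gold_L = max(L_values)
    if gold_L not in L_values:
        raise ValueError(f"gold standard L={gold_L} absent from L grid {L_values}")

    matched = _matched_claims(dataset, codebook)
    patient_ids = dataset.patients["patient_id"].tolist()
    conditions = list(codebook.conditions)
    inc = _present_pairs(matched, 0, incidence_months, pair_pooling, mixed_rule)

    records: dict[int, pd.DataFrame] = {}
    for L in L_values:
        prev = _present_pairs(matched, -L, 0, pair_pooling, mixed_rule)
        records[L] = _records_from_pairs(patient_ids, conditions, prev, inc, L)

    by_cond = {
        L: dict(tuple(rec.groupby("condition", observed=False)))
        for L, rec in records.items()
    }
    rows = []
    for condition in conditions:
        gold_rec = by_cond[gold_L][condition]
        for L in L_values:
            rows.append(misclassification(by_cond[L][condition], gold_rec))
    grid = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    if return_records:
        return grid, pd.concat(records.values(), ignore_index=True)
    return grid
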