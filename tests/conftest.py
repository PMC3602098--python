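"""Shared fixtures: the builtin codebook, random-cohort builders, and an
independent brute-force reclassifier used as the oracle for the vectorized
classification path."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from claims_lookback import (
    Claim,
    CohortDataset,
    ConditionCodebook,
    WindowSpec,
    detect,
)
from claims_lookback.classify import GROUPS
from claims_lookback.cohort import add_months

INDEX = dt.date(2001, 7, 1)


@pytest.fixture(scope="session")
def codebook() -> ConditionCodebook:
    return ConditionCodebook.builtin()


@pytest.fixture(scope="session")
def all_sample_codes(codebook) -> list[str]:
    codes: list[str] = []
    for cond in codebook.conditions:
        codes.extend(codebook.sample_codes(cond))
    return sorted(set(codes))


def make_patients(n: int, index: dt.date = INDEX, cohort: str = "indexed") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [f"p{i:03d}" for i in range(1, n + 1)],
            "cohort": cohort,
            "eligibility_start": pd.Timestamp(add_months(index, -36)),
            "index_date": pd.Timestamp(index),
        }
    )


def make_dataset(patients: pd.DataFrame, claim_rows: list[tuple]) -> CohortDataset:
    """claim_rows: (patient_id, date, setting, code) tuples."""
    claims = pd.DataFrame(
        claim_rows, columns=["patient_id", "service_date", "setting", "code"]
    )
    claims["service_date"] = pd.to_datetime(claims["service_date"])
    return CohortDataset(patients=patients, claims=claims)


def random_cohort(
    rng: np.random.Generator,
    codebook: ConditionCodebook,
    sample_codes: list[str],
    n_patients: int,
    max_claims: int = 8,
) -> CohortDataset:
    """Random small cohort: random first-of-month index dates, claims spread
    across (and slightly beyond) the observation span, codes drawn from the
    codebook's member codes plus non-matching noise codes."""
    months = rng.integers(0, 36, size=n_patients)
    rows = []
    patients = []
    noise_codes = ["79902", "v700", "78900"]
    pool = list(sample_codes) + noise_codes
    for i in range(n_patients):
        pid = f"p{i:03d}"
        index = add_months(dt.date(2000, 1, 1), int(months[i]))
        patients.append(
            (pid, "indexed", add_months(index, -36), index)
        )
        for _ in range(int(rng.integers(0, max_claims + 1))):
            offset = int(rng.integers(-37 * 30, 4 * 30))
            date = index + dt.timedelta(days=offset)
            setting = ["inpatient", "outpatient_facility", "physician"][
                int(rng.integers(0, 3))
            ]
            code = pool[int(rng.integers(0, len(pool)))]
            rows.append((pid, date.isoformat(), setting, code))
    pdf = pd.DataFrame(
        patients, columns=["patient_id", "cohort", "eligibility_start", "index_date"]
    )
    pdf["eligibility_start"] = pd.to_datetime(pdf["eligibility_start"])
    pdf["index_date"] = pd.to_datetime(pdf["index_date"])
    return make_dataset(pdf, rows)


def brute_force_classify(
    dataset: CohortDataset,
    codebook: ConditionCodebook,
    lookback_months: int,
    incidence_months: int = 3,
    **switches,
) -> pd.DataFrame:
    """Per-patient scalar reclassifier: applies :func:`detect` window by
    window, entirely independent of the vectorized group-by path."""
    rows = []
    by_patient: dict[str, list[Claim]] = {
        pid: [] for pid in dataset.patients["patient_id"]
    }
    for r in dataset.claims.itertuples(index=False):
        by_patient[r.patient_id].append(
            Claim(r.patient_id, r.service_date.date(), r.setting, r.code)
        )
    for p in dataset.patients.itertuples(index=False):
        spec = WindowSpec(p.index_date.date(), lookback_months, incidence_months)
        for condition in codebook.conditions:
            claims = by_patient[p.patient_id]
            pre = detect(
                claims, condition, codebook, spec.prevalence_interval, **switches
            ).present
            post = detect(
                claims, condition, codebook, spec.incidence_interval, **switches
            ).present
            group = (
                "both"
                if pre and post
                else "prevalence_only"
                if pre
                else "incidence_only"
                if post
                else "neither"
            )
            rows.append((p.patient_id, condition, lookback_months, group))
    out = pd.DataFrame(
        rows, columns=["patient_id", "condition", "lookback_months", "group"]
    )
    out["group"] = pd.Categorical(out["group"], categories=GROUPS)
    return out


def sorted_records(records: pd.DataFrame) -> pd.DataFrame:
    return (
        records.sort_values(["patient_id", "condition"])
        .reset_index(drop=True)
        .astype({"lookback_months": int})
    )
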