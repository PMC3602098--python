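"""Domain model and delimited-file I/O for patient rosters and claims.

A cohort is a patient table (one row per patient: id, cohort label,
eligibility start, index date) plus a claims table (one row per
claim-diagnosis: patient id, service date, care setting, diagnosis code).
Index dates anchor the analysis windows and must fall on the first day of a
month with at least 36 calendar months of prior eligibility — the standard
continuous-coverage inclusion criterion for Medicare-claims cohorts.

Three analytic care settings are distinguished: ``inpatient``,
``outpatient_facility`` and ``physician``.  Common input dialect tokens
(``snf``, ``home_health``, ``dme``) are accepted and mapped to
``outpatient_facility`` so that the single-claim detection rule, which
applies to inpatient stays only, is never applied to them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .codebook import CodebookError, normalize_code

__all__ = [
    "Claim",
    "CohortDataset",
    "CohortValidationError",
    "SETTINGS",
    "add_months",
    "first_of_month",
    "read_cohort",
    "write_cohort",
]

SETTINGS: tuple[str, ...] = ("inpatient", "outpatient_facility", "physician")

#: Input dialect tokens accepted on read and collapsed to analytic settings.
SETTING_ALIASES: dict[str, str] = {
    "snf": "outpatient_facility",
    "home_health": "outpatient_facility",
    "dme": "outpatient_facility",
}

PATIENT_COLUMNS = ("patient_id", "cohort", "eligibility_start", "index_date")
CLAIM_COLUMNS = ("patient_id", "service_date", "setting", "code")

REQUIRED_PRE_INDEX_MONTHS = 36


class CohortValidationError(ValueError):
    """One or more malformed rows; carries per-row messages."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        preview = "; ".join(problems[:5])
        more = f" (+{len(problems) - 5} more)" if len(problems) > 5 else ""
        super().__init__(f"{len(problems)} validation problem(s): {preview}{more}")


@dataclass(frozen=True)
class Claim:
    """One diagnosis occurrence on a date, in a care setting."""

    patient_id: str
    service_date: dt.date
    setting: str
    code: str


@dataclass
class CohortDataset:
    """Validated patient roster + claim list, with provenance metadata."""

    patients: pd.DataFrame
    claims: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def claims_for(self, patient_id: str) -> list[Claim]:
        """Claims of one patient as :class:`Claim` objects (scalar API)."""
        sub = self.claims[self.claims["patient_id"] == patient_id]
        return [
            Claim(r.patient_id, r.service_date.date(), r.setting, r.code)
            for r in sub.itertuples(index=False)
        ]

    def equals(self, other: "CohortDataset") -> bool:
        """Field-for-field equality of roster and claims (metadata ignored)."""
        a_p = self.patients.sort_values(list(PATIENT_COLUMNS)).reset_index(drop=True)
        b_p = other.patients.sort_values(list(PATIENT_COLUMNS)).reset_index(drop=True)
        a_c = self.claims.sort_values(list(CLAIM_COLUMNS)).reset_index(drop=True)
        b_c = other.claims.sort_values(list(CLAIM_COLUMNS)).reset_index(drop=True)
        return a_p.equals(b_p) and a_c.equals(b_c)


def first_of_month(date: dt.date) -> bool:
    return date.day == 1


def add_months(date: dt.date, months: int) -> dt.date:
    """Calendar-month offset; exact on first-of-month dates."""
    y, m = divmod(date.year * 12 + (date.month - 1) + months, 12)
    last = [31, 29 if y % 4 == 0 and (y % 100 != 0 or y % 400 == 0) else 28,
            31, 30, 31, 30, 31, 31, 30, 31, 30, 31][m]
    return dt.date(y, m + 1, min(date.day, last))


def _parse_dates(series: pd.Series, label: str, problems: list[str]) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    for idx in series.index[parsed.isna()]:
        problems.append(f"{label} row {idx + 2}: unparseable date {series[idx]!r}")
    return parsed


def _melt_wide_claims(table: pd.DataFrame) -> pd.DataFrame:
    """Accept the wide dialect with dx1..dxN columns; melt to one row per
    claim-diagnosis."""
    dx_cols = [c for c in table.columns if c.startswith("dx") and c[2:].isdigit()]
    keep = [c for c in ("patient_id", "service_date", "setting") if c in table.columns]
    long = table.melt(id_vars=keep, value_vars=dx_cols, value_name="code")
    long = long.drop(columns="variable").dropna(subset=["code"])
    long = long[long["code"].astype(str).str.strip() != ""]
    return long.reset_index(drop=True)


def read_cohort(patients_path: str | Path, claims_path: str | Path) -> CohortDataset:
    """Read and validate ``patients.csv`` + ``claims.csv``.

    Codes are normalized (dots removed, case folded), dialect settings
    mapped, and referential integrity enforced; every malformed row is
    reported with its file row number in a single
    :class:`CohortValidationError` — nothing is silently dropped.
    """
    patients = pd.read_csv(patients_path, dtype=str)
    claims = pd.read_csv(claims_path, dtype=str)

    problems: list[str] = []
    missing_p = set(PATIENT_COLUMNS) - set(patients.columns)
    if missing_p:
        raise CohortValidationError(
            [f"patients file missing columns: {sorted(missing_p)}"]
        )
    if "code" not in claims.columns and any(
        c.startswith("dx") for c in claims.columns
    ):
        claims = _melt_wide_claims(claims)
    missing_c = set(CLAIM_COLUMNS) - set(claims.columns)
    if missing_c:
        raise CohortValidationError([f"claims file missing columns: {sorted(missing_c)}"])

    n_patient_rows, n_claim_rows = len(patients), len(claims)

    patients = patients.copy()
    patients["eligibility_start"] = _parse_dates(
        patients["eligibility_start"], "patients", problems
    )
    patients["index_date"] = _parse_dates(patients["index_date"], "patients", problems)

    ok = patients["index_date"].notna() & patients["eligibility_start"].notna()
    for idx in patients.index[ok]:
        index_date = patients.at[idx, "index_date"].date()
        elig = patients.at[idx, "eligibility_start"].date()
        if not first_of_month(index_date):
            problems.append(
                f"patients row {idx + 2}: index_date {index_date.isoformat()} "
                "is not the first day of a month"
            )
        elif add_months(index_date, -REQUIRED_PRE_INDEX_MONTHS) < elig:
            problems.append(
                f"patients row {idx + 2}: fewer than {REQUIRED_PRE_INDEX_MONTHS} "
                "months of eligibility before index_date"
            )
    bad_cohort = ~patients["cohort"].isin(["indexed", "sham"])
    for idx in patients.index[bad_cohort]:
        problems.append(
            f"patients row {idx + 2}: unknown cohort {patients.at[idx, 'cohort']!r}"
        )
    dup = patients["patient_id"].duplicated()
    for idx in patients.index[dup]:
        problems.append(
            f"patients row {idx + 2}: duplicate patient_id "
            f"{patients.at[idx, 'patient_id']!r}"
        )

    claims = claims.copy()
    claims["service_date"] = _parse_dates(claims["service_date"], "claims", problems)
    claims["setting"] = claims["setting"].replace(SETTING_ALIASES)
    bad_setting = ~claims["setting"].isin(SETTINGS)
    for idx in claims.index[bad_setting]:
        problems.append(
            f"claims row {idx + 2}: unknown setting {claims.at[idx, 'setting']!r}"
        )

    codes = []
    for idx, raw in claims["code"].items():
        try:
            codes.append(normalize_code(raw))
        except CodebookError as exc:
            problems.append(f"claims row {idx + 2}: {exc}")
            codes.append(None)
    claims["code"] = codes

    roster = set(patients["patient_id"])
    orphan = ~claims["patient_id"].isin(roster)
    for idx in claims.index[orphan]:
        problems.append(
            f"claims row {idx + 2}: orphan claim for unknown patient "
            f"{claims.at[idx, 'patient_id']!r}"
        )

    if problems:
        raise CohortValidationError(problems)

    meta = {
        "patients_path": str(patients_path),
        "claims_path": str(claims_path),
        "n_patient_rows": n_patient_rows,
        "n_claim_rows": n_claim_rows,
    }
    return CohortDataset(
        patients=patients.reset_index(drop=True),
        claims=claims.reset_index(drop=True),
        meta=meta,
    )


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write ``patients.csv`` and ``claims.csv``; ISO dates, stable order.

    Round-trips: ``read_cohort(*write_cohort(d).values())`` equals ``d``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients = dataset.patients.copy()
    for col in ("eligibility_start", "index_date"):
        patients[col] = pd.to_datetime(patients[col]).dt.strftime("%Y-%m-%d")
    claims = dataset.claims.copy()
    claims["service_date"] = pd.to_datetime(claims["service_date"]).dt.strftime(
        "%Y-%m-%d"
    )
    patients_path = out / "patients.csv"
    claims_path = out / "claims.csv"
    patients[list(PATIENT_COLUMNS)].to_csv(patients_path, index=False)
    claims[list(CLAIM_COLUMNS)].to_csv(claims_path, index=False)
    return {"patients": patients_path, "claims": claims_path}
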