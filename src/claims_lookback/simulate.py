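"""Synthetic administrative-claims cohorts with known ground truth.

Real linked cancer-registry/Medicare claims are access-restricted, so this
module generates cohorts that emulate their structure: each patient has an
index date on the first day of a month (a diagnosis month, or a "sham" date
for the comparison cohort) preceded by 36 months of eligibility and followed
by a 3-month incidence period.  Per condition, a patient is prevalent at
baseline with probability ``prevalence``, or develops the condition during
the 39-month observation span under a constant ``onset_hazard`` (per month).
Once a condition is present, diagnosis claims arrive as independent Poisson
processes — ``inpatient_rate`` per month for inpatient stays and
``outpatient_rate`` per month for non-inpatient claims (split evenly between
outpatient-facility and physician settings) — with intensity multiplied by
``detection_bias`` inside the near-index bias window.  That multiplier
emulates the diagnostic-workup detection bias around a sentinel event such
as a cancer diagnosis; the "sham" style has no bias.

Simulation time runs in continuous index-relative months on ``[-36, 3)``
and is mapped to calendar days month-by-month, so an L-month lookback
window contains a ``Poisson(rate * L)`` claim count *exactly* and the
closed-form oracles below are exact:

* ``expected_miss_probability(lam, L) = exp(-lam * L)`` — the chance a
  prevalent, single-claim-detectable condition leaves no claim in an
  L-month window;
* ``expected_fpf_inpatient_poisson`` — the expected false positive fraction
  under inpatient-only detection, used for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .codebook import ConditionCodebook
from .cohort import CohortDataset

__all__ = [
    "ConditionParams",
    "SimulationConfig",
    "default_condition_params",
    "simulate",
    "expected_miss_probability",
    "expected_fpf_inpatient_poisson",
]

PREVALENCE_SPAN_MONTHS = 36
TRUTH_COLUMNS = ("patient_id", "condition", "status", "onset_date")


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition generator parameters.

    prevalence:
        Baseline probability the condition pre-dates the observation window.
    onset_hazard:
        Constant new-onset hazard per month during the 39-month span.
    inpatient_rate / outpatient_rate:
        Poisson claim intensities (claims per month) once the condition is
        present; outpatient claims split evenly between outpatient-facility
        and physician settings.
    detection_bias:
        Intensity multiplier (>= 1) inside the near-index bias window.
    """

    prevalence: float
    onset_hazard: float
    inpatient_rate: float
    outpatient_rate: float
    detection_bias: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        for name in ("onset_hazard", "inpatient_rate", "outpatient_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.detection_bias < 1.0:
            raise ValueError("detection_bias must be >= 1")


# Illustrative study conditions: baseline prevalences follow the published
# per-1,000 prevalence proportions of the 12 conditions; claim rates reflect
# how often each condition's diagnosis appears on claims (chronic conditions
# under regular management code more often than quiescent ones).
_BASE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    # condition: (prevalence, onset_hazard, inpatient_rate, outpatient_rate)
    "Cerebrovascular disease": (0.055, 0.002, 0.020, 0.12),
    "Congestive heart failure": (0.077, 0.002, 0.030, 0.15),
    "Chronic obstructive pulmonary disease": (0.066, 0.002, 0.020, 0.15),
    "Depression": (0.035, 0.002, 0.010, 0.12),
    "Diabetes": (0.091, 0.002, 0.010, 0.20),
    "Hip fracture": (0.017, 0.004, 0.030, 0.10),
    "Hypertension": (0.320, 0.004, 0.010, 0.30),
    "Liver disease": (0.003, 0.0005, 0.010, 0.10),
    "Myocardial infarction": (0.035, 0.002, 0.030, 0.10),
    "Osteoarthritis": (0.084, 0.003, 0.005, 0.15),
    "Osteoporosis": (0.041, 0.003, 0.005, 0.12),
    "Renal disease": (0.008, 0.0005, 0.020, 0.10),
}

INDEXED_DETECTION_BIAS = 3.0


def default_condition_params(cohort_style: str = "indexed") -> dict[str, ConditionParams]:
    """Default per-condition parameters for a cohort style.

    The ``indexed`` style carries a detection-bias multiplier of
    ``3.0`` (diagnostic workup around the index event); ``sham`` has none.
    """
    beta = INDEXED_DETECTION_BIAS if cohort_style == "indexed" else 1.0
    return {
        cond: ConditionParams(*vals, detection_bias=beta)
        for cond, vals in _BASE_PARAMS.items()
    }


@dataclass
class SimulationConfig:
    """Full description of one simulated cohort; identical configs (same
    seed included) produce identical datasets."""

    n_patients: int
    cohort_style: str = "indexed"
    seed: int = 0
    conditions: Optional[Mapping[str, ConditionParams]] = None
    bias_window_months: Optional[float] = None  # pre-index part of bias window
    incidence_months: int = 3
    index_years: tuple[int, int] = (2000, 2002)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.cohort_style not in ("indexed", "sham"):
            raise ValueError(f"cohort_style must be 'indexed' or 'sham', got {self.cohort_style!r}")
        if self.incidence_months <= 0:
            raise ValueError("incidence_months must be positive")
        if self.conditions is None:
            self.conditions = default_condition_params(self.cohort_style)
        else:
            self.conditions = dict(self.conditions)
            for cond, params in self.conditions.items():
                if not isinstance(params, ConditionParams):
                    raise ValueError(f"parameters for {cond!r} must be ConditionParams")
        if self.bias_window_months is None:
            self.bias_window_months = 3.0 if self.cohort_style == "indexed" else 0.0
        if self.bias_window_months < 0:
            raise ValueError("bias_window_months must be >= 0")
        if not (self.index_years[0] <= self.index_years[1]):
            raise ValueError("index_years must be an increasing (first, last) pair")

    # -- config file round-trip ---------------------------------------

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        defaults = data.pop("defaults", {})
        raw_conditions = data.pop("conditions", None)
        conditions = None
        if raw_conditions is not None:
            conditions = {}
            for cond, block in raw_conditions.items():
                merged = {**defaults, **(block or {})}
                conditions[cond] = ConditionParams(**merged)
        if "index_years" in data:
            data["index_years"] = tuple(data["index_years"])
        return cls(conditions=conditions, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "cohort_style": self.cohort_style,
            "seed": self.seed,
            "bias_window_months": self.bias_window_months,
            "incidence_months": self.incidence_months,
            "index_years": list(self.index_years),
            "conditions": {c: asdict(p) for c, p in self.conditions.items()},
        }


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def _months_to_dates(index_month: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Map continuous index-relative months to calendar days.

    The integer part selects the calendar month; the fraction selects the
    day within that month, so month boundaries map exactly to calendar-month
    boundaries.
    """
    whole = np.floor(m).astype("int64")
    frac = m - whole
    month = index_month + whole
    month_start = month.astype("datetime64[D]")
    days_in_month = ((month + 1).astype("datetime64[D]") - month_start).astype("int64")
    day = np.floor(frac * days_in_month).astype("int64")
    return month_start + day


def _segment_claims(
    rng: np.random.Generator,
    seg_start: np.ndarray,
    seg_end: np.ndarray,
    rate: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson claim times for per-patient segments of constant intensity.

    Returns (patient row indices, claim month-times)."""
    length = np.clip(seg_end - seg_start, 0.0, None)
    counts = rng.poisson(rate * length)
    rows = np.repeat(np.arange(len(length)), counts)
    u = rng.random(rows.size)
    times = np.repeat(seg_start, counts) + u * np.repeat(length, counts)
    return rows, times


def simulate(
    config: SimulationConfig, codebook: Optional[ConditionCodebook] = None
) -> tuple[CohortDataset, pd.DataFrame]:
    """Generate a cohort and its ground truth.

    Returns ``(dataset, truth)`` where ``truth`` has one row per patient x
    condition with ``status`` in {``prevalent``, ``incident``, ``absent``}
    and the true ``onset_date`` (the day before eligibility start for
    baseline-prevalent conditions; missing for ``absent``).
    """
    if codebook is None:
        codebook = ConditionCodebook.builtin()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    inc_m = float(config.incidence_months)
    span = float(PREVALENCE_SPAN_MONTHS)

    width = max(5, len(str(max(n, 1))))
    patient_ids = np.array([f"P{i:0{width}d}" for i in range(1, n + 1)])

    y0, y1 = config.index_years
    first = np.datetime64(f"{y0}-01", "M")
    n_months = (y1 - y0 + 1) * 12
    index_month = first + rng.integers(0, n_months, size=n)
    index_date = index_month.astype("datetime64[D]")
    elig_start = (index_month - PREVALENCE_SPAN_MONTHS).astype("datetime64[D]")

    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "cohort": config.cohort_style,
            "eligibility_start": pd.to_datetime(elig_start).astype("datetime64[ns]"),
            "index_date": pd.to_datetime(index_date).astype("datetime64[ns]"),
        }
    )

    claim_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    bias_start = -float(config.bias_window_months)

    for condition in sorted(config.conditions):
        params = config.conditions[condition]
        codes = np.array(codebook.sample_codes(condition))

        prevalent = rng.random(n) < params.prevalence
        # constant-hazard onset during the observation span for the rest
        if params.onset_hazard > 0:
            wait = rng.exponential(1.0 / params.onset_hazard, size=n)
        else:
            wait = np.full(n, np.inf)
        onset_m = np.where(prevalent, -np.inf, -span + wait)
        active = onset_m < inc_m  # condition ever present during observation

        status = np.full(n, "absent", dtype=object)
        status[(onset_m < 0)] = "prevalent"
        status[(onset_m >= 0) & (onset_m < inc_m)] = "incident"

        onset_date = np.full(n, np.datetime64("NaT", "D"))
        in_span = np.isfinite(onset_m) & active
        if in_span.any():
            onset_date[in_span] = _months_to_dates(
                index_month[in_span], onset_m[in_span]
            )
        onset_date[prevalent] = elig_start[prevalent] - 1
        truth_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids,
                    "condition": condition,
                    "status": status,
                    "onset_date": pd.to_datetime(onset_date).astype("datetime64[ns]"),
                }
            )
        )

        idx = np.flatnonzero(active)
        if idx.size == 0:
            continue
        a = np.clip(onset_m[idx], -span, None)  # active interval [a, inc_m)
        mid = np.maximum(a, bias_start)  # bias window [-bw, inc_m)
        for setting_rate, is_inpatient in (
            (params.inpatient_rate, True),
            (params.outpatient_rate, False),
        ):
            if setting_rate == 0:
                continue
            base = np.full(idx.size, setting_rate)
            rows1, t1 = _segment_claims(rng, a, mid, base)
            rows2, t2 = _segment_claims(rng, mid, np.full(idx.size, inc_m),
                                        base * params.detection_bias)
            rows = np.concatenate([rows1, rows2])
            times = np.concatenate([t1, t2])
            if rows.size == 0:
                continue
            pat_rows = idx[rows]
            dates = _months_to_dates(index_month[pat_rows], times)
            if is_inpatient:
                settings = np.full(rows.size, "inpatient", dtype=object)
            else:
                settings = np.where(
                    rng.random(rows.size) < 0.5, "outpatient_facility", "physician"
                )
            claim_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": patient_ids[pat_rows],
                        "service_date": pd.to_datetime(dates).astype("datetime64[ns]"),
                        "setting": settings,
                        "code": rng.choice(codes, size=rows.size),
                    }
                )
            )

    if claim_frames:
        claims = pd.concat(claim_frames, ignore_index=True)
        claims = claims.sort_values(
            ["patient_id", "service_date", "setting", "code"]
        ).reset_index(drop=True)
    else:
        claims = pd.DataFrame(columns=["patient_id", "service_date", "setting", "code"])
        claims["service_date"] = pd.to_datetime(claims["service_date"])

    if truth_frames:
        truth = pd.concat(truth_frames, ignore_index=True)
        truth = truth.sort_values(["patient_id", "condition"]).reset_index(drop=True)
    else:
        truth = pd.DataFrame(columns=list(TRUTH_COLUMNS))

    meta = {
        "source": "simulate",
        "seed": config.seed,
        "config": config.to_dict(),
    }
    dataset = CohortDataset(patients=patients, claims=claims, meta=meta)
    return dataset, truth


# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------


def expected_miss_probability(lambda_total: float, L: float) -> float:
    """P(no claim in an L-month window) for a Poisson(lambda) claim process:
    ``exp(-lambda * L)``."""
    if lambda_total < 0:
        raise ValueError("lambda_total must be >= 0")
    if L <= 0:
        raise ValueError("L must be > 0")
    return math.exp(-lambda_total * L)


def expected_fpf_inpatient_poisson(
    lam: float, L: float, beta: float, incidence_months: float, gold_L: float
) -> float:
    """Expected false positive fraction under the simplest claim model.

    Assumes every patient is prevalent (baseline prevalence 1, no new
    onsets), inpatient-only detection (single-claim rule) with Poisson
    intensity ``lam`` per month, multiplied by ``beta`` inside the incidence
    window only.  A false positive at lookback L is a patient with a claim
    in the incidence window, none in the last L months, and at least one in
    the gold-standard window; dividing by the gold-standard detected-
    prevalent count gives

        FPF(L) = (1 - exp(-beta*lam*inc)) * (exp(-lam*L) - exp(-lam*gold_L))
                 / (1 - exp(-lam*gold_L))
    """
    if lam <= 0:
        raise ValueError("lam must be > 0 (FPF undefined at lam=0)")
    if not 0 < L <= gold_L:
        raise ValueError("need 0 < L <= gold_L")
    if incidence_months <= 0:
        raise ValueError("incidence_months must be > 0")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    p_inc = 1.0 - math.exp(-beta * lam * incidence_months)
    return (
        p_inc
        * (math.exp(-lam * L) - math.exp(-lam * gold_L))
        / (1.0 - math.exp(-lam * gold_L))
    )
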