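"""Condition detection within a date window, per patient.

Two claim-based rules, applied to the claims of one patient that fall inside
a half-open date interval and carry a code matching the condition:

* **Rule A (inpatient):** a single inpatient claim identifies the condition,
  counted at its first occurrence.
* **Rule B (outpatient pair):** outpatient-facility and physician claims are
  pooled, and two such claims at least 30 days apart identify the condition,
  with the first occurrence taken as the onset date.  "At least 30 days" is
  inclusive: a pair exactly 30 days apart qualifies.

The overall onset is the earlier of the two rules' candidate onsets
(inpatient wins ties).  Intervals are half-open ``[start, end)``: a claim
dated exactly on the index date belongs to the incidence period, since
index dates are first-of-month and diagnosis-day workup claims are
post-index.  Presence is evaluated *independently* per window — a 30-day
pair straddling the index date qualifies in neither window.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional

from .codebook import ConditionCodebook
from .cohort import Claim

__all__ = ["Interval", "DetectionResult", "detect", "presence_profile"]

MIN_PAIR_GAP_DAYS = 30


@dataclass(frozen=True)
class Interval:
    """Half-open calendar-date interval ``[start, end)``."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")

    def __contains__(self, date: dt.date) -> bool:
        return self.start <= date < self.end


@dataclass(frozen=True)
class DetectionResult:
    present: bool
    onset_date: Optional[dt.date] = None
    basis: Optional[str] = None  # "inpatient_single" | "outpatient_pair"

    def __post_init__(self) -> None:
        if self.present != (self.onset_date is not None):
            raise ValueError("onset_date must be present iff the condition is")


def _pair_onset(dates: list[dt.date]) -> Optional[dt.date]:
    """Earliest date participating in a >=30-day pair, or None.

    Equivalent to: the earliest date, when latest - earliest >= 30 days."""
    if len(dates) < 2:
        return None
    lo, hi = min(dates), max(dates)
    if (hi - lo).days >= MIN_PAIR_GAP_DAYS:
        return lo
    return None


def detect(
    claims: Iterable[Claim],
    condition: str,
    codebook: ConditionCodebook,
    window: Interval,
    *,
    pair_pooling: str = "pooled",
    mixed_rule: bool = False,
) -> DetectionResult:
    """Apply the detection rules to one patient's claims within ``window``.

    Parameters
    ----------
    pair_pooling:
        ``"pooled"`` (default) lets a qualifying pair mix outpatient-facility
        and physician claims; ``"per_setting"`` requires both members of a
        pair to share a setting (sensitivity-analysis switch).
    mixed_rule:
        If True, an inpatient claim may also serve as one member of a
        30-day pair (off by default; the two rules are independent).
    """
    if pair_pooling not in ("pooled", "per_setting"):
        raise ValueError(f"pair_pooling must be 'pooled' or 'per_setting', got {pair_pooling!r}")

    matching = [
        c
        for c in claims
        if c.service_date in window and codebook.matches(c.code, condition)
    ]
    inpatient = sorted(c.service_date for c in matching if c.setting == "inpatient")
    outpatient = [c for c in matching if c.setting != "inpatient"]

    candidates: list[tuple[dt.date, str]] = []
    if inpatient:
        candidates.append((inpatient[0], "inpatient_single"))

    if pair_pooling == "pooled":
        pools = [[c.service_date for c in outpatient]]
    else:
        pools = [
            [c.service_date for c in outpatient if c.setting == setting]
            for setting in ("outpatient_facility", "physician")
        ]
    if mixed_rule:
        pools = [pool + inpatient for pool in pools]
    for pool in pools:
        onset = _pair_onset(pool)
        if onset is not None:
            candidates.append((onset, "outpatient_pair"))

    if not candidates:
        return DetectionResult(present=False)
    # min date wins; inpatient wins ties ("inpatient_single" < "outpatient_pair")
    onset, basis = min(candidates)
    return DetectionResult(present=True, onset_date=onset, basis=basis)


def presence_profile(
    claims: Iterable[Claim],
    condition: str,
    codebook: ConditionCodebook,
    prevalence_window: Interval,
    incidence_window: Interval,
    **switches,
) -> tuple[bool, bool]:
    """Presence flags in the prevalence and incidence windows, evaluated
    independently (claims outside a window are invisible to it).

    The windows must abut at the index date.
    """
    if prevalence_window.end != incidence_window.start:
        raise ValueError(
            "prevalence and incidence windows must abut: "
            f"{prevalence_window.end} != {incidence_window.start}"
        )
    claims = list(claims)
    pre = detect(claims, condition, codebook, prevalence_window, **switches)
    post = detect(claims, condition, codebook, incidence_window, **switches)
    return pre.present, post.present
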