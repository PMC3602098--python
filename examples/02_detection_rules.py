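"""Apply the claims-based detection rules to one patient's claims.

A condition is present in a window if it has one inpatient claim (counted at
first occurrence) or two non-inpatient claims at least 30 days apart (onset
at the first).  Windows are half-open and evaluated independently, so a
pair straddling the index date counts in neither period."""

import datetime as dt

from claims_lookback import Claim, ConditionCodebook, Interval, detect, presence_profile

codebook = ConditionCodebook.builtin()
index = dt.date(2001, 7, 1)
prev = Interval(dt.date(1998, 7, 1), index)  # 36-month prevalence period
inc = Interval(index, dt.date(2001, 10, 1))  # 3-month incidence period


def claim(date, setting, code="25000"):
    return Claim("p1", date, setting, code)


cases = {
    "single inpatient claim": [claim(dt.date(2001, 7, 15), "inpatient")],
    "physician pair 15 days apart": [
        claim(dt.date(2001, 7, 2), "physician"),
        claim(dt.date(2001, 7, 17), "physician"),
    ],
    "physician pair exactly 30 days apart": [
        claim(dt.date(2001, 7, 2), "physician"),
        claim(dt.date(2001, 8, 1), "physician"),
    ],
}
for label, claims in cases.items():
    res = detect(claims, "Diabetes", codebook, inc)
    print(f"{label:<40} present={res.present!s:<5} onset={res.onset_date} basis={res.basis}")

straddle = [
    claim(dt.date(2001, 6, 11), "physician"),
    claim(dt.date(2001, 7, 21), "physician"),
]
profile = presence_profile(straddle, "Diabetes", codebook, prev, inc)
print(f"\npair straddling the index date -> (prevalence, incidence) = {profile}")
print(
    "\nThe 30-day rule is inclusive (exactly 30 days qualifies), and because\n"
    "each period is searched independently, the straddling pair identifies\n"
    "the condition in neither period."
)
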