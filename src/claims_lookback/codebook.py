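"""ICD-9-CM condition code lists and diagnosis-code matching.

Administrative claims identify chronic conditions through lists of ICD-9-CM
diagnosis codes written in the conventional epidemiology shorthand: plain
codes (``496``), wildcarded codes (``250.xx``, ``296.2x``) and ranges
(``430-437.1``, ``401.xx-405.xx``).  This module parses that shorthand into
:class:`CodePattern` objects, holds the fixed 12-condition roster as a
:class:`ConditionCodebook`, and decides whether a (normalized) diagnosis code
matches a condition.

Matching semantics
------------------
Codes are compared dotless and case-folded.  The ICD-9-CM decimal hierarchy
is honoured by *prefix* semantics: a plain code such as ``496`` also matches
any more-specific descendant (``4961``) because claims carry variable coding
specificity, and a wildcard is a position-dropper (``296.2x`` is the prefix
``2962``), never a single-character matcher.  A range ``A-B`` matches a code
when its decimal-family value lies in ``[A, B]`` inclusive, where the upper
bound covers all of its own descendants (``437.1`` covers ``4371``,
``43710`` ... ``43719``).  V and E codes order within their own letter family
only; ranges never span families.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CodePattern",
    "ConditionCodebook",
    "CodebookError",
    "normalize_code",
    "parse_pattern",
    "code_matches",
    "CONDITIONS",
]

#: Fixed roster, in the order the condition table prints them.
CONDITIONS: tuple[str, ...] = (
    "Cerebrovascular disease",
    "Congestive heart failure",
    "Chronic obstructive pulmonary disease",
    "Depression",
    "Diabetes",
    "Hip fracture",
    "Hypertension",
    "Liver disease",
    "Myocardial infarction",
    "Osteoarthritis",
    "Osteoporosis",
    "Renal disease",
)

_CODE_RE = re.compile(r"^(?:[ve])?\d{2,5}$")
_RAW_RE = re.compile(r"^[VvEe]?\d{1,5}(?:\.\d{0,4})?$")


class CodebookError(ValueError):
    """Malformed code, pattern, or codebook input."""


def normalize_code(raw_code: str) -> str:
    """Normalize an ICD-9-CM diagnosis code to dotless, case-folded form.

    ``"250.00" -> "25000"``, ``"V42.7" -> "v427"``.  Idempotent.  Raises
    :class:`CodebookError` for text that does not have ICD-9-CM lexical
    shape (3-5 significant characters, optional leading V/E, optional dot).
    """
    text = str(raw_code).strip()
    if not text:
        raise CodebookError("empty diagnosis code")
    if not _RAW_RE.match(text):
        raise CodebookError(f"malformed ICD-9-CM code: {raw_code!r}")
    code = text.replace(".", "").lower()
    if not _CODE_RE.match(code) or not 3 <= len(code) <= 5:
        raise CodebookError(f"malformed ICD-9-CM code: {raw_code!r}")
    return code


def _strip_wildcards(stem: str) -> str:
    # wildcards are position-droppers: "250xx" -> "250"
    return stem.rstrip("x")


def _normalize_bound(raw: str) -> str:
    text = raw.strip().replace(".", "").lower()
    stem = _strip_wildcards(text)
    if not _CODE_RE.match(stem):
        raise CodebookError(f"malformed pattern bound: {raw!r}")
    return stem


def _family(code: str) -> str:
    return code[0] if code[0] in "ve" else ""


def _digits(code: str) -> str:
    return code.lstrip("ve")


def _key(code: str, pad: str) -> str:
    """5-wide comparison key for the digit part of a normalized code."""
    return _digits(code).ljust(5, pad)


@dataclass(frozen=True)
class CodePattern:
    """One parsed entry of a condition's code list.

    ``kind`` is ``"exact"`` (a plain printed code; still matches its
    descendants), ``"prefix"`` (wildcarded) or ``"range"``.  ``stem`` holds
    the normalized code stem for exact/prefix; ``lower``/``upper`` the
    normalized bounds for ranges.
    """

    kind: str
    stem: str = ""
    lower: str = ""
    upper: str = ""

    def __post_init__(self) -> None:
        if self.kind in ("exact", "prefix"):
            if not _CODE_RE.match(self.stem):
                raise CodebookError(f"invalid pattern stem: {self.stem!r}")
        elif self.kind == "range":
            if not (_CODE_RE.match(self.lower) and _CODE_RE.match(self.upper)):
                raise CodebookError(f"invalid range bounds: {self.lower!r}-{self.upper!r}")
            if _family(self.lower) != _family(self.upper):
                raise CodebookError(
                    f"range spans letter families: {self.lower!r}-{self.upper!r}"
                )
            if _key(self.lower, "0") > _key(self.upper, "9"):
                raise CodebookError(f"empty range: {self.lower!r}-{self.upper!r}")
        else:
            raise CodebookError(f"unknown pattern kind: {self.kind!r}")

    def matches(self, code: str) -> bool:
        """Whether a normalized code falls under this pattern."""
        if self.kind in ("exact", "prefix"):
            return code.startswith(self.stem)
        if _family(code) != _family(self.lower):
            return False
        key = _key(code, "0")
        return _key(self.lower, "0") <= key <= _key(self.upper, "9")


def parse_pattern(raw_pattern: str) -> CodePattern:
    """Parse one code-list entry into a :class:`CodePattern`.

    Accepts plain codes (``"496"``), trailing-wildcard codes (``"250.xx"``),
    and ranges whose ends may carry wildcards (``"401.xx-405.xx"``).
    """
    text = str(raw_pattern).strip()
    if not text:
        raise CodebookError("empty code pattern")
    if "-" in text:
        parts = text.split("-")
        if len(parts) != 2:
            raise CodebookError(f"unparseable range pattern: {raw_pattern!r}")
        return CodePattern(
            kind="range",
            lower=_normalize_bound(parts[0]),
            upper=_normalize_bound(parts[1]),
        )
    flat = text.replace(".", "").lower()
    stem = _strip_wildcards(flat)
    if not _CODE_RE.match(stem):
        raise CodebookError(f"unparseable code pattern: {raw_pattern!r}")
    kind = "prefix" if stem != flat else "exact"
    return CodePattern(kind=kind, stem=stem)


class ConditionCodebook:
    """Mapping condition name -> list of :class:`CodePattern`.

    The default (:meth:`builtin`) codebook carries the fixed roster of 12
    chronic and acute conditions common in older adults, each with its
    published ICD-9-CM code list.
    """

    def __init__(self, patterns: Mapping[str, Iterable[CodePattern]]):
        self._patterns: dict[str, tuple[CodePattern, ...]] = {
            cond: tuple(pats) for cond, pats in patterns.items()
        }
        for cond, pats in self._patterns.items():
            if not pats:
                raise CodebookError(f"condition {cond!r} has an empty pattern list")

    # -- constructors -------------------------------------------------

    @classmethod
    def builtin(cls) -> "ConditionCodebook":
        """The packaged 12-condition codebook."""
        with resources.as_file(
            resources.files("claims_lookback") / "data" / "condition_codes.csv"
        ) as path:
            book = cls.from_csv(path)
        missing = set(CONDITIONS) - set(book.conditions)
        if missing:  # pragma: no cover - fixture integrity
            raise CodebookError(f"builtin codebook missing conditions: {sorted(missing)}")
        return book

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConditionCodebook":
        """Read a delimited table with columns ``condition,pattern``."""
        table = pd.read_csv(path, dtype=str)
        required = {"condition", "pattern"}
        if not required.issubset(table.columns):
            raise CodebookError(
                f"codebook file {path} must have columns {sorted(required)}"
            )
        mapping: dict[str, list[CodePattern]] = {}
        for row in table.itertuples(index=False):
            mapping.setdefault(row.condition, []).append(parse_pattern(row.pattern))
        return cls(mapping)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "ConditionCodebook":
        """Build from ``{condition: [pattern text, ...]}``."""
        return cls(
            {cond: [parse_pattern(p) for p in pats] for cond, pats in mapping.items()}
        )

    # -- queries ------------------------------------------------------

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self._patterns)

    def patterns(self, condition: str) -> tuple[CodePattern, ...]:
        try:
            return self._patterns[condition]
        except KeyError:
            raise CodebookError(f"unknown condition: {condition!r}") from None

    def matches(self, code: str, condition: str) -> bool:
        return any(p.matches(code) for p in self.patterns(condition))

    def conditions_matching(self, code: str) -> tuple[str, ...]:
        """All conditions whose code list covers ``code`` (may be several:
        e.g. ``4030`` is both hypertensive and renal disease)."""
        return tuple(c for c in self._patterns if self.matches(code, c))

    def match_table(self, codes: Iterable[str]) -> pd.DataFrame:
        """Map distinct normalized codes to conditions (columns
        ``code,condition``), for vectorized joins against claim tables."""
        rows = [
            (code, cond)
            for code in dict.fromkeys(codes)
            for cond in self.conditions_matching(code)
        ]
        return pd.DataFrame(rows, columns=["code", "condition"], dtype=str)

    def sample_codes(self, condition: str) -> tuple[str, ...]:
        """A deterministic set of concrete member codes per condition,
        used by the claims simulator to stamp diagnosis codes."""
        out: list[str] = []
        for pat in self.patterns(condition):
            if pat.kind in ("exact", "prefix"):
                candidates = [pat.stem, (pat.stem + "00")[:5]]
            else:
                candidates = [pat.lower, (pat.lower + "00")[:5], pat.upper]
            for cand in candidates:
                if 3 <= len(cand) <= 5 and pat.matches(cand):
                    out.append(cand)
        return tuple(dict.fromkeys(out))


def code_matches(code: str, condition: str, codebook: ConditionCodebook) -> bool:
    """True iff the normalized ``code`` matches at least one pattern of
    ``condition`` in ``codebook``."""
    return codebook.matches(code, condition)
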