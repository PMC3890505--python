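"""Roster input and exclusion filtering.

Reads teacher-completed pupil rosters (CSV), derives ages, and applies the
study's exclusion rules with a complete audit trail.  Exclusion reasons are
applied in a fixed precedence so each excluded pupil is counted exactly once:

1. parental opt-out;
2. in class for less than one month (or time-in-class unrecorded);
3. special needs;
4. heavy missingness — at least 30% of the scored items unanswered, or more
   than one domain with no answered item at all.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from datetime import date, datetime

from .instrument import DOMAINS, InstrumentRegistry

__all__ = [
    "PupilRecord",
    "ParsedRoster",
    "ExclusionPolicy",
    "ExclusionLog",
    "RosterFormatError",
    "MANDATORY_COLUMNS",
    "INDICATOR_COLUMNS",
    "read_roster",
    "compute_age",
    "apply_exclusions",
]

INDICATOR_COLUMNS = (
    "struggles_with_schoolwork",
    "needs_assessment",
    "on_waiting_list",
    "receiving_supports",
)

MANDATORY_COLUMNS = (
    "pupil_id",
    "gender",
    "date_of_birth",
    "assessment_date",
    "months_in_class",
    "simd_quintile",
    "first_language_ok",
    "esl",
    "special_needs",
    "opted_out",
) + INDICATOR_COLUMNS

#: Tokens treated as missing wherever they appear.
MISSING_TOKENS = {"", "dk", "don't know", "dont know", "na", "n/a"}

_TRUE_TOKENS = {"1", "y", "yes", "true"}
_FALSE_TOKENS = {"0", "n", "no", "false"}


class RosterFormatError(ValueError):
    """Raised when a roster file violates the CSV contract."""


class AgeError(ValueError):
    """Raised when assessment precedes birth."""


@dataclass
class PupilRecord:
    """One pupil's raw responses plus demographic/administrative metadata."""

    pupil_id: str
    gender: str  # "male" | "female" | "unrecorded"
    date_of_birth: date | None
    assessment_date: date | None
    months_in_class: float | None
    simd_quintile: int | None
    first_language_ok: bool | None
    esl: bool | None
    special_needs: bool
    opted_out: bool
    indicators: dict = field(default_factory=dict)
    responses: dict = field(default_factory=dict)  # item_id -> raw token

    @property
    def age_years(self) -> float:
        return compute_age(self)


@dataclass
class ParsedRoster:
    records: list
    issues: list

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


@dataclass
class ExclusionPolicy:
    """Thresholds governing who enters the analysed cohort."""

    min_months_in_class: float = 1.0
    max_missing_fraction: float = 0.30  # exclude at >= this fraction missing
    max_fully_missing_domains: int = 1  # exclude if MORE than this many


EXCLUSION_CATEGORIES = (
    "excluded_optout",
    "excluded_short_enrolment",
    "excluded_special_needs",
    "excluded_missingness",
)


@dataclass
class ExclusionLog:
    """Per-pupil inclusion decision plus category counts."""

    decisions: dict  # pupil_id -> "included" | excluded_* category
    roster_n: int

    @property
    def counts(self) -> dict:
        out = {c: 0 for c in ("included",) + EXCLUSION_CATEGORIES}
        for d in self.decisions.values():
            out[d] += 1
        return out

    @property
    def analysed_n(self) -> int:
        return self.counts["included"]

    @property
    def excluded_n(self) -> int:
        return self.roster_n - self.analysed_n

    def to_json(self) -> str:
        return json.dumps(
            {"roster_n": self.roster_n, "analysed_n": self.analysed_n,
             "counts": self.counts},
            indent=2, sort_keys=True,
        )

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["pupil_id", "decision"])
        for pid, d in self.decisions.items():
            w.writerow([pid, d])
        return buf.getvalue()


def _parse_date(tok: str):
    if tok is None or tok.strip().lower() in MISSING_TOKENS:
        return None
    return datetime.strptime(tok.strip(), "%Y-%m-%d").date()


def _parse_flag(tok, default=None):
    if tok is None:
        return default
    t = str(tok).strip().lower()
    if t in MISSING_TOKENS:
        return default
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    return default


def _parse_gender(tok: str) -> str:
    t = (tok or "").strip().lower()
    if t in {"m", "male", "boy"}:
        return "male"
    if t in {"f", "female", "girl"}:
        return "female"
    return "unrecorded"


def read_roster(source, reg: InstrumentRegistry) -> ParsedRoster:
    """Parse a roster CSV against the instrument registry.

    ``source`` may be CSV text, a file-like object, or a path.  Item columns
    are matched by canonical ``item_id``; unknown response tokens are stored
    as missing and logged as parse issues rather than rejected, so a single
    mistyped cell never drops a pupil.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" not in source and source.endswith(".csv"):
        with open(source, newline="") as fh:
            text = fh.read()
    else:
        text = source

    reader = csv.DictReader(io.StringIO(text))
    header = reader.fieldnames or []
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in header]
    if missing_cols:
        raise RosterFormatError(
            "roster is missing mandatory columns: " + ", ".join(missing_cols)
        )

    from .scoring import valid_tokens  # local import to avoid a cycle

    item_cols = [c for c in header if c in reg]
    records: list[PupilRecord] = []
    issues: list[str] = []
    for rownum, row in enumerate(reader, start=2):
        pid = (row.get("pupil_id") or "").strip()
        if not pid:
            issues.append(f"row {rownum}: empty pupil_id")
            pid = f"row{rownum}"
        try:
            dob = _parse_date(row.get("date_of_birth"))
            adate = _parse_date(row.get("assessment_date"))
        except ValueError:
            issues.append(f"{pid}: unparseable date")
            dob = adate = None

        months_tok = (row.get("months_in_class") or "").strip().lower()
        months = None
        if months_tok not in MISSING_TOKENS:
            try:
                months = float(months_tok)
            except ValueError:
                issues.append(f"{pid}: bad months_in_class {months_tok!r}")
        quint_tok = (row.get("simd_quintile") or "").strip().lower()
        quintile = None
        if quint_tok not in MISSING_TOKENS:
            try:
                quintile = int(quint_tok)
            except ValueError:
                quintile = None
            if quintile is not None and not 1 <= quintile <= 5:
                issues.append(f"{pid}: simd_quintile {quint_tok!r} outside 1-5")
                quintile = None

        responses: dict[str, str] = {}
        for col in item_cols:
            tok = (row.get(col) or "").strip()
            if tok.lower() in MISSING_TOKENS:
                continue
            item = reg[col]
            if item.scored and tok.lower() not in valid_tokens(item):
                issues.append(f"{pid}: unknown token {tok!r} for item {col}")
                continue
            responses[col] = tok

        rec = PupilRecord(
            pupil_id=pid,
            gender=_parse_gender(row.get("gender")),
            date_of_birth=dob,
            assessment_date=adate,
            months_in_class=months,
            simd_quintile=quintile,
            first_language_ok=_parse_flag(row.get("first_language_ok")),
            esl=_parse_flag(row.get("esl")),
            special_needs=bool(_parse_flag(row.get("special_needs"), False)),
            opted_out=bool(_parse_flag(row.get("opted_out"), False)),
            indicators={c: _parse_flag(row.get(c), False) for c in INDICATOR_COLUMNS},
            responses=responses,
        )
        if dob is not None and adate is not None:
            if adate < dob:
                issues.append(f"{pid}: assessed before birth")
            else:
                age = compute_age(rec)
                if not 3.5 <= age < 8.5:
                    issues.append(f"{pid}: age {age:.2f} outside [3.5, 8.5)")
        records.append(rec)
    return ParsedRoster(records, issues)


def compute_age(rec: PupilRecord) -> float:
    """Decimal age at assessment on a 365.25-day year."""
    if rec.date_of_birth is None or rec.assessment_date is None:
        raise AgeError(f"{rec.pupil_id}: both dates required")
    days = (rec.assessment_date - rec.date_of_birth).days
    if days < 0:
        raise AgeError(f"{rec.pupil_id}: assessment precedes birth")
    return days / 365.25


def _missingness(rec: PupilRecord, reg: InstrumentRegistry):
    """(fraction of scored items missing, number of fully missing domains)."""
    scored = reg.scored_items
    answered_by_domain = {d: 0 for d in DOMAINS}
    n_answered = 0
    for it in scored:
        if rec.responses.get(it.item_id) is not None:
            answered_by_domain[it.domain] += 1
            n_answered += 1
    frac_missing = 1.0 - n_answered / len(scored)
    fully_missing = sum(1 for d in DOMAINS if answered_by_domain[d] == 0)
    return frac_missing, fully_missing


def apply_exclusions(
    roster,
    reg: InstrumentRegistry,
    policy: ExclusionPolicy | None = None,
):
    """Filter a roster into the analysed cohort.

    Returns ``(analysed_records, ExclusionLog)``.  Each excluded pupil is
    assigned the first matching category in precedence order; the log always
    conserves the roster (included + excluded = input size).  An empty
    analysed cohort is legal.
    """
    policy = policy or ExclusionPolicy()
    records = list(roster)
    decisions: dict[str, str] = {}
    analysed: list[PupilRecord] = []
    for rec in records:
        if rec.opted_out:
            decisions[rec.pupil_id] = "excluded_optout"
            continue
        if rec.months_in_class is None or (
            rec.months_in_class < policy.min_months_in_class
        ):
            decisions[rec.pupil_id] = "excluded_short_enrolment"
            continue
        if rec.special_needs:
            decisions[rec.pupil_id] = "excluded_special_needs"
            continue
        frac_missing, fully_missing = _missingness(rec, reg)
        # guard against float drift at the exact 30% boundary
        if (
            frac_missing >= policy.max_missing_fraction - 1e-12
            or fully_missing > policy.max_fully_missing_domains
        ):
            decisions[rec.pupil_id] = "excluded_missingness"
            continue
        decisions[rec.pupil_id] = "included"
        analysed.append(rec)
    return analysed, ExclusionLog(decisions, roster_n=len(records))
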