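"""Reading, linking and filtering FAERS quarterly extract files.

FAERS (the FDA Adverse Event Reporting System) distributes each quarter as a
set of "$"-delimited ASCII tables: DEMO (one row per report version), DRUG,
REAC, OUTC, INDI and THER, all keyed by ``primaryid``.  This module parses the
post-2012Q4 schema (``primaryid`` / ``caseid`` / ``caseversion``), links the
tables into :class:`CaseReport` objects, collapses follow-up versions of the
same case, and filters to reports naming a target drug as primary suspect.

The legacy LAERS (ISR-keyed, pre-2012Q4) layout is not supported.
"""

from __future__ import annotations

import csv
import datetime as _dt
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, SchemaError

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: FAERS ``occp_cod`` values -> reporter-occupation categories.
OCCUPATION_MAP = {
    "CN": "CONSUMER",
    "MD": "PHYSICIAN",
    "PH": "PHARMACIST",
    "OT": "OTHER_HEALTH_PROFESSIONAL",
    "RN": "REGISTERED_NURSE",
    "LW": "LAWYER",
}

_ROUTE_MAP = {
    "SUBCUTANEOUS": "SUBCUTANEOUS",
    "ORAL": "ORAL",
    "INTRAMUSCULAR": "INTRAMUSCULAR",
    "INTRAVENOUS": "INTRAVENOUS",
    "INTRAVENOUS (NOT OTHERWISE SPECIFIED)": "INTRAVENOUS",
    "INTRAVENOUS DRIP": "INTRAVENOUS",
}

#: FAERS age unit codes -> factor converting the raw value to years.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

TABLE_NAMES = ("demo", "drug", "reac", "outc", "indi", "ther")

_REQUIRED_COLUMNS = {
    "demo": ("primaryid", "caseid", "caseversion"),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "indi": ("primaryid", "indi_pt"),
    "ther": ("primaryid", "dsg_drug_seq", "start_dt"),
}


@dataclass(frozen=True, order=True)
class FaersDate:
    """A possibly partial FAERS date (YYYYMMDD, YYYYMM or YYYY numeric form).

    Partial dates keep year-month or year precision and are flagged imprecise;
    imprecise dates cannot be used for time-to-onset arithmetic.
    """

    year: int
    month: int = 0
    day: int = 0

    @property
    def precision(self) -> str:
        if self.day:
            return "day"
        if self.month:
            return "month"
        return "year"

    @property
    def is_precise(self) -> bool:
        return self.precision == "day"

    def to_date(self) -> _dt.date | None:
        """The exact calendar date, or None when the date is imprecise."""
        if not self.is_precise:
            return None
        return _dt.date(self.year, self.month, self.day)

    @classmethod
    def parse(cls, raw: str | None) -> "FaersDate | None":
        if raw is None:
            return None
        raw = raw.strip()
        if not raw or not raw.isdigit():
            return None
        try:
            if len(raw) == 8:
                d = _dt.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
                return cls(d.year, d.month, d.day)
            if len(raw) == 6:
                y, m = int(raw[:4]), int(raw[4:6])
                if 1 <= m <= 12:
                    return cls(y, m)
                return None
            if len(raw) == 4:
                return cls(int(raw))
        except ValueError:
            return None
        return None


@dataclass(frozen=True)
class DrugEntry:
    """One DRUG row: a medicine named on a report, with its suspect role."""

    drug_name: str
    active_ingredient: str | None = None
    role: str = "C"  # PS / SS / C / I
    route: str = "UNK"
    therapy_start_date: FaersDate | None = None


@dataclass(frozen=True)
class CaseReport:
    """One linked, per-version FAERS safety report."""

    primaryid: str
    caseid: str
    caseversion: int
    sex: str = "UNK"  # F / M / UNK
    age_years: float | None = None
    age_code_raw: str = ""
    weight_kg: float | None = None
    country: str | None = None
    reporter_occupation: str = "UNK"
    event_date: FaersDate | None = None
    receipt_date: FaersDate | None = None
    drugs: tuple[DrugEntry, ...] = ()
    reactions: tuple[str, ...] = ()
    outcomes: tuple[str, ...] = ()
    indications: tuple[str, ...] = ()


@dataclass
class ParseIssues:
    """Counted (never silently dropped) anomalies seen while parsing."""

    counts: Counter = field(default_factory=Counter)
    messages: list[str] = field(default_factory=list)

    def record(self, kind: str, message: str | None = None) -> None:
        self.counts[kind] += 1
        if message is not None and len(self.messages) < 1000:
            self.messages.append(f"{kind}: {message}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_text(self) -> str:
        lines = [f"{k}\t{v}" for k, v in sorted(self.counts.items())]
        return "\n".join(lines + self.messages)


@dataclass
class RawQuarter:
    """The six parsed tables of one FAERS quarter, columns lower-cased."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    ther: pd.DataFrame
    quarter_label: str = ""
    issues: ParseIssues = field(default_factory=ParseIssues)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def _read_dollar_table(path: Path, required: Sequence[str], issues: ParseIssues) -> pd.DataFrame:
    """Parse one $-delimited FAERS table.

    Rows with a deviating field count are counted as parse issues and
    excluded; they are never silently dropped without record.
    """
    with open(path, "r", encoding="utf-8", errors="replace", newline="") as fh:
        reader = csv.reader(fh, delimiter="$")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, header row required")
        header = [h.strip().lower() for h in header]
        for col in required:
            if col not in header:
                raise SchemaError(f"{path}: missing mandatory column '{col}'")
        width = len(header)
        rows: list[list[str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and row[0].strip() == ""):
                continue
            if len(row) != width:
                issues.record("malformed_row", f"{path.name}:{lineno} has {len(row)} fields, expected {width}")
                continue
            rows.append(row)
    frame = pd.DataFrame(rows, columns=header, dtype=str)
    if frame.empty:
        frame = pd.DataFrame(columns=header, dtype=str)
    return frame


def locate_quarter_files(directory: Path) -> dict[str, Path]:
    """Find DEMO/DRUG/REAC/OUTC/INDI/THER files (e.g. DEMO23Q3.txt) in a directory."""
    directory = Path(directory)
    paths: dict[str, Path] = {}
    for name in TABLE_NAMES:
        matches = sorted(directory.glob(f"{name.upper()}*.txt")) + sorted(directory.glob(f"{name}*.txt"))
        if not matches:
            raise ConfigurationError(f"no {name.upper()} table found in {directory}")
        paths[name] = matches[0]
    return paths


def parse_quarter(
    paths: Mapping[str, Path] | Path | str,
    quarter_label: str = "",
    schema: str = "faers",
) -> RawQuarter:
    """Parse one quarter's six tables into a :class:`RawQuarter`.

    ``paths`` is either a mapping ``{"demo": Path, ...}`` or a directory that
    contains files named like ``DEMO23Q3.txt``.  Only the modern
    (post-2012Q4) ``schema="faers"`` dialect is supported.
    """
    if schema != "faers":
        raise ConfigurationError(f"unknown schema dialect '{schema}' (supported: 'faers')")
    if isinstance(paths, (str, Path)):
        paths = locate_quarter_files(Path(paths))
    issues = ParseIssues()
    tables = {}
    for name in TABLE_NAMES:
        if name not in paths:
            raise ConfigurationError(f"no path supplied for the {name.upper()} table")
        tables[name] = _read_dollar_table(Path(paths[name]), _REQUIRED_COLUMNS[name], issues)
    return RawQuarter(quarter_label=quarter_label, issues=issues, **tables)


def write_quarter(raw: RawQuarter, directory: Path, quarter_suffix: str = "") -> dict[str, Path]:
    """Serialize a RawQuarter back to $-delimited files (round-trip support)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name in TABLE_NAMES:
        path = directory / f"{name.upper()}{quarter_suffix}.txt"
        raw.table(name).to_csv(path, sep="$", index=False, lineterminator="\n")
        out[name] = path
    return out


def normalize_age(age_value, age_code: str) -> float | None:
    """Convert a FAERS (age, age_cod) pair to years.

    Codes: DEC decades, YR years, MON months, WK weeks, DY days, HR hours.
    An empty code with a value present is treated as years.  Non-numeric
    values and out-of-range results (<0 or >150 years) map to missing.
    """
    if age_value is None:
        return None
    text = str(age_value).strip()
    if not text:
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    code = (age_code or "").strip().upper()
    factor = AGE_UNIT_TO_YEARS.get(code) if code else 1.0
    if factor is None:
        return None
    years = value * factor
    if years < 0.0 or years > 150.0:
        return None
    return years


def _to_float(text: str | None) -> float | None:
    if text is None:
        return None
    text = text.strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        return None


def _get(row, column: str) -> str:
    value = row.get(column, "")
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value).strip()


def normalize_route(raw: str) -> str:
    text = (raw or "").strip().upper()
    if not text or text in {"UNKNOWN", "UNK"}:
        return "UNK"
    return _ROUTE_MAP.get(text, "OTHER")


def build_case_reports(raw: RawQuarter) -> list[CaseReport]:
    """Link a quarter's tables into per-version :class:`CaseReport` objects.

    Reports lacking any DRUG or REAC row are excluded (and counted): a
    spontaneous report without a medicine or a reaction carries no
    drug-event information.
    """
    issues = raw.issues
    by_pid: dict[str, dict[str, list]] = defaultdict(lambda: defaultdict(list))
    for name in ("drug", "reac", "outc", "indi", "ther"):
        frame = raw.table(name)
        for rec in frame.to_dict("records"):
            pid = str(rec.get("primaryid", "")).strip()
            if pid:
                by_pid[pid][name].append(rec)

    reports: list[CaseReport] = []
    for rec in raw.demo.to_dict("records"):
        pid = _get(rec, "primaryid")
        caseid = _get(rec, "caseid")
        if not pid or not caseid:
            issues.record("demo_missing_key", f"demo row without primaryid/caseid")
            continue
        try:
            caseversion = int(_get(rec, "caseversion") or "1")
        except ValueError:
            issues.record("bad_caseversion", f"primaryid {pid}")
            caseversion = 1
        linked = by_pid.get(pid, {})

        ther_by_seq: dict[str, FaersDate | None] = {}
        for trow in linked.get("ther", []):
            seq = _get(trow, "dsg_drug_seq")
            ther_by_seq[seq] = FaersDate.parse(_get(trow, "start_dt"))

        drugs: list[DrugEntry] = []
        for drow in sorted(linked.get("drug", []), key=lambda r: _seq_key(_get(r, "drug_seq"))):
            role = _get(drow, "role_cod").upper()
            if role not in ROLE_CODES:
                issues.record("unknown_role_cod", f"primaryid {pid} role '{role}'")
                continue
            name = _get(drow, "drugname")
            if not name:
                issues.record("empty_drugname", f"primaryid {pid}")
                continue
            ai = _get(drow, "prod_ai") or None
            drugs.append(
                DrugEntry(
                    drug_name=name,
                    active_ingredient=ai,
                    role=role,
                    route=normalize_route(_get(drow, "route")),
                    therapy_start_date=ther_by_seq.get(_get(drow, "drug_seq")),
                )
            )
        reactions = tuple(
            pt for rrow in linked.get("reac", []) if (pt := _get(rrow, "pt"))
        )
        if not drugs or not reactions:
            issues.record("report_without_drug_or_reaction", f"primaryid {pid}")
            continue

        outcomes = []
        for orow in linked.get("outc", []):
            code = _get(orow, "outc_cod").upper()
            if code in OUTCOME_CODES:
                outcomes.append(code)
            elif code:
                issues.record("unknown_outc_cod", f"primaryid {pid} code '{code}'")
        indications = tuple(
            ind for irow in linked.get("indi", []) if (ind := _get(irow, "indi_pt"))
        )

        age_raw, age_code = _get(rec, "age"), _get(rec, "age_cod")
        age_years = normalize_age(age_raw, age_code)
        if age_raw and age_years is None:
            issues.record("unusable_age", f"primaryid {pid} age '{age_raw}' code '{age_code}'")
        sex = _get(rec, "sex").upper()
        occ = _get(rec, "occp_cod").upper()
        reports.append(
            CaseReport(
                primaryid=pid,
                caseid=caseid,
                caseversion=caseversion,
                sex=sex if sex in {"F", "M"} else "UNK",
                age_years=age_years,
                age_code_raw=age_code,
                weight_kg=_to_float(_get(rec, "wt")),
                country=_get(rec, "reporter_country") or None,
                reporter_occupation=OCCUPATION_MAP.get(occ, "UNK"),
                event_date=FaersDate.parse(_get(rec, "event_dt")),
                receipt_date=FaersDate.parse(_get(rec, "fda_dt")),
                drugs=tuple(drugs),
                reactions=reactions,
                outcomes=tuple(outcomes),
                indications=indications,
            )
        )
    return reports


def load_quarter_reports(
    paths: Mapping[str, Path] | Path | str, quarter_label: str = ""
) -> tuple[list[CaseReport], ParseIssues]:
    """Convenience: parse a quarter and link it into case reports."""
    raw = parse_quarter(paths, quarter_label=quarter_label)
    return build_case_reports(raw), raw.issues


def _seq_key(seq: str):
    return (0, int(seq)) if seq.isdigit() else (1, seq)


def _id_key(identifier: str):
    # numeric-aware ordering so "9" < "10"; non-numeric ids sort after
    return (0, int(identifier), "") if identifier.isdigit() else (1, 0, identifier)


def _version_key(report: CaseReport):
    receipt = report.receipt_date or FaersDate(0)
    return (report.caseversion, receipt, _id_key(report.primaryid))


def deduplicate(
    reports: Iterable[CaseReport],
    deleted_caseids: Iterable[str] = (),
) -> list[CaseReport]:
    """Collapse case versions: keep, per caseid, the highest ``caseversion``
    (ties broken by latest receipt date, then largest primaryid), and drop
    any caseid on the FDA deleted-case list entirely.

    Idempotent; output ordered by caseid for determinism.
    """
    deleted = {str(c).strip() for c in deleted_caseids}
    best: dict[str, CaseReport] = {}
    for report in reports:
        if report.caseid in deleted:
            continue
        current = best.get(report.caseid)
        if current is None or _version_key(report) > _version_key(current):
            best[report.caseid] = report
    return [best[cid] for cid in sorted(best, key=_id_key)]


def read_deleted_caseids(path: Path) -> set[str]:
    """Read a deleted-case list, one caseid per line."""
    with open(path, "r", encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def _normalize_name(text: str) -> str:
    return " ".join(text.split()).casefold()


def matches_target(entry: DrugEntry, synonyms: Sequence[str], mode: str = "substring") -> bool:
    """Does a drug entry's name or active ingredient match any synonym?"""
    if mode not in {"substring", "exact"}:
        raise ConfigurationError(f"unknown match mode '{mode}'")
    needles = [_normalize_name(s) for s in synonyms if s.strip()]
    for raw in (entry.drug_name, entry.active_ingredient or ""):
        hay = _normalize_name(raw)
        if not hay:
            continue
        for needle in needles:
            if (mode == "substring" and needle in hay) or (mode == "exact" and needle == hay):
                return True
    return False


def is_target_ps(report: CaseReport, synonyms: Sequence[str], mode: str = "substring") -> bool:
    return any(d.role == "PS" and matches_target(d, synonyms, mode) for d in report.drugs)


def filter_primary_suspect(
    reports: Iterable[CaseReport],
    synonyms: Sequence[str],
    mode: str = "substring",
) -> list[CaseReport]:
    """Retain reports with >=1 primary-suspect drug entry matching a synonym.

    Matching is case-insensitive over both the verbatim drug name and the
    active-ingredient field, after trimming and collapsing whitespace;
    ``mode`` is "substring" (default, FAERS verbatims are noisy) or "exact".
    """
    if not [s for s in synonyms if s.strip()]:
        raise ConfigurationError("synonym list must be non-empty")
    return [r for r in reports if is_target_ps(r, synonyms, mode)]


def reports_to_frame(reports: Sequence[CaseReport]) -> pd.DataFrame:
    """Flatten case reports to a table (list fields joined by '|')."""
    rows = []
    for r in reports:
        rows.append(
            {
                "primaryid": r.primaryid,
                "caseid": r.caseid,
                "caseversion": r.caseversion,
                "sex": r.sex,
                "age_years": r.age_years,
                "weight_kg": r.weight_kg,
                "country": r.country or "",
                "reporter_occupation": r.reporter_occupation,
                "event_date": _date_str(r.event_date),
                "receipt_date": _date_str(r.receipt_date),
                "n_drugs": len(r.drugs),
                "ps_drugs": "|".join(d.drug_name for d in r.drugs if d.role == "PS"),
                "reactions": "|".join(r.reactions),
                "outcomes": "|".join(r.outcomes),
                "indications": "|".join(r.indications),
            }
        )
    columns = [
        "primaryid", "caseid", "caseversion", "sex", "age_years", "weight_kg",
        "country", "reporter_occupation", "event_date", "receipt_date",
        "n_drugs", "ps_drugs", "reactions", "outcomes", "indications",
    ]
    return pd.DataFrame(rows, columns=columns)


def _date_str(d: FaersDate | None) -> str:
    if d is None:
        return ""
    if d.precision == "day":
        return f"{d.year:04d}{d.month:02d}{d.day:02d}"
    if d.precision == "month":
        return f"{d.year:04d}{d.month:02d}"
    return f"{d.year:04d}"
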