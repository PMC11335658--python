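"""Clinical-characteristics summary of a deduplicated, drug-filtered corpus.

Produces the standard "basic information" table of a spontaneous-report
study: report year, gender, age bands, time to event onset, reporter
occupation, top reporting countries, administration route, outcomes and top
indications, each as (count, percent).

Denominator conventions differ by section and are recorded per section:

* ``TOTAL_REPORTS`` — year, gender, age, reporter, country, route and
  indications are percentages of all reports.
* ``SECTION_RECORDS`` — outcomes are percentages of outcome *records* (a
  report with two outcomes contributes twice), and time-to-onset percentages
  use the reports with any onset determination, the in-section "Unknown"
  bucket included; reports with no therapy/event date record at all are
  excluded from that section.

Percentages are rounded half-up to 2 decimals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .faers_io import CaseReport, matches_target

TOTAL_REPORTS = "TOTAL_REPORTS"
SECTION_RECORDS = "SECTION_RECORDS"

AGE_BANDS = ("<18", "18-45", "45-65", "65-75", ">=75", "Unknown")
TTO_BANDS = ("<7", "7-28", "28-60", ">=60", "Unknown")

OUTCOME_LABELS = {
    "HO": "Hospitalization",
    "OT": "Other serious",
    "DE": "Death",
    "DS": "Disability",
    "LT": "Life threatening",
    "RI": "Required intervention",
    "CA": "Congenital anomaly",
}

OCCUPATION_LABELS = {
    "CONSUMER": "Consumer",
    "PHYSICIAN": "Physician",
    "PHARMACIST": "Pharmacist",
    "OTHER_HEALTH_PROFESSIONAL": "Other health-professional",
    "REGISTERED_NURSE": "Registered Nurse",
    "LAWYER": "Lawyer",
    "UNK": "Unknown",
}


def percent(count: int, denominator: int) -> float:
    """count/denominator as a percentage, rounded half-up to 2 decimals."""
    if denominator <= 0:
        return 0.0
    value = Decimal(count) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Section:
    name: str
    denominator_policy: str
    denominator: int
    rows: tuple[tuple[str, int, float], ...]  # (category, count, percent)


@dataclass(frozen=True)
class CharacteristicsTable:
    sections: tuple[Section, ...]

    def section(self, name: str) -> Section:
        for s in self.sections:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sections:
            for category, count, pct in s.rows:
                rows.append((s.name, category, count, pct, s.denominator_policy, s.denominator))
        return pd.DataFrame(
            rows,
            columns=["section", "category", "count", "percent", "denominator_policy", "denominator"],
        )


def age_band(age_years: float | None) -> str:
    """Half-open age bands: [0,18), [18,45), [45,65), [65,75), [75, inf)."""
    if age_years is None:
        return "Unknown"
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18-45"
    if age_years < 65:
        return "45-65"
    if age_years < 75:
        return "65-75"
    return ">=75"


def tto_band(days: int | None) -> str:
    """Half-open onset bands: [0,7), [7,28), [28,60), [60, inf)."""
    if days is None or days < 0:
        return "Unknown"
    if days < 7:
        return "<7"
    if days < 28:
        return "7-28"
    if days < 60:
        return "28-60"
    return ">=60"


def time_to_onset(report: CaseReport, target_synonyms: Sequence[str]) -> tuple[int | None, str]:
    """Days from the earliest target primary-suspect therapy start to the event.

    Negative gaps, missing dates, or dates with less than day precision are
    an unknown onset.  Returns (days or None, band label).
    """
    event = report.event_date.to_date() if report.event_date else None
    starts = [
        d.therapy_start_date.to_date()
        for d in report.drugs
        if d.role == "PS"
        and d.therapy_start_date is not None
        and matches_target(d, target_synonyms)
    ]
    starts = [s for s in starts if s is not None]
    if event is None or not starts:
        return None, "Unknown"
    days = (event - min(starts)).days
    if days < 0:
        return None, "Unknown"
    return days, tto_band(days)


def _has_onset_record(report: CaseReport, target_synonyms: Sequence[str]) -> bool:
    """A report enters the onset section if it carries any therapy-start or
    event date at all (the in-section Unknown bucket); reports with neither
    record are excluded from the section entirely."""
    if report.event_date is not None:
        return True
    return any(
        d.role == "PS" and d.therapy_start_date is not None and matches_target(d, target_synonyms)
        for d in report.drugs
    )


def top_indications(reports: Iterable[CaseReport], k: int) -> list[tuple[str, int, float]]:
    """Top-k indications: counted once per report, percent of total reports,
    sorted by count descending with alphabetical tie-break."""
    reports = list(reports)
    total = len(reports)
    counts: Counter = Counter()
    for report in reports:
        for ind in set(report.indications):
            counts[ind] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[: max(k, 0)]
    return [(ind, n, percent(n, total)) for ind, n in ranked]


def _partition_section(name: str, counter: Counter, order: Sequence[str], denominator: int) -> Section:
    rows = tuple(
        (cat, counter.get(cat, 0), percent(counter.get(cat, 0), denominator)) for cat in order
    )
    return Section(name, TOTAL_REPORTS, denominator, rows)


def summarize(
    reports: Sequence[CaseReport],
    target_synonyms: Sequence[str] = (),
    top_k_indications: int = 6,
    top_k_countries: int = 5,
) -> CharacteristicsTable:
    """The full clinical-characteristics table for a report corpus.

    Input should already be deduplicated and filtered to the target drug as
    primary suspect.  Permutation-invariant over report order.
    """
    total = len(reports)

    years: Counter = Counter()
    sexes: Counter = Counter()
    ages: Counter = Counter()
    occupations: Counter = Counter()
    countries: Counter = Counter()
    routes: Counter = Counter()
    outcomes: Counter = Counter()
    onsets: Counter = Counter()
    n_onset = 0

    for report in reports:
        years[str(report.receipt_date.year) if report.receipt_date else "Unknown"] += 1
        sexes[{"F": "Female", "M": "Male"}.get(report.sex, "Unknown")] += 1
        ages[age_band(report.age_years)] += 1
        occupations[OCCUPATION_LABELS.get(report.reporter_occupation, "Unknown")] += 1
        countries[report.country or "Unknown"] += 1
        route = next(
            (d.route for d in report.drugs if d.role == "PS" and matches_target(d, target_synonyms)),
            None,
        ) if target_synonyms else next((d.route for d in report.drugs if d.role == "PS"), None)
        routes[(route or "UNK").capitalize() if route not in (None, "UNK") else "Other"] += 1
        for code in report.outcomes:
            outcomes[OUTCOME_LABELS.get(code, code)] += 1
        if _has_onset_record(report, target_synonyms):
            n_onset += 1
            _, band = time_to_onset(report, target_synonyms)
            onsets[band] += 1

    sections = [
        _partition_section("Year of report", years, sorted(years), total),
        _partition_section("Gender", sexes, ("Female", "Male", "Unknown"), total),
        _partition_section("Age", ages, AGE_BANDS, total),
        Section(
            "Time to event onset (days)", SECTION_RECORDS, n_onset,
            tuple((band, onsets.get(band, 0), percent(onsets.get(band, 0), n_onset)) for band in TTO_BANDS),
        ),
        _partition_section(
            "Reporter", occupations,
            sorted(occupations, key=lambda cat: (-occupations[cat], cat)), total,
        ),
        _top_k_section("Reported countries", countries, top_k_countries, total),
        _partition_section(
            "Route", routes, sorted(routes, key=lambda cat: (-routes[cat], cat)), total
        ),
        Section(
            "Outcomes", SECTION_RECORDS, sum(outcomes.values()),
            tuple(
                (cat, outcomes[cat], percent(outcomes[cat], sum(outcomes.values())))
                for cat in sorted(outcomes, key=lambda cat: (-outcomes[cat], cat))
            ),
        ),
        Section(
            f"Indications (top {top_k_indications})", TOTAL_REPORTS, total,
            tuple(top_indications(reports, top_k_indications)),
        ),
    ]
    return CharacteristicsTable(tuple(sections))


def _top_k_section(name: str, counter: Counter, k: int, denominator: int) -> Section:
    ranked = sorted(
        ((cat, n) for cat, n in counter.items() if cat != "Unknown"),
        key=lambda kv: (-kv[1], kv[0]),
    )
    top = ranked[:k]
    other = sum(n for _, n in ranked[k:]) + counter.get("Unknown", 0)
    rows = [(cat, n, percent(n, denominator)) for cat, n in top]
    if other:
        rows.append(("Other", other, percent(other, denominator)))
    rows.sort(key=lambda row: (-row[1], row[0]))
    return Section(name, TOTAL_REPORTS, denominator, tuple(rows))
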