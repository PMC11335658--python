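"""Drug-event pair counting and 2x2 contingency tables.

Disproportionality statistics compare, for one drug-event pair, the observed
report count against its expectation under independence within the whole
database.  The 2x2 table for a target drug and an event term is

    =============  ==============  ==================
                   event term      all other terms
    target drug    a               b
    other drugs    c               d
    =============  ==============  ==================

The default counting unit is the distinct (report, term) pair: a report
listing the same PT twice contributes one pair, and ``n`` is the total number
of such pairs in the database (the "adverse event" total of spontaneous-report
studies).  Report-level counting (each report counts once per term regardless
of the unit total) is available as an alternative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, ConsistencyError
from .faers_io import CaseReport, is_target_ps
from .meddra import PtSocMap, map_pt

PAIR_UNIT = "REPORT_PT_PAIR"
REPORT_UNIT = "REPORT"


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d cells for one drug-event pair."""

    a: int
    b: int
    c: int
    d: int
    term: str = ""
    level: str = "PT"  # PT or SOC
    unit: str = PAIR_UNIT

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConsistencyError(
                f"negative cell in table for '{self.term}': "
                f"(a,b,c,d)=({self.a},{self.b},{self.c},{self.d})"
            )

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/n, the count expected under independence."""
        n = self.n
        return (self.a + self.b) * (self.a + self.c) / n if n else 0.0

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class PairCounts:
    """Per-term target counts plus the margins needed to build 2x2 tables."""

    level: str
    unit: str
    a: Counter = field(default_factory=Counter)  # term -> target pair count
    event_margin: Counter = field(default_factory=Counter)  # term -> a+c
    drug_margin: int = 0  # a+b (total target pairs)
    n: int = 0
    subgroup: str = ""

    @property
    def terms(self) -> list[str]:
        return sorted(self.event_margin)


def _report_terms(report: CaseReport, level: str, pt_soc_map: PtSocMap | None) -> set[str]:
    if level == "PT":
        return set(report.reactions)
    if level == "SOC":
        if pt_soc_map is None:
            raise ConfigurationError("SOC-level counting requires a PT->SOC map")
        return {map_pt(pt_soc_map, pt) for pt in report.reactions}
    raise ConfigurationError(f"unknown counting level '{level}'")


def count_pairs(
    reports: Iterable[CaseReport],
    target_synonyms: Sequence[str],
    level: str = "PT",
    pt_soc_map: PtSocMap | None = None,
    unit: str = PAIR_UNIT,
    match_mode: str = "substring",
    subgroup: str = "",
) -> PairCounts:
    """Count distinct (report, term) pairs for the target drug and the margins.

    ``a[term]`` is the number of distinct reports that are target-PS and
    mention the term; the drug margin a+b sums target pairs over all terms;
    the event margin a+c counts the term over all reports; ``n`` is the total
    pair count (or the report count under ``unit="REPORT"``).  Duplicate
    mentions of one term within a report count once.
    """
    if unit not in {PAIR_UNIT, REPORT_UNIT}:
        raise ConfigurationError(f"unknown counting unit '{unit}'")
    counts = PairCounts(level=level, unit=unit, subgroup=subgroup)
    for report in reports:
        terms = _report_terms(report, level, pt_soc_map)
        target = is_target_ps(report, target_synonyms, match_mode)
        for term in terms:
            counts.event_margin[term] += 1
            if target:
                counts.a[term] += 1
        if unit == PAIR_UNIT:
            counts.n += len(terms)
            if target:
                counts.drug_margin += len(terms)
        else:
            counts.n += 1
            if target:
                counts.drug_margin += 1
    return counts


def build_table(counts: PairCounts, term: str, level: str | None = None) -> ContingencyTable:
    """Assemble the 2x2 table for one term from pair counts.

    b = drug margin - a; c = event margin - a; d = n - a - b - c.  Negative
    cells indicate inconsistent margins and raise :class:`ConsistencyError`.
    """
    a = counts.a.get(term, 0)
    b = counts.drug_margin - a
    c = counts.event_margin.get(term, 0) - a
    d = counts.n - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d, term=term, level=level or counts.level, unit=counts.unit)


def aggregate_soc(
    reports: Iterable[CaseReport],
    pt_soc_map: PtSocMap,
    target_synonyms: Sequence[str],
    unit: str = PAIR_UNIT,
    match_mode: str = "substring",
    subgroup: str = "",
) -> PairCounts:
    """SOC-level pair counts: one distinct (report, SOC) pair per report-SOC,
    so a report mentioning two PTs of the same SOC contributes once to that
    SOC, and ``n`` is recomputed at the report-SOC pair level."""
    reports = list(reports)
    return count_pairs(
        reports, target_synonyms, level="SOC", pt_soc_map=pt_soc_map,
        unit=unit, match_mode=match_mode, subgroup=subgroup,
    )


# ---------------------------------------------------------------------------
# Subgroups


@dataclass(frozen=True)
class SubgroupSpec:
    """A pure, composable predicate over case reports.

    Any combination of a reporter-occupation set, a sex value and an age
    lower bound; unspecified components do not constrain.  Reports with
    missing age fail an age-restricted predicate.
    """

    name: str
    occupations: frozenset[str] | None = None
    sex: str | None = None
    min_age: float | None = None

    def matches(self, report: CaseReport) -> bool:
        if self.occupations is not None and report.reporter_occupation not in self.occupations:
            return False
        if self.sex is not None and report.sex != self.sex:
            return False
        if self.min_age is not None:
            if report.age_years is None or report.age_years < self.min_age:
                return False
        return True


HEALTH_PROFESSIONAL = SubgroupSpec(
    "health_professional",
    occupations=frozenset(
        {"PHYSICIAN", "PHARMACIST", "OTHER_HEALTH_PROFESSIONAL", "REGISTERED_NURSE"}
    ),
)
FEMALE = SubgroupSpec("female", sex="F")
AGE_45_PLUS = SubgroupSpec("age_ge_45", min_age=45.0)

#: The standard subset analyses: reports from healthcare professionals,
#: female patients, and patients aged 45 and older.
DEFAULT_SUBGROUPS = (HEALTH_PROFESSIONAL, FEMALE, AGE_45_PLUS)


def apply_subgroup(reports: Iterable[CaseReport], spec: SubgroupSpec) -> list[CaseReport]:
    """Exactly the reports satisfying the predicate; downstream counts then
    use the subgroup's own n (comparator = same-subgroup non-target pairs)."""
    return [r for r in reports if spec.matches(r)]


# ---------------------------------------------------------------------------
# Full drug x term cells (the MGPS prior is fitted across the whole database)


def drug_event_cells(
    reports: Sequence[CaseReport],
    level: str = "PT",
    pt_soc_map: PtSocMap | None = None,
    include_zero_cells: bool = True,
) -> pd.DataFrame:
    """Observed/expected counts for the full cross-product of primary-suspect
    drugs and event terms: columns (drug, term, a, expected).

    The drug axis is the report's primary-suspect drug name(s); E is the
    independence expectation (drug margin x event margin / n) in the distinct
    (report, term) pair unit.  Zero-observation cells of the cross-product are
    included by default, as the empirical-Bayes prior is fitted over all
    cells, not just those with events.
    """
    pair_a: Counter = Counter()
    drug_margin: Counter = Counter()
    event_margin: Counter = Counter()
    n = 0
    for report in reports:
        terms = _report_terms(report, level, pt_soc_map)
        ps_drugs = sorted({d.drug_name.strip().upper() for d in report.drugs if d.role == "PS"})
        n += len(terms)
        for term in terms:
            event_margin[term] += 1
        for drug in ps_drugs:
            drug_margin[drug] += len(terms)
            for term in terms:
                pair_a[(drug, term)] += 1
    rows = []
    drugs = sorted(drug_margin)
    terms = sorted(event_margin)
    for drug in drugs:
        for term in terms:
            a = pair_a.get((drug, term), 0)
            if a == 0 and not include_zero_cells:
                continue
            expected = drug_margin[drug] * event_margin[term] / n if n else 0.0
            rows.append((drug, term, a, drug_margin[drug], event_margin[term], n, expected))
    return pd.DataFrame(
        rows,
        columns=["drug", "term", "a", "drug_margin", "event_margin", "n", "expected"],
    )
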