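"""FAERS-like synthetic data with known statistical structure.

The generator emits one quarter's worth of "$"-delimited DEMO/DRUG/REAC/
OUTC/INDI/THER tables in the modern (post-2012Q4) schema, plus a toy PT->SOC
table, an FDA-style deleted-case list and a ground-truth manifest, so the
whole pipeline is testable without downloading FAERS.

Statistical structure: each report draws a primary-suspect drug and a set of
reaction PTs from background frequency simplexes; for (drug, PT) pairs
"planted" in the configuration, the PT's selection probability is multiplied
by a relative reporting rate rr >= 1 when that drug is the report's primary
suspect and renormalized — planting the signal on exactly the quantity
lambda that disproportionality methods estimate.  Duplicate case versions,
deleted cases, missing demographics and partial dates are injected at
configurable rates.  All randomness flows from one seed: identical
(config, seed) produces byte-identical files.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

TARGET_DRUG_NAME = "TERIPARATIDE"

_OUTCOME_CODES = ("HO", "OT", "DE", "DS", "LT", "RI", "CA")
_OUTCOME_PROBS = (0.45, 0.35, 0.10, 0.04, 0.04, 0.015, 0.005)
_OCC_CODES = ("CN", "MD", "", "OT", "PH", "RN", "LW")
_OCC_PROBS = (0.60, 0.15, 0.10, 0.07, 0.05, 0.02, 0.01)
_COUNTRIES = ("US", "JP", "ES", "DE", "FR", "GB", "IT", "CA")
_COUNTRY_PROBS = (0.60, 0.09, 0.07, 0.06, 0.06, 0.05, 0.04, 0.03)
_ROUTES = ("", "SUBCUTANEOUS", "ORAL", "INTRAMUSCULAR", "INTRAVENOUS")
_ROUTE_PROBS = (0.62, 0.28, 0.06, 0.03, 0.01)
_TARGET_INDICATIONS = (
    "OSTEOPOROSIS", "OSTEOPOROSIS POSTMENOPAUSAL", "OSTEOPENIA",
    "BONE DISORDER", "ARTHRITIS", "BONE DENSITY DECREASED",
)
_TARGET_IND_PROBS = (0.62, 0.12, 0.09, 0.08, 0.05, 0.04)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic corpus.

    Defaults emulate a mid-sized spontaneous-reporting extract dominated by
    an elderly female population on the target drug, with a handful of
    planted drug-PT associations at known relative reporting rates.
    """

    n_reports: int = 20_000
    n_drugs: int = 25
    n_pts: int = 120
    n_socs: int = 12
    target_drug_share: float = 0.15
    #: (drug index, pt index, relative reporting rate >= 1); drug 0 is the
    #: target.  Defaults plant on mid-rank PTs, where the post-renormalization
    #: selection probability stays close to rr times background.
    planted: tuple[tuple[int, int, float], ...] = ((0, 40, 10.0), (0, 60, 10.0), (0, 80, 5.0))
    drugs_per_report: float = 2.0
    pts_per_report: float = 3.0
    duplicate_rate: float = 0.05
    deleted_rate: float = 0.01
    missing_sex_rate: float = 0.02
    missing_age_rate: float = 0.30
    missing_date_rate: float = 0.35
    imprecise_date_rate: float = 0.10
    seed: int = 0
    quarter_label: str = "2023Q3"

    def validate(self) -> None:
        if self.n_reports <= 0 or self.n_drugs <= 1 or self.n_pts <= 1 or self.n_socs < 1:
            raise ConfigurationError("n_reports, n_drugs, n_pts must exceed 1; n_socs >= 1")
        if not (0.0 < self.target_drug_share < 1.0):
            raise ConfigurationError("target_drug_share must lie in (0, 1)")
        for rate_name in ("duplicate_rate", "deleted_rate", "missing_sex_rate",
                          "missing_age_rate", "missing_date_rate", "imprecise_date_rate"):
            rate = getattr(self, rate_name)
            if not (0.0 <= rate < 1.0):
                raise ConfigurationError(f"{rate_name} must lie in [0, 1)")
        for drug, pt, rr in self.planted:
            if not (0 <= drug < self.n_drugs):
                raise ConfigurationError(f"planted drug index {drug} out of range")
            if not (0 <= pt < self.n_pts):
                raise ConfigurationError(f"planted pt index {pt} out of range")
            if rr < 1.0:
                raise ConfigurationError("planted rr must be >= 1")
        if self.drugs_per_report < 1 or self.pts_per_report < 1:
            raise ConfigurationError("drugs_per_report and pts_per_report must be >= 1")


def drug_name(index: int) -> str:
    return TARGET_DRUG_NAME if index == 0 else f"DRUG_{index:03d}"


def pt_name(index: int) -> str:
    return f"PT_{index:04d}"


def soc_name(index: int) -> str:
    return f"SOC_{index:02d}"


@dataclass
class GroundTruthManifest:
    """What the generator planted, for recovery testing."""

    config: dict
    planted: list[dict]                     # drug, pt, rr, realized_a
    duplicate_caseids: list[str]
    deleted_caseids: list[str]
    n_demo_rows: int
    n_unique_cases: int
    expected_survivors: int                 # unique cases minus deleted
    expected_target_ps_reports: int         # survivors with the target drug as PS
    target_pt_counts: dict[str, int]        # surviving target-PS distinct (report, PT) counts
    pt_soc_path: str = ""

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: Path) -> "GroundTruthManifest":
        return cls(**json.loads(Path(path).read_text()))


def _background_simplex(n: int, decay: float) -> np.ndarray:
    weights = 1.0 / np.arange(1, n + 1) ** decay
    return weights / weights.sum()


def _date_str(day: _dt.date) -> str:
    return f"{day.year:04d}{day.month:02d}{day.day:02d}"


@dataclass
class _Report:
    caseid: int
    ps_drug: int
    extra_drugs: list[tuple[int, str]]      # (drug index, role)
    pts: list[int]
    sex: str
    age_value: str
    age_code: str
    weight: str
    occ: str
    country: str
    routes: list[str]
    outcomes: list[str]
    indication: str
    start_date: str
    event_date: str
    receipt_date: str


def emit_pt_soc_map(config: SynthConfig, path: Path) -> Path:
    """Round-robin toy PT->SOC table: PT i belongs to SOC (i mod n_socs)."""
    config.validate()
    path = Path(path)
    lines = ["pt,soc"]
    for i in range(config.n_pts):
        lines.append(f"{pt_name(i)},{soc_name(i % config.n_socs)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def generate(config: SynthConfig, out_dir: Path) -> tuple[dict[str, Path], GroundTruthManifest]:
    """Write one synthetic quarter plus manifest; returns (paths, manifest)."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    drug_probs = _background_simplex(config.n_drugs - 1, 0.8)  # non-target drugs
    pt_probs = _background_simplex(config.n_pts, 0.7)
    planted_by_drug: dict[int, list[tuple[int, float]]] = {}
    for drug, pt, rr in config.planted:
        planted_by_drug.setdefault(drug, []).append((pt, rr))

    epoch = _dt.date(2015, 1, 1)
    span_days = (_dt.date(2022, 12, 31) - epoch).days

    reports: list[_Report] = []
    for i in range(config.n_reports):
        caseid = 1_000_000 + i
        if rng.random() < config.target_drug_share:
            ps_drug = 0
        else:
            ps_drug = 1 + int(rng.choice(config.n_drugs - 1, p=drug_probs))

        n_extra = int(rng.poisson(config.drugs_per_report - 1.0))
        extra: list[tuple[int, str]] = []
        if n_extra:
            pool = [d for d in range(config.n_drugs) if d != ps_drug]
            chosen = rng.choice(len(pool), size=min(n_extra, len(pool)), replace=False)
            for j in np.sort(chosen):
                role = str(rng.choice(["SS", "C", "I"], p=[0.30, 0.55, 0.15]))
                extra.append((pool[int(j)], role))

        n_pts_i = min(1 + int(rng.poisson(config.pts_per_report - 1.0)), config.n_pts)
        probs = pt_probs
        if ps_drug in planted_by_drug:
            probs = pt_probs.copy()
            for pt, rr in planted_by_drug[ps_drug]:
                probs[pt] *= rr
            probs = probs / probs.sum()
        pts = sorted(int(p) for p in rng.choice(config.n_pts, size=n_pts_i, replace=False, p=probs))

        sex = "" if rng.random() < config.missing_sex_rate else ("F" if rng.random() < 0.9 else "M")
        if rng.random() < config.missing_age_rate:
            age_value, age_code = "", ""
        else:
            age_years = float(np.clip(rng.normal(70.0, 12.0), 18.0, 100.0))
            unit = rng.random()
            if unit < 0.8:
                age_value, age_code = f"{age_years:.1f}", "YR"
            elif unit < 0.9:
                age_value, age_code = f"{age_years / 10.0:.2f}", "DEC"
            else:
                age_value, age_code = str(int(round(age_years * 12))), "MON"
        weight = f"{rng.normal(62.0, 11.0):.1f}" if rng.random() < 0.4 else ""
        occ = str(rng.choice(_OCC_CODES, p=_OCC_PROBS))
        country = str(rng.choice(_COUNTRIES, p=_COUNTRY_PROBS))
        routes = [str(rng.choice(_ROUTES, p=_ROUTE_PROBS)) for _ in range(1 + len(extra))]

        n_outc = int(rng.choice([0, 1, 2, 3], p=[0.35, 0.45, 0.15, 0.05]))
        outcomes = [
            str(c) for c in rng.choice(_OUTCOME_CODES, size=n_outc, replace=False, p=_OUTCOME_PROBS)
        ]

        if ps_drug == 0:
            indication = str(rng.choice(_TARGET_INDICATIONS, p=_TARGET_IND_PROBS))
        else:
            indication = f"INDICATION_{int(rng.integers(config.n_drugs)):03d}"

        start = epoch + _dt.timedelta(days=int(rng.integers(span_days)))
        gap = int(round(float(rng.lognormal(mean=np.log(40.0), sigma=1.5))))
        event = start + _dt.timedelta(days=gap)
        receipt = event + _dt.timedelta(days=int(rng.integers(5, 120)))
        start_s = "" if rng.random() < config.missing_date_rate else _date_str(start)
        if rng.random() < config.missing_date_rate:
            event_s = ""
        elif rng.random() < config.imprecise_date_rate:
            event_s = f"{event.year:04d}{event.month:02d}"
        else:
            event_s = _date_str(event)
        receipt_s = _date_str(receipt)

        reports.append(
            _Report(
                caseid=caseid, ps_drug=ps_drug, extra_drugs=extra, pts=pts, sex=sex,
                age_value=age_value, age_code=age_code, weight=weight, occ=occ,
                country=country, routes=routes, outcomes=outcomes, indication=indication,
                start_date=start_s, event_date=event_s, receipt_date=receipt_s,
            )
        )

    n_dup = int(config.duplicate_rate * config.n_reports)
    dup_indices = sorted(int(i) for i in rng.choice(config.n_reports, size=n_dup, replace=False))
    n_del = int(config.deleted_rate * config.n_reports)
    del_indices = sorted(int(i) for i in rng.choice(config.n_reports, size=n_del, replace=False))
    deleted_caseids = {str(reports[i].caseid) for i in del_indices}

    demo_rows, drug_rows, reac_rows, outc_rows, indi_rows, ther_rows = [], [], [], [], [], []

    def emit_version(r: _Report, version: int, receipt_shift: int) -> None:
        pid = f"{r.caseid}{version}"
        receipt = r.receipt_date
        if receipt_shift and receipt:
            day = _dt.datetime.strptime(receipt, "%Y%m%d").date() + _dt.timedelta(days=receipt_shift)
            receipt = _date_str(day)
        demo_rows.append(
            f"{pid}${r.caseid}${version}${r.event_date}${r.age_value}${r.age_code}"
            f"${r.sex}${r.weight}${r.occ}${r.country}${receipt}"
        )
        entries = [(r.ps_drug, "PS")] + r.extra_drugs
        for seq, ((drug, role), route) in enumerate(zip(entries, r.routes), start=1):
            name = drug_name(drug)
            drug_rows.append(f"{pid}${r.caseid}${seq}${role}${name}${name}${route}")
            if seq == 1:
                indi_rows.append(f"{pid}${r.caseid}${seq}${r.indication}")
                if r.start_date:
                    ther_rows.append(f"{pid}${r.caseid}${seq}${r.start_date}")
        for pt in r.pts:
            reac_rows.append(f"{pid}${r.caseid}${pt_name(pt)}")
        for code in r.outcomes:
            outc_rows.append(f"{pid}${r.caseid}${code}")

    for r in reports:
        emit_version(r, 1, 0)
    for i in dup_indices:
        emit_version(reports[i], 2, 30)

    suffix = config.quarter_label[2:4] + config.quarter_label[4:]  # 2023Q3 -> 23Q3
    headers = {
        "demo": "primaryid$caseid$caseversion$event_dt$age$age_cod$sex$wt$occp_cod$reporter_country$fda_dt",
        "drug": "primaryid$caseid$drug_seq$role_cod$drugname$prod_ai$route",
        "reac": "primaryid$caseid$pt",
        "outc": "primaryid$caseid$outc_cod",
        "indi": "primaryid$caseid$indi_drug_seq$indi_pt",
        "ther": "primaryid$caseid$dsg_drug_seq$start_dt",
    }
    rows = {
        "demo": demo_rows, "drug": drug_rows, "reac": reac_rows,
        "outc": outc_rows, "indi": indi_rows, "ther": ther_rows,
    }
    paths: dict[str, Path] = {}
    for name in headers:
        path = out_dir / f"{name.upper()}{suffix}.txt"
        path.write_text("\n".join([headers[name]] + rows[name]) + "\n")
        paths[name] = path

    deleted_path = out_dir / "DELETED_CASES.txt"
    deleted_path.write_text("\n".join(sorted(deleted_caseids)) + ("\n" if deleted_caseids else ""))
    paths["deleted"] = deleted_path
    pt_soc_path = emit_pt_soc_map(config, out_dir / "pt_soc_map.csv")
    paths["pt_soc_map"] = pt_soc_path

    survivors = [r for r in reports if str(r.caseid) not in deleted_caseids]
    target_pt_counts: dict[str, int] = {}
    for r in survivors:
        if r.ps_drug == 0:
            for pt in set(r.pts):
                key = pt_name(pt)
                target_pt_counts[key] = target_pt_counts.get(key, 0) + 1
    planted_entries = []
    for drug, pt, rr in config.planted:
        realized = sum(
            1 for r in survivors if r.ps_drug == drug and pt in r.pts
        )
        planted_entries.append(
            {"drug": drug_name(drug), "pt": pt_name(pt), "rr": rr, "realized_a": realized}
        )
    manifest = GroundTruthManifest(
        config=asdict(config),
        planted=planted_entries,
        duplicate_caseids=[str(reports[i].caseid) for i in dup_indices],
        deleted_caseids=sorted(deleted_caseids),
        n_demo_rows=len(demo_rows),
        n_unique_cases=len(reports),
        expected_survivors=len(survivors),
        expected_target_ps_reports=sum(1 for r in survivors if r.ps_drug == 0),
        target_pt_counts=dict(sorted(target_pt_counts.items())),
        pt_soc_path=pt_soc_path.name,  # relative: keeps files byte-identical across out dirs
    )
    manifest.to_json(out_dir / "manifest.json")
    paths["manifest"] = out_dir / "manifest.json"
    return paths, manifest
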