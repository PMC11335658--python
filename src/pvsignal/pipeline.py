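"""End-to-end orchestration: parse -> dedup -> filter -> describe -> detect.

One :class:`RunConfig` drives the whole flow and every artifact it writes:

* ``characteristics.csv`` — the clinical-characteristics summary (overall and
  one block per subgroup).
* ``pt_signals.csv`` / ``soc_signals.csv`` — one row per term with the 2x2
  cells, all four statistics, interval bounds and per-algorithm flags.
* ``waterfall.csv`` — all PT rows ordered by EBGM descending (the data
  behind a signal-intensity waterfall plot).
* ``top30_pt.csv`` — the EBGM-ranked head of the PT table.
* ``pt_signals_<subgroup>.csv`` — subgroup signal tables with the subgroup's
  own margins.
* ``run_metadata.json`` — thresholds, options and defaults in effect.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .contingency import (
    DEFAULT_SUBGROUPS, PAIR_UNIT, PairCounts, SubgroupSpec, apply_subgroup,
    build_table, count_pairs, drug_event_cells,
)
from .descriptive import summarize
from .errors import ConfigurationError, PvSignalError
from .faers_io import (
    CaseReport, deduplicate, filter_primary_suspect, load_quarter_reports,
    read_deleted_caseids, reports_to_frame,
)
from .meddra import PtSocMap, load_pt_soc_map
from .signal_stats import (
    BcpnnPrior, MgpsHyperParams, Thresholds, fit_mgps_prior, score_table,
)

logger = logging.getLogger("pvsignal")

DEFAULT_SYNONYMS = ("TERIPARATIDE", "FORTEO", "FORSTEO", "BONSITY")

SIGNAL_COLUMNS = [
    "term", "level", "subgroup", "a", "b", "c", "d", "n", "expected",
    "ror", "ror_lo95", "ror_hi95", "prr", "prr_lo95", "prr_hi95", "chi2",
    "ic", "ic025", "ebgm", "ebgm05",
    "flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps", "flag_combined",
]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; every field has a documented default."""

    quarter_dirs: tuple[str, ...] = ()
    pt_soc_map: str = ""
    out_dir: str = "pvsignal_out"
    deleted_case_list: str = ""           # optional path, one caseid per line
    apply_deleted: bool = True
    target_synonyms: tuple[str, ...] = DEFAULT_SYNONYMS
    match_mode: str = "substring"         # or "exact"
    counting_unit: str = PAIR_UNIT        # REPORT_PT_PAIR or REPORT
    zero_policy: str = "haldane"          # or "none"
    yates: bool = True
    ic_method: str = "exact"              # or "approx"
    thresholds: Thresholds = field(default_factory=Thresholds)
    subgroups: tuple[SubgroupSpec, ...] = DEFAULT_SUBGROUPS
    top_k: int = 30
    top_k_indications: int = 6
    min_a_report: int = 1                 # score terms with at least this many target cases
    seed: int = 0

    @classmethod
    def from_json(cls, path: Path | str) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        if "subgroups" in raw:
            raw["subgroups"] = tuple(
                SubgroupSpec(
                    name=s["name"],
                    occupations=frozenset(s["occupations"]) if s.get("occupations") else None,
                    sex=s.get("sex"),
                    min_age=s.get("min_age"),
                )
                for s in raw["subgroups"]
            )
        for key in ("quarter_dirs", "target_synonyms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _scores_frame(
    counts: PairCounts,
    hyper: MgpsHyperParams,
    config: RunConfig,
    subgroup: str = "",
) -> pd.DataFrame:
    rows = []
    for term in counts.terms:
        table = build_table(counts, term)
        if table.a < config.min_a_report:
            continue
        s = score_table(
            table, hyper, prior=BcpnnPrior(), thresholds=config.thresholds,
            zero_policy=config.zero_policy, yates=config.yates,
            ic_method=config.ic_method, subgroup=subgroup,
        )
        rows.append(
            {
                "term": s.term, "level": s.level, "subgroup": subgroup,
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "n": table.n, "expected": s.expected,
                "ror": s.ror, "ror_lo95": s.ror_lo95, "ror_hi95": s.ror_hi95,
                "prr": s.prr, "prr_lo95": s.prr_lo95, "prr_hi95": s.prr_hi95,
                "chi2": s.chi2, "ic": s.ic, "ic025": s.ic025,
                "ebgm": s.ebgm, "ebgm05": s.ebgm05,
                "flag_ror": s.flags.ror, "flag_prr": s.flags.prr,
                "flag_bcpnn": s.flags.bcpnn, "flag_mgps": s.flags.mgps,
                "flag_combined": s.flags.combined,
            }
        )
    frame = pd.DataFrame(rows, columns=SIGNAL_COLUMNS)
    return frame.sort_values("term", kind="mergesort").reset_index(drop=True)


def _fit_prior_for(
    reports: Sequence[CaseReport], level: str, pt_soc_map: PtSocMap | None, seed: int
) -> MgpsHyperParams:
    cells = drug_event_cells(reports, level=level, pt_soc_map=pt_soc_map)
    return fit_mgps_prior(cells["a"].to_numpy(), cells["expected"].to_numpy(), seed=seed)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def load_reports(config: RunConfig) -> tuple[list[CaseReport], str]:
    """Parse all configured quarters and deduplicate across them; returns
    the surviving reports plus the combined parse-issue log text."""
    if not config.quarter_dirs:
        raise ConfigurationError("run config names no quarter directories")
    reports: list[CaseReport] = []
    issue_blocks: list[str] = []
    for directory in config.quarter_dirs:
        quarter, issues = load_quarter_reports(directory, quarter_label=Path(directory).name)
        logger.info("parsed %s: %d reports, %d parse issues", directory, len(quarter), issues.total)
        issue_blocks.append(f"# {directory}\n{issues.to_text()}".rstrip())
        reports.extend(quarter)
    deleted: set[str] = set()
    if config.apply_deleted:
        for directory in config.quarter_dirs:
            candidate = Path(directory) / "DELETED_CASES.txt"
            if candidate.exists():
                deleted |= read_deleted_caseids(candidate)
        if config.deleted_case_list:
            deleted |= read_deleted_caseids(Path(config.deleted_case_list))
    return deduplicate(reports, deleted), "\n".join(issue_blocks) + "\n"


def subgroup_runs(
    reports: Sequence[CaseReport],
    hyper: MgpsHyperParams,
    config: RunConfig,
    pt_soc_map: PtSocMap | None = None,
    level: str = "PT",
) -> dict[str, pd.DataFrame]:
    """One signal table per subgroup, each with the subgroup's own margins."""
    out: dict[str, pd.DataFrame] = {}
    for spec in config.subgroups:
        members = apply_subgroup(reports, spec)
        if not members:
            logger.warning("subgroup '%s' is empty", spec.name)
            out[spec.name] = pd.DataFrame(columns=SIGNAL_COLUMNS)
            continue
        counts = count_pairs(
            members, config.target_synonyms, level=level, pt_soc_map=pt_soc_map,
            unit=config.counting_unit, match_mode=config.match_mode, subgroup=spec.name,
        )
        out[spec.name] = _scores_frame(counts, hyper, config, subgroup=spec.name)
    return out


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the full flow; returns the artifact paths.

    Raises a stage-named :class:`PvSignalError` on failure; partial outputs
    are removed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        reports, issue_log = load_reports(config)
        target_reports = filter_primary_suspect(
            reports, config.target_synonyms, config.match_mode
        )
        logger.info(
            "%d deduplicated reports, %d with target drug as primary suspect",
            len(reports), len(target_reports),
        )

        pt_soc = load_pt_soc_map(config.pt_soc_map) if config.pt_soc_map else None

        artifacts: dict[str, Path] = {}

        characteristics = summarize(
            target_reports, config.target_synonyms,
            top_k_indications=config.top_k_indications,
        ).to_frame()
        characteristics.insert(0, "subgroup", "")
        blocks = [characteristics]
        for spec in config.subgroups:
            sub = summarize(
                apply_subgroup(target_reports, spec), config.target_synonyms,
                top_k_indications=config.top_k_indications,
            ).to_frame()
            sub.insert(0, "subgroup", spec.name)
            blocks.append(sub)
        path = out_dir / "characteristics.csv"
        _write_csv(pd.concat(blocks, ignore_index=True), path)
        written.append(path)
        artifacts["characteristics"] = path

        frame = reports_to_frame(target_reports)
        path = out_dir / "case_reports.csv"
        _write_csv(frame, path)
        written.append(path)
        artifacts["case_reports"] = path
        path = out_dir / "case_reports.parquet"  # columnar cache
        frame.to_parquet(path, index=False)
        written.append(path)
        artifacts["case_reports_cache"] = path

        path = out_dir / "parse_issues.txt"
        path.write_text(issue_log)
        written.append(path)
        artifacts["parse_issues"] = path

        hyper_pt = _fit_prior_for(reports, "PT", None, config.seed)
        pt_counts = count_pairs(
            reports, config.target_synonyms, level="PT",
            unit=config.counting_unit, match_mode=config.match_mode,
        )
        pt_frame = _scores_frame(pt_counts, hyper_pt, config)
        path = out_dir / "pt_signals.csv"
        _write_csv(pt_frame, path)
        written.append(path)
        artifacts["pt_signals"] = path

        waterfall = pt_frame.sort_values(
            ["ebgm", "term"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        path = out_dir / "waterfall.csv"
        _write_csv(waterfall, path)
        written.append(path)
        artifacts["waterfall"] = path

        path = out_dir / "top30_pt.csv"
        _write_csv(waterfall.head(config.top_k), path)
        written.append(path)
        artifacts["top30_pt"] = path

        if pt_soc is not None:
            hyper_soc = _fit_prior_for(reports, "SOC", pt_soc, config.seed)
            soc_counts = count_pairs(
                reports, config.target_synonyms, level="SOC", pt_soc_map=pt_soc,
                unit=config.counting_unit, match_mode=config.match_mode,
            )
            path = out_dir / "soc_signals.csv"
            _write_csv(_scores_frame(soc_counts, hyper_soc, config), path)
            written.append(path)
            artifacts["soc_signals"] = path

        for name, frame in subgroup_runs(reports, hyper_pt, config).items():
            path = out_dir / f"pt_signals_{name}.csv"
            _write_csv(frame, path)
            written.append(path)
            artifacts[f"pt_signals_{name}"] = path

        metadata = {
            "pvsignal_version": __version__,
            "seed": config.seed,
            "target_synonyms": list(config.target_synonyms),
            "match_mode": config.match_mode,
            "counting_unit": config.counting_unit,
            "zero_policy": config.zero_policy,
            "yates_correction": config.yates,
            "ic_method": config.ic_method,
            "thresholds": asdict(config.thresholds),
            "dedup_rule": "max caseversion, ties by latest receipt date then largest primaryid",
            "apply_deleted": config.apply_deleted,
            "subgroups": [s.name for s in config.subgroups],
            "mgps_prior_pt": {
                k: v for k, v in asdict(hyper_pt).items()
            },
            "n_reports_deduplicated": len(reports),
            "n_reports_target_ps": len(target_reports),
        }
        path = out_dir / "run_metadata.json"
        path.write_text(json.dumps(metadata, indent=1, sort_keys=True) + "\n")
        written.append(path)
        artifacts["run_metadata"] = path
        return artifacts
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PvSignalError):
            raise
        raise PvSignalError(f"pipeline failed: {exc}") from exc
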