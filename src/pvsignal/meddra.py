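"""MedDRA preferred-term (PT) to system-organ-class (SOC) mapping.

MedDRA itself is licensed, so the dictionary content is never bundled: the
user supplies a two-column table (pt, soc).  Each PT maps to exactly one SOC
(the primary-SOC convention used by single-axis tabulations); MedDRA
multi-axiality is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DataError, SchemaError

UNMAPPED_SOC = "UNMAPPED"


def _key(pt: str) -> str:
    return " ".join(pt.split()).casefold()


@dataclass
class PtSocMap:
    """A primary-SOC lookup: case-insensitive PT text -> SOC name."""

    entries: dict[str, str] = field(default_factory=dict)  # casefolded pt -> soc
    soc_universe: frozenset[str] = frozenset()
    n_unmapped_lookups: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pt: str) -> bool:
        return _key(pt) in self.entries


def load_pt_soc_map(path: Path | str) -> PtSocMap:
    """Load a (pt, soc) CSV.

    Identical duplicate rows are collapsed; a PT appearing with two distinct
    SOCs violates the primary-SOC convention and raises :class:`DataError`
    naming the PT.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for col in ("pt", "soc"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing mandatory column '{col}'")
    entries: dict[str, str] = {}
    for pt, soc in zip(frame["pt"], frame["soc"]):
        pt_text, soc_text = pt.strip(), soc.strip()
        if not pt_text:
            continue
        key = _key(pt_text)
        if key in entries and entries[key] != soc_text:
            raise DataError(
                f"PT '{pt_text}' maps to both '{entries[key]}' and '{soc_text}'"
            )
        entries[key] = soc_text
    return PtSocMap(entries=entries, soc_universe=frozenset(entries.values()))


def map_pt(pt_soc_map: PtSocMap, pt: str) -> str:
    """The SOC of a PT; unmapped PTs return the ``UNMAPPED`` sentinel (counted)."""
    soc = pt_soc_map.entries.get(_key(pt))
    if soc is None:
        pt_soc_map.n_unmapped_lookups += 1
        return UNMAPPED_SOC
    return soc
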