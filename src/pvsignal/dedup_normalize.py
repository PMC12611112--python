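"""Report deduplication, drug-name normalization and primary-suspect selection.

FAERS re-publishes a case every time it is updated, so one CASEID commonly
appears under several PRIMARYIDs.  Following the FDA-recommended rule, the
record kept per CASEID is the one with the latest FDA_DT, ties broken by the
highest PRIMARYID (numeric comparison when both parse as integers).

Drug names in FAERS are verbatim reporter text; study drugs are recognised
through an explicit synonym dictionary (generic names, trade names and known
misspellings), matched case-insensitively after whitespace folding — no fuzzy
matching.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .faers_io import CalendarDate, CaseRecord

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def _fold(name: str) -> str:
    return _WS.sub(" ", name.strip()).casefold()


@dataclass
class SynonymDictionary:
    """Case-insensitive verbatim drug name -> canonical target name."""

    entries: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SynonymDictionary":
        return cls({_fold(k): v for k, v in mapping.items()})

    @classmethod
    def from_csv(cls, path: str | Path) -> "SynonymDictionary":
        """Two-column CSV: verbatim, canonical (header row required)."""
        entries: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries[_fold(row["verbatim"])] = row["canonical"].strip()
        return cls(entries)

    @property
    def canonical_names(self) -> frozenset[str]:
        return frozenset(self.entries.values())

    def lookup(self, verbatim: str) -> str | None:
        return self.entries.get(_fold(verbatim))


def default_synonyms() -> SynonymDictionary:
    """The shipped dictionary for the two copper chelators."""
    path = Path(__file__).parent / "data" / "synonyms.csv"
    return SynonymDictionary.from_csv(path)


def normalize_drug_name(verbatim: str, dictionary: SynonymDictionary) -> str | None:
    """Canonical name for a verbatim drug string, or ``None`` if unknown."""
    return dictionary.lookup(verbatim)


def compare_dates(x: CalendarDate, y: CalendarDate) -> int:
    """-1/0/1 ordering; missing month/day sort earliest."""
    kx, ky = x.sort_key, y.sort_key
    return (kx > ky) - (kx < ky)


def _primaryid_key(pid: str) -> tuple[int, int] | tuple[int, str]:
    try:
        return (0, int(pid))
    except ValueError:
        logger.warning("non-numeric PRIMARYID %r in dedup tie-break; "
                       "falling back to string comparison", pid)
        return (1, pid)


def _caseid_sort_key(caseid: str):
    return (0, int(caseid)) if caseid.isdigit() else (1, caseid)


@dataclass(slots=True)
class DedupResult:
    kept: list[CaseRecord]
    removed_count: int


def deduplicate(records: Sequence[CaseRecord]) -> DedupResult:
    """One record per CASEID: latest FDA_DT, then highest PRIMARYID.

    Output is sorted ascending by CASEID (numerically when possible), so the
    kept set is independent of input order.
    """
    best: dict[str, CaseRecord] = {}
    for record in records:
        current = best.get(record.caseid)
        if current is None:
            best[record.caseid] = record
            continue
        new_key = (record.fda_dt.sort_key, _primaryid_key(record.primaryid))
        cur_key = (current.fda_dt.sort_key, _primaryid_key(current.primaryid))
        if new_key > cur_key:
            best[record.caseid] = record
    kept = sorted(best.values(), key=lambda r: _caseid_sort_key(r.caseid))
    return DedupResult(kept=kept, removed_count=len(records) - len(kept))


class UnknownDrugError(ValueError):
    def __init__(self, drug: str, known: Iterable[str]):
        super().__init__(
            f"unknown canonical drug {drug!r}; known targets: {sorted(known)}")
        self.drug = drug


def select_primary_suspect(records: Sequence[CaseRecord], drug: str,
                           known_targets: Iterable[str] | None = None,
                           ) -> list[CaseRecord]:
    """Reports where ``drug`` is the Primary Suspect.

    Reports in which the drug appears only as secondary suspect, concomitant
    or interacting are excluded.
    """
    if known_targets is not None and drug not in set(known_targets):
        raise UnknownDrugError(drug, known_targets)
    return [r for r in records if r.has_role(drug, "PS")]
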