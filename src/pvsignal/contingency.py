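"""Fourfold (2x2) contingency tables for drug-event pairs and SOC rollups.

The counting unit throughout is the unique (report, preferred term) pair: a
report listing k distinct PTs contributes k pairs to its group's total, which
is why a study can collect 442 reports but 1,452 adverse events.  For a
queried target drug the comparator ("other drugs") is every deduplicated
report in which that drug is not the primary suspect — including reports of
the other study drug.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

from .faers_io import CaseRecord

if TYPE_CHECKING:  # pragma: no cover
    from .dpa_stats import SignalResult


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Fourfold table for one (drug, event) pair.

    a: target-drug reports with the target AE; b: target-drug reports with
    other AEs; c: other-drug reports with the target AE; d: other-drug
    reports with other AEs.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


class UnmappedPtError(KeyError):
    def __init__(self, pt: str):
        super().__init__(f"PT not in PT->SOC map: {pt!r}")
        self.pt = pt


@dataclass
class PtSocMap:
    """Total map from preferred term to its (single) system organ class."""

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PtSocMap":
        """Two-column CSV with header (pt, soc)."""
        mapping: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                mapping[row["pt"].strip()] = row["soc"].strip()
        return cls(mapping)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["pt", "soc"])
            for pt in sorted(self.mapping):
                writer.writerow([pt, self.mapping[pt]])

    def lookup(self, pt: str) -> str:
        try:
            return self.mapping[pt]
        except KeyError:
            raise UnmappedPtError(pt) from None


BACKGROUND = "background"


@dataclass(slots=True)
class PairCounts:
    """(report, PT) pair counts per group plus the overall margin.

    ``group_counts[g][pt]`` counts reports in group g listing pt, where g is
    a canonical target name or :data:`BACKGROUND` (reports with no target as
    primary suspect).  ``overall[pt]`` counts every report listing pt once,
    so the comparator margin for target t is ``overall - group_counts[t]``.
    """

    group_counts: dict[str, Counter]
    overall: Counter

    def total(self, group: str) -> int:
        return sum(self.group_counts[group].values())

    @property
    def overall_total(self) -> int:
        return sum(self.overall.values())


def count_drug_event_pairs(records: Sequence[CaseRecord],
                           targets: Iterable[str]) -> PairCounts:
    """Count unique (report, PT) pairs per target group and overall.

    A report contributes to each target group for which it is a
    primary-suspect report, otherwise to the background group.  (A report
    that is primary suspect for several targets at once counts in each of
    their groups; its pairs then also appear in the other target's
    comparator margin, a degenerate corner the deduplicated data essentially
    never produces.)
    """
    targets = list(targets)
    counts = PairCounts(
        group_counts={g: Counter() for g in [*targets, BACKGROUND]},
        overall=Counter(),
    )
    for record in records:
        groups = [t for t in targets if record.has_role(t, "PS")] or [BACKGROUND]
        for pt in record.events:
            counts.overall[pt] += 1
            for g in groups:
                counts.group_counts[g][pt] += 1
    return counts


def build_2x2(counts: PairCounts, group: str, pt: str) -> ContingencyTable:
    """The fourfold table for one (target, PT) pair against all other drugs."""
    a = counts.group_counts[group][pt]
    b = counts.total(group) - a
    c = counts.overall[pt] - a
    d = (counts.overall_total - counts.total(group)) - c
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"inconsistent counts for ({group}, {pt}): a={a} b={b} c={c} d={d}")
    return ContingencyTable(a, b, c, d)


def soc_distribution(signals: Sequence["SignalResult"],
                     soc_map: PtSocMap) -> pd.DataFrame:
    """Distribution of positive signals over system organ classes.

    ``n`` for a SOC is the sum of case counts *a* over the positive-signal
    PTs mapped to it; ``percent`` is its share of the summed case counts.
    Rows are sorted by n descending, SOC ascending.
    """
    n_by_soc: Counter = Counter()
    for sig in signals:
        if sig.combined_signal and not sig.excluded:
            n_by_soc[soc_map.lookup(sig.pt)] += sig.a
    total = sum(n_by_soc.values())
    rows = [
        {"soc": soc, "n": n, "percent": 100.0 * n / total if total else 0.0}
        for soc, n in sorted(n_by_soc.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["soc", "n", "percent"])


def soc_distribution_from_counts(n_by_soc: Mapping[str, int]) -> pd.DataFrame:
    """Same table computed directly from per-SOC case counts."""
    total = sum(n_by_soc.values())
    rows = [
        {"soc": soc, "n": n, "percent": 100.0 * n / total if total else 0.0}
        for soc, n in sorted(n_by_soc.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["soc", "n", "percent"])
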