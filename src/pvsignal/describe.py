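"""Report-level descriptive statistics (demographics, outcomes, countries).

These are the per-drug report characteristics a pharmacovigilance study
tabulates before signal mining: sex, weight and age strata, reporting-year
bins, outcome codes with the serious-outcome aggregate, and reporter
countries, each as count and percent of the drug's report total.  The
count-based helpers are exposed separately so the same arithmetic can be
applied to any printed count table.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import pandas as pd

from .faers_io import CaseRecord

#: Outcome codes counted as serious: hospitalization, disability,
#: life-threatening, death.
SERIOUS_OUTCOMES = frozenset({"HO", "DS", "LT", "DE"})

#: Default strata, mirroring the usual report-table bins.
WEIGHT_BINS = (("<50", 0, 50), ("50-100", 50, 100.0000001), (">100", 100.0000001, 1e9))
AGE_BINS_DEFAULT = (("<20", 0, 20), ("20-40", 20, 41), ("41-65", 41, 66),
                    (">65", 66, 1e9))
AGE_BINS_DECADES = tuple((f"{lo}-{lo + 9}", lo, lo + 10)
                         for lo in range(1, 91, 10))
YEAR_BINS_DEFAULT = (("2004-2009", 2004, 2010), ("2010-2015", 2010, 2016),
                     ("2016-2021", 2016, 2022), ("2022-2024", 2022, 2025))


def percent(n: float, total: float) -> float:
    """Share of a total as a percentage (0 when the total is empty)."""
    return 100.0 * n / total if total else 0.0


def serious_outcome_share(outcome_counts: Mapping[str, int],
                          total_reports: int) -> float:
    """Percent of reports with a serious outcome (HO + DS + LT + DE)."""
    serious = sum(outcome_counts.get(code, 0) for code in SERIOUS_OUTCOMES)
    return percent(serious, total_reports)


def sex_ratio(n_reference: float, n_other: float, decimals: int = 1) -> float:
    """The x of an "1 : x" ratio (reference count = 1), rounded."""
    if n_other == 0:
        raise ValueError("reference count is zero")
    return round(n_reference / n_other, decimals)


def _bin_label(value: float | None, bins) -> str:
    if value is None:
        return "unknown"
    for label, lo, hi in bins:
        if lo <= value < hi:
            return label
    return "unknown"


def demographics_table(records: Sequence[CaseRecord], drug: str,
                       age_bins=AGE_BINS_DEFAULT,
                       year_bins=YEAR_BINS_DEFAULT) -> pd.DataFrame:
    """Stacked (characteristic, stratum, n, percent) table for one drug's
    report set; percents are of the drug's report total."""
    total = len(records)
    blocks: list[tuple[str, Counter]] = []

    sex = Counter(r.sex for r in records)
    blocks.append(("sex", sex))

    weight = Counter(_bin_label(r.weight_kg, WEIGHT_BINS) for r in records)
    blocks.append(("weight_kg", weight))

    age = Counter(_bin_label(r.age_years, age_bins) for r in records)
    blocks.append(("age_years", age))

    year = Counter(_bin_label(r.fda_dt.year, year_bins) for r in records)
    blocks.append(("reporting_year", year))

    outcome = Counter()
    for r in records:
        if not r.outcomes:
            outcome["unknown"] += 1
        else:
            for code in r.outcomes:
                outcome[code] += 1
    blocks.append(("outcome", outcome))

    country = Counter(r.country for r in records)
    blocks.append(("country", country))

    rows = []
    for characteristic, counter in blocks:
        for stratum, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append({"drug": drug, "characteristic": characteristic,
                         "stratum": stratum, "n": n,
                         "percent": percent(n, total)})
    serious = serious_outcome_share(outcome, total)
    rows.append({"drug": drug, "characteristic": "outcome",
                 "stratum": "serious (HO+DS+LT+DE)",
                 "n": sum(outcome.get(c, 0) for c in SERIOUS_OUTCOMES),
                 "percent": serious})
    return pd.DataFrame(rows, columns=["drug", "characteristic", "stratum",
                                       "n", "percent"])
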