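"""Sex-stratified reporting odds ratios within one drug's report set.

The 2x2 here compares event frequency between female and male reports of the
same drug, oriented so ROR > 1 means female-predominant reporting (a
male-predominant event such as dystonia carries ROR < 1).  Reports of
unknown sex cannot enter a sex fourfold table and are dropped listwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .contingency import PtSocMap
from .faers_io import CaseRecord


@dataclass(frozen=True, slots=True)
class SexContingency:
    """a_f/b_f: female reports with/without the PT; a_m/b_m: male ditto."""

    a_f: int
    b_f: int
    a_m: int
    b_m: int


def _sex_counts(records: Sequence[CaseRecord], pt: str) -> SexContingency:
    a_f = b_f = a_m = b_m = 0
    for r in records:
        if r.sex == "female":
            if pt in r.events:
                a_f += 1
            else:
                b_f += 1
        elif r.sex == "male":
            if pt in r.events:
                a_m += 1
            else:
                b_m += 1
    return SexContingency(a_f, b_f, a_m, b_m)


def sex_stratified_ror(records: Sequence[CaseRecord], drug: str, pt: str,
                       correction: bool = False,
                       ) -> tuple[float | None, tuple[float | None, float | None],
                                  SexContingency]:
    """Female-vs-male ROR for one PT among the drug's primary-suspect
    reports (callers pass the already-selected report set).

    ROR = (a_f * b_m) / (b_f * a_m); CI as for the drug-level ROR.  A zero
    cell makes the estimate not evaluable unless the Haldane 0.5 correction
    is enabled.
    """
    counts = _sex_counts(records, pt)
    cells = (counts.a_f, counts.b_f, counts.a_m, counts.b_m)
    if correction and 0 in cells:
        a_f, b_f, a_m, b_m = (c + 0.5 for c in cells)
    else:
        a_f, b_f, a_m, b_m = (float(c) for c in cells)
    if 0 in (a_f, b_f, a_m, b_m):
        return None, (None, None), counts
    estimate = (a_f * b_m) / (b_f * a_m)
    half = 1.96 * math.sqrt(1 / a_f + 1 / b_f + 1 / a_m + 1 / b_m)
    return estimate, (estimate * math.exp(-half), estimate * math.exp(half)), counts


SUBGROUP_COLUMNS = ["pt", "soc", "n_female", "n_male", "n_total",
                    "ror", "ror_low", "ror_high"]


def subgroup_screen(records: Sequence[CaseRecord], drug: str,
                    soc_map: PtSocMap | None = None,
                    top_n: int = 50,
                    correction: bool = False) -> pd.DataFrame:
    """Ranked sex-stratified table of the drug's most-reported events.

    Only PTs reported at least once in each sex are eligible ("common to
    both males and females"); they rank by combined female+male count
    descending (PT ascending on ties) and the table truncates to ``top_n``.
    """
    known_sex = [r for r in records if r.sex in ("female", "male")]
    pts = sorted({pt for r in known_sex for pt in r.events})
    rows = []
    for pt in pts:
        est, (lo, hi), counts = sex_stratified_ror(known_sex, drug, pt,
                                                   correction=correction)
        if counts.a_f < 1 or counts.a_m < 1:
            continue
        rows.append({
            "pt": pt,
            "soc": soc_map.lookup(pt) if soc_map is not None else "",
            "n_female": counts.a_f,
            "n_male": counts.a_m,
            "n_total": counts.a_f + counts.a_m,
            "ror": est, "ror_low": lo, "ror_high": hi,
        })
    rows.sort(key=lambda row: (-row["n_total"], row["pt"]))
    return pd.DataFrame(rows[:max(top_n, 0)], columns=SUBGROUP_COLUMNS)
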