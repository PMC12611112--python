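"""Disproportionality statistics: ROR, PRR, BCPNN information component.

For one (drug, event) fourfold table with cells a, b, c, d and N = a+b+c+d:

* ROR = ad/bc, with 95% CI exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d)).
  Positive when the CI lower bound exceeds 1 and a >= 3.
* PRR = [a/(a+b)] / [c/(c+d)], with the Pearson statistic
  chi2 = (ad-bc)^2 · N / [(a+b)(c+d)(a+c)(b+d)] (no continuity correction).
  Positive when PRR > 2, chi2 > 4 and a >= 3.
* BCPNN IC = log2( a·N / ((a+c)(a+b)) ), the observed-to-expected reporting
  ratio in bits, with credibility bounds IC ± 2·sqrt(V(IC)) using the
  closed-form posterior variance of Bate et al. (1998).  Positive when the
  lower bound IC025 > 0.

A pair is a *signal* only when all three methods are positive — the
conjunction trades sensitivity for specificity.  Zero cells make ROR (and
the IC at a = 0) not evaluable rather than raising; an optional Haldane 0.5
continuity correction is available for comparability with other tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats as _sps

from .contingency import (ContingencyTable, PairCounts, PtSocMap,
                          build_2x2, count_drug_event_pairs)
from .dedup_normalize import select_primary_suspect
from .faers_io import CaseRecord


@dataclass(frozen=True, slots=True)
class BcpnnPriors:
    """Prior constants of the Bate et al. closed-form IC variance."""

    gamma11: float = 1.0
    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    z: float = 2.0  # half-width multiplier printed as "2·V(IC)^0.5"


@dataclass(frozen=True, slots=True)
class SignalCriteria:
    """Positivity thresholds for the three methods (defaults as published)."""

    ror_ci_low: float = 1.0
    min_cases: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0


@dataclass(frozen=True, slots=True)
class DpaEstimates:
    """Point estimates and interval bounds; ``None`` marks not-evaluable."""

    ror: float | None
    ror_low: float | None
    ror_high: float | None
    prr: float | None
    chi2: float | None
    ic: float | None
    ic025: float | None
    ic975: float | None


def _corrected(t: ContingencyTable, correction: bool) -> tuple[float, float, float, float]:
    if correction and 0 in t.cells:
        return tuple(x + 0.5 for x in t.cells)  # Haldane-Anscombe
    return tuple(float(x) for x in t.cells)


def ror(t: ContingencyTable, correction: bool = False,
        ) -> tuple[float | None, tuple[float | None, float | None]]:
    """Reporting odds ratio with 95% CI; any zero cell -> not evaluable
    (unless the Haldane correction is enabled)."""
    a, b, c, d = _corrected(t, correction)
    if 0 in (a, b, c, d):
        return None, (None, None)
    estimate = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = 1.96 * se
    return estimate, (estimate * math.exp(-half), estimate * math.exp(half))


def prr(t: ContingencyTable, correction: bool = False,
        ) -> tuple[float | None, float | None]:
    """Proportional reporting ratio and its Pearson chi-squared statistic.

    PRR is not evaluable when no comparator report carries the event (c = 0)
    or the drug has no pairs at all; chi2 is not evaluable when any margin
    is zero.
    """
    a, b, c, d = _corrected(t, correction)
    n = a + b + c + d
    estimate: float | None
    if a + b == 0 or c + d == 0 or c == 0:
        estimate = None
    else:
        estimate = (a / (a + b)) / (c / (c + d))
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        chi2 = None
    else:
        chi2 = (a * d - b * c) ** 2 * n / math.prod(margins)
    return estimate, chi2


def _ic_variance(a: float, ab: float, ac: float, n: float,
                 priors: BcpnnPriors) -> float:
    p = priors
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / (
        (ab + p.alpha1) * (ac + p.beta1))
    return (1 / math.log(2)) ** 2 * (
        (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
        + (n - ab + p.alpha - p.alpha1) / ((ab + p.alpha1) * (1 + n + p.alpha))
        + (n - ac + p.beta - p.beta1) / ((ac + p.beta1) * (1 + n + p.beta))
    )


def bcpnn_ic(t: ContingencyTable, priors: BcpnnPriors = BcpnnPriors(),
             ) -> tuple[float | None, float | None, float | None]:
    """Information component with lower/upper credibility bounds.

    The point IC needs a >= 1 (log2 of the observed/expected ratio); at
    a = 0 the pair is reported not evaluable — such pairs are never
    screened anyway, since screening only considers events observed with
    the drug.
    """
    a, b, c, d = (float(x) for x in t.cells)
    n = a + b + c + d
    ab, ac = a + b, a + c
    if a == 0 or ab == 0 or ac == 0:
        return None, None, None
    ic = math.log2(a * n / (ac * ab))
    half = priors.z * math.sqrt(_ic_variance(a, ab, ac, n, priors))
    return ic, ic - half, ic + half


def estimate_all(t: ContingencyTable, correction: bool = False,
                 priors: BcpnnPriors = BcpnnPriors()) -> DpaEstimates:
    ror_est, (ror_lo, ror_hi) = ror(t, correction)
    prr_est, chi2 = prr(t, correction)
    ic, ic025, ic975 = bcpnn_ic(t, priors)
    return DpaEstimates(ror_est, ror_lo, ror_hi, prr_est, chi2, ic, ic025, ic975)


@dataclass(frozen=True, slots=True)
class MethodFlags:
    ror: bool
    prr: bool
    bcpnn: bool

    @property
    def combined(self) -> bool:
        return self.ror and self.prr and self.bcpnn


def evaluate_criteria(t: ContingencyTable, e: DpaEstimates,
                      criteria: SignalCriteria = SignalCriteria()) -> MethodFlags:
    """Apply the three positivity rules and their conjunction."""
    flag_ror = (e.ror_low is not None and e.ror_low > criteria.ror_ci_low
                and t.a >= criteria.min_cases)
    flag_prr = (e.prr is not None and e.prr > criteria.prr_min
                and e.chi2 is not None and e.chi2 > criteria.chi2_min
                and t.a >= criteria.min_cases)
    flag_bcpnn = e.ic025 is not None and e.ic025 > criteria.ic025_min
    return MethodFlags(flag_ror, flag_prr, flag_bcpnn)


def fisher_exact(t: ContingencyTable) -> float:
    """Conditional two-sided Fisher exact p for the fourfold table."""
    table = [[t.a, t.b], [t.c, t.d]]
    return float(_sps.fisher_exact(table, alternative="two-sided")[1])


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment over a family of m tests: min(1, m*p)."""
    if m <= 0:
        raise ValueError(f"family size must be positive, got {m}")
    if m < len(p_values):
        raise ValueError(f"family size {m} smaller than list ({len(p_values)})")
    return [min(1.0, m * p) for p in p_values]


@dataclass(slots=True)
class SignalResult:
    """One screened (drug, PT) pair."""

    drug: str
    pt: str
    a: int
    table: ContingencyTable
    estimates: DpaEstimates
    flag_ror: bool
    flag_prr: bool
    flag_bcpnn: bool
    combined_signal: bool
    soc: str
    fisher_p: float
    p_adjust: float
    excluded: bool = False
    exclusion_reason: str | None = None


class ExclusionList:
    """Case-insensitive substring patterns marking non-AE preferred terms
    (product-quality/use-issue/indication terms)."""

    def __init__(self, patterns: Iterable[str]):
        self.patterns = [p.strip() for p in patterns if p.strip()]
        self._folded = [p.casefold() for p in self.patterns]

    @classmethod
    def from_file(cls, path: str | Path) -> "ExclusionList":
        with open(path, encoding="utf-8") as fh:
            lines = [ln.strip() for ln in fh
                     if ln.strip() and not ln.lstrip().startswith("#")]
        return cls(lines)

    def match(self, pt: str) -> str | None:
        """The first matching pattern, or None."""
        folded = pt.casefold()
        for pattern, fold in zip(self.patterns, self._folded):
            if fold in folded:
                return pattern
        return None


def default_exclusions() -> ExclusionList:
    return ExclusionList.from_file(Path(__file__).parent / "data" / "exclusions.txt")


@dataclass(slots=True)
class ScreenResult:
    """Output of the end-to-end screen for one drug."""

    drug: str
    signals: list[SignalResult]            # final, post-exclusion
    excluded: list[SignalResult]
    n_reports: int                         # primary-suspect reports
    n_pairs: int                           # (report, PT) pairs for the drug
    n_pts_tested: int

    @property
    def positive(self) -> list[SignalResult]:
        return [s for s in self.signals if s.combined_signal]


def _rank_key(sig: SignalResult):
    ror_est = sig.estimates.ror
    return (-sig.a, -(ror_est if ror_est is not None else -math.inf), sig.pt)


def screen_signals(records: Sequence[CaseRecord], drug: str,
                   soc_map: PtSocMap,
                   exclusions: ExclusionList | None = None,
                   criteria: SignalCriteria = SignalCriteria(),
                   priors: BcpnnPriors = BcpnnPriors(),
                   correction: bool = False,
                   targets: Iterable[str] | None = None,
                   counts: PairCounts | None = None) -> ScreenResult:
    """End-to-end disproportionality screen of one drug against the rest.

    For every PT reported at least once with the drug: build the fourfold
    table, compute all three estimates, the positivity flags, the Fisher
    exact p and its Bonferroni adjustment (family = PTs tested for this
    drug).  PTs on the exclusion list are marked and moved to
    ``excluded``.  Results sort by case count descending, then ROR
    descending, then PT.
    """
    if exclusions is None:
        exclusions = ExclusionList([])
    target_set = set(targets) if targets is not None else {drug}
    target_set.add(drug)
    if counts is None:
        counts = count_drug_event_pairs(records, sorted(target_set))
    ps_records = select_primary_suspect(records, drug)

    pts = sorted(pt for pt, n in counts.group_counts[drug].items() if n >= 1)
    m = len(pts)
    results: list[SignalResult] = []
    for pt in pts:
        table = build_2x2(counts, drug, pt)
        est = estimate_all(table, correction=correction, priors=priors)
        flags = evaluate_criteria(table, est, criteria)
        p = fisher_exact(table)
        pattern = exclusions.match(pt)
        results.append(SignalResult(
            drug=drug, pt=pt, a=table.a, table=table, estimates=est,
            flag_ror=flags.ror, flag_prr=flags.prr, flag_bcpnn=flags.bcpnn,
            combined_signal=flags.combined,
            soc=soc_map.lookup(pt),
            fisher_p=p,
            p_adjust=bonferroni([p], m)[0],
            excluded=pattern is not None,
            exclusion_reason=pattern,
        ))
    results.sort(key=_rank_key)
    kept = [s for s in results if not s.excluded]
    dropped = [s for s in results if s.excluded]
    return ScreenResult(
        drug=drug, signals=kept, excluded=dropped,
        n_reports=len(ps_records),
        n_pairs=counts.total(drug),
        n_pts_tested=m,
    )


def intersect_signals(sig_a: Sequence[SignalResult],
                      sig_b: Sequence[SignalResult]) -> set[str]:
    """PTs with a combined signal for both drugs (post-exclusion lists)."""
    pos_a = {s.pt for s in sig_a if s.combined_signal and not s.excluded}
    pos_b = {s.pt for s in sig_b if s.combined_signal and not s.excluded}
    return pos_a & pos_b


def volcano_table(signals: Sequence[SignalResult]) -> pd.DataFrame:
    """Volcano-plot coordinates: log10 ROR vs -log10 adjusted Fisher p.

    Rows with a not-evaluable ROR are omitted; p_adjust of exactly 1 maps to
    y = 0 and p_adjust of 0 is floored at 1e-300 to keep y finite.
    """
    rows = []
    for sig in signals:
        if sig.excluded or sig.estimates.ror is None:
            continue
        p_adj = sig.p_adjust
        y = 0.0 if p_adj >= 1.0 else -math.log10(max(p_adj, 1e-300))
        rows.append({
            "pt": sig.pt,
            "log_ror": math.log10(sig.estimates.ror),
            "neg_log10_p_adjust": y,
            "case_count": sig.a,
        })
    return pd.DataFrame(rows, columns=["pt", "log_ror",
                                       "neg_log10_p_adjust", "case_count"])


SIGNAL_CSV_COLUMNS = [
    "drug", "pt", "soc", "n", "ror", "ror_low", "ror_high", "prr", "chi2",
    "ic", "ic025", "flag_ror", "flag_prr", "flag_bcpnn", "signal",
    "fisher_p", "p_adjust", "excluded", "exclusion_reason",
]


def signals_to_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Flatten signal results into the standard output table."""
    rows = []
    for s in results:
        e = s.estimates
        rows.append({
            "drug": s.drug, "pt": s.pt, "soc": s.soc, "n": s.a,
            "ror": e.ror, "ror_low": e.ror_low, "ror_high": e.ror_high,
            "prr": e.prr, "chi2": e.chi2, "ic": e.ic, "ic025": e.ic025,
            "flag_ror": s.flag_ror, "flag_prr": s.flag_prr,
            "flag_bcpnn": s.flag_bcpnn, "signal": s.combined_signal,
            "fisher_p": s.fisher_p, "p_adjust": s.p_adjust,
            "excluded": s.excluded, "exclusion_reason": s.exclusion_reason or "",
        })
    return pd.DataFrame(rows, columns=SIGNAL_CSV_COLUMNS)
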