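# Methods

## Data model and ingestion

A FAERS-style quarter is seven `$`-delimited ASCII tables sharing a
`PRIMARYID` key.  Parsing is deliberately literal: fields are split on the
delimiter, trimmed, and never coerced; ragged rows are rejected into an
auditable report rather than repaired; unknown columns are ignored so
layout changes across quarters do not break ingestion.  Dates are 4-, 6-
or 8-digit tokens and are kept as partial dates with an explicit precision
(`year`/`month`/`day`) instead of being imputed at parse time — the
consumers decide: the dedup comparison sorts missing parts earliest, and
onset-time extraction requires day precision by default.

Records assemble one `CaseRecord` per `PRIMARYID`.  A `PRIMARYID` seen in
several quarterly files (routine for updated cases) keeps the
later-parsed DEMO row; because deduplication then keeps the latest
`FDA_DT` per `CASEID` anyway, the choice only affects which identical-ID
fragments are joined, not which case version survives.  Records with
demographics but no reaction rows are kept with zero events so report
denominators remain correct.

## Deduplication and drug coding

FAERS re-publishes a case on every update, so one `CASEID` appears under
multiple `PRIMARYID`s.  Per `CASEID` the pipeline keeps the record
maximizing (`FDA_DT`, numeric `PRIMARYID`) in that priority — "highest"
is numeric because FAERS `PRIMARYID`s are numeric; a non-numeric ID falls
back to string comparison with a logged warning.  The operation is
idempotent and input-order invariant (output sorts by `CASEID`).

Drug recognition is dictionary-exact after case-folding and whitespace
collapse, never fuzzy: misspellings must be enumerated.  The shipped
dictionary covers penicillamine (d-penicillamine, penicilamine, Cuprimine,
Depen) and trientine (trientine HCl/hydrochloride, Syprine, Cuprior) and
is overridable via CSV.  Only reports where the queried drug is the
Primary Suspect (`ROLE_COD = PS`) enter that drug's numerator; reports
where it appears as secondary suspect, concomitant or interacting are
comparator reports.

## Disproportionality statistics

The counting unit is the unique (report, preferred term) pair; a report
listing k distinct PTs contributes k pairs.  For drug D and term E, with
a = D-reports listing E, b = D's other pairs, c/d the analogues over all
other reports, and N = a+b+c+d:

- ROR = ad/bc with 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`;
- PRR = [a/(a+b)]/[c/(c+d)] with the Pearson χ² statistic (no continuity
  correction);
- IC = log₂(a·N/((a+c)(a+b))) with credibility bounds IC ± 2·√V(IC).

The IC variance uses the closed-form posterior of Bate et al. (1998) with
priors γ₁₁ = 1, α₁ = β₁ = 1, α = β = 2:

    V(IC) = (1/ln 2)² · [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                        + (N−a−b+α−α₁)/((a+b+α₁)(1+N+α))
                        + (N−a−c+β−β₁)/((a+c+β₁)(1+N+β)) ],
    γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)).

Prior constants and the half-width multiplier 2 are config-exposed
(`BcpnnPriors`), since different BCPNN implementations vary here while the
point IC is standard.

Zero-cell policy: no correction by default — a zero cell makes ROR (and
the IC at a = 0) *not evaluable*, a value rather than an exception; an
optional Haldane 0.5 correction exists for comparability with other tools.
A pair with a = 0 never reaches the screen, which only tests terms
observed at least once with the drug.

A term is a **signal** when all three positivity rules hold (ROR CI low
> 1 with a ≥ 3; PRR > 2 with χ² > 4 and a ≥ 3; IC025 > 0).  The
conjunction is deliberately conservative: on null synthetic data the
flagged fraction stays below 5%.  Fisher exact p-values (conditional
two-sided, via scipy) are Bonferroni-adjusted with family = number of
terms tested for that drug, since each drug is screened separately.
Exclusion patterns (product-quality, use-issue and indication terms) are
applied case-insensitively as substring matches *after* screening, so every
exclusion is auditable in the excluded-signals output.  Ranked outputs
order by case count descending, then ROR descending, then term — a
deterministic frequency-first presentation.

SOC rollups sum case counts a over positive-signal terms per System Organ
Class; percents are of the summed case counts, which is the definition
consistent with the published per-drug SOC totals.

## Time to onset

TTO = event date − earliest Primary-Suspect therapy start date, in days,
strictly positive, day-precision dates only (an option imputes
month-precision dates to day 1; off by default because it manufactures
negative TTOs).  Outliers are excluded with Tukey fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR]; quartiles interpolate linearly between
order statistics at positions 1 + (n−1)p ("type 7"), and the published
medians are computed after exclusion.  The fence multiplier and quartile
convention are configurable because the field rarely states them.

The kept sample is fit by maximum likelihood to Weibull(α, β)
(scale days, dimensionless shape) in (log α, log β) coordinates with an
analytic gradient (BFGS, convergence at gradient norm < 1e−8 within 200
iterations, else an error carrying the trace).  95% CIs are Wald
intervals from the observed information on the log parameters,
exponentiated so bounds stay positive.  The failure label follows the
point estimate — β < 1 "early" (decreasing hazard), β > 1 "wear-out",
β ≈ 1 "random" — with whether the CI excludes 1 reported alongside rather
than deciding the label.  Degenerate inputs (n < 3, non-positive or
constant samples) raise instead of fitting silently.

Note an interaction the full pipeline inherits: Tukey fences truncate the
heavy right tail of a β < 1 Weibull, so pipeline-level fits are biased
toward larger β and smaller α relative to the generating parameters.
Parameter-recovery claims are therefore stated for the fitter on
untruncated samples; the pipeline-level fit is a descriptive summary of
the post-exclusion sample, exactly as in practice.

## Sex subgroup

Within one drug's Primary-Suspect reports, each term's 2×2 compares
female vs male reporting; ROR = (a_f·b_m)/(b_f·a_m), oriented so ROR > 1
means female-predominant.  Unknown-sex reports cannot enter the table and
are dropped listwise.  Only terms reported in both sexes are ranked (by
combined count, descending), truncated to the top 50 by default.

## Synthetic data generator

The generator is first-class, tested code that emits the exact ingestion
dialect plus a serialized ground truth.  Defaults encode the study
conditions: two target drugs at 5% and 3.5% report share against a
background of common drugs; per-drug sex distributions (54.5/36.7/8.8 and
42.4/38.0/19.6 female/male/unknown), outcome laws with serious-outcome
shares near 33.7% and 26.6%, and country laws (US 48.6% and 85.5%)
mirroring the published report margins; onset times from
Weibull(453.17, 0.55) and (177.20, 0.76); ~85% missing weight, ~45%
missing age; terms drawn from a Zipf(1.5) background of 200 synthetic PTs
(1 + Poisson(2.3) terms per report, matching ≈3.3 events/report); 5% of
cases re-emitted as later-dated duplicates; 10% of start/event dates
degraded to month precision; 1% of background reports carrying a target
drug as concomitant to exercise role filtering.  Planted associations
multiply the target drug's selection weight for a term by the configured
relative risk, leaving the background untouched (classic
signal-injection design); the preset plants RRs {15, 5, 1} per drug at
mid-frequency ranks, where RR = 15 yields expected case counts well above
10.  Term selection uses Gumbel top-k perturbation per drug group, which
keeps weighted sampling without replacement vectorized and deterministic.

What the generator does **not** emulate: reporting trends over calendar
time, correlated term co-occurrence (real syndromes), drug polypharmacy
beyond a single concomitant flag, regional coding quirks, or
reporting-probability heterogeneity across outcomes.  Passing recovery
tests therefore demonstrates correctness of the statistical machinery
under the stated sampling model, not performance on real FAERS data —
the published real-data signal tables are not reproducible without the
actual extract, and no test claims otherwise.

## Problem sizes and determinism

The standard verification sizes are n = 20,000 reports × 10 seeds for
signal recovery and specificity, n = 500 × 20 seeds per parameter pair
for Weibull recovery, and n = 4,000–6,000 for dialect/dedup round trips —
sizes at which the binomial sampling error of every checked margin is
well below the tested tolerances.  All randomness flows from explicit
seeds through one generator per dataset with a fixed draw order, so a
(config, seed) pair yields byte-identical files and the whole pipeline is
byte-deterministic given (dataset, config).

## Known limitations

- Multi-axial MedDRA is out of scope: the PT→SOC map is single-valued,
  and only the PT and SOC levels exist (no HLT/HLGT).
- The comparator for a queried drug is "all reports where it is not
  primary suspect", which includes the other study drug's reports; a
  report that is primary suspect for *both* targets counts in both
  numerators and is imperfectly removed from the cross-comparator — a
  corner the deduplicated data essentially never produces.
- No censoring or competing-risks handling in the Weibull model; onset
  times are treated as fully observed.
- Bonferroni is the only multiplicity correction offered, matching the
  published analysis; FDR alternatives were left out deliberately.
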