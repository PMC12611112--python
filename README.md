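# pvsignal

Disproportionality signal detection and time-to-onset analysis for
FAERS-style spontaneous adverse-event reports, built around a comparative
safety screen of the two copper chelators used in Wilson's disease,
penicillamine and trientine.

Spontaneous-report databases such as the FDA Adverse Event Reporting System
(FAERS) publish each quarter as seven `$`-delimited tables (DEMO, DRUG,
REAC, THER, INDI, OUTC, RPSR).  `pvsignal` turns that raw dialect into a
reproducible pharmacovigilance pipeline:

1. **Ingest & deduplicate** — parse the quarterly tables, join them on
   `PRIMARYID`, then keep one record per `CASEID` (latest `FDA_DT`, ties
   broken by highest `PRIMARYID`, the FDA-recommended rule).
2. **Normalize & select** — recognise study drugs through an explicit
   synonym dictionary (generic/trade names and known misspellings such as
   "Penicilamine") and keep only reports where the target drug is the
   *Primary Suspect*.
3. **Screen** — for every (drug, preferred term) pair build the fourfold
   table (a, b, c, d) against all other reports and compute three
   disproportionality statistics:

   | method | statistic | positive when |
   |---|---|---|
   | ROR | ad/bc, 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` | CI low > 1 and a ≥ 3 |
   | PRR | [a/(a+b)]/[c/(c+d)] with Pearson χ² | PRR > 2, χ² > 4, a ≥ 3 |
   | BCPNN | IC = log₂(a·N/((a+c)(a+b))), bounds IC ± 2·√V(IC) | IC025 > 0 |

   A pair is a *signal* only when all three methods are positive; Fisher
   exact p-values with per-drug Bonferroni adjustment feed the volcano
   table, and an editable exclusion list removes product-quality/use-issue
   terms after screening.
4. **Aggregate & model** — roll positive signals up to System Organ
   Classes, fit a two-parameter Weibull to onset times (days from therapy
   start to event, Tukey-fence outlier exclusion) and classify the hazard
   (shape β < 1 = early failure), and compute sex-stratified RORs
   (ROR > 1 = female-predominant).
5. **Simulate** — a first-class synthetic-data generator emits the exact
   FAERS dialect with planted drug-event associations at known relative
   risk, injected duplicates, realistic missingness and Weibull onset
   times, so the whole pipeline is verifiable at desk scale without the
   real download.

## Worked example

```
$ pvsignal simulate --out-dir ds --seed 42 --n-reports 20000
dataset written to ds
$ pvsignal signals --data-dir ds --drug penicillamine --out-dir out
penicillamine: 1015 reports, 3367 pairs, 4 combined signals (3 PTs excluded)
$ pvsignal tto --data-dir ds --drug penicillamine --out-dir out
penicillamine: n=803 median=152d alpha=247.75 beta=0.64 (early failure)
```

The dataset plants "Event term 012" at relative risk 15 and
"Event term 025" at relative risk 5 for penicillamine.  The combined
signals in `out/signals_penicillamine.csv`:

```
            pt   n   ror  ror_low  prr    chi2   ic  ic025
Event term 012 450 10.95     9.72 9.62 2336.23 2.74   2.58
Event term 025  46  3.14     2.30 3.12   56.86 1.49   1.04
Event term 051  11  2.09     1.12 2.08    5.58 0.98   0.10
Event term 096   5  2.81     1.10 2.81    5.07 1.36   0.10
```

Both planted terms are recovered with all three methods positive (n is the
case count a; the two extra terms are chance positives of the kind the
three-way AND keeps rare).  The onset-time fit recovers an early-failure
pattern: β = 0.64 < 1, a decreasing hazard, with the caveat that Tukey
fences truncate the long Weibull tail and shift α below the generating
scale.  `pvsignal describe`, `pvsignal subgroup` and `pvsignal report-all`
emit the demographic, sex-stratified and remaining tables.

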