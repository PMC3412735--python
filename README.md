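# gitransit

Statistical-moment analysis and simulation of biomagnetic
gastrointestinal-transit recordings in small animals.

AC biosusceptometry follows a magnetic test meal — a ferrofluid drink or
a ferrite pellet — through the gut by placing a gradiometric sensor over
the gastric and cecal projections of the abdomen and logging the signal
intensity (mV) every 10 minutes for seven hours or more. The gastric
signal falls as the stomach empties; the cecal signal rises as the meal
arrives. `gitransit` turns those two traces into the three transit
summaries used to compare meal regimes and treatment effects, and ships
a generative model of the whole experiment so every step is testable
against closed-form oracles.

## The statistic

Let R(t) be the gastric retention fraction (normalized to R = 1 at
ingestion) and C(t) the cumulative cecal arrival fraction (normalized to
its plateau). The package computes first moments of the underlying rate
distributions as areas, by the trapezoidal rule on the 10-min sample
grid:

- **MGET** (mean gastric emptying time) = ∫ R(t) dt
- **MCAT** (mean cecum arrival time) = ∫ (1 − C(t)) dt
- **MSITT** (mean small-intestinal transit time) = MCAT − MGET

plus the legacy half-emptying time **t₅₀** (first crossing of R = 0.5)
for comparison. Group results are mean ± SD; liquid-vs-solid contrasts
within the same animals use the paired Student t-test, with the t tail
probability computed in-package from the regularized incomplete beta
function. The simulator couples a stomach (first-order emptying for
liquids, power-exponential exp(−(kt)^β) with a lag for solids) to a
chain of N well-mixed intestinal compartments draining into the cecum,
and maps compartment masses to mV through a first-order gradiometer
response V = gain · m · (d⁻ᵖ − (d+L)⁻ᵖ) with a 15-cm baseline L.

## Worked example

```python
from gitransit import TransitStudy

study = TransitStudy.from_simulation(n_animals=3, seed=11)
print(study.fit().summary())
```

```
Gastrointestinal transit — statistical-moment analysis
=======================================================

animal_id   meal  mget_min  mcat_min  msitt_min  t50_min  warnings
     rat1 liquid      81.2     189.0      107.8     56.2
     rat2 liquid     104.7     183.5       78.8     80.6  emptying incomplete at end of record (final retention 0.022 > 0.02); MGET is truncated
     rat3 liquid      91.2     179.4       88.2     63.0  arrival plateau not reached (final value 0.965 < 0.980); MCAT is right-censored and biased low
     rat1  solid     136.2     231.1       95.0    124.0
     rat2  solid     171.3     262.1       90.7    161.0  arrival plateau not reached (final value 0.953 < 0.980); MCAT is right-censored and biased low
     rat3  solid     153.0     255.6      102.6    148.2  arrival plateau not reached (final value 0.969 < 0.980); MCAT is right-censored and biased low

 liquid: MGET 92.3 ± 11.8   MCAT 184.0 ± 4.8   MSITT 91.6 ± 14.8   (n=3)
  solid: MGET 153.5 ± 17.6   MCAT 249.6 ± 16.3   MSITT 96.1 ± 6.0   (n=3)

Paired liquid vs solid (two-sided):
  MGET   t = -18.082, df = 2, p = 0.0030 *
  MCAT   t = -5.580, df = 2, p = 0.0306 *
  MSITT  t = -0.516, df = 2, p = 0.6570
```

(Warnings column abbreviated here only by line wrapping; the values are
verbatim program output.) The reading: the solid meal empties much more
slowly (MGET 153 vs 92 min) and reaches the cecum later (MCAT 250 vs
184 min), while the small-intestinal transit itself (MSITT ≈ 90–96 min)
is the same for both meals — stomach physiology, not intestinal
propulsion, distinguishes the regimes. Each animal serves as its own
control, which is what the paired test exploits. Quality warnings
(incomplete emptying, censored arrival plateau) stay attached to the
animal they concern.

The same analysis is available from the shell:

```
gitransit simulate --meal liquid --n-animals 6 --seed 1 --out recs/
gitransit analyze recs/*.csv --out results.csv
gitransit validate --seed 1          # kill-and-measure study, prints Pearson r
gitransit table1                     # reference-table reproduction report
gitransit run --seed 1 --out run1/   # full paired cohort end to end
```

`gitransit table1` recomputes every derivable cell of the embedded
six-rat reference table (per-animal MSITT identities, rounded Mean and
SD rows, paired contrasts) and exits non-zero on any mismatch beyond the
documented one-minute independent-rounding artifact.

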