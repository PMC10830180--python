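# medsignal

Automated categorization and signal monitoring of spontaneously reported
medication errors.

Pharmacovigilance teams must classify every reported medication error —
an unintended failure in the treatment or vaccination process — and watch
for safety signals in the resulting stream of individual case safety
reports. Doing this manually is slow and inconsistent. `medsignal`
implements a rule-based classifier that works directly on MedDRA-style
preferred terms (PTs), together with the surrounding machinery a safety
department needs: disproportionality screening, trend series, tabulations,
and a synthetic report generator so everything can be exercised without
licensed terminology or proprietary safety data.

## The categorization algorithm

Each dose of each suspect product in a case is assigned exactly one
category from the PT set *E* attributed to that (product, dose), in strict
precedence order:

1. **conflicting** — *E* contains both the PT *"Circumstance or
   information capable of leading to medication error"* and a PT
   containing the word *"intercepted"*. Mutually inconsistent coding; the
   case is routed to data correction.
2. **potential error** — *E* contains the circumstance PT.
3. **intercepted error** — *E* contains an "intercepted" PT (the error was
   caught before reaching the patient).
4. Otherwise, with *M* = *E* ∩ SMQ("medication error") and *H* = the
   non-*M* terms that are valid harm events:
   *M* = ∅ → **no medication error**; *H* = ∅ → **medication error
   without harm**; else → **medication error with harm**, with *H* the
   coreported adverse events.

Coreported events count as harm by default (no causality assessment). The
exception is an **exclusion set** derived from the terminology hierarchy:
PTs whose primary SOC is *product issues*, PTs under the HLGT *off-label
uses and intentional product misuses/uses issues*, PTs under the HLTs
*adverse effect absent*, *exposure associated with pregnancy, delivery and
lactation*, *normal newborn status*, *normal pregnancy, labor and
delivery*, and the PT *breastfeeding*.

## Signal detection

For a product–event pair, distinct cases are cross-tabulated per stratum
(sex × age group × country × half-year) as a 2×2 table and the
proportional reporting ratio PRR = (a/(a+b)) / (c/(c+d)) is pooled across
strata with the Mantel–Haenszel estimator; the 95% CI uses the
Greenland–Robins variance on the log scale (Woolf's formula in the
single-stratum case). A pair is a **signal of disproportionate reporting**
when the lower 95% confidence limit is strictly above 2 and at least 3
cases report the pair.

## Worked example

```python
from medsignal import (GeneratorConfig, classify_database, detect_signals,
                       generate_cases, mini_dictionary, ratio_series)

dictionary = mini_dictionary()
cases, truth = generate_cases(GeneratorConfig(seed=42, n_cases=2000), dictionary)
result = classify_database(cases, dictionary)
print(result.table["category"].value_counts())
```

```
category
no_medication_error    1482
me_without_harm         621
me_with_harm            325
potential_error         123
intercepted_error        93
conflicting              30
```

The 2,674 rows are (case, product, dose) triples: the same case may be an
error for one co-administered product and a non-error for the other. The
30 conflicting triples are also collected in `result.conflicts`, the
integrity report of cases needing correction. The trend of no-harm errors
over all reports for one product:

```python
print(ratio_series(result.table, "HZ-VAX", "me_without_harm", bin_width="quarter").head(4))
```

```
 bin_start  numerator  denominator    ratio
2017-10-01         25          115 0.217391
2018-01-01         28          118 0.237288
2018-04-01         32          125 0.256000
2018-07-01         31          113 0.274336
```

Each ratio is the share of the product's distinct cases in that quarter
classified as an error without harm — proportions, not absolute counts,
so reporting-volume swings cancel. Finally, a disproportionality screen:

```python
top = detect_signals(result.table)[0]
print(top.product_name, top.pt_name, round(top.prr, 2), top.is_signal)
```

```
FLU-VAX Circumstance or information capable of leading to medication error 2.04 False
```

The pair reports PRR 2.04 with CI [1.43, 2.89] over 73 cases: not a
signal, because the lower confidence limit does not exceed 2.

The same pipeline is available from the shell:

```bash
medsignal simulate --out-dir data --seed 42 --n-cases 2000
medsignal classify --cases data/cases.jsonl --dict data/terms.csv \
    --smq data/smq.csv --out data/cls.csv --conflicts data/conflicts.csv
medsignal signal --classifications data/cls.csv --out data/signals.csv
medsignal trend --classifications data/cls.csv --product HZ-VAX \
    --category me_without_harm --out data/trend.csv
medsignal table --classifications data/cls.csv --dict data/terms.csv \
    --smq data/smq.csv --product HZ-VAX --period 2019-01-01:2019-12-31 \
    --out data/table.csv
```

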