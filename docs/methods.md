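# Methods

## Scope and data model

`medsignal` operates on spontaneous (unsolicited) individual case safety
reports. One case carries reporter metadata (receipt date, country, sex,
age group), one or more suspect products (co-administration), one or more
recorded doses per product, and zero or more PT-coded events, each
optionally linked to a product and dose. Classification happens at the
(case, product, dose) triple, because one report can legitimately mix
categories: an error after dose 2 but not dose 1, or an error for one
co-administered product only.

The case-exchange format is JSON-lines rather than ICH E2B XML: the
classifier needs exactly the fields above, and product/dose linkage — the
one E2B(R3) feature the algorithm exploits — is carried as two optional
fields on each event.

### Event attribution

Spontaneous data often omit linkage, and an unlinked event must not
silently vanish from any classification. The attribution rule is
deliberately conservative:

* event linked to (product, dose): attributed to that dose only;
* event linked to a product without a dose: attributed to all doses of
  that product;
* fully unlinked event: attributed to all doses of all suspect products.

This is a documented design choice, not something the reporting stream
can express; it errs toward over-counting harm, consistent with treating
coreported events as harm by default.

## Terminology

The dictionary models the PT → HLT → HLGT → SOC lineage (a PT may link to
several SOCs, exactly one of them primary) plus named SMQ membership
lists. All name matching is case-insensitive with internal whitespace
collapsed; the stored spelling is canonical for output. PTs are matched
by name rather than code because the classification rules are phrased
over names (including the substring rule for "intercepted", implemented
as a whole-word, case-insensitive match so that a hypothetical
"unintercepted" would not trigger).

The exclusion set (terms that never count as harm) is **derived from the
hierarchy at load time** — primary-SOC rule, HLGT rule, HLT rule,
explicit-PT rule — rather than stored as a hard-coded list, so a
terminology version update only requires a refreshed dictionary file.
Each member records which rule(s) admitted it, and a self-audit test
re-checks every member against the raw records.

A term can be both an SMQ member and an exclusion member (e.g. device
PTs with primary SOC *product issues*). The classifier tests SMQ
membership first, so such a term counts as the error itself; the
exclusion set only filters the *non*-SMQ remainder.

## Classification semantics

The decision procedure and its precedence (conflicting > potential >
intercepted > SMQ/harm partition) are described in the README. Two
scoping choices matter:

* "All PTs reported" in the without-harm rule ranges over the
  dose-attributed set *E*, not the whole case — consistent with
  classifying "for the dose of product X". The whole-case reading would
  make co-administration classification impossible.
* The intercepted rule's temporal qualifier ("circumstance not reported
  after a dose") is implemented as set membership within *E*, not date
  arithmetic, since event dates are frequently absent.

`no_medication_error` is an explicit sixth output value: non-error
reports must flow through to provide denominators for trend ratios and
contingency tables. In strict mode an unknown reported PT aborts with an
error identifying the case; in lenient mode it is treated as a non-SMQ,
non-excluded harm candidate and logged, the conservative reading for
harm counting.

## Disproportionality statistics

The proportional reporting ratio of a 2×2 table of distinct cases is
PRR = (a/(a+b)) / (c/(c+d)), target product vs all other products in the
database. Strata (default: sex × age group × country × half-year of
receipt) are pooled with the Mantel–Haenszel-type ratio

PRR_MH = Σₖ aₖ(cₖ+dₖ)/Nₖ / Σₖ cₖ(aₖ+bₖ)/Nₖ,

with the Greenland–Robins variance for ln PRR_MH. For a single stratum
this variance reduces algebraically to Woolf's 1/a − 1/(a+b) + 1/c −
1/(c+d), so the pooled estimator collapses exactly to the crude PRR and
Woolf CI — a property the tests verify to 1e-12 relative tolerance.

Numerical edge handling: a pair with an empty product or comparator
margin, or with c = 0 (infinite ratio), is flagged **non-estimable**
rather than reported as a number; output tables never carry NaN or
infinity. An optional Haldane–Anscombe correction adds 0.5 to all four
cells when enabled (off by default). Uninformative strata are dropped
from pooling; the case count n = Σ aₖ sums over all strata.

The signal rule — lower 95% confidence limit strictly above 2 **and** at
least 3 cases — is strict on both counts: ci_low = 2.0 exactly is not a
signal, and two cases are never a signal regardless of the ratio.

Counting is at the distinct-case level throughout (a case with two doses
or two qualifying PTs counts once per cell), matching the convention that
tabulation grand totals are distinct cases, not column sums.

## Trend series and tabulations

Time bins default to calendar months keyed on receipt date (quarter,
half-year and year also available); bins are contiguous and half-open. A
bin with no reports for the product has an absent ratio (NaN), never 0.

When one case has doses in several categories for the same product, the
reporting layer rolls the case up to a single category using the fixed
precedence conflicting > potential > intercepted > with-harm >
without-harm > no-error, i.e. rule order first, then harm before
no-harm. This makes the six per-bin category ratios of a product a true
partition (they sum to 1 in every non-empty bin), which in turn makes
ratio trends comparable across categories. For cases whose doses agree —
the overwhelming majority — the rollup coincides with the dose-level
category.

HLT composition percentages can legitimately sum to more than 100 per
bin, because one case may report error terms under several HLTs; this
mirrors the tabulation footnote convention and is documented in the
function's output contract.

## Synthetic data

The generator exists so every other module is testable without licensed
MedDRA or proprietary safety data. It has two parts.

**Mini-dictionary.** A fixed, curated vocabulary of 63 PTs: the
circumstance PT, two "intercepted" PTs, a 31-member "medication error"
SMQ drawn from the vaccination-error vocabulary (administration,
preparation, storage, dispensing, prescribing errors …), ~20 harm PTs
from the common post-vaccination reactogenicity vocabulary (injection
site reactions, pyrexia, headache …), and at least one PT per exclusion
rule, including one PT with a secondary SOC linkage. Being curated, the
written files are byte-identical across runs by construction.

**Case generator.** For every (case, product, dose) triple an intended
category is drawn first — conflicting with probability `conflict_rate`,
otherwise from `category_mix` — and a PT set *realizing* that category is
then emitted with explicit (product, dose) links. The ground-truth table
therefore serves as an exact round-trip oracle: classifier output must
match it on 100% of triples, and any mismatch is a bug, not sampling
noise. Excluded-pool terms are injected into a fraction of error cases
to exercise exclusion-neutrality.

Default study conditions: 1,000 cases over October 2017 – December 2020;
two products at 75/25 market share; category mix 55% no error, 25%
without harm, 12% with harm, 4% potential, 4% intercepted; conflict rate
1%; co-administration 10%; second dose 20%; six reporting countries
dominated by the US. These emulate the reporting profile of a recently
launched adult vaccine. An optional launch-spike window replaces the
without-harm probability (default scenario: 52% during the first launch
month), reproducing the qualitative launch-period phenomenon that
error reporting peaks shortly after licensure.

What the generator does **not** emulate: duplicate reports, reporter
qualifications, narrative text, coding drift over time, secular trends in
reporting volume, and correlation between demographics and category.
Passing tests therefore demonstrate the correctness of the machinery on
cleanly coded data, not robustness to real-world coding noise — the
lenient modes and the conflict report are the hooks for the latter.

## Problem sizes and calibration checks

The acceptance checks run at: 4,096-subset exhaustive classifier
equivalence against an independently transcribed rule oracle; a
10,000-case round-trip database (~13,000 triples); 1,000-replicate null
simulation for CI calibration (coverage required within 93–97%);
20-seed power study for a pair injected at a 10× reporting rate (0.5 vs
0.05, ~60 co-reporting cases), required detected in ≥19/20 seeds;
chi-square goodness of fit of the category mix at α = 0.01 on 10,000
cases. These sizes give stable statistics while keeping a full suite run
in well under a minute of compute.

## Known limitations

* No causality assessment: with multiple suspects in one with-harm
  report, the harmed product cannot always be identified; the attribution
  rule then assigns the harm to every suspect dose.
* The SMQ is a flat membership list; the narrow/broad scope distinction
  of real SMQs is not modelled.
* The exclusion list derivation must be re-validated after a terminology
  version update (new branches may appear under the keyed names).
* PRR-based screening is a hypothesis-generating device; reporting
  ratios from spontaneous data quantify reporting behaviour, not risk.
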