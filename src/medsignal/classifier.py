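"""Rule-based categorization of medication errors per (case, product, dose).

Each dose of each suspect product in a case receives exactly one of six
categories, decided over E, the set of PT-coded events attributed to that
dose (see :func:`medsignal.case_store.attributed_events`), in strict
precedence order:

1. ``conflicting`` — E contains both the circumstance PT ("circumstance or
   information capable of leading to medication error") and at least one PT
   containing the word "intercepted". Mutually inconsistent coding; the
   case needs correction.
2. ``potential_error`` — E contains the circumstance PT.
3. ``intercepted_error`` — E contains an "intercepted" PT (circumstance
   absent, by precedence).
4. Otherwise partition E into M = E ∩ SMQ("medication error"),
   X = (E \\ M) ∩ exclusion set, H = E \\ M \\ X:
   M empty -> ``no_medication_error``; H empty -> ``me_without_harm``;
   else ``me_with_harm`` with H as the harm terms.

Coreported events are counted as harm by default, with no causality
assessment; only the terminology-derived exclusion set disqualifies a
coreported term. ``no_medication_error`` is an explicit output value so
that non-error reports remain available as denominators downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

from .case_store import CaseReport, attributed_events
from .dictionary import CIRCUMSTANCE_PT, Dictionary
from .errors import ClassificationError, MedsignalError
from ._text import canon, contains_intercepted

logger = logging.getLogger(__name__)


class Category(str, Enum):
    POTENTIAL_ERROR = "potential_error"
    INTERCEPTED_ERROR = "intercepted_error"
    ME_WITHOUT_HARM = "me_without_harm"
    ME_WITH_HARM = "me_with_harm"
    CONFLICTING = "conflicting"
    NO_MEDICATION_ERROR = "no_medication_error"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: All categories, in reporting order.
CATEGORIES = tuple(Category)

#: Case-level rollup precedence used by the reporting layer: when one case
#: has doses in several categories, the case is counted once, under the
#: first matching category in this order (rule order first, then harm
#: before no-harm, with non-errors last).
ROLLUP_PRECEDENCE = (
    Category.CONFLICTING,
    Category.POTENTIAL_ERROR,
    Category.INTERCEPTED_ERROR,
    Category.ME_WITH_HARM,
    Category.ME_WITHOUT_HARM,
    Category.NO_MEDICATION_ERROR,
)


@dataclass(frozen=True)
class DoseClassification:
    case_id: str
    product_name: str
    dose_index: int
    category: Category
    trigger_terms: frozenset[str]
    harm_terms: frozenset[str]
    excluded_terms: frozenset[str]


def classify_dose(
    case: CaseReport,
    product_name: str,
    dose_index: int,
    dictionary: Dictionary,
    mode: str = "strict",
) -> DoseClassification:
    """Categorize one (product, dose) of a case.

    In ``strict`` mode a reported PT absent from the dictionary raises
    :class:`ClassificationError`; in ``lenient`` mode the term is treated
    as a non-SMQ, non-excluded harm candidate and a warning is logged.
    """
    if not any(
        p.product_name == product_name and any(d.dose_index == dose_index for d in p.doses)
        for p in case.products
    ):
        raise ClassificationError(
            f"case {case.case_id}: no dose {dose_index} of product {product_name!r}"
        )

    raw = attributed_events(case, product_name, dose_index)
    smq = dictionary.me_smq
    exclusion = dictionary.exclusion

    # resolve to canonical dictionary spellings; unknown terms handled per mode
    known: dict[str, str] = {}  # canonical -> display spelling
    unknown: set[str] = set()
    for name in raw:
        if dictionary.has_pt(name):
            known[canon(name)] = dictionary.display_name(name)
        else:
            if mode == "strict":
                raise ClassificationError(
                    f"case {case.case_id}: reported term {name!r} not in dictionary"
                )
            logger.warning(
                "case %s: term %r not in dictionary; treated as harm candidate",
                case.case_id,
                name,
            )
            unknown.add(name)

    has_circumstance = CIRCUMSTANCE_PT in known
    intercepted = {d for k, d in known.items() if contains_intercepted(k)}
    me_terms = {d for k, d in known.items() if k in smq.member_pt_names}
    non_me = {d for k, d in known.items() if k not in smq.member_pt_names}
    excluded = {d for d in non_me if d in exclusion}
    harm = (non_me - excluded) | unknown

    def result(category, trigger=(), harm_out=()):
        return DoseClassification(
            case_id=case.case_id,
            product_name=product_name,
            dose_index=dose_index,
            category=category,
            trigger_terms=frozenset(trigger),
            harm_terms=frozenset(harm_out),
            excluded_terms=frozenset(excluded),
        )

    circumstance_display = known.get(CIRCUMSTANCE_PT)
    if has_circumstance and intercepted:
        return result(Category.CONFLICTING, {circumstance_display} | intercepted)
    if has_circumstance:
        return result(Category.POTENTIAL_ERROR, {circumstance_display})
    if intercepted:
        return result(Category.INTERCEPTED_ERROR, intercepted)
    if not me_terms:
        return result(Category.NO_MEDICATION_ERROR)
    if not harm:
        return result(Category.ME_WITHOUT_HARM, me_terms)
    return result(Category.ME_WITH_HARM, me_terms, harm)


def classify_case(
    case: CaseReport, dictionary: Dictionary, mode: str = "strict"
) -> list[DoseClassification]:
    """One classification per (product, dose), in product order then dose order.

    The same case may legitimately land in different categories across
    products (co-administration: only one product was misadministered) and
    across doses (an error reported after the second dose only).
    """
    out = []
    for product in case.products:
        for dose in sorted(product.doses, key=lambda d: d.dose_index):
            try:
                out.append(
                    classify_dose(case, product.product_name, dose.dose_index, dictionary, mode)
                )
            except MedsignalError as exc:
                raise ClassificationError(
                    f"case {case.case_id}, product {product.product_name!r}, "
                    f"dose {dose.dose_index}: {exc}"
                ) from exc
    return out


TABLE_COLUMNS = [
    "case_id",
    "product_name",
    "dose_index",
    "category",
    "trigger_terms",
    "harm_terms",
    "excluded_terms",
    "event_terms",
    "receipt_date",
    "country",
    "sex",
    "age_group",
]


@dataclass
class ClassificationResult:
    """Flat dose-level classification table plus the conflict integrity report."""

    table: pd.DataFrame  # columns = TABLE_COLUMNS
    conflicts: pd.DataFrame  # subset of table with category == conflicting
    n_cases: int
    n_skipped: int
    errors: list[str]


def _join(terms: Iterable[str]) -> str:
    return "|".join(sorted(terms))


def classify_database(
    cases: Iterable[CaseReport], dictionary: Dictionary, mode: str = "strict"
) -> ClassificationResult:
    """Classify a stream of cases into a flat dose-level table.

    Each row joins one :class:`DoseClassification` with the case metadata
    needed downstream (receipt date, country, sex, age group) plus the full
    attributed event-term list. Conflicting rows are additionally collected
    into an integrity report for follow-up and correction. In ``lenient``
    mode, per-case failures are skipped and summarized; ``strict`` aborts.
    """
    rows = []
    errors: list[str] = []
    n_cases = 0
    n_skipped = 0
    for case in cases:
        try:
            classifications = classify_case(case, dictionary, mode)
        except MedsignalError as exc:
            if mode == "strict":
                raise
            errors.append(str(exc))
            n_skipped += 1
            continue
        n_cases += 1
        for cl in classifications:
            events = attributed_events(case, cl.product_name, cl.dose_index)
            display = {
                dictionary.display_name(e) if dictionary.has_pt(e) else e for e in events
            }
            rows.append(
                {
                    "case_id": cl.case_id,
                    "product_name": cl.product_name,
                    "dose_index": cl.dose_index,
                    "category": cl.category.value,
                    "trigger_terms": _join(cl.trigger_terms),
                    "harm_terms": _join(cl.harm_terms),
                    "excluded_terms": _join(cl.excluded_terms),
                    "event_terms": _join(display),
                    "receipt_date": case.receipt_date.isoformat(),
                    "country": case.country,
                    "sex": case.sex,
                    "age_group": case.age_group,
                }
            )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    conflicts = table[table["category"] == Category.CONFLICTING.value].reset_index(drop=True)
    if n_skipped:
        logger.warning("skipped %d case(s) with classification errors", n_skipped)
    return ClassificationResult(
        table=table, conflicts=conflicts, n_cases=n_cases, n_skipped=n_skipped, errors=errors
    )
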