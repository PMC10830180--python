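"""Disproportionality statistics: stratified proportional reporting ratio.

For a product–event pair, each stratum (by default sex x age group x
country x half-year of receipt) contributes a 2x2 table of **distinct
cases**:

====================  ==============  ==============
cases                  event present   event absent
target product         a               b
all other products     c               d
====================  ==============  ==============

Crude PRR = (a/(a+b)) / (c/(c+d)). Strata are pooled with the
Mantel–Haenszel ratio estimator

    PRR_MH = sum_k a_k (c_k+d_k)/N_k  /  sum_k c_k (a_k+b_k)/N_k

with the Greenland–Robins variance for ln PRR_MH, which collapses exactly
to the Woolf variance 1/a - 1/(a+b) + 1/c - 1/(c+d) for a single stratum.
The 95% CI uses the normal approximation on the log scale.

A **signal of disproportionate reporting** is declared when the lower 95%
confidence limit of the stratified PRR is strictly above 2 and at least 3
cases report the pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .errors import NonEstimableError

DEFAULT_STRATA = ("sex", "age_group", "country", "half_year")


@dataclass(frozen=True)
class ContingencyTable:
    stratum_key: tuple
    a: int  # target product & target event
    b: int  # target product & other events only
    c: int  # other products & target event
    d: int  # other products & other events only

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class PrrEstimate:
    """Pooled PRR with log-normal CI; ``estimable`` is False when any piece
    of the estimate is undefined (no informative stratum, zero margin)."""

    prr: float
    ci_low: float
    ci_high: float
    n_cases: int
    estimable: bool


@dataclass(frozen=True)
class SignalResult:
    product_name: str
    pt_name: str
    n_cases: int
    prr: float
    ci_low: float
    ci_high: float
    is_signal: bool
    estimable: bool


def _half_year(receipt_date: str) -> str:
    y, m = receipt_date[:4], int(receipt_date[5:7])
    return f"{y}H{1 if m <= 6 else 2}"


def case_level_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the dose-level classification table to one row per case.

    Columns: case_id, receipt_date, country, sex, age_group, half_year,
    products (frozenset), events (frozenset of reported PT names).
    """
    rows = []
    for case_id, grp in table.groupby("case_id", sort=True):
        first = grp.iloc[0]
        events: set[str] = set()
        for terms in grp["event_terms"]:
            if terms:
                events.update(terms.split("|"))
        rows.append(
            {
                "case_id": case_id,
                "receipt_date": first["receipt_date"],
                "country": first["country"],
                "sex": first["sex"],
                "age_group": first["age_group"],
                "half_year": _half_year(first["receipt_date"]),
                "products": frozenset(grp["product_name"]),
                "events": frozenset(events),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "case_id",
            "receipt_date",
            "country",
            "sex",
            "age_group",
            "half_year",
            "products",
            "events",
        ],
    )


def build_contingency(
    table: pd.DataFrame,
    product_name: str,
    pt_name: str,
    strata: Sequence[str] = DEFAULT_STRATA,
) -> list[ContingencyTable]:
    """Stratified 2x2 tables for one product–event pair, distinct-case counted.

    Empty strata are omitted; each emitted table partitions the distinct
    cases of its stratum. Unknown product or PT (never seen in the table)
    raises :class:`LookupError`.
    """
    cases = case_level_frame(table)
    if not any(product_name in p for p in cases["products"]):
        raise LookupError(f"product {product_name!r} not present in classification table")
    if not any(pt_name in e for e in cases["events"]):
        raise LookupError(f"PT {pt_name!r} not reported in classification table")
    out = []
    for key, grp in cases.groupby(list(strata), sort=True):
        has_p = grp["products"].apply(lambda s: product_name in s)
        has_e = grp["events"].apply(lambda s: pt_name in s)
        a = int((has_p & has_e).sum())
        b = int((has_p & ~has_e).sum())
        c = int((~has_p & has_e).sum())
        d = int((~has_p & ~has_e).sum())
        if not isinstance(key, tuple):
            key = (key,)
        out.append(ContingencyTable(stratum_key=key, a=a, b=b, c=c, d=d))
    return out


def prr(table: ContingencyTable, continuity: bool = False) -> float:
    """Crude proportional reporting ratio of one 2x2 table.

    With ``continuity`` a Haldane–Anscombe +0.5 is added to all four cells.
    Raises :class:`NonEstimableError` when a margin is empty or when c = 0
    without correction (the ratio would be infinite, which is reported as
    non-estimable rather than a number).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if a + b == 0 or c + d == 0:
        raise NonEstimableError("empty product or comparator margin")
    if c == 0:
        raise NonEstimableError("no comparator cases with the event (c = 0)")
    return (a / (a + b)) / (c / (c + d))


def stratified_prr(
    tables: Sequence[ContingencyTable],
    alpha: float = 0.05,
    continuity: bool = False,
) -> PrrEstimate:
    """Mantel–Haenszel-pooled PRR with Greenland–Robins log-scale CI.

    Strata with an empty product or comparator margin are uninformative
    and dropped from pooling; ``n_cases`` sums a over all given strata.
    Collapses to the crude PRR and Woolf CI for a single stratum. Returns
    an explicitly non-estimable result (never NaN/inf posing as a value)
    when no stratum is informative or a pooled margin is zero.
    """
    n_cases = sum(t.a for t in tables)
    not_estimable = PrrEstimate(
        prr=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
        n_cases=n_cases, estimable=False,
    )
    num = den = var_num = 0.0
    informative = 0
    for t in tables:
        a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
        if continuity:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        n1, n0 = a + b, c + d
        if n1 == 0 or n0 == 0:
            continue
        informative += 1
        big_n = n1 + n0
        num += a * n0 / big_n
        den += c * n1 / big_n
        var_num += ((a + c) * n1 * n0 - a * c * big_n) / big_n**2
    if informative == 0 or num == 0 or den == 0:
        return not_estimable
    estimate = num / den
    variance = var_num / (num * den)
    if variance <= 0:
        return not_estimable
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(variance)
    log_prr = math.log(estimate)
    return PrrEstimate(
        prr=estimate,
        ci_low=math.exp(log_prr - half),
        ci_high=math.exp(log_prr + half),
        n_cases=n_cases,
        estimable=True,
    )


def signal_rule(
    estimate: PrrEstimate, threshold: float = 2.0, min_cases: int = 3
) -> bool:
    """The signal-of-disproportionate-reporting decision.

    True iff the estimate is estimable, its lower confidence limit is
    **strictly** above ``threshold`` and at least ``min_cases`` distinct
    cases report the pair. A pair below the case minimum is never a
    signal no matter how extreme its ratio.
    """
    return bool(
        estimate.estimable
        and estimate.ci_low > threshold
        and estimate.n_cases >= min_cases
    )


def detect_signals(
    table: pd.DataFrame,
    strata: Sequence[str] = DEFAULT_STRATA,
    alpha: float = 0.05,
    threshold: float = 2.0,
    min_cases: int = 3,
    continuity: bool = False,
) -> list[SignalResult]:
    """Screen every observed product–event pair for disproportionate reporting.

    One result per pair with at least one reporting case. A pair is a
    signal iff it is estimable, its lower CI bound is strictly above
    ``threshold`` and it has at least ``min_cases`` distinct cases.
    Sorted by ci_low descending (non-estimable pairs last), ties broken by
    (product, PT).
    """
    cases = case_level_frame(table)
    # accumulate stratified counts in one pass over cases
    totals: dict[tuple, int] = {}
    prod_counts: dict[tuple, dict[str, int]] = {}
    evt_counts: dict[tuple, dict[str, int]] = {}
    pair_counts: dict[tuple, dict[tuple[str, str], int]] = {}
    pairs: set[tuple[str, str]] = set()
    for row in cases.itertuples(index=False):
        key = tuple(getattr(row, s) for s in strata)
        totals[key] = totals.get(key, 0) + 1
        pc = prod_counts.setdefault(key, {})
        ec = evt_counts.setdefault(key, {})
        xc = pair_counts.setdefault(key, {})
        for p in row.products:
            pc[p] = pc.get(p, 0) + 1
        for e in row.events:
            ec[e] = ec.get(e, 0) + 1
        for p in row.products:
            for e in row.events:
                xc[(p, e)] = xc.get((p, e), 0) + 1
                pairs.add((p, e))

    results = []
    for product, event in sorted(pairs):
        tables = []
        for key, total in totals.items():
            np_ = prod_counts[key].get(product, 0)
            ne = evt_counts[key].get(event, 0)
            a = pair_counts[key].get((product, event), 0)
            tables.append(
                ContingencyTable(
                    stratum_key=key, a=a, b=np_ - a, c=ne - a, d=total - np_ - ne + a
                )
            )
        est = stratified_prr(tables, alpha=alpha, continuity=continuity)
        if est.n_cases < 1:
            continue
        is_signal = signal_rule(est, threshold=threshold, min_cases=min_cases)
        results.append(
            SignalResult(
                product_name=product,
                pt_name=event,
                n_cases=est.n_cases,
                prr=est.prr,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                is_signal=is_signal,
                estimable=est.estimable,
            )
        )
    results.sort(
        key=lambda r: (
            not r.estimable,
            -(r.ci_low if r.estimable else 0.0),
            r.product_name,
            r.pt_name,
        )
    )
    return results


def signals_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Tabular form of signal results; non-estimable numeric fields are empty."""
    return pd.DataFrame(
        [
            {
                "product_name": r.product_name,
                "pt_name": r.pt_name,
                "n_cases": r.n_cases,
                "prr": round(r.prr, 6) if r.estimable else "",
                "ci_low": round(r.ci_low, 6) if r.estimable else "",
                "ci_high": round(r.ci_high, 6) if r.estimable else "",
                "is_signal": r.is_signal,
                "estimable": r.estimable,
            }
            for r in results
        ],
        columns=[
            "product_name",
            "pt_name",
            "n_cases",
            "prr",
            "ci_low",
            "ci_high",
            "is_signal",
            "estimable",
        ],
    )
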