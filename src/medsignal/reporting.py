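"""Trend series and tabulations over the dose-level classification table.

All quantities count **distinct cases**: one spontaneous report counts
once per bin/cell even when it carries several doses or several PTs (so a
tabulation's grand total is a distinct-case count, not the column sum).

When one case has doses in several categories for the same product, the
case is rolled up to a single category using
:data:`medsignal.classifier.ROLLUP_PRECEDENCE`; this makes the per-bin
category ratios of one product a partition (they sum to 1 in every
non-empty bin). Ratios are shown instead of absolute counts because
changes in reporting volume affect numerator and denominator alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classifier import CATEGORIES, ROLLUP_PRECEDENCE, Category
from .dictionary import Dictionary

_FREQ = {"month": "M", "quarter": "Q", "half_year": "2Q", "year": "Y"}


def _validate_category(category: str | Category) -> str:
    return Category(category).value


def _bin(dates: pd.Series, bin_width: str) -> pd.Series:
    if bin_width not in _FREQ:
        raise ValueError(f"bin_width must be one of {sorted(_FREQ)}, got {bin_width!r}")
    return pd.PeriodIndex(pd.to_datetime(dates), freq=_FREQ[bin_width])


def _product_cases(table: pd.DataFrame, product_name: str, country: str | None) -> pd.DataFrame:
    sub = table[table["product_name"] == product_name]
    if country is not None:
        sub = sub[sub["country"] == country]
    return sub


def _rollup(sub: pd.DataFrame) -> pd.DataFrame:
    """One row per case with its rolled-up category and receipt date."""
    rank = {c.value: i for i, c in enumerate(ROLLUP_PRECEDENCE)}
    out = (
        sub.assign(_rank=sub["category"].map(rank))
        .sort_values(["case_id", "_rank"], kind="mergesort")
        .groupby("case_id", sort=True)
        .first()
        .reset_index()[["case_id", "category", "receipt_date"]]
    )
    return out


def ratio_series(
    table: pd.DataFrame,
    product_name: str,
    category: str | Category,
    bin_width: str = "month",
    country: str | None = None,
) -> pd.DataFrame:
    """Per-bin ratio of a product's cases in one category over all its cases.

    Columns: bin_start, numerator, denominator, ratio. Bins are contiguous
    calendar periods spanning the product's reporting range; the ratio is
    NaN (absent), not 0, in bins without any report for the product.
    """
    category = _validate_category(category)
    sub = _product_cases(table, product_name, country)
    if sub.empty:
        return pd.DataFrame(columns=["bin_start", "numerator", "denominator", "ratio"])
    rolled = _rollup(sub)
    bins = _bin(rolled["receipt_date"], bin_width)
    rolled = rolled.assign(_bin=bins)
    full = pd.period_range(bins.min(), bins.max(), freq=_FREQ[bin_width])
    denom = rolled.groupby("_bin", sort=True)["case_id"].nunique().reindex(full, fill_value=0)
    numer = (
        rolled[rolled["category"] == category]
        .groupby("_bin", sort=True)["case_id"]
        .nunique()
        .reindex(full, fill_value=0)
    )
    return pd.DataFrame(
        {
            "bin_start": full.to_timestamp().date,
            "numerator": numer.to_numpy(),
            "denominator": denom.to_numpy(),
            "ratio": (numer / denom.where(denom > 0)).to_numpy(),
        }
    )


def pt_ratio_series(
    table: pd.DataFrame,
    product_name: str,
    pt_name: str,
    bin_width: str = "month",
    country: str | None = None,
) -> pd.DataFrame:
    """Per-bin ratio of the product's cases reporting one PT over all its cases."""
    sub = _product_cases(table, product_name, country)
    if sub.empty:
        return pd.DataFrame(columns=["bin_start", "numerator", "denominator", "ratio"])
    per_case = (
        sub.assign(
            _has=sub["event_terms"].apply(lambda t: pt_name in t.split("|") if t else False)
        )
        .groupby("case_id", sort=True)
        .agg(_has=("_has", "any"), receipt_date=("receipt_date", "first"))
        .reset_index()
    )
    bins = _bin(per_case["receipt_date"], bin_width)
    per_case = per_case.assign(_bin=bins)
    full = pd.period_range(bins.min(), bins.max(), freq=_FREQ[bin_width])
    denom = per_case.groupby("_bin", sort=True)["case_id"].nunique().reindex(full, fill_value=0)
    numer = (
        per_case[per_case["_has"]]
        .groupby("_bin", sort=True)["case_id"]
        .nunique()
        .reindex(full, fill_value=0)
    )
    return pd.DataFrame(
        {
            "bin_start": full.to_timestamp().date,
            "numerator": numer.to_numpy(),
            "denominator": denom.to_numpy(),
            "ratio": (numer / denom.where(denom > 0)).to_numpy(),
        }
    )


_ERROR_CATEGORIES = tuple(c.value for c in CATEGORIES if c is not Category.NO_MEDICATION_ERROR)


def hlt_composition_series(
    table: pd.DataFrame,
    dictionary: Dictionary,
    product_name: str,
    bin_width: str = "month",
) -> pd.DataFrame:
    """Per-bin share of medication-error cases reporting each error HLT.

    For each bin, the denominator is the distinct cases of the product in
    any error category; a case contributes to every HLT (primary lineage)
    of its triggering error terms, so the percentages of a bin may exceed
    100 in total. Columns: bin_start, hlt_name, n_cases, pct.
    """
    sub = _product_cases(table, product_name, None)
    sub = sub[sub["category"].isin(_ERROR_CATEGORIES)]
    if sub.empty:
        return pd.DataFrame(columns=["bin_start", "hlt_name", "n_cases", "pct"])
    sub = sub.assign(_bin=_bin(sub["receipt_date"], bin_width))
    rows = []
    for bin_key, grp in sub.groupby("_bin", sort=True):
        me_cases = grp["case_id"].nunique()
        hlt_cases: dict[str, set[str]] = {}
        for row in grp.itertuples(index=False):
            for term in (row.trigger_terms or "").split("|"):
                if not term:
                    continue
                hlt = dictionary.primary_record(term).hlt_name
                hlt_cases.setdefault(hlt, set()).add(row.case_id)
        for hlt in sorted(hlt_cases):
            n = len(hlt_cases[hlt])
            rows.append(
                {
                    "bin_start": bin_key.to_timestamp().date(),
                    "hlt_name": hlt,
                    "n_cases": n,
                    "pct": 100.0 * n / me_cases,
                }
            )
    return pd.DataFrame(rows, columns=["bin_start", "hlt_name", "n_cases", "pct"])


@dataclass(frozen=True)
class MeTabulation:
    """Errors by HLT and PT, for a selected period vs the cumulative total.

    ``grand_total_*`` are distinct-case counts and may be below the column
    sums, since one case can report several PTs.
    """

    frame: pd.DataFrame  # hlt_name, pt_name, period_count, total_count
    grand_total_period: int
    grand_total_total: int

    def to_frame(self) -> pd.DataFrame:
        grand = pd.DataFrame(
            [
                {
                    "hlt_name": "Grand total",
                    "pt_name": "",
                    "period_count": self.grand_total_period,
                    "total_count": self.grand_total_total,
                }
            ]
        )
        return pd.concat([self.frame, grand], ignore_index=True)


def me_table(
    table: pd.DataFrame,
    dictionary: Dictionary,
    product_name: str,
    category: str | Category,
    window: tuple[str, str] | None = None,
    freeze_date: str | None = None,
) -> MeTabulation:
    """Tabulate a product's error terms by HLT and PT.

    Counts distinct cases per (HLT, PT) over the trigger terms of the
    product's doses in the given category. ``window`` = (start, end) ISO
    dates, inclusive, selects the period column; the total column runs
    from the first case to ``freeze_date`` (default: end of data). Rows
    sorted by HLT then PT, case-insensitively.
    """
    category = _validate_category(category)
    sub = table[(table["product_name"] == product_name) & (table["category"] == category)]
    if freeze_date is not None:
        sub = sub[sub["receipt_date"] <= freeze_date]
    pt_cases: dict[tuple[str, str], set[str]] = {}
    pt_cases_period: dict[tuple[str, str], set[str]] = {}
    all_cases: set[str] = set()
    period_cases: set[str] = set()
    for row in sub.itertuples(index=False):
        in_window = window is not None and window[0] <= row.receipt_date <= window[1]
        all_cases.add(row.case_id)
        if in_window:
            period_cases.add(row.case_id)
        for term in (row.trigger_terms or "").split("|"):
            if not term:
                continue
            key = (dictionary.primary_record(term).hlt_name, dictionary.display_name(term))
            pt_cases.setdefault(key, set()).add(row.case_id)
            if in_window:
                pt_cases_period.setdefault(key, set()).add(row.case_id)
    rows = [
        {
            "hlt_name": hlt,
            "pt_name": pt,
            "period_count": len(pt_cases_period.get((hlt, pt), ())),
            "total_count": len(cases),
        }
        for (hlt, pt), cases in sorted(
            pt_cases.items(), key=lambda kv: (kv[0][0].casefold(), kv[0][1].casefold())
        )
    ]
    frame = pd.DataFrame(rows, columns=["hlt_name", "pt_name", "period_count", "total_count"])
    return MeTabulation(
        frame=frame,
        grand_total_period=len(period_cases),
        grand_total_total=len(all_cases),
    )


def coreported_ae_table(table: pd.DataFrame, product_name: str) -> pd.DataFrame:
    """Most frequent coreported adverse events among with-harm classifications.

    Counts distinct cases per harm PT (never error terms, never excluded
    terms) for the product, sorted by count descending then PT name.
    Columns: pt_name, n_cases.
    """
    sub = table[
        (table["product_name"] == product_name)
        & (table["category"] == Category.ME_WITH_HARM.value)
    ]
    counts: dict[str, set[str]] = {}
    for row in sub.itertuples(index=False):
        for term in (row.harm_terms or "").split("|"):
            if term:
                counts.setdefault(term, set()).add(row.case_id)
    rows = [
        {"pt_name": pt, "n_cases": len(cases)}
        for pt, cases in sorted(counts.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]
    return pd.DataFrame(rows, columns=["pt_name", "n_cases"])
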