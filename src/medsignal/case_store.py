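"""Individual case safety reports at case -> product -> dose -> event depth.

One spontaneous report ("case") carries reporter metadata, one or more
suspect products (co-administration), one or more recorded doses per
product, and zero or more PT-coded events. Events may be explicitly linked
to a product and dose; spontaneous data often lack that linkage, so the
attribution rule in :func:`attributed_events` is deliberately conservative:
an unlinked event attaches to every dose of every suspect product, and a
product-linked but dose-unlinked event attaches to every dose of that
product. Unlinked events must never silently vanish from a classification.

Storage format is UTF-8 JSON-lines, one case per line.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator

from .errors import CaseFormatError, CaseIntegrityError

logger = logging.getLogger(__name__)

SEXES = ("female", "male", "unknown")


@dataclass(frozen=True)
class EventTerm:
    pt_name: str
    linked_product: str | None = None
    linked_dose_index: int | None = None

    def __post_init__(self):
        if self.linked_dose_index is not None and self.linked_product is None:
            raise CaseIntegrityError(
                f"event {self.pt_name!r} links a dose but no product"
            )


@dataclass(frozen=True)
class DoseRecord:
    dose_index: int  # 1-based ordinal of administration
    dose_date: date | None = None

    def __post_init__(self):
        if self.dose_index < 1:
            raise CaseIntegrityError(f"dose_index must be positive, got {self.dose_index}")


@dataclass(frozen=True)
class SuspectProduct:
    product_name: str
    doses: tuple[DoseRecord, ...] = (DoseRecord(1),)

    def __post_init__(self):
        # sources without dosing information get a materialized dose 1
        if not self.doses:
            object.__setattr__(self, "doses", (DoseRecord(1),))
        indices = [d.dose_index for d in self.doses]
        if len(indices) != len(set(indices)):
            raise CaseIntegrityError(
                f"product {self.product_name!r} has duplicate dose_index values"
            )


@dataclass(frozen=True)
class CaseReport:
    case_id: str
    receipt_date: date
    country: str
    sex: str
    age_group: str
    products: tuple[SuspectProduct, ...] = ()
    events: tuple[EventTerm, ...] = ()

    def __post_init__(self):
        if self.sex not in SEXES:
            raise CaseIntegrityError(
                f"case {self.case_id}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        names = {p.product_name for p in self.products}
        if len(names) != len(self.products):
            raise CaseIntegrityError(f"case {self.case_id}: duplicate suspect product names")
        by_name = {p.product_name: p for p in self.products}
        for ev in self.events:
            if ev.linked_product is not None:
                prod = by_name.get(ev.linked_product)
                if prod is None:
                    raise CaseIntegrityError(
                        f"case {self.case_id}: event {ev.pt_name!r} links unknown "
                        f"product {ev.linked_product!r}"
                    )
                if ev.linked_dose_index is not None and ev.linked_dose_index not in {
                    d.dose_index for d in prod.doses
                }:
                    raise CaseIntegrityError(
                        f"case {self.case_id}: event {ev.pt_name!r} links unknown dose "
                        f"{ev.linked_dose_index} of {ev.linked_product!r}"
                    )


def attributed_events(case: CaseReport, product_name: str, dose_index: int) -> list[str]:
    """PT names attributed to one (product, dose) of the case.

    Explicit (product, dose) links attach only there; product-only links
    attach to all doses of that product; fully unlinked events attach to
    all doses of all suspect products.
    """
    out = []
    for ev in case.events:
        if ev.linked_product is None:
            out.append(ev.pt_name)
        elif ev.linked_product == product_name:
            if ev.linked_dose_index is None or ev.linked_dose_index == dose_index:
                out.append(ev.pt_name)
    return out


# -- JSON-lines serialization --------------------------------------------


def _case_to_obj(case: CaseReport) -> dict:
    return {
        "case_id": case.case_id,
        "receipt_date": case.receipt_date.isoformat(),
        "country": case.country,
        "sex": case.sex,
        "age_group": case.age_group,
        "products": [
            {
                "product_name": p.product_name,
                "doses": [
                    {
                        "dose_index": d.dose_index,
                        "dose_date": d.dose_date.isoformat() if d.dose_date else None,
                    }
                    for d in p.doses
                ],
            }
            for p in case.products
        ],
        "events": [
            {
                "pt_name": e.pt_name,
                "linked_product": e.linked_product,
                "linked_dose_index": e.linked_dose_index,
            }
            for e in case.events
        ],
    }


def _obj_to_case(obj: dict) -> CaseReport:
    try:
        products = tuple(
            SuspectProduct(
                product_name=p["product_name"],
                doses=tuple(
                    DoseRecord(
                        dose_index=int(d["dose_index"]),
                        dose_date=date.fromisoformat(d["dose_date"])
                        if d.get("dose_date")
                        else None,
                    )
                    for d in p.get("doses") or [{"dose_index": 1}]
                ),
            )
            for p in obj.get("products", [])
        )
        events = tuple(
            EventTerm(
                pt_name=e["pt_name"],
                linked_product=e.get("linked_product"),
                linked_dose_index=int(e["linked_dose_index"])
                if e.get("linked_dose_index") is not None
                else None,
            )
            for e in obj.get("events", [])
        )
        return CaseReport(
            case_id=str(obj["case_id"]),
            receipt_date=date.fromisoformat(obj["receipt_date"]),
            country=obj["country"],
            sex=obj["sex"],
            age_group=obj["age_group"],
            products=products,
            events=events,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CaseFormatError(f"invalid case record: {exc}") from exc


def read_cases(path: str | Path, mode: str = "strict") -> Iterator[CaseReport]:
    """Stream validated cases from a JSON-lines file.

    Single-pass; only case ids are retained across records (for duplicate
    detection). In ``strict`` mode (default) a malformed line aborts the
    read with its line number; in ``lenient`` mode it is logged and
    skipped. Duplicate case ids are integrity errors in both modes.
    """
    if mode not in {"strict", "lenient"}:
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CaseFormatError(f"not valid JSON: {exc}") from exc
                case = _obj_to_case(obj)
            except (CaseFormatError, CaseIntegrityError) as exc:
                if mode == "strict":
                    if isinstance(exc, CaseIntegrityError):
                        raise CaseIntegrityError(f"line {lineno}: {exc}") from exc
                    raise CaseFormatError(str(exc), lineno) from exc
                logger.warning("skipping malformed case at line %d: %s", lineno, exc)
                continue
            if case.case_id in seen:
                raise CaseIntegrityError(f"duplicate case_id {case.case_id!r} at line {lineno}")
            seen.add(case.case_id)
            yield case


def write_cases(cases: Iterable[CaseReport], path: str | Path) -> int:
    """Write cases as JSON-lines; returns the record count.

    The stream is validated (duplicate ids) before any byte reaches
    ``path``; output is written to a temporary file and atomically renamed.
    """
    path = Path(path)
    materialized = list(cases)
    seen: set[str] = set()
    for case in materialized:
        if case.case_id in seen:
            raise CaseIntegrityError(f"duplicate case_id {case.case_id!r} in output stream")
        seen.add(case.case_id)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            for case in materialized:
                fh.write(json.dumps(_case_to_obj(case), ensure_ascii=False))
                fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return len(materialized)
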