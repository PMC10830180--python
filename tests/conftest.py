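from datetime import date

import pytest

from medsignal.case_store import CaseReport, DoseRecord, EventTerm, SuspectProduct
from medsignal.synthetic import mini_dictionary


@pytest.fixture(scope="session")
def dictionary():
    return mini_dictionary()


def make_case(
    case_id="C0000001",
    events=(),
    products=("VAX-A",),
    doses_per_product=1,
    receipt="2019-03-15",
    country="US",
    sex="female",
    age_group="50-64",
):
    """Compact case builder.

    ``events`` entries are either a bare PT name (unlinked) or a tuple
    (pt_name, product, dose_index) with product/dose possibly None.
    ``products`` entries are either a name (gets ``doses_per_product``
    doses) or a (name, n_doses) tuple.
    """
    prods = []
    for p in products:
        name, n = p if isinstance(p, tuple) else (p, doses_per_product)
        prods.append(
            SuspectProduct(name, tuple(DoseRecord(i + 1) for i in range(n)))
        )
    evs = []
    for e in events:
        if isinstance(e, str):
            evs.append(EventTerm(e))
        else:
            pt, prod, dose = (e + (None, None))[:3]
            evs.append(EventTerm(pt, prod, dose))
    return CaseReport(
        case_id=case_id,
        receipt_date=date.fromisoformat(receipt),
        country=country,
        sex=sex,
        age_group=age_group,
        products=tuple(prods),
        events=tuple(evs),
    )
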