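import numpy as np
import pytest

from medsignal.classifier import CATEGORIES, classify_database
from medsignal.reporting import (
    coreported_ae_table,
    hlt_composition_series,
    me_table,
    pt_ratio_series,
    ratio_series,
)
from medsignal.synthetic import GeneratorConfig, generate_cases

from conftest import make_case


@pytest.fixture(scope="module")
def synth_table(dictionary):
    cases, _ = generate_cases(GeneratorConfig(seed=21, n_cases=600), dictionary)
    return classify_database(cases, dictionary).table


def test_all_error_bin_has_ratio_one(dictionary):
    cases = [
        make_case(case_id=f"C{i}", events=["Incorrect dose administered"],
                  products=("X",), receipt="2019-05-10")
        for i in range(5)
    ]
    table = classify_database(cases, dictionary).table
    series = ratio_series(table, "X", "me_without_harm")
    assert len(series) == 1
    assert series.iloc[0]["ratio"] == pytest.approx(1.0)


def test_bin_without_product_cases_has_absent_ratio(dictionary):
    cases = [
        make_case(case_id="C1", events=[], products=("X",), receipt="2019-01-10"),
        make_case(case_id="C2", events=[], products=("X",), receipt="2019-03-10"),
    ]
    table = classify_database(cases, dictionary).table
    series = ratio_series(table, "X", "me_without_harm")
    assert len(series) == 3  # contiguous months including the empty one
    feb = series[series["bin_start"].astype(str) == "2019-02-01"]
    assert feb["denominator"].item() == 0
    assert np.isnan(feb["ratio"].item())


def test_unknown_category_rejected(synth_table):
    with pytest.raises(ValueError):
        ratio_series(synth_table, "HZ-VAX", "not_a_category")


def test_category_ratios_partition_every_bin(synth_table):
    """Across the six categories the per-bin ratios of one product sum to 1."""
    series = [
        ratio_series(synth_table, "HZ-VAX", c.value) for c in CATEGORIES
    ]
    total = sum(s["ratio"].fillna(0.0) for s in series)
    occupied = series[0]["denominator"] > 0
    assert np.allclose(total[occupied], 1.0, atol=1e-9)
    assert (total[~occupied] == 0.0).all()


def test_pt_ratio_series_bounds(dictionary):
    cases = [
        make_case(case_id="C1", events=["Incorrect route of product administration"],
                  products=("X",), receipt="2019-04-02"),
        make_case(case_id="C2", events=["Incorrect dose administered"],
                  products=("X",), receipt="2019-04-20"),
    ]
    table = classify_database(cases, dictionary).table
    hit = pt_ratio_series(table, "X", "Incorrect route of product administration")
    assert hit.iloc[0]["ratio"] == pytest.approx(0.5)
    miss = pt_ratio_series(table, "X", "Product storage error")
    assert (miss["numerator"] == 0).all()


def test_pt_ratio_rate_shift_is_recovered(dictionary):
    """A PT emitted twice as often in the second half of the stream shows a
    ~2x step in its fitted per-bin ratio."""
    rng = np.random.default_rng(7)
    pt = "Inappropriate schedule of product administration"
    cases = []
    for i in range(800):
        early = i < 400
        month = (i // 67) % 6 + 1  # 6 months per segment
        rate = 0.15 if early else 0.30
        events = [pt] if rng.random() < rate else ["Headache"]
        cases.append(
            make_case(
                case_id=f"C{i:04d}",
                events=events,
                products=("X",),
                receipt=f"{2019 if early else 2020}-{month:02d}-15",
            )
        )
    table = classify_database(cases, dictionary).table
    series = pt_ratio_series(table, "X", pt)
    series = series[series["denominator"] > 0]
    year = series["bin_start"].astype(str).str[:4]
    mean_early = series[year == "2019"]["ratio"].mean()
    mean_late = series[year == "2020"]["ratio"].mean()
    assert mean_late / mean_early == pytest.approx(2.0, rel=0.35)


def test_hlt_composition_single_hlt_is_100_pct(dictionary):
    cases = [
        make_case(case_id=f"C{i}", events=["Incorrect dose administered"],
                  products=("X",), receipt="2019-05-10")
        for i in range(3)
    ]
    table = classify_database(cases, dictionary).table
    comp = hlt_composition_series(table, dictionary, "X")
    assert list(comp["hlt_name"]) == ["Product administration errors and issues"]
    assert comp["pct"].item() == pytest.approx(100.0)


def test_hlt_composition_recovers_known_mix(dictionary):
    rng = np.random.default_rng(3)
    a = "Incorrect dose administered"  # Product administration errors and issues
    b = "Product storage error"  # Product storage errors and issues ...
    cases = []
    for i in range(1000):
        term = a if rng.random() < 0.7 else b
        cases.append(
            make_case(case_id=f"C{i:04d}", events=[term], products=("X",),
                      receipt="2019-06-15")
        )
    table = classify_database(cases, dictionary).table
    comp = hlt_composition_series(table, dictionary, "X")
    pct = dict(zip(comp["hlt_name"], comp["pct"]))
    assert pct["Product administration errors and issues"] == pytest.approx(70.0, abs=4.0)
    assert pct["Product storage errors and issues in the product use system"] == pytest.approx(
        30.0, abs=4.0
    )


def test_hlt_composition_empty_without_error_cases(dictionary):
    cases = [make_case(case_id="C1", events=["Pyrexia"], products=("X",))]
    table = classify_database(cases, dictionary).table
    assert hlt_composition_series(table, dictionary, "X").empty


class TestMeTable:
    def test_one_case_two_hlts_grand_total_is_distinct(self, dictionary):
        case = make_case(
            case_id="C1",
            events=["Incorrect dose administered", "Product storage error"],
            products=("X",),
            receipt="2020-02-10",
        )
        table = classify_database([case], dictionary).table
        tab = me_table(table, dictionary, "X", "me_without_harm",
                       window=("2020-01-01", "2020-06-30"))
        assert len(tab.frame) == 2
        assert set(tab.frame["total_count"]) == {1}
        assert tab.grand_total_total == 1  # distinct case, not the column sum
        assert tab.grand_total_period == 1

    def test_empty_window_zeroes_period_not_total(self, dictionary):
        case = make_case(case_id="C1", events=["Incorrect dose administered"],
                         products=("X",), receipt="2020-02-10")
        table = classify_database([case], dictionary).table
        tab = me_table(table, dictionary, "X", "me_without_harm",
                       window=("1999-01-01", "1999-12-31"))
        assert (tab.frame["period_count"] == 0).all()
        assert tab.grand_total_period == 0
        assert tab.grand_total_total == 1

    def test_hand_tallied_fixture(self, dictionary):
        # five cases; C3 reports two PTs (same HLT); C5 is a different category
        cases = [
            make_case(case_id="C1", events=["Incorrect dose administered"],
                      products=("X",), receipt="2020-01-10"),
            make_case(case_id="C2", events=["Incorrect dose administered"],
                      products=("X",), receipt="2020-02-10"),
            make_case(case_id="C3",
                      events=["Incorrect dose administered", "Extra dose administered"],
                      products=("X",), receipt="2020-03-10"),
            make_case(case_id="C4", events=["Product storage error"],
                      products=("X",), receipt="2019-03-10"),
            make_case(case_id="C5",
                      events=["Incorrect dose administered", "Pyrexia"],
                      products=("X",), receipt="2020-03-20"),
        ]
        table = classify_database(cases, dictionary).table
        tab = me_table(table, dictionary, "X", "me_without_harm",
                       window=("2020-01-01", "2020-12-31"))
        rows = {
            (r.hlt_name, r.pt_name): (r.period_count, r.total_count)
            for r in tab.frame.itertuples(index=False)
        }
        assert rows == {
            ("Product administration errors and issues", "Extra dose administered"): (1, 1),
            ("Product administration errors and issues", "Incorrect dose administered"): (3, 3),
            ("Product storage errors and issues in the product use system",
             "Product storage error"): (0, 1),
        }
        assert tab.grand_total_period == 3  # C1, C2, C3
        assert tab.grand_total_total == 4  # + C4; C5 is with-harm

    def test_invariant_to_row_order(self, dictionary, synth_table):
        tab1 = me_table(synth_table, dictionary, "HZ-VAX", "me_without_harm")
        shuffled = synth_table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        tab2 = me_table(shuffled, dictionary, "HZ-VAX", "me_without_harm")
        assert tab1.frame.equals(tab2.frame)
        assert tab1.grand_total_total == tab2.grand_total_total


class TestCoreportedAeTable:
    def test_empty_without_harm_cases(self, dictionary):
        case = make_case(case_id="C1", events=["Incorrect dose administered"], products=("X",))
        table = classify_database([case], dictionary).table
        assert coreported_ae_table(table, "X").empty

    def test_single_case_two_harm_terms(self, dictionary):
        case = make_case(
            case_id="C1",
            events=["Incorrect dose administered", "Pyrexia", "Headache", "Breastfeeding"],
            products=("X",),
        )
        table = classify_database([case], dictionary).table
        tab = coreported_ae_table(table, "X")
        # harm terms only: never the error term, never the excluded term
        assert dict(zip(tab["pt_name"], tab["n_cases"])) == {"Pyrexia": 1, "Headache": 1}
        assert list(tab["pt_name"]) == ["Headache", "Pyrexia"]  # tie -> alphabetical

    def test_counts_match_generator_tally(self, dictionary):
        cases, truth = generate_cases(GeneratorConfig(seed=13, n_cases=400), dictionary)
        table = classify_database(cases, dictionary).table
        for product in ("HZ-VAX", "FLU-VAX"):
            tab = coreported_ae_table(table, product)
            want: dict[str, set[str]] = {}
            sub = truth[(truth.product_name == product) & (truth.category == "me_with_harm")]
            for row in sub.itertuples(index=False):
                for term in row.harm_terms.split("|"):
                    want.setdefault(term, set()).add(row.case_id)
            assert dict(zip(tab["pt_name"], tab["n_cases"])) == {
                k: len(v) for k, v in want.items()
            }
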