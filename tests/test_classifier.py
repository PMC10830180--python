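from itertools import combinations

import pytest
from hypothesis import given, settings, strategies as st

from medsignal.classifier import Category, classify_case, classify_database, classify_dose
from medsignal.errors import ClassificationError
from medsignal.synthetic import GeneratorConfig, generate_cases

from conftest import make_case
from _oracle import prose_category

CIRC = "Circumstance or information capable of leading to medication error"
INTER = "Intercepted medication error"

# 12-term fixture vocabulary drawn from the mini terminology:
# 4 SMQ members (incl. the circumstance PT), 1 "intercepted" PT,
# 4 harm PTs, 3 excluded PTs
VOCAB = [
    CIRC,
    "Incorrect dose administered",
    "Wrong product administered",
    "Product storage error",
    INTER,
    "Pyrexia",
    "Headache",
    "Injection site pain",
    "Chills",
    "Breastfeeding",
    "No adverse event",
    "Off label use",
]


def classify_terms(terms, dictionary, mode="strict"):
    case = make_case(events=[(t, "VAX-A", 1) for t in terms], products=("VAX-A",))
    return classify_dose(case, "VAX-A", 1, dictionary, mode)


@pytest.mark.parametrize(
    "terms, expected",
    [
        ([CIRC], Category.POTENTIAL_ERROR),
        ([INTER], Category.INTERCEPTED_ERROR),
        ([INTER, CIRC], Category.CONFLICTING),
        (["Incorrect dose administered", "Pyrexia"], Category.ME_WITH_HARM),
        (["Incorrect dose administered", "Breastfeeding"], Category.ME_WITHOUT_HARM),
        (["Incorrect dose administered"], Category.ME_WITHOUT_HARM),
        (["Pyrexia"], Category.NO_MEDICATION_ERROR),
        ([], Category.NO_MEDICATION_ERROR),
        # circumstance beats the harm branch even with harm terms present
        ([CIRC, "Incorrect dose administered", "Pyrexia"], Category.POTENTIAL_ERROR),
        # excluded term coreported with error still carries no harm
        (["Product storage error", "No adverse event", "Off label use"],
         Category.ME_WITHOUT_HARM),
        # a product-issue PT that is an SMQ member counts as the error itself
        (["Syringe issue"], Category.ME_WITHOUT_HARM),
    ],
)
def test_rule_examples(dictionary, terms, expected):
    result = classify_terms(terms, dictionary)
    assert result.category is expected


def test_with_harm_evidence_terms(dictionary):
    r = classify_terms(["Incorrect dose administered", "Pyrexia", "Breastfeeding"], dictionary)
    assert r.category is Category.ME_WITH_HARM
    assert r.trigger_terms == {"Incorrect dose administered"}
    assert r.harm_terms == {"Pyrexia"}
    assert r.excluded_terms == {"Breastfeeding"}


def test_conflicting_trigger_contains_both_sides(dictionary):
    r = classify_terms([INTER, CIRC, "Pyrexia"], dictionary)
    assert r.category is Category.CONFLICTING
    assert CIRC in r.trigger_terms and INTER in r.trigger_terms


def test_case_insensitive_and_whitespace_tolerant_matching(dictionary):
    r = classify_terms(["INCORRECT  DOSE   ADMINISTERED", "pYREXIA"], dictionary)
    assert r.category is Category.ME_WITH_HARM
    assert r.harm_terms == {"Pyrexia"}  # canonical dictionary spelling


def test_word_boundary_on_intercepted(dictionary):
    # substring matches like a hypothetical "unintercepted" must not trigger
    from medsignal._text import contains_intercepted

    assert contains_intercepted("Intercepted drug administration error")
    assert not contains_intercepted("Uninterceptedness issue")


def test_unknown_term_strict_raises_lenient_counts_as_harm(dictionary):
    with pytest.raises(ClassificationError, match="Zzz unknown"):
        classify_terms(["Incorrect dose administered", "Zzz unknown"], dictionary)
    r = classify_terms(["Incorrect dose administered", "Zzz unknown"], dictionary, "lenient")
    assert r.category is Category.ME_WITH_HARM
    assert r.harm_terms == {"Zzz unknown"}


def test_exhaustive_equivalence_with_prose_oracle(dictionary):
    """Over all 4096 subsets of the 12-term vocabulary the rule engine and
    an independent transcription of the published rules agree exactly."""
    smq = [n for n in dictionary.pt_names() if n in dictionary.me_smq]
    excl = [n for n in dictionary.pt_names() if n in dictionary.exclusion]
    mismatches = []
    for k in range(len(VOCAB) + 1):
        for subset in combinations(VOCAB, k):
            got = classify_terms(subset, dictionary).category.value
            want = prose_category(subset, smq, excl)
            if got != want:
                mismatches.append((subset, got, want))
    assert not mismatches, mismatches[:5]


_subsets = st.sets(st.sampled_from(VOCAB), max_size=6)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(terms=_subsets, harm=st.sampled_from(["Pyrexia", "Headache", "Chills"]))
def test_adding_harm_escalates_without_harm(dictionary, terms, harm):
    base = classify_terms(terms, dictionary)
    if base.category is Category.ME_WITHOUT_HARM:
        grown = classify_terms(set(terms) | {harm}, dictionary)
        assert grown.category is Category.ME_WITH_HARM


@settings(max_examples=200, derandomize=True, deadline=None)
@given(terms=_subsets, extra=st.sampled_from(VOCAB))
def test_conflicting_absorbs_any_addition(dictionary, terms, extra):
    base = classify_terms(terms, dictionary)
    if base.category is Category.CONFLICTING:
        grown = classify_terms(set(terms) | {extra}, dictionary)
        assert grown.category is Category.CONFLICTING


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    terms=_subsets,
    excluded=st.sets(st.sampled_from(["Breastfeeding", "No adverse event", "Off label use"]),
                     min_size=1),
)
def test_excluded_terms_are_category_neutral(dictionary, terms, excluded):
    base = classify_terms(terms, dictionary)
    grown = classify_terms(set(terms) | excluded, dictionary)
    assert grown.category is base.category


class TestCaseLevel:
    def test_coadministration_separates_products(self, dictionary):
        case = make_case(
            events=[("Wrong product administered", "VAX-A", 1)],
            products=("VAX-A", "VAX-B"),
        )
        got = {(c.product_name, c.category) for c in classify_case(case, dictionary)}
        assert got == {
            ("VAX-A", Category.ME_WITHOUT_HARM),
            ("VAX-B", Category.NO_MEDICATION_ERROR),
        }

    def test_dose_linked_error_separates_doses(self, dictionary):
        case = make_case(
            events=[("Expired product administered", "VAX-A", 2)],
            products=(("VAX-A", 2),),
        )
        by_dose = {c.dose_index: c.category for c in classify_case(case, dictionary)}
        assert by_dose == {1: Category.NO_MEDICATION_ERROR, 2: Category.ME_WITHOUT_HARM}

    def test_zero_events_all_doses_non_error(self, dictionary):
        case = make_case(events=[], products=(("VAX-A", 2), ("VAX-B", 1)))
        cats = [c.category for c in classify_case(case, dictionary)]
        assert cats == [Category.NO_MEDICATION_ERROR] * 3

    def test_output_is_product_then_dose_ordered(self, dictionary):
        case = make_case(events=[], products=(("VAX-B", 2), ("VAX-A", 1)))
        keys = [(c.product_name, c.dose_index) for c in classify_case(case, dictionary)]
        assert keys == [("VAX-B", 1), ("VAX-B", 2), ("VAX-A", 1)]


class TestDatabaseLevel:
    def test_totality_one_row_per_triple(self, dictionary):
        cases, truth = generate_cases(GeneratorConfig(seed=2, n_cases=300), dictionary)
        result = classify_database(cases, dictionary)
        n_triples = sum(len(p.doses) for c in cases for p in c.products)
        assert len(result.table) == n_triples == len(truth)
        assert result.table.groupby("category").size().sum() == n_triples

    def test_conflict_report_lists_exactly_injected_conflicts(self, dictionary):
        cases, truth = generate_cases(
            GeneratorConfig(seed=9, n_cases=400, conflict_rate=0.05), dictionary
        )
        result = classify_database(cases, dictionary)
        want = set(
            truth[truth.category == "conflicting"][
                ["case_id", "product_name", "dose_index"]
            ].itertuples(index=False, name=None)
        )
        got = set(
            result.conflicts[["case_id", "product_name", "dose_index"]].itertuples(
                index=False, name=None
            )
        )
        assert got == want and len(want) > 0

    def test_empty_stream(self, dictionary):
        result = classify_database([], dictionary)
        assert result.table.empty and result.conflicts.empty

    def test_deterministic_output(self, dictionary):
        cases, _ = generate_cases(GeneratorConfig(seed=4, n_cases=100), dictionary)
        t1 = classify_database(cases, dictionary).table
        t2 = classify_database(cases, dictionary).table
        assert t1.to_csv(index=False) == t2.to_csv(index=False)
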