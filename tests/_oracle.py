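"""Independent brute-force transcription of the published categorization rules.

Deliberately written directly from the rule prose, without reusing any of
the package's classifier code, so it can serve as an oracle in exhaustive
equivalence tests. Operates on plain sets of (already canonical) strings.
"""

import re

CIRCUMSTANCE = "circumstance or information capable of leading to medication error"
_INTERCEPTED = re.compile(r"\bintercepted\b")


def _canon(name: str) -> str:
    return " ".join(name.split()).casefold()


def prose_category(terms, smq_members, excluded) -> str:
    """Category for the set of PTs reported after one dose of one product.

    ``smq_members`` and ``excluded`` are collections of PT names (any
    capitalization); returns the category string.
    """
    t = {_canon(x) for x in terms}
    smq = {_canon(x) for x in smq_members}
    excl = {_canon(x) for x in excluded}

    has_circumstance = CIRCUMSTANCE in t
    has_intercepted = any(_INTERCEPTED.search(x) for x in t)

    # a PT containing "intercepted" together with the circumstance PT is
    # mutually inconsistent coding
    if has_circumstance and has_intercepted:
        return "conflicting"
    # the circumstance PT alone marks a potential error
    if has_circumstance:
        return "potential_error"
    # an "intercepted" PT, circumstance absent
    if has_intercepted:
        return "intercepted_error"
    # otherwise: errors are the SMQ members; everything else is harm unless
    # it is one of the non-valid coreported terms
    me = {x for x in t if x in smq}
    if not me:
        return "no_medication_error"
    valid_harm = {x for x in t - me if x not in excl}
    if valid_harm:
        return "me_with_harm"
    return "me_without_harm"
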