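"""Name canonicalization shared by the terminology and classifier layers.

MedDRA-style term capitalization is inconsistent across sources, so all
matching is done on a canonical key: case-folded with internal whitespace
collapsed to single spaces. Display spellings are preserved separately.
"""

import re

_WS = re.compile(r"\s+")

# whole-word match; "unintercepted" must not match
INTERCEPTED_WORD = re.compile(r"\bintercepted\b")


def canon(name: str) -> str:
    """Canonical matching key for a term or query name."""
    return _WS.sub(" ", name.strip()).casefold()


def contains_intercepted(name: str) -> bool:
    """True when the term name contains the standalone word 'intercepted'."""
    return INTERCEPTED_WORD.search(canon(name)) is not None
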