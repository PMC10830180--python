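"""MedDRA-like terminology: PT -> HLT -> HLGT -> SOC lineage plus SMQ sets.

The classifier keys on three pieces of terminology state:

* membership of the ``medication error`` SMQ (which terms *are* errors),
* a derived **exclusion set** of preferred terms that never count as harm
  when coreported with an error (product-issue terms, off-label/misuse
  terms, absence-of-effect and normal pregnancy/newborn terms, and the PT
  "breastfeeding"),
* the literal special terms ("circumstance or information capable of
  leading to medication error", terms containing the word "intercepted").

The exclusion set is derived from the hierarchy at load time rather than
hard-coded, so a terminology version update only requires a new dictionary
file, not a code change.

Input format: two delimited tables (``terms`` + ``smq_members``), either as
two files or one file with ``[terms]`` / ``[smq]`` section markers. Genuine
MedDRA distribution files are license-restricted and out of scope.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import DictionaryFormatError, DictionaryIntegrityError, TermLookupError
from ._text import canon, contains_intercepted

ME_SMQ_NAME = "medication error"
CIRCUMSTANCE_PT = "circumstance or information capable of leading to medication error"

# Hierarchy branches whose PTs are not valid harm events.
PRODUCT_ISSUES_SOC = "product issues"
OFF_LABEL_HLGT = "off-label uses and intentional product misuses/uses issues"
EXCLUDED_HLTS = frozenset(
    {
        "adverse effect absent",
        "exposure associated with pregnancy, delivery and lactation",
        "normal newborn status",
        "normal pregnancy, labor and delivery",
    }
)
EXCLUDED_PTS = frozenset({"breastfeeding"})

TERMS_COLUMNS = ("pt_name", "pt_code", "hlt_name", "hlgt_name", "soc_name", "is_primary_soc")
SMQ_COLUMNS = ("smq_name", "pt_name")

RULE_PRIMARY_SOC = "primary-SOC"
RULE_HLGT = "HLGT"
RULE_HLT = "HLT"
RULE_EXPLICIT_PT = "explicit-PT"


@dataclass(frozen=True)
class TermRecord:
    """One PT-to-SOC linkage with its HLT/HLGT lineage."""

    pt_name: str
    pt_code: str
    hlt_name: str
    hlgt_name: str
    soc_name: str
    is_primary_soc: bool


@dataclass(frozen=True)
class SmqSet:
    """A named Standardised MedDRA Query: a flat set of member PTs."""

    smq_name: str
    member_pt_names: frozenset[str]  # canonical keys

    def __contains__(self, pt_name: str) -> bool:
        return canon(pt_name) in self.member_pt_names


@dataclass(frozen=True)
class ExclusionSet:
    """PTs not considered valid harm events, with the rule(s) that admitted each."""

    pt_names: frozenset[str]  # canonical keys
    provenance: Mapping[str, frozenset[str]]  # canonical key -> rule names

    def __contains__(self, pt_name: str) -> bool:
        return canon(pt_name) in self.pt_names

    def __len__(self) -> int:
        return len(self.pt_names)


class Dictionary:
    """Validated terminology with cached SMQ sets and exclusion set."""

    def __init__(self, records: Iterable[TermRecord], smqs: Iterable[SmqSet]):
        self._records: dict[str, list[TermRecord]] = {}
        self._primary: dict[str, TermRecord] = {}
        for rec in records:
            key = canon(rec.pt_name)
            linkages = self._records.setdefault(key, [])
            if any(canon(r.soc_name) == canon(rec.soc_name) for r in linkages):
                raise DictionaryIntegrityError(
                    f"duplicate (pt_name, soc_name) linkage for PT {rec.pt_name!r} "
                    f"under SOC {rec.soc_name!r}"
                )
            linkages.append(rec)
            if rec.is_primary_soc:
                if key in self._primary:
                    raise DictionaryIntegrityError(
                        f"PT {rec.pt_name!r} has more than one primary-SOC linkage"
                    )
                self._primary[key] = rec
        missing_primary = sorted(k for k in self._records if k not in self._primary)
        if missing_primary:
            raise DictionaryIntegrityError(
                "PT(s) with no primary-SOC linkage: " + ", ".join(missing_primary)
            )
        for rec in (r for recs in self._records.values() for r in recs):
            if not (rec.hlt_name and rec.hlgt_name and rec.soc_name):
                raise DictionaryIntegrityError(
                    f"PT {rec.pt_name!r} has an empty HLT/HLGT/SOC field"
                )

        self._smqs: dict[str, SmqSet] = {}
        for smq in smqs:
            orphans = sorted(m for m in smq.member_pt_names if m not in self._records)
            if orphans:
                raise DictionaryIntegrityError(
                    f"SMQ {smq.smq_name!r} references unknown PT(s): " + ", ".join(orphans)
                )
            self._smqs[canon(smq.smq_name)] = smq

        self._exclusion = build_exclusion_set(self)

    # -- lookups ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def has_pt(self, pt_name: str) -> bool:
        return canon(pt_name) in self._records

    def pt_names(self) -> list[str]:
        """Display spellings of all PTs, in primary-record spelling."""
        return [rec.pt_name for rec in self._primary.values()]

    def records(self, pt_name: str) -> list[TermRecord]:
        try:
            return list(self._records[canon(pt_name)])
        except KeyError:
            raise TermLookupError(f"unknown PT: {pt_name!r}") from None

    def primary_record(self, pt_name: str) -> TermRecord:
        try:
            return self._primary[canon(pt_name)]
        except KeyError:
            raise TermLookupError(f"unknown PT: {pt_name!r}") from None

    def display_name(self, pt_name: str) -> str:
        """The dictionary's stored spelling for a (possibly differently cased) PT."""
        return self.primary_record(pt_name).pt_name

    def smq(self, smq_name: str) -> SmqSet:
        try:
            return self._smqs[canon(smq_name)]
        except KeyError:
            raise TermLookupError(f"unknown SMQ: {smq_name!r}") from None

    def smq_names(self) -> list[str]:
        return [s.smq_name for s in self._smqs.values()]

    @property
    def me_smq(self) -> SmqSet:
        """The 'medication error' SMQ; required by the classifier."""
        return self.smq(ME_SMQ_NAME)

    @property
    def exclusion(self) -> ExclusionSet:
        return self._exclusion

    def is_me_term(self, pt_name: str) -> bool:
        """Whether the PT belongs to the 'medication error' SMQ.

        Raises :class:`TermLookupError` if the PT is absent from the
        dictionary entirely — an unknown term must never silently read
        as "not an error".
        """
        if not self.has_pt(pt_name):
            raise TermLookupError(f"unknown PT: {pt_name!r}")
        return pt_name in self.me_smq

    def is_intercepted_term(self, pt_name: str) -> bool:
        return contains_intercepted(pt_name)


def build_exclusion_set(dictionary: Dictionary) -> ExclusionSet:
    """Derive the set of PTs that never count as harm.

    Union of four hierarchy rules: (a) primary SOC "product issues";
    (b) any linkage under the off-label/misuse HLGT; (c) any linkage under
    one of the four absence-of-effect / pregnancy / newborn HLTs;
    (d) the explicit PT "breastfeeding". Deterministic given the
    dictionary; an empty result is legal.
    """
    provenance: dict[str, set[str]] = {}

    def admit(key: str, rule: str) -> None:
        provenance.setdefault(key, set()).add(rule)

    for key in dictionary._records:
        primary = dictionary._primary[key]
        if canon(primary.soc_name) == PRODUCT_ISSUES_SOC:
            admit(key, RULE_PRIMARY_SOC)
        for rec in dictionary._records[key]:
            if canon(rec.hlgt_name) == OFF_LABEL_HLGT:
                admit(key, RULE_HLGT)
            if canon(rec.hlt_name) in EXCLUDED_HLTS:
                admit(key, RULE_HLT)
        if key in EXCLUDED_PTS:
            admit(key, RULE_EXPLICIT_PT)

    return ExclusionSet(
        pt_names=frozenset(provenance),
        provenance={k: frozenset(v) for k, v in provenance.items()},
    )


# -- file I/O ------------------------------------------------------------


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _parse_bool(value: str, context: str) -> bool:
    v = value.strip().casefold()
    if v in {"true", "1", "yes", "y"}:
        return True
    if v in {"false", "0", "no", "n"}:
        return False
    raise DictionaryFormatError(f"{context}: cannot parse boolean {value!r}")


def _read_table(text: str, delimiter: str, required: tuple[str, ...], what: str) -> list[dict]:
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    if reader.fieldnames is None:
        return []
    fields = [f.strip() for f in reader.fieldnames]
    for col in required:
        if col not in fields:
            raise DictionaryFormatError(f"{what} table is missing required column {col!r}")
    rows = []
    for raw in reader:
        rows.append({k.strip(): (v or "").strip() for k, v in raw.items() if k is not None})
    return rows


def _split_sections(text: str) -> tuple[str, str | None]:
    """Split a single file on ``[terms]`` / ``[smq]`` marker lines."""
    sections: dict[str, list[str]] = {}
    current = "terms"
    for line in text.splitlines():
        marker = line.strip().casefold()
        if marker in {"[terms]", "[smq]"}:
            current = marker[1:-1]
            continue
        sections.setdefault(current, []).append(line)
    terms = "\n".join(sections.get("terms", []))
    smq = "\n".join(sections["smq"]) if "smq" in sections else None
    return terms, smq


def load_dictionary(terms_path: str | Path, smq_path: str | Path | None = None) -> Dictionary:
    """Load and validate a terminology from delimited files.

    ``terms_path`` may be a terms-only file (with ``smq_path`` giving the
    SMQ membership table) or a combined file with ``[terms]``/``[smq]``
    section markers. Delimiter is comma for ``.csv``, tab otherwise.
    """
    terms_path = Path(terms_path)
    if not terms_path.exists():
        raise DictionaryFormatError(f"terminology file not found: {terms_path}")
    delim = _delimiter_for(terms_path)
    terms_text, inline_smq = _split_sections(terms_path.read_text(encoding="utf-8"))

    if smq_path is not None:
        smq_path = Path(smq_path)
        if not smq_path.exists():
            raise DictionaryFormatError(f"SMQ file not found: {smq_path}")
        smq_text = _split_sections(smq_path.read_text(encoding="utf-8"))[0]
        smq_delim = _delimiter_for(smq_path)
    elif inline_smq is not None:
        smq_text, smq_delim = inline_smq, delim
    else:
        raise DictionaryFormatError(
            f"no SMQ membership table: pass smq_path or add an [smq] section to {terms_path}"
        )

    records = []
    for row in _read_table(terms_text, delim, TERMS_COLUMNS, "terms"):
        records.append(
            TermRecord(
                pt_name=row["pt_name"],
                pt_code=row["pt_code"],
                hlt_name=row["hlt_name"],
                hlgt_name=row["hlgt_name"],
                soc_name=row["soc_name"],
                is_primary_soc=_parse_bool(
                    row["is_primary_soc"], f"PT {row['pt_name']!r}"
                ),
            )
        )

    members: dict[str, set[str]] = {}
    smq_display: dict[str, str] = {}
    for row in _read_table(smq_text, smq_delim, SMQ_COLUMNS, "smq_members"):
        key = canon(row["smq_name"])
        smq_display.setdefault(key, row["smq_name"])
        members.setdefault(key, set()).add(canon(row["pt_name"]))
    smqs = [
        SmqSet(smq_name=smq_display[k], member_pt_names=frozenset(v))
        for k, v in members.items()
    ]
    return Dictionary(records, smqs)
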