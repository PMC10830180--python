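"""Synthetic terminology and spontaneous-report generator with ground truth.

Real MedDRA is licensed and real safety databases are proprietary, so this
module provides (a) a curated mini-dictionary carrying every special term
the classifier keys on — the circumstance PT, "intercepted" PTs, a
"medication error" SMQ drawn from the vaccination-error vocabulary, a harm
vocabulary of common post-vaccination reactogenicity terms, and at least
one PT per exclusion rule — and (b) a case generator that first draws the
intended category of every (case, product, dose) triple and then emits PT
sets whose rule-based classification is exactly that category. The emitted
ground-truth table therefore serves as an exact round-trip oracle for the
classifier: any disagreement is a bug, not noise.

Every event is emitted with an explicit (product, dose) link so that
attribution is unambiguous. All randomness flows from a single seeded
generator; identical configurations produce byte-identical files.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .case_store import CaseReport, DoseRecord, EventTerm, SuspectProduct, write_cases
from .classifier import Category
from .dictionary import (
    CIRCUMSTANCE_PT,
    ME_SMQ_NAME,
    Dictionary,
    SmqSet,
    TermRecord,
)
from .errors import ConfigError
from ._text import canon, contains_intercepted

_SOC_INJ = "Injury, poisoning and procedural complications"
_SOC_GEN = "General disorders and administration site conditions"
_SOC_PROD = "Product issues"
_HLGT_ME = "Medication errors and other product use errors and issues"
_HLGT_OFFLABEL = "Off-label uses and intentional product misuses/uses issues"

# (pt_name, hlt_name, hlgt_name, soc_name, is_primary_soc, in_me_smq)
_VOCABULARY: list[tuple[str, str, str, str, bool, bool]] = [
    # --- medication-error SMQ terms -----------------------------------
    ("Circumstance or information capable of leading to medication error",
     "Medication errors, product use errors and issues NEC", _HLGT_ME, _SOC_INJ, True, True),
    ("Intercepted medication error",
     "Medication errors, product use errors and issues NEC", _HLGT_ME, _SOC_INJ, True, True),
    ("Intercepted product prescribing error",
     "Product prescribing errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Medication error",
     "Medication errors, product use errors and issues NEC", _HLGT_ME, _SOC_INJ, True, True),
    ("Vaccination error",
     "Medication errors, product use errors and issues NEC", _HLGT_ME, _SOC_INJ, True, True),
    ("Wrong technique in product usage process",
     "Medication errors, product use errors and issues NEC", _HLGT_ME, _SOC_INJ, True, True),
    ("Product use issue",
     "Medication errors, product use errors and issues NEC", _HLGT_ME, _SOC_INJ, True, True),
    ("Accidental exposure to product",
     "Accidental exposures to product", "Exposures, chemical injuries and poisoning",
     _SOC_INJ, True, True),
    ("Accidental overdose",
     "Product administration errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Accidental underdose",
     "Product administration errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Expired product administered",
     "Product administration errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Extra dose administered",
     "Product administration errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Inappropriate schedule of product administration",
     "Product administration errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Incomplete course of vaccination",
     "Product administration errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Incorrect dose administered",
     "Product administration errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Incorrect route of product administration",
     "Product administration errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Product administered at inappropriate site",
     "Product administration errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Product administered to patient of inappropriate age",
     "Product administration errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Wrong product administered",
     "Product administration errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Product preparation error",
     "Product preparation errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Product preparation issue",
     "Product preparation errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Product storage error",
     "Product storage errors and issues in the product use system", _HLGT_ME, _SOC_INJ,
     True, True),
    ("Product dispensing error",
     "Product dispensing errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Product prescribing error",
     "Product prescribing errors and issues", _HLGT_ME, _SOC_INJ, True, True),
    ("Overdose", "Overdoses NEC", "Overdoses and underdoses", _SOC_INJ, True, True),
    ("Underdose", "Underdoses NEC", "Overdoses and underdoses", _SOC_INJ, True, True),
    ("Occupational exposure to product",
     "Occupational exposures", "Exposures, chemical injuries and poisoning",
     _SOC_INJ, True, True),
    ("Exposure via skin contact",
     "Pathways and sources of exposure", "Exposures, chemical injuries and poisoning",
     _SOC_INJ, True, True),
    # product-issue PTs that are ALSO medication-error SMQ members:
    # SMQ membership takes precedence over the exclusion set
    ("Syringe issue",
     "Device physical property and chemical issues", "Device issues", _SOC_PROD, True, True),
    ("Needle issue",
     "Device physical property and chemical issues", "Device issues", _SOC_PROD, True, True),
    ("Product packaging issue",
     "Product packaging issues", "Product quality issues", _SOC_PROD, True, True),
    # --- exclusion-only branches --------------------------------------
    ("Product label issue",
     "Product label issues", "Product quality issues", _SOC_PROD, True, False),
    ("Product distribution issue",
     "Product distribution and storage issues", "Product supply and distribution issues",
     _SOC_PROD, True, False),
    ("Off label use",
     "Off label uses", _HLGT_OFFLABEL, _SOC_INJ, True, False),
    ("Intentional product misuse",
     "Intentional product misuses", _HLGT_OFFLABEL, _SOC_INJ, True, False),
    ("No adverse event",
     "Adverse effect absent", "Therapeutic and nontherapeutic responses", _SOC_GEN,
     True, False),
    ("Maternal exposure during pregnancy",
     "Exposure associated with pregnancy, delivery and lactation",
     "Exposures, chemical injuries and poisoning", _SOC_INJ, True, False),
    ("Maternal exposure during pregnancy",
     "Exposure associated with pregnancy, delivery and lactation",
     "Pregnancy related maternal complications",
     "Pregnancy, puerperium and perinatal conditions", False, False),
    ("Normal newborn",
     "Normal newborn status", "Neonatal and perinatal conditions",
     "Pregnancy, puerperium and perinatal conditions", True, False),
    ("Normal pregnancy",
     "Normal pregnancy, labor and delivery", "Pregnancy conditions",
     "Pregnancy, puerperium and perinatal conditions", True, False),
    ("Breastfeeding",
     "Lactation issues", "Pregnancy, labour, delivery and postpartum conditions",
     "Reproductive system and breast disorders", True, False),
    # --- harm vocabulary (reactogenicity and related) -----------------
    ("Injection site pain", "Injection site reactions", "Administration site reactions",
     _SOC_GEN, True, False),
    ("Injection site erythema", "Injection site reactions", "Administration site reactions",
     _SOC_GEN, True, False),
    ("Injection site swelling", "Injection site reactions", "Administration site reactions",
     _SOC_GEN, True, False),
    ("Injection site pruritus", "Injection site reactions", "Administration site reactions",
     _SOC_GEN, True, False),
    ("Pyrexia", "Febrile disorders", "Body temperature conditions", _SOC_GEN, True, False),
    ("Chills", "Febrile disorders", "Body temperature conditions", _SOC_GEN, True, False),
    ("Pain", "Pain and discomfort NEC", "General system disorders NEC", _SOC_GEN, True, False),
    ("Fatigue", "Asthenic conditions", "General system disorders NEC", _SOC_GEN, True, False),
    ("Malaise", "Asthenic conditions", "General system disorders NEC", _SOC_GEN, True, False),
    ("Influenza like illness", "General signs and symptoms NEC",
     "General system disorders NEC", _SOC_GEN, True, False),
    ("Headache", "Headaches NEC", "Headaches", "Nervous system disorders", True, False),
    ("Dizziness", "Neurological signs and symptoms NEC", "Neurological disorders NEC",
     "Nervous system disorders", True, False),
    ("Pain in extremity", "Musculoskeletal and connective tissue pain and discomfort",
     "Musculoskeletal and connective tissue disorders NEC",
     "Musculoskeletal and connective tissue disorders", True, False),
    ("Myalgia", "Muscle related signs and symptoms",
     "Musculoskeletal and connective tissue disorders NEC",
     "Musculoskeletal and connective tissue disorders", True, False),
    ("Arthralgia", "Joint related signs and symptoms",
     "Joint disorders", "Musculoskeletal and connective tissue disorders", True, False),
    ("Erythema", "Erythemas", "Epidermal and dermal conditions",
     "Skin and subcutaneous tissue disorders", True, False),
    ("Rash", "Rashes, eruptions and exanthems NEC", "Epidermal and dermal conditions",
     "Skin and subcutaneous tissue disorders", True, False),
    ("Urticaria", "Urticarias", "Angioedema and urticaria",
     "Skin and subcutaneous tissue disorders", True, False),
    ("Pruritus", "Pruritus NEC", "Epidermal and dermal conditions",
     "Skin and subcutaneous tissue disorders", True, False),
    ("Nausea", "Nausea and vomiting symptoms", "Gastrointestinal signs and symptoms",
     "Gastrointestinal disorders", True, False),
    ("Vomiting", "Nausea and vomiting symptoms", "Gastrointestinal signs and symptoms",
     "Gastrointestinal disorders", True, False),
    ("Herpes zoster", "Herpes viral infections", "Viral infectious disorders",
     "Infections and infestations", True, False),
    ("Vaccination failure", "Vaccination related complications",
     "Infections - pathogen unspecified", "Infections and infestations", True, False),
]

# reporting-frequency weights used when drawing terms; unlisted terms get 1
_ME_WEIGHTS = {
    "Incomplete course of vaccination": 40,
    "Inappropriate schedule of product administration": 20,
    "Incorrect dose administered": 20,
    "Product preparation issue": 13,
    "Product storage error": 7,
    "Incorrect route of product administration": 7,
    "Extra dose administered": 4,
    "Accidental underdose": 3,
    "Vaccination error": 3,
    "Product preparation error": 7,
    "Accidental exposure to product": 2,
    "Exposure via skin contact": 2,
}
_HARM_WEIGHTS = {
    "Injection site pain": 26,
    "Injection site erythema": 23,
    "Pain in extremity": 17,
    "Pyrexia": 15,
    "Pain": 15,
    "Injection site swelling": 15,
    "Headache": 12,
    "Chills": 10,
    "Erythema": 10,
    "Herpes zoster": 10,
    "Fatigue": 10,
    "Influenza like illness": 8,
    "Rash": 7,
    "Myalgia": 6,
    "Arthralgia": 6,
}


def _term_records() -> list[TermRecord]:
    pt_codes: dict[str, str] = {}
    records = []
    for pt, hlt, hlgt, soc, primary, _ in _VOCABULARY:
        code = pt_codes.setdefault(pt, f"1{len(pt_codes):07d}")
        records.append(TermRecord(pt, code, hlt, hlgt, soc, primary))
    return records


def mini_dictionary() -> Dictionary:
    """The curated in-memory terminology (identical to the written files)."""
    members = frozenset(canon(pt) for pt, *_, smq in _VOCABULARY if smq)
    return Dictionary(_term_records(), [SmqSet(ME_SMQ_NAME, members)])


def generate_dictionary(out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``terms.csv`` and ``smq.csv`` for the curated mini-terminology.

    Content is a fixed curated vocabulary (no randomness), so repeated
    runs are byte-identical by construction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    terms_path = out_dir / "terms.csv"
    smq_path = out_dir / "smq.csv"

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["pt_name", "pt_code", "hlt_name", "hlgt_name", "soc_name", "is_primary_soc"])
    for rec in _term_records():
        writer.writerow(
            [rec.pt_name, rec.pt_code, rec.hlt_name, rec.hlgt_name, rec.soc_name,
             "true" if rec.is_primary_soc else "false"]
        )
    terms_path.write_text(buf.getvalue(), encoding="utf-8")

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["smq_name", "pt_name"])
    for pt, *_, smq in _VOCABULARY:
        if smq:
            writer.writerow([ME_SMQ_NAME, pt])
    smq_path.write_text(buf.getvalue(), encoding="utf-8")
    return terms_path, smq_path


# -- generator configuration ---------------------------------------------


@dataclass(frozen=True)
class LaunchSpike:
    """A post-launch window with an elevated share of no-harm error reports."""

    start: date
    end: date  # inclusive
    p_me_without_harm: float

    def covers(self, d: date) -> bool:
        return self.start <= d <= self.end


def _default_category_mix() -> dict[str, float]:
    return {
        Category.NO_MEDICATION_ERROR.value: 0.55,
        Category.ME_WITHOUT_HARM.value: 0.25,
        Category.ME_WITH_HARM.value: 0.12,
        Category.POTENTIAL_ERROR.value: 0.04,
        Category.INTERCEPTED_ERROR.value: 0.04,
    }


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic spontaneous-report stream.

    The category mix, conflict rate, co-administration and multi-dose
    rates, and demographic marginals below emulate a vaccine safety
    database in the years around a product launch; term pools default to
    the full dictionary vocabulary partitioned by role.
    """

    seed: int = 0
    n_cases: int = 1000
    date_start: date = date(2017, 10, 1)
    date_end: date = date(2020, 12, 31)
    products: tuple[tuple[str, float], ...] = (("HZ-VAX", 0.75), ("FLU-VAX", 0.25))
    category_mix: dict[str, float] = field(default_factory=_default_category_mix)
    conflict_rate: float = 0.01
    coadmin_rate: float = 0.10
    multidose_rate: float = 0.20
    countries: dict[str, float] = field(
        default_factory=lambda: {"US": 0.50, "GB": 0.15, "DE": 0.12, "FR": 0.08,
                                 "CA": 0.08, "JP": 0.07}
    )
    sexes: dict[str, float] = field(
        default_factory=lambda: {"female": 0.55, "male": 0.40, "unknown": 0.05}
    )
    age_groups: dict[str, float] = field(
        default_factory=lambda: {"18-49": 0.10, "50-64": 0.35, "65-79": 0.35,
                                 "80+": 0.15, "unknown": 0.05}
    )
    me_term_pool: dict[str, float] | None = None
    harm_term_pool: dict[str, float] | None = None
    excluded_term_pool: dict[str, float] | None = None
    launch_spike: LaunchSpike | None = None

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        data = dict(data)
        for key in ("date_start", "date_end"):
            if isinstance(data.get(key), str):
                data[key] = date.fromisoformat(data[key])
        if "products" in data:
            data["products"] = tuple((str(n), float(w)) for n, w in data["products"])
        spike = data.get("launch_spike")
        if isinstance(spike, Mapping):
            data["launch_spike"] = LaunchSpike(
                start=date.fromisoformat(str(spike["start"])),
                end=date.fromisoformat(str(spike["end"])),
                p_me_without_harm=float(spike["p_me_without_harm"]),
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown generator config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def validate(self, dictionary: Dictionary) -> None:
        mix_total = sum(self.category_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ConfigError(f"category_mix probabilities sum to {mix_total}, not 1")
        valid = {c.value for c in Category} - {Category.CONFLICTING.value}
        if set(self.category_mix) - valid:
            raise ConfigError(
                f"category_mix keys must be in {sorted(valid)} "
                "(conflicting cases are governed by conflict_rate)"
            )
        for name, rate in (
            ("conflict_rate", self.conflict_rate),
            ("coadmin_rate", self.coadmin_rate),
            ("multidose_rate", self.multidose_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {rate}")
        if len(self.products) < 2 and self.coadmin_rate > 0:
            raise ConfigError("coadmin_rate > 0 requires at least two products")
        smq = dictionary.me_smq
        exclusion = dictionary.exclusion
        for pool_name, pool in (
            ("me_term_pool", self.me_term_pool),
            ("harm_term_pool", self.harm_term_pool),
            ("excluded_term_pool", self.excluded_term_pool),
        ):
            if pool is None:
                continue
            for pt in pool:
                if not dictionary.has_pt(pt):
                    raise ConfigError(f"{pool_name} references unknown PT {pt!r}")
                if pool_name == "me_term_pool" and pt not in smq:
                    raise ConfigError(f"{pool_name} PT {pt!r} is not in the ME SMQ")
                if pool_name == "harm_term_pool" and (pt in smq or pt in exclusion):
                    raise ConfigError(
                        f"{pool_name} PT {pt!r} must be outside the SMQ and exclusion set"
                    )

    def resolved_pools(self, dictionary: Dictionary) -> tuple[dict, dict, dict, list[str]]:
        """(me_pool, harm_pool, excluded_pool, intercepted_terms) with weights."""
        smq = dictionary.me_smq
        exclusion = dictionary.exclusion
        names = sorted(dictionary.pt_names())
        intercepted = [n for n in names if contains_intercepted(n)]
        if self.me_term_pool is not None:
            me_pool = dict(self.me_term_pool)
        else:
            me_pool = {
                n: float(_ME_WEIGHTS.get(n, 1))
                for n in names
                if n in smq and canon(n) != CIRCUMSTANCE_PT and not contains_intercepted(n)
            }
        if self.harm_term_pool is not None:
            harm_pool = dict(self.harm_term_pool)
        else:
            harm_pool = {
                n: float(_HARM_WEIGHTS.get(n, 1))
                for n in names
                if n not in smq and n not in exclusion and not contains_intercepted(n)
            }
        if self.excluded_term_pool is not None:
            excluded_pool = dict(self.excluded_term_pool)
        else:
            excluded_pool = {n: 1.0 for n in names if n in exclusion and n not in smq}
        return me_pool, harm_pool, excluded_pool, intercepted


# -- case generation ------------------------------------------------------


class _Sampler:
    def __init__(self, rng: np.random.Generator, pool: Mapping[str, float]):
        self.rng = rng
        self.names = list(pool)
        w = np.asarray([pool[n] for n in self.names], dtype=float)
        self.p = w / w.sum()

    def draw(self, k: int = 1) -> list[str]:
        k = min(k, len(self.names))
        idx = self.rng.choice(len(self.names), size=k, replace=False, p=self.p)
        return [self.names[i] for i in idx]


def generate_cases(
    config: GeneratorConfig, dictionary: Dictionary
) -> tuple[list[CaseReport], pd.DataFrame]:
    """Draw cases and the exact per-triple ground truth.

    For every (case, product, dose) triple an intended category is drawn
    first — conflicting with probability ``conflict_rate``, otherwise from
    ``category_mix`` (inside the launch-spike window the no-harm error
    probability is replaced by the boosted value, the remaining categories
    rescaled). PT sets realizing the intended category are then emitted
    with explicit (product, dose) links, so the classifier must reproduce
    the ground truth exactly.
    """
    config.validate(dictionary)
    rng = np.random.default_rng(config.seed)
    me_pool, harm_pool, excluded_pool, intercepted = config.resolved_pools(dictionary)
    if not me_pool or not harm_pool or not intercepted:
        raise ConfigError("term pools must be non-empty (ME, harm, intercepted)")
    me_s = _Sampler(rng, me_pool)
    harm_s = _Sampler(rng, harm_pool)
    excl_s = _Sampler(rng, excluded_pool) if excluded_pool else None
    circumstance = dictionary.display_name(CIRCUMSTANCE_PT)

    # base category probabilities over all six categories
    base = {c.value: 0.0 for c in Category}
    base[Category.CONFLICTING.value] = config.conflict_rate
    for cat, p in config.category_mix.items():
        base[cat] = (1.0 - config.conflict_rate) * p
    cat_names = [c.value for c in Category]
    base_p = np.asarray([base[c] for c in cat_names])

    spike_p = None
    if config.launch_spike is not None:
        boosted = config.launch_spike.p_me_without_harm
        rest = dict(base)
        me_wo = rest.pop(Category.ME_WITHOUT_HARM.value)
        scale = (1.0 - boosted) / (1.0 - me_wo) if me_wo < 1.0 else 0.0
        spike = {c: p * scale for c, p in rest.items()}
        spike[Category.ME_WITHOUT_HARM.value] = boosted
        spike_p = np.asarray([spike[c] for c in cat_names])

    product_names = [n for n, _ in config.products]
    product_w = np.asarray([w for _, w in config.products], dtype=float)
    product_w = product_w / product_w.sum()

    def marginal(d: Mapping[str, float]) -> str:
        names = list(d)
        w = np.asarray([d[n] for n in names], dtype=float)
        return names[rng.choice(len(names), p=w / w.sum())]

    n_days = (config.date_end - config.date_start).days
    cases: list[CaseReport] = []
    truth_rows: list[dict] = []
    for i in range(config.n_cases):
        case_id = f"C{i + 1:07d}"
        receipt = config.date_start + timedelta(days=int(rng.integers(0, n_days + 1)))
        country = marginal(config.countries)
        sex = marginal(config.sexes)
        age_group = marginal(config.age_groups)

        chosen = [product_names[rng.choice(len(product_names), p=product_w)]]
        if len(product_names) > 1 and rng.random() < config.coadmin_rate:
            others = [n for n in product_names if n != chosen[0]]
            chosen.append(others[int(rng.integers(0, len(others)))])

        products = []
        events: list[EventTerm] = []
        p_vec = (
            spike_p
            if config.launch_spike is not None and config.launch_spike.covers(receipt)
            else base_p
        )
        for product in chosen:
            n_doses = 2 if rng.random() < config.multidose_rate else 1
            doses = tuple(
                DoseRecord(dose_index=j + 1, dose_date=receipt - timedelta(days=30 * (n_doses - 1 - j)))
                for j in range(n_doses)
            )
            products.append(SuspectProduct(product_name=product, doses=doses))
            for dose in doses:
                cat = cat_names[rng.choice(len(cat_names), p=p_vec)]
                terms, harm_terms = _emit_terms(
                    cat, rng, me_s, harm_s, excl_s, intercepted, circumstance
                )
                for t in terms:
                    events.append(
                        EventTerm(pt_name=t, linked_product=product,
                                  linked_dose_index=dose.dose_index)
                    )
                truth_rows.append(
                    {
                        "case_id": case_id,
                        "product_name": product,
                        "dose_index": dose.dose_index,
                        "category": cat,
                        "harm_terms": "|".join(sorted(harm_terms)),
                    }
                )
        cases.append(
            CaseReport(
                case_id=case_id,
                receipt_date=receipt,
                country=country,
                sex=sex,
                age_group=age_group,
                products=tuple(products),
                events=tuple(events),
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["case_id", "product_name", "dose_index", "category", "harm_terms"],
    )
    return cases, truth


def _emit_terms(category, rng, me_s, harm_s, excl_s, intercepted, circumstance):
    """PT set whose rule-based classification is exactly ``category``."""
    terms: list[str] = []
    harm_terms: list[str] = []
    if category == Category.NO_MEDICATION_ERROR.value:
        k = int(rng.choice([0, 1, 2], p=[0.3, 0.5, 0.2]))
        if k:
            terms += harm_s.draw(k)
    elif category == Category.POTENTIAL_ERROR.value:
        terms.append(circumstance)
        if rng.random() < 0.3:
            terms += harm_s.draw(1)
    elif category == Category.INTERCEPTED_ERROR.value:
        terms.append(intercepted[int(rng.integers(0, len(intercepted)))])
        if rng.random() < 0.3:
            terms += harm_s.draw(1)
    elif category == Category.CONFLICTING.value:
        terms.append(circumstance)
        terms.append(intercepted[int(rng.integers(0, len(intercepted)))])
        if rng.random() < 0.3:
            terms += harm_s.draw(1)
    elif category == Category.ME_WITHOUT_HARM.value:
        terms += me_s.draw(int(rng.choice([1, 2], p=[0.7, 0.3])))
        if excl_s is not None and rng.random() < 0.25:
            terms += excl_s.draw(1)
    elif category == Category.ME_WITH_HARM.value:
        terms += me_s.draw(int(rng.choice([1, 2], p=[0.7, 0.3])))
        harm_terms = harm_s.draw(int(rng.choice([1, 2], p=[0.6, 0.4])))
        terms += harm_terms
        if excl_s is not None and rng.random() < 0.15:
            terms += excl_s.draw(1)
    else:  # pragma: no cover - guarded by config validation
        raise ConfigError(f"cannot emit terms for category {category!r}")
    return terms, harm_terms


def generate(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the full synthetic bundle: terms, SMQ, cases, ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    terms_path, smq_path = generate_dictionary(out_dir)
    dictionary = mini_dictionary()
    cases, truth = generate_cases(config, dictionary)
    cases_path = out_dir / "cases.jsonl"
    write_cases(cases, cases_path)
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path, index=False, lineterminator="\n")
    return {
        "terms": terms_path,
        "smq": smq_path,
        "cases": cases_path,
        "truth": truth_path,
    }
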