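"""Cohort construction: drug-name standardization, target/background split,
PT→SOC mapping, age subgrouping, and descriptive demographics.

The target cohort is defined the way FAERS pharmacovigilance studies define
it: reports naming the study drug as primary suspect (role code PS) with an
indication in the configured indication set; everything else is background.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

from .faers_io import CaseReport

logger = logging.getLogger("pvdisprop")

#: Default indication set for an inflammatory-bowel-disease cohort
#: (configurable; matched case-insensitively).
DEFAULT_IBD_INDICATIONS = frozenset(
    {
        "Ulcerative colitis",
        "Colitis ulcerative",
        "Crohn's disease",
        "Inflammatory bowel disease",
    }
)

AGE_GROUPS = ("under18", "a18to65", "over65", "unknown")

UNMAPPED_SOC = "Unmapped"


# ---------------------------------------------------------------------------
# Drug-name standardization
# ---------------------------------------------------------------------------


@dataclass
class SynonymDictionary:
    """Canonical drug name → set of synonyms, matched case- and
    punctuation-insensitively as token subsequences of the verbatim name."""

    synonyms: dict[str, set[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for canonical, syns in self.synonyms.items():
            for s in syns:
                key = " ".join(_tokens(s))
                if key in seen and seen[key] != canonical:
                    raise ValueError(f"synonym '{s}' maps to both {seen[key]} and {canonical}")
                seen[key] = canonical

    @classmethod
    def default(cls) -> "SynonymDictionary":
        return cls({"upadacitinib": {"RINVOQ", "UPADACITINIB"}})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynonymDictionary":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({str(k): {str(s) for s in v} for k, v in raw.items()})


def _tokens(s: str) -> list[str]:
    return re.sub(r"[^0-9a-z]+", " ", s.lower()).split()


def standardize_drug_name(verbatim: str, dictionary: SynonymDictionary) -> str | None:
    """Map a verbatim drug string to its canonical name, or ``None``.

    A synonym matches when its token sequence appears contiguously among the
    verbatim name's tokens, so "RINVOQ 45MG TABLET" and "upadacitinib."
    both match while "ADALIMUMAB" does not.
    """
    toks = _tokens(verbatim)
    for canonical, syns in dictionary.synonyms.items():
        for syn in syns:
            st = _tokens(syn)
            n = len(st)
            if n and any(toks[i : i + n] == st for i in range(len(toks) - n + 1)):
                return canonical
    return None


def standardize_cases(cases: list[CaseReport], dictionary: SynonymDictionary) -> int:
    """Fill ``canonical_name`` on every drug entry in place; returns the
    number of entries matched."""
    matched = 0
    for case in cases:
        for entry in case.drugs:
            entry.canonical_name = standardize_drug_name(entry.verbatim_name, dictionary)
            matched += entry.canonical_name is not None
    return matched


# ---------------------------------------------------------------------------
# Cohort selection
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Disjoint target/background partition of the deduplicated cases."""

    target_cases: list[CaseReport]
    background_cases: list[CaseReport]
    target_drug: str = ""
    indication_terms: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.target_cases) + len(self.background_cases)


def _case_indications(case: CaseReport, drug_entry=None) -> set[str]:
    terms = {t.casefold() for t in case.indications}
    if drug_entry is not None:
        terms |= {t.casefold() for t in drug_entry.indications}
    return terms


def select_cohort(
    cases: list[CaseReport],
    target_drug: str,
    role: str = "PS",
    indication_terms: frozenset[str] | set[str] | None = None,
) -> Cohort:
    """Split cases into target (study drug in the given role with a
    qualifying indication) and background (everything else).

    Indication matching is case-insensitive and accepts the term on the
    matching drug entry or on the case itself.  With
    ``indication_terms=None`` any indication (or none) qualifies.
    """
    if indication_terms is None:
        ind_keys: set[str] | None = None
    else:
        ind_keys = {t.casefold() for t in indication_terms}
    target, background = [], []
    for case in cases:
        hit = False
        for entry in case.drugs:
            if entry.canonical_name != target_drug or entry.role != role:
                continue
            if ind_keys is None or (_case_indications(case, entry) & ind_keys):
                hit = True
                break
        (target if hit else background).append(case)
    if not target:
        logger.warning("select_cohort: empty target cohort for drug '%s'", target_drug)
    return Cohort(
        target_cases=target,
        background_cases=background,
        target_drug=target_drug,
        indication_terms=frozenset(indication_terms or ()),
    )


def assign_age_group(age_years: float | None) -> str:
    """Age subgroup: [0,18) → under18, [18,65) → a18to65, [65,∞) → over65,
    missing → unknown."""
    if age_years is None:
        return "unknown"
    if age_years < 18:
        return "under18"
    if age_years < 65:
        return "a18to65"
    return "over65"


# ---------------------------------------------------------------------------
# PT → SOC vocabulary
# ---------------------------------------------------------------------------


@dataclass
class VocabularyMap:
    """Preferred-term → system-organ-class lookup (case-insensitive).

    This is a flat two-column stand-in for the licensed MedDRA hierarchy:
    the bundled map covers the terms emitted by the synthetic generator plus
    a selection of published upadacitinib signal terms; users supply their
    own TSV for real analyses.
    """

    pt_to_soc: dict[str, str]
    _keyed: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._keyed = {pt.casefold(): soc for pt, soc in self.pt_to_soc.items()}

    def lookup(self, pt: str) -> str:
        soc = self._keyed.get(pt.strip().casefold())
        if soc is None:
            logger.warning("map_pt_to_soc: unmapped PT '%s'", pt)
            return UNMAPPED_SOC
        return soc

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VocabularyMap":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        df.columns = [c.strip().lower() for c in df.columns]
        return cls(dict(zip(df["pt"], df["soc"])))

    @classmethod
    def bundled(cls) -> "VocabularyMap":
        with resources.as_file(resources.files("pvdisprop") / "data" / "pt_soc.tsv") as p:
            return cls.from_tsv(p)


def map_pt_to_soc(pt: str, vocab: VocabularyMap) -> str:
    """Exact case-insensitive PT→SOC lookup; unmapped terms route to
    "Unmapped" with a logged warning."""
    return vocab.lookup(pt)


# ---------------------------------------------------------------------------
# Descriptive demographics
# ---------------------------------------------------------------------------


def round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def percentage(count: int, denominator: int, ndigits: int = 2) -> float:
    """100·count/denominator rounded half-up; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * count / denominator, ndigits)


AGE_GROUP_LABELS = {"under18": "<18", "a18to65": "18-65", "over65": ">=65", "unknown": "Unknown"}

OUTCOME_LABELS = {
    "hospitalization": "Hospitalization",
    "death": "Death",
    "life_threatening": "Life threatening",
    "disability": "Disability",
}
OTHER_SERIOUS = "Other serious"


def demographics_from_counts(
    factor_counts: dict[str, dict[str, int]],
    denominators: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Build a demographics table directly from per-level counts.

    The denominator of each factor defaults to the sum of its level counts;
    ``denominators`` overrides per factor (used e.g. when a factor is
    tabulated over mentions rather than cases).
    """
    rows = []
    for factor, levels in factor_counts.items():
        denom = (denominators or {}).get(factor, sum(levels.values()))
        for level, count in levels.items():
            rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "count": count,
                    "percent": percentage(count, denom),
                }
            )
    return pd.DataFrame(rows, columns=["factor", "level", "count", "percent"])


def summarize_demographics(cases: list[CaseReport]) -> pd.DataFrame:
    """Descriptive summary of a cohort: report year, sex, age band, country,
    reporter type and serious outcomes, with counts and percentages.

    Single-denominator factors use the cohort size; the serious-outcomes
    factor is mention-level (a case contributes one count per outcome code)
    and its percentages use total mentions as denominator, so a case with
    several outcomes is counted under each.
    """
    n = len(cases)
    factors: dict[str, dict[str, int]] = {}

    years: dict[str, int] = {}
    for c in cases:
        label = str(c.fda_date.year) if c.fda_date else "Unknown"
        years[label] = years.get(label, 0) + 1
    factors["Year"] = dict(sorted(years.items()))

    sexes = {"Female": 0, "Male": 0, "Unknown": 0}
    for c in cases:
        sexes["Female" if c.sex == "F" else "Male" if c.sex == "M" else "Unknown"] += 1
    factors["Sex"] = sexes

    ages = {AGE_GROUP_LABELS[g]: 0 for g in AGE_GROUPS}
    for c in cases:
        ages[AGE_GROUP_LABELS[assign_age_group(c.age_years)]] += 1
    factors["Age (years)"] = ages

    countries: dict[str, int] = {}
    for c in cases:
        countries[c.country] = countries.get(c.country, 0) + 1
    factors["Country"] = dict(sorted(countries.items(), key=lambda kv: (-kv[1], kv[0])))

    reporters: dict[str, int] = {}
    for c in cases:
        label = c.reporter.capitalize()
        reporters[label] = reporters.get(label, 0) + 1
    factors["Reporter"] = dict(sorted(reporters.items(), key=lambda kv: (-kv[1], kv[0])))

    outcomes = {label: 0 for label in OUTCOME_LABELS.values()}
    outcomes[OTHER_SERIOUS] = 0
    n_mentions = 0
    for c in cases:
        for code in c.outcomes:
            label = OUTCOME_LABELS.get(code, OTHER_SERIOUS)
            outcomes[label] += 1
            n_mentions += 1
    factors["Serious outcomes"] = outcomes

    denominators = {f: n for f in factors}
    denominators["Serious outcomes"] = n_mentions
    return demographics_from_counts(factors, denominators)
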