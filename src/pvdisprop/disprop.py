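"""Disproportionality statistics for spontaneous-report signal detection.

For each adverse-event term a fourfold (2×2) table is built over distinct
(case, term) pairs:

    =============  ============  ============
                   target term   other terms
    target drug        a             b
    other drugs        c             d
    =============  ============  ============

and four estimators are computed with 95% intervals:

* ROR  = ad/(bc), CI on the log scale with SE = sqrt(1/a+1/b+1/c+1/d)
* PRR  = [a/(a+b)] / [c/(c+d)], Pearson χ² without continuity correction,
  CI on the log scale with SE = sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d))
* IC   = log2 of the relative reporting ratio aN/((a+c)(a+b)), with a
  two-sided 95% band IC ± 2·sqrt(V); V is a delta-method variance by
  default, or closed-form Bayesian posterior moments ("bate1998")
* EBGM = the same observed/expected ratio aN/((a+c)(a+b)) on the natural
  scale, CI like the ROR's.  No empirical-Bayes shrinkage is applied, so
  IC == log2(EBGM) holds identically; a gamma–Poisson shrinkage fit is out
  of scope.

A term is flagged as a signal when any (or, configurably, all) of the four
published threshold rules fire; terms with fewer than ``min_a`` target
reports (default 3) are never evaluated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .cohort import Cohort, VocabularyMap, assign_age_group
from .faers_io import CaseReport

logger = logging.getLogger("pvdisprop")

LN2 = math.log(2.0)
Z95 = 1.96

SIGNAL_COLUMNS = [
    "SOC", "PT", "n",
    "ROR", "ROR_lo95", "ROR_hi95",
    "PRR", "PRR_lo95", "PRR_hi95", "chi2",
    "IC", "IC025", "EBGM", "EBGM05",
    "flags",
]


@dataclass
class ContingencyTable:
    """Fourfold counts for one drug–term pair (distinct (case, term) pairs)."""

    term: str
    level: str  # "PT" or "SOC"
    a: float
    b: float
    c: float
    d: float
    soc: str = ""
    corrected: bool = False  # Haldane–Anscombe +0.5 applied

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass
class SignalScores:
    """All four estimators, intervals and χ² for one term."""

    term: str
    n: int
    ror: float
    ror_lo95: float
    ror_hi95: float
    prr: float
    prr_lo95: float
    prr_hi95: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    soc: str = ""
    undefined: bool = False
    corrected: bool = False


@dataclass
class SignalCriteria:
    """Published joint signal-detection thresholds.

    ror_rule: lower 95% CI bound > 1 and n ≥ min_n;
    prr_rule: PRR ≥ 2 (or > 2 with ``prr_inclusive=False``), χ² ≥ 4, n ≥ min_n;
    ic_rule: IC025 > 0;  ebgm_rule: EBGM05 > 2.
    ``combine`` is "any" (default: one firing rule flags a signal) or "all".
    """

    min_n: int = 3
    ror_ci_threshold: float = 1.0
    prr_threshold: float = 2.0
    prr_inclusive: bool = True
    chi2_threshold: float = 4.0
    ic025_threshold: float = 0.0
    ebgm05_threshold: float = 2.0
    combine: str = "any"


# ---------------------------------------------------------------------------
# Fourfold-table construction
# ---------------------------------------------------------------------------


def _case_terms(case: CaseReport, level: str, vocab: VocabularyMap | None) -> set[str]:
    if level == "PT":
        return {t for t in case.reactions}
    if vocab is None:
        raise ValueError("SOC-level analysis requires a VocabularyMap")
    return {vocab.lookup(t) for t in case.reactions}


def _term_counts(cases: Iterable[CaseReport], level: str, vocab: VocabularyMap | None):
    """Distinct (case, term) pair counts: per-term case counts keyed
    casefolded (first spelling wins for display) and the total pair count."""
    counts: dict[str, int] = {}
    display: dict[str, str] = {}
    total = 0
    for case in cases:
        terms = _case_terms(case, level, vocab)
        total += len(terms)
        for t in terms:
            key = t.casefold()
            display.setdefault(key, t)
            counts[key] = counts.get(key, 0) + 1
    return counts, display, total


def build_contingency(
    cohort: Cohort,
    level: str = "PT",
    min_a: int = 3,
    vocab: VocabularyMap | None = None,
    background_mode: str = "rest",
) -> list[ContingencyTable]:
    """Build one fourfold table per term with at least ``min_a`` target
    reports.

    Counting unit is the distinct (case, term) pair — a case contributes at
    most one count to any term — so a+b is the total number of target pairs
    and c+d the total number of background pairs.  ``background_mode``:

    * "rest" (default): c/d come from every non-target case;
    * "same_indication": c/d restricted to background cases that carry one
      of the cohort's indication terms (comparator with the same underlying
      disease).
    """
    if background_mode not in ("rest", "same_indication"):
        raise ValueError(f"unknown background_mode '{background_mode}'")
    background = cohort.background_cases
    if background_mode == "same_indication":
        keys = {t.casefold() for t in cohort.indication_terms}
        background = [
            case
            for case in background
            if ({t.casefold() for t in case.indications}
                | {t.casefold() for e in case.drugs for t in e.indications}) & keys
        ]
    tcounts, tdisplay, t_total = _term_counts(cohort.target_cases, level, vocab)
    bcounts, bdisplay, b_total = _term_counts(background, level, vocab)

    tables = []
    for key in sorted(tcounts):
        a = tcounts[key]
        if a < min_a:
            continue
        c = bcounts.get(key, 0)
        term = tdisplay.get(key) or bdisplay.get(key, key)
        soc = vocab.lookup(term) if (vocab is not None and level == "PT") else (term if level == "SOC" else "")
        tables.append(
            ContingencyTable(
                term=term, level=level, soc=soc,
                a=a, b=t_total - a, c=c, d=b_total - c,
            )
        )
    return tables


def apply_zero_cell_correction(t: ContingencyTable) -> ContingencyTable:
    """Haldane–Anscombe continuity correction: if b or c is zero, add 0.5
    to all four cells (flagged) so every estimator stays finite."""
    if t.b == 0 or t.c == 0:
        return ContingencyTable(
            term=t.term, level=t.level, soc=t.soc,
            a=t.a + 0.5, b=t.b + 0.5, c=t.c + 0.5, d=t.d + 0.5,
            corrected=True,
        )
    return t


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def ror_stat(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with 95% CI on the log scale."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if b * c == 0 or a * d == 0:
        return math.nan, math.nan, math.nan
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se)


def prr_stat(t: ContingencyTable) -> tuple[float, float, float, float]:
    """Proportional reporting ratio, its 95% CI, and the uncorrected
    Pearson χ² of the fourfold table."""
    a, b, c, d = t.a, t.b, t.c, t.d
    N = a + b + c + d
    chi2 = 0.0
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom > 0:
        chi2 = (a * d - b * c) ** 2 * N / denom
    if c == 0 or a == 0 or a + b == 0:
        return math.nan, math.nan, math.nan, chi2
    prr = (a * (c + d)) / (c * (a + b))
    se_sq = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(se_sq, 0.0))
    return prr, prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se), chi2


def _ic_variance_delta(a: float, ab: float, ac: float, N: float) -> float:
    # delta-method variance of log2[a·N/((a+c)(a+b))]; each margin term is
    # >= 1/N so the variance is non-negative on every table
    return (1 / LN2) ** 2 * (1 / a + 1 / ac + 1 / ab - 3 / N)


def _ic_moments_bate(a: float, ab: float, ac: float, N: float) -> tuple[float, float]:
    # closed-form posterior mean/variance of the information component with
    # conventional unit priors (Bate et al.-style BCPNN)
    a1, b1 = 1.0, 1.0  # row/column Beta priors
    g11 = 1.0
    alpha = beta = 2.0
    gamma = g11 * (N + alpha) * (N + beta) / ((ab + a1) * (ac + b1))
    e_ic = math.log2(
        (a + g11) * (N + alpha) * (N + beta) / ((N + gamma) * (ab + a1) * (ac + b1))
    )
    v_ic = (1 / LN2) ** 2 * (
        (N - a + gamma - g11) / ((a + g11) * (1 + N + gamma))
        + (N - ab + alpha - a1) / ((ab + a1) * (1 + N + alpha))
        + (N - ac + beta - b1) / ((ac + b1) * (1 + N + beta))
    )
    return e_ic, v_ic


def ic_stat(t: ContingencyTable, mode: str = "delta") -> tuple[float, float]:
    """Information component (log2 observed/expected) and its lower
    95% bound IC − 2·sqrt(V).

    ``mode="delta"`` (default) takes the point value from the plain
    relative reporting ratio with a delta-method variance; ``"bate1998"``
    uses closed-form Bayesian posterior moments with unit priors.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    N = a + b + c + d
    ab, ac = a + b, a + c
    if a == 0 or ab == 0 or ac == 0:
        return math.nan, math.nan
    if mode == "delta":
        ic = math.log2(a * N / (ac * ab))
        v = _ic_variance_delta(a, ab, ac, N)
    elif mode == "bate1998":
        ic, v = _ic_moments_bate(a, ab, ac, N)
    else:
        raise ValueError(f"unknown IC mode '{mode}'")
    return ic, ic - 2.0 * math.sqrt(v)


def ebgm_stat(t: ContingencyTable) -> tuple[float, float]:
    """Observed/expected reporting ratio aN/((a+c)(a+b)) with its lower 95%
    bound on the log scale (no empirical-Bayes shrinkage)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    N = a + b + c + d
    if a == 0 or (a + b) == 0 or (a + c) == 0:
        return math.nan, math.nan
    ebgm = a * N / ((a + c) * (a + b))
    if min(b, c, d) <= 0:
        return ebgm, math.nan
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ebgm, ebgm * math.exp(-Z95 * se)


def compute_scores(t: ContingencyTable, ic_mode: str = "delta") -> SignalScores:
    """Evaluate all four estimators on one table (zero-cell correction
    applied first when needed)."""
    n = int(round(t.a))
    tc = apply_zero_cell_correction(t)
    ror, ror_lo, ror_hi = ror_stat(tc)
    prr, prr_lo, prr_hi, chi2 = prr_stat(tc)
    ic, ic025 = ic_stat(tc, mode=ic_mode)
    ebgm, ebgm05 = ebgm_stat(tc)
    vals = (ror, prr, ic, ebgm)
    return SignalScores(
        term=t.term, soc=t.soc, n=n,
        ror=ror, ror_lo95=ror_lo, ror_hi95=ror_hi,
        prr=prr, prr_lo95=prr_lo, prr_hi95=prr_hi, chi2=chi2,
        ic=ic, ic025=ic025, ebgm=ebgm, ebgm05=ebgm05,
        undefined=any(math.isnan(v) for v in vals),
        corrected=tc.corrected,
    )


# ---------------------------------------------------------------------------
# Criteria and ranking
# ---------------------------------------------------------------------------


def _safe_gt(x: float, threshold: float) -> bool:
    return not math.isnan(x) and x > threshold


def evaluate_signal(s: SignalScores, criteria: SignalCriteria | None = None) -> dict[str, bool]:
    """Apply the four threshold rules; an undefined statistic fails its rule."""
    cr = criteria or SignalCriteria()
    n_ok = s.n >= cr.min_n
    prr_ok = (
        (s.prr >= cr.prr_threshold if cr.prr_inclusive else s.prr > cr.prr_threshold)
        if not math.isnan(s.prr)
        else False
    )
    rules = {
        "ror_rule": n_ok and _safe_gt(s.ror_lo95, cr.ror_ci_threshold),
        "prr_rule": n_ok and prr_ok and not math.isnan(s.chi2) and s.chi2 >= cr.chi2_threshold,
        "ic_rule": _safe_gt(s.ic025, cr.ic025_threshold),
        "ebgm_rule": _safe_gt(s.ebgm05, cr.ebgm05_threshold),
    }
    rules["signal"] = any(v for k, v in rules.items() if k != "signal") if cr.combine == "any" else all(
        v for k, v in rules.items() if k != "signal"
    )
    return rules


def scores_to_frame(scores: list[SignalScores], criteria: SignalCriteria | None = None) -> pd.DataFrame:
    """Tabulate scores in the standard signal-table column layout."""
    rows = []
    for s in scores:
        rules = evaluate_signal(s, criteria)
        flags = [k[:-5].upper() for k in ("ror_rule", "prr_rule", "ic_rule", "ebgm_rule") if rules[k]]
        if s.corrected:
            flags.append("corrected")
        rows.append(
            {
                "SOC": s.soc, "PT": s.term, "n": s.n,
                "ROR": s.ror, "ROR_lo95": s.ror_lo95, "ROR_hi95": s.ror_hi95,
                "PRR": s.prr, "PRR_lo95": s.prr_lo95, "PRR_hi95": s.prr_hi95,
                "chi2": s.chi2, "IC": s.ic, "IC025": s.ic025,
                "EBGM": s.ebgm, "EBGM05": s.ebgm05,
                "signal": rules["signal"],
                "flags": ",".join(flags),
            }
        )
    return pd.DataFrame(rows, columns=SIGNAL_COLUMNS[:-1] + ["signal", "flags"])


RANK_COLUMN = {"ror": "ROR", "prr": "PRR", "ic": "IC", "ebgm": "EBGM", "n": "n"}


def rank_signals(table: pd.DataFrame, by: str = "ror", top_k: int | None = None) -> pd.DataFrame:
    """Sort a signal table descending by one statistic; ties break by larger
    n, then term name ascending (deterministic)."""
    col = RANK_COLUMN.get(by, by)
    out = table.sort_values(
        [col, "n", "PT"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out.head(top_k) if top_k is not None else out


def signal_table(
    cohort: Cohort,
    level: str = "PT",
    min_a: int = 3,
    vocab: VocabularyMap | None = None,
    criteria: SignalCriteria | None = None,
    background_mode: str = "rest",
    ic_mode: str = "delta",
    rank_by: str = "ror",
    top_k: int | None = None,
) -> pd.DataFrame:
    """Full per-term analysis: fourfold tables → scores → criteria → ranked
    table (the Table 4-style layout)."""
    tables = build_contingency(cohort, level=level, min_a=min_a, vocab=vocab,
                               background_mode=background_mode)
    scores = [compute_scores(t, ic_mode=ic_mode) for t in tables]
    return rank_signals(scores_to_frame(scores, criteria), by=rank_by, top_k=top_k)


def subgroup_analysis(
    cohort: Cohort,
    level: str = "PT",
    min_a: int = 3,
    vocab: VocabularyMap | None = None,
    criteria: SignalCriteria | None = None,
    ic_mode: str = "delta",
    rank_by: str = "ror",
    top_k: int | None = None,
    subgroup_background: str = "within",
) -> dict[str, pd.DataFrame]:
    """Repeat the analysis inside each age band (<18, 18–65, ≥65).

    ``subgroup_background="within"`` (default, the common convention in
    FAERS subgroup analyses) restricts the background to the same age band;
    ``"global"`` keeps the full background.
    """
    out: dict[str, pd.DataFrame] = {}
    for group in ("under18", "a18to65", "over65"):
        target = [c for c in cohort.target_cases if assign_age_group(c.age_years) == group]
        if subgroup_background == "within":
            background = [c for c in cohort.background_cases if assign_age_group(c.age_years) == group]
        else:
            background = cohort.background_cases
        if not target:
            logger.warning("subgroup_analysis: no target cases in group %s", group)
            out[group] = pd.DataFrame(columns=SIGNAL_COLUMNS[:-1] + ["signal", "flags"])
            continue
        sub = Cohort(target, background, cohort.target_drug, cohort.indication_terms)
        out[group] = signal_table(
            sub, level=level, min_a=min_a, vocab=vocab, criteria=criteria,
            ic_mode=ic_mode, rank_by=rank_by, top_k=top_k,
        )
    return out
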