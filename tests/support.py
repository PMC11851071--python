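"""Shared test helpers: a minimal CaseReport factory and an independent
exact-rational oracle for the fourfold-table statistics.

The oracle evaluates every estimator with ``fractions.Fraction`` arithmetic
(points exactly; intervals from independently written float expressions) and
deliberately shares no code with the implementation under test.
"""

from __future__ import annotations

import math
from datetime import date
from fractions import Fraction as F

from pvdisprop import CaseReport, DrugEntry


def mk_case(
    caseid: str,
    pts: set[str] | list[str],
    target: bool = False,
    role: str = "PS",
    indication: str | None = "Ulcerative colitis",
    age: float | None = 40.0,
    sex: str = "F",
    start: date | None = None,
    event: date | None = None,
    country: str = "US",
    reporter: str = "consumer",
    outcomes: set[str] | None = None,
) -> CaseReport:
    """Construct a standardized case with one primary-suspect drug."""
    if target:
        drug = DrugEntry(1, role, "RINVOQ", canonical_name="upadacitinib")
    else:
        drug = DrugEntry(1, role, "ASPIRIN", canonical_name=None)
    if start is not None:
        drug.start_date, drug.start_precise = start, True
    if indication is not None:
        drug.indications.add(indication)
    return CaseReport(
        primaryid=caseid + "1",
        caseid=caseid,
        fda_date=date(2023, 6, 1),
        fda_precise=True,
        sex=sex,
        age_years=age,
        country=country,
        reporter=reporter,
        outcomes=outcomes or set(),
        event_date=event,
        event_precise=event is not None,
        drugs=[drug],
        reactions=set(pts),
    )


LN2 = math.log(2.0)


def oracle_scores(a: int, b: int, c: int, d: int) -> dict[str, float]:
    """Brute-force evaluation of all statistics in exact rational arithmetic
    (point values) with independently coded interval expressions."""
    fa, fb, fc, fd = F(a), F(b), F(c), F(d)
    N = fa + fb + fc + fd
    ror = fa * fd / (fb * fc)
    prr = fa * (fc + fd) / (fc * (fa + fb))
    chi2 = (fa * fd - fb * fc) ** 2 * N / ((fa + fb) * (fc + fd) * (fa + fc) * (fb + fd))
    rrr = fa * N / ((fa + fc) * (fa + fb))

    se_log_odds = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    se_log_prop = math.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    ic = math.log2(rrr.numerator) - math.log2(rrr.denominator)
    v_ic = (1.0 / LN2) ** 2 * float(F(1, a) + F(1, a + c) + F(1, a + b) - F(3, 1) / N)
    return {
        "ror": float(ror),
        "ror_lo95": float(ror) * math.exp(-1.96 * se_log_odds),
        "ror_hi95": float(ror) * math.exp(1.96 * se_log_odds),
        "prr": float(prr),
        "prr_lo95": float(prr) * math.exp(-1.96 * se_log_prop),
        "prr_hi95": float(prr) * math.exp(1.96 * se_log_prop),
        "chi2": float(chi2),
        "ic": ic,
        "ic025": ic - 2.0 * math.sqrt(v_ic),
        "ebgm": float(rrr),
        "ebgm05": float(rrr) * math.exp(-1.96 * se_log_odds),
    }


def relerr(x: float, y: float) -> float:
    if x == y:
        return 0.0
    return abs(x - y) / max(abs(x), abs(y), 1e-300)
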