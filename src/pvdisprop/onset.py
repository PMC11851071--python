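"""Time-to-onset analysis: days from suspect-drug therapy start to the
adverse event, summarized as median/IQR and binned counts."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import percentage
from .faers_io import CaseReport

#: Default bins (days): [0,30], (30,90], (90,180], (180,365], (365,inf).
#: "1 month" is 30 days, "3 months" 90, "1 year" 365.
DEFAULT_BINS: list[tuple[float, float]] = [
    (0, 30),
    (30, 90),
    (90, 180),
    (180, 365),
    (365, math.inf),
]


def bin_label(lo: float, hi: float) -> str:
    if math.isinf(hi):
        return f">{int(lo)}d"
    if lo == 0:
        return f"0-{int(hi)}d"
    return f"{int(lo) + 1}-{int(hi)}d"


@dataclass
class OnsetSummary:
    n_with_onset: int
    median_days: float
    q1_days: float
    q3_days: float
    bin_counts: dict[str, int]
    bin_percent: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"bin": label, "count": self.bin_counts[label], "percent": self.bin_percent[label]}
            for label in self.bin_counts
        ]
        return pd.DataFrame(rows, columns=["bin", "count", "percent"])


def compute_onset_days(case: CaseReport, target_drug: str) -> int | None:
    """Days from the earliest precise therapy start of a primary-suspect
    target-drug entry to the event date.

    Reports with a missing or imprecise (year- or month-only) date on
    either side, or an event before therapy start, yield ``None`` — they
    are excluded from the summary, mirroring the exclusion of inaccurate,
    missing or unknown onset times.
    """
    if case.event_date is None or not case.event_precise:
        return None
    starts = [
        e.start_date
        for e in case.drugs
        if e.canonical_name == target_drug and e.role == "PS"
        and e.start_date is not None and e.start_precise
    ]
    if not starts:
        return None
    days = (case.event_date - min(starts)).days
    return days if days >= 0 else None


def summarize_onset(
    days: list[int],
    bins: list[tuple[float, float]] | None = None,
) -> OnsetSummary:
    """Median, quartiles (linear interpolation, numpy's default type-7) and
    binned counts/percentages of onset times."""
    if not days:
        raise ValueError("summarize_onset: no onset times supplied")
    bins = bins if bins is not None else DEFAULT_BINS
    arr = np.asarray(days, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    counts: dict[str, int] = {}
    for lo, hi in bins:
        label = bin_label(lo, hi)
        if lo == bins[0][0]:  # first bin closed on the left
            counts[label] = int(((arr >= lo) & (arr <= hi)).sum())
        else:
            counts[label] = int(((arr > lo) & (arr <= hi)).sum())
    n = len(days)
    percents = {label: percentage(cnt, n) for label, cnt in counts.items()}
    return OnsetSummary(
        n_with_onset=n,
        median_days=float(med),
        q1_days=float(q1),
        q3_days=float(q3),
        bin_counts=counts,
        bin_percent=percents,
    )


def cohort_onset(cases: list[CaseReport], target_drug: str,
                 bins: list[tuple[float, float]] | None = None) -> OnsetSummary:
    """Onset summary over a list of target cases (cases without a usable
    onset are silently excluded)."""
    days = [d for c in cases if (d := compute_onset_days(c, target_drug)) is not None]
    return summarize_onset(days, bins)
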