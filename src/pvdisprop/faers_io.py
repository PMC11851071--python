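"""Readers for FAERS-style quarterly ASCII extracts.

FAERS (the FDA Adverse Event Reporting System) distributes each quarter as
seven "$"-delimited text tables: DEMO (demographics/administrative), DRUG,
REAC (MedDRA reaction terms), OUTC (outcomes), RPSR (report sources), THER
(therapy dates) and INDI (indications).  This module parses those tables,
removes duplicate case versions, and joins everything into case-level
:class:`CaseReport` records keyed by ``primaryid``.

Only the post-2012 primaryid-keyed ASCII dialect is supported; the legacy
ISR-keyed AERS format and the XML dialect are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

logger = logging.getLogger("pvdisprop")

DEFAULT_DELIMITER = "$"

TABLE_NAMES = ("demo", "drug", "reac", "outc", "rpsr", "ther", "indi")

#: Minimum columns each table must declare in its header (matched
#: case-insensitively).  Anything beyond these is carried along untouched.
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid"),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "rpsr": ("primaryid",),
    "ther": ("primaryid", "dsg_drug_seq", "start_dt"),
    "indi": ("primaryid", "indi_drug_seq", "indi_pt"),
}

#: Age-unit codes and their factor to years.
AGE_UNIT_TO_YEARS: dict[str, float] = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: Weight-unit codes and their factor to kilograms.
WEIGHT_UNIT_TO_KG: dict[str, float] = {"KG": 1.0, "LBS": 0.45359237, "GMS": 0.001}

AGE_YEARS_RANGE = (0.0, 120.0)
WEIGHT_KG_RANGE = (0.0, 500.0)

OUTCOME_CODES: dict[str, str] = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital_anomaly",
    "RI": "required_intervention",
    "OT": "other",
}

REPORTER_CODES: dict[str, str] = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other",
    "RN": "other",
    "LW": "other",
    "HP": "other",
}

DRUG_ROLES = ("PS", "SS", "C", "I")


class SchemaError(ValueError):
    """A table is missing a required column."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class RawQuarter:
    """Parsed record sets of one quarterly extract (pandas DataFrames,
    all-string dtype, lower-cased column names)."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    rpsr: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    quarter_label: str = ""
    n_bad_rows: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


@dataclass
class DrugEntry:
    """One drug mention inside a report.

    ``role`` is the FAERS role code: PS (primary suspect), SS (secondary
    suspect), C (concomitant) or I (interacting).  ``canonical_name`` stays
    ``None`` until drug-name standardization runs.
    """

    drug_seq: int
    role: str
    verbatim_name: str
    canonical_name: str | None = None
    start_date: date | None = None
    start_precise: bool = False
    end_date: date | None = None
    indications: set[str] = field(default_factory=set)


@dataclass
class CaseReport:
    """One deduplicated safety report (one per CASEID)."""

    primaryid: str
    caseid: str
    fda_date: date | None = None
    fda_precise: bool = False
    sex: str = "unknown"  # F / M / unknown
    age_years: float | None = None
    weight_kg: float | None = None
    country: str = "unknown"
    reporter: str = "unknown"
    outcomes: set[str] = field(default_factory=set)
    event_date: date | None = None
    event_precise: bool = False
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: set[str] = field(default_factory=set)
    indications: set[str] = field(default_factory=set)


@dataclass
class AssemblyStats:
    """Case-flow bookkeeping for the run log."""

    n_raw_demo: int = 0
    n_duplicates_removed: int = 0
    n_cases: int = 0
    n_orphan_rows: dict[str, int] = field(default_factory=dict)
    n_age_anomalies: int = 0
    n_weight_anomalies: int = 0


# ---------------------------------------------------------------------------
# Parsing primitives
# ---------------------------------------------------------------------------


def parse_faers_date(value: object) -> tuple[date | None, bool]:
    """Parse a FAERS date field.

    Returns ``(date, precise)``.  8-digit YYYYMMDD values are precise;
    6-digit YYYYMM and 4-digit YYYY values are padded with 01 and flagged
    imprecise (they still order dedup but are excluded from onset
    computation).  Anything else is missing.
    """
    if value is None:
        return None, False
    s = str(value).strip()
    if not s.isdigit():
        return None, False
    try:
        if len(s) == 8:
            return date(int(s[:4]), int(s[4:6]), int(s[6:8])), True
        if len(s) == 6:
            return date(int(s[:4]), int(s[4:6]), 1), False
        if len(s) == 4:
            return date(int(s), 1, 1), False
    except ValueError:
        return None, False
    return None, False


def _date_sort_key(value: object) -> int:
    """Integer sort key for dedup ordering; missing dates sort earliest."""
    if value is None:
        return -1
    s = str(value).strip()
    if not s.isdigit():
        return -1
    if len(s) == 8:
        return int(s)
    if len(s) == 6:
        return int(s) * 100 + 1
    if len(s) == 4:
        return int(s) * 10000 + 101
    return -1


def normalize_age(age_value: object, age_code: object) -> float | None:
    """Convert an (age, unit-code) pair to years.

    Unrecognized codes, unparseable values and results outside [0, 120]
    years yield ``None`` (the caller counts those as anomalies).
    """
    if age_value is None or age_code is None:
        return None
    code = str(age_code).strip().upper()
    factor = AGE_UNIT_TO_YEARS.get(code)
    if factor is None:
        return None
    try:
        years = float(str(age_value).strip()) * factor
    except ValueError:
        return None
    lo, hi = AGE_YEARS_RANGE
    if not (lo <= years <= hi):
        return None
    return years


def normalize_weight(wt_value: object, wt_code: object) -> float | None:
    """Convert a (weight, unit-code) pair to kilograms; mirror of
    :func:`normalize_age` with a [0, 500] kg plausibility window."""
    if wt_value is None or wt_code is None:
        return None
    code = str(wt_code).strip().upper()
    factor = WEIGHT_UNIT_TO_KG.get(code)
    if factor is None:
        return None
    try:
        kg = float(str(wt_value).strip()) * factor
    except ValueError:
        return None
    lo, hi = WEIGHT_KG_RANGE
    if not (lo <= kg <= hi):
        return None
    return kg


# ---------------------------------------------------------------------------
# Table reading
# ---------------------------------------------------------------------------


def read_table(path: str | Path, table: str, delimiter: str = DEFAULT_DELIMITER) -> pd.DataFrame:
    """Read one "$"-delimited FAERS ASCII table.

    Column names are matched case-insensitively and lower-cased; all values
    are kept as strings.  Rows with the wrong number of fields are counted
    and skipped, never fatal.  A missing required column raises
    :class:`SchemaError` naming the table and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table.upper()} file not found: {path}")
    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        engine="python",
        on_bad_lines="skip",
    )
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS.get(table, ()):
        if col not in df.columns:
            raise SchemaError(f"table {table.upper()}: required column '{col}' missing from {path}")
    # empty strings -> missing marker stays as ""; strip stray whitespace
    for col in df.columns:
        df[col] = df[col].str.strip()
    df = df[df["primaryid"] != ""].reset_index(drop=True)
    return df


def read_quarter(
    paths: dict[str, str | Path],
    delimiter: str = DEFAULT_DELIMITER,
    quarter_label: str = "",
) -> RawQuarter:
    """Read the seven tables of one quarterly extract.

    ``paths`` maps table name ("demo", "drug", ...) to its file.  Missing
    optional tables (rpsr) may be omitted; DEMO, DRUG and REAC are required.
    """
    tables: dict[str, pd.DataFrame] = {}
    n_bad: dict[str, int] = {}
    for name in TABLE_NAMES:
        if name in paths:
            raw_lines = sum(1 for _ in open(paths[name], encoding="utf-8", errors="replace")) - 1
            tables[name] = read_table(paths[name], name, delimiter)
            n_bad[name] = max(0, raw_lines - len(tables[name]))
        else:
            if name in ("demo", "drug", "reac"):
                raise FileNotFoundError(f"required table {name.upper()} not supplied")
            tables[name] = pd.DataFrame(columns=list(REQUIRED_COLUMNS[name]))
            n_bad[name] = 0
    return RawQuarter(quarter_label=quarter_label, n_bad_rows=n_bad, **tables)


def find_quarter_files(directory: str | Path) -> dict[str, Path]:
    """Locate the seven tables inside a directory by file-name prefix
    (DEMO*.txt, DRUG*.txt, ... case-insensitive)."""
    directory = Path(directory)
    paths: dict[str, Path] = {}
    for name in TABLE_NAMES:
        hits = sorted(
            p for p in directory.iterdir()
            if p.is_file() and p.name.lower().startswith(name) and p.suffix.lower() == ".txt"
        )
        if hits:
            paths[name] = hits[0]
    return paths


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


def deduplicate_cases(demo: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep one DEMO record per CASEID: the most recent by FDA_DT.

    Ties on (caseid, fda_dt) keep the larger primaryid — in FAERS practice a
    later primaryid is the later submission.  Missing dates sort earliest,
    so any dated record wins over an undated one.  Returns the surviving
    records and the number removed.
    """
    if "caseid" not in demo.columns:
        raise SchemaError("table DEMO: required column 'caseid' missing")
    df = demo.copy()
    df["_fda_key"] = df.get("fda_dt", pd.Series("", index=df.index)).map(_date_sort_key)
    df["_pid_key"] = pd.to_numeric(df["primaryid"], errors="coerce").fillna(-1)
    df = df.sort_values(
        ["caseid", "_fda_key", "_pid_key", "primaryid"], kind="mergesort"
    ).drop_duplicates("caseid", keep="last")
    removed = len(demo) - len(df)
    df = df.drop(columns=["_fda_key", "_pid_key"]).sort_index().reset_index(drop=True)
    if removed:
        logger.info("deduplicate_cases: removed %d duplicate case version(s)", removed)
    return df, removed


# ---------------------------------------------------------------------------
# Assembly into CaseReports
# ---------------------------------------------------------------------------


def _get(row: dict, col: str) -> str:
    v = row.get(col, "")
    return "" if v is None else str(v)


def _iter_rows(df: pd.DataFrame):
    # column-wise iteration; much faster than iterrows on large extracts
    cols = list(df.columns)
    for values in zip(*(df[c].tolist() for c in cols)):
        yield dict(zip(cols, values))


def _clean_pt(pt: str) -> str:
    return " ".join(pt.split())


def assemble_cases(quarters: list[RawQuarter]) -> tuple[list[CaseReport], AssemblyStats]:
    """Join the seven tables into deduplicated case-level records.

    Deduplication runs across the union of all quarters (a follow-up in a
    later quarter supersedes the original).  Child rows whose primaryid has
    no surviving DEMO record — including the earlier versions of
    deduplicated cases — are dropped and counted as orphans.
    """
    stats = AssemblyStats()
    demo_all = pd.concat([q.demo for q in quarters], ignore_index=True)
    stats.n_raw_demo = len(demo_all)
    demo, stats.n_duplicates_removed = deduplicate_cases(demo_all)

    keep = set(demo["primaryid"])
    child: dict[str, pd.DataFrame] = {}
    for name in ("drug", "reac", "outc", "rpsr", "ther", "indi"):
        tbl = pd.concat([q.table(name) for q in quarters], ignore_index=True)
        if len(tbl):
            mask = tbl["primaryid"].isin(keep)
            stats.n_orphan_rows[name] = int((~mask).sum())
            tbl = tbl[mask]
        else:
            stats.n_orphan_rows[name] = 0
        child[name] = tbl

    cases: dict[str, CaseReport] = {}
    for row in _iter_rows(demo):
        pid = _get(row, "primaryid")
        fda_date, fda_precise = parse_faers_date(_get(row, "fda_dt"))
        event_date, event_precise = parse_faers_date(_get(row, "event_dt"))
        sex = _get(row, "sex").upper()
        age_raw = _get(row, "age")
        age = normalize_age(age_raw, _get(row, "age_cod")) if age_raw else None
        if age_raw and age is None:
            stats.n_age_anomalies += 1
        wt_raw = _get(row, "wt")
        wt = normalize_weight(wt_raw, _get(row, "wt_cod")) if wt_raw else None
        if wt_raw and wt is None:
            stats.n_weight_anomalies += 1
        country = _get(row, "occr_country") or _get(row, "reporter_country") or "unknown"
        occp = _get(row, "occp_cod").upper()
        cases[pid] = CaseReport(
            primaryid=pid,
            caseid=_get(row, "caseid"),
            fda_date=fda_date,
            fda_precise=fda_precise,
            sex=sex if sex in ("F", "M") else "unknown",
            age_years=age,
            weight_kg=wt,
            country=country,
            reporter=REPORTER_CODES.get(occp, "unknown" if not occp else "other"),
            event_date=event_date,
            event_precise=event_precise,
        )

    for row in _iter_rows(child["drug"]):
        case = cases.get(_get(row, "primaryid"))
        if case is None:
            continue
        try:
            seq = int(float(_get(row, "drug_seq") or "0"))
        except ValueError:
            seq = 0
        role = _get(row, "role_cod").upper()
        case.drugs.append(
            DrugEntry(
                drug_seq=seq,
                role=role if role in DRUG_ROLES else "C",
                verbatim_name=_get(row, "drugname"),
            )
        )

    for row in _iter_rows(child["reac"]):
        case = cases.get(_get(row, "primaryid"))
        pt = _clean_pt(_get(row, "pt"))
        if case is None or not pt:
            continue
        if pt.casefold() not in {r.casefold() for r in case.reactions}:
            case.reactions.add(pt)

    for row in _iter_rows(child["outc"]):
        case = cases.get(_get(row, "primaryid"))
        code = _get(row, "outc_cod").upper()
        if case is not None and code in OUTCOME_CODES:
            case.outcomes.add(OUTCOME_CODES[code])

    for row in _iter_rows(child["ther"]):
        case = cases.get(_get(row, "primaryid"))
        if case is None:
            continue
        try:
            seq = int(float(_get(row, "dsg_drug_seq") or "0"))
        except ValueError:
            continue
        start, precise = parse_faers_date(_get(row, "start_dt"))
        end, _ = parse_faers_date(_get(row, "end_dt"))
        for entry in case.drugs:
            if entry.drug_seq == seq:
                entry.start_date, entry.start_precise = start, precise
                entry.end_date = end

    for row in _iter_rows(child["indi"]):
        case = cases.get(_get(row, "primaryid"))
        term = _clean_pt(_get(row, "indi_pt"))
        if case is None or not term:
            continue
        try:
            seq = int(float(_get(row, "indi_drug_seq") or "0"))
        except ValueError:
            seq = 0
        attached = False
        for entry in case.drugs:
            if entry.drug_seq == seq:
                entry.indications.add(term)
                attached = True
                break
        if not attached:
            case.indications.add(term)

    stats.n_cases = len(cases)
    out = [cases[pid] for pid in demo["primaryid"]]
    return out, stats


def cases_to_dataframe(cases: list[CaseReport]) -> pd.DataFrame:
    """Flatten cases to one row each for inspection/serialization
    (nested fields JSON-encoded)."""
    import json

    rows = []
    for c in cases:
        rows.append(
            {
                "primaryid": c.primaryid,
                "caseid": c.caseid,
                "fda_date": c.fda_date.isoformat() if c.fda_date else "",
                "sex": c.sex,
                "age_years": c.age_years if c.age_years is not None else "",
                "weight_kg": c.weight_kg if c.weight_kg is not None else "",
                "country": c.country,
                "reporter": c.reporter,
                "outcomes": json.dumps(sorted(c.outcomes)),
                "event_date": c.event_date.isoformat() if c.event_date else "",
                "reactions": json.dumps(sorted(c.reactions)),
                "indications": json.dumps(sorted(c.indications)),
                "drugs": json.dumps(
                    [
                        {
                            "drug_seq": d.drug_seq,
                            "role": d.role,
                            "verbatim_name": d.verbatim_name,
                            "canonical_name": d.canonical_name,
                            "indications": sorted(d.indications),
                        }
                        for d in c.drugs
                    ]
                ),
            }
        )
    return pd.DataFrame(rows)
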