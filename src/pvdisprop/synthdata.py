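"""Synthetic FAERS-style data with known ground truth.

The generator writes the seven quarterly ASCII tables (DEMO, DRUG, REAC,
OUTC, RPSR, THER, INDI) in the "$"-delimited dialect the reader consumes,
for a configurable number of cases, and records exactly what it planted in
a :class:`Manifest`: which cases are target-drug/indication cases, each
case's reaction set and onset time, and the realized fourfold counts
(a, b, c, d) per preferred term.  Reporting-rate ratios can be planted on
chosen terms among the target cohort, letting recovery tests compare
estimated against planted disproportionality.

Everything is driven by one numpy Generator seeded from the config, so the
same config always produces byte-identical files and manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np

TARGET_CANONICAL = "upadacitinib"

#: Verbatim spellings used for the target drug, to exercise standardization.
TARGET_VERBATIMS = ("RINVOQ", "UPADACITINIB", "rinvoq 45mg")

BACKGROUND_DRUGS = (
    "ADALIMUMAB", "INFLIXIMAB", "METHOTREXATE", "PREDNISONE", "ASPIRIN",
    "IBUPROFEN", "METFORMIN", "ATORVASTATIN", "LISINOPRIL", "OMEPRAZOLE",
)

IBD_INDICATIONS = ("Ulcerative colitis", "Crohn's disease", "Inflammatory bowel disease")
NON_IBD_INDICATION = "Rheumatoid arthritis"

#: (PT, SOC, background reporting probability).  Mean ~1.75 PTs per case.
DEFAULT_PT_CATALOG: tuple[tuple[str, str, float], ...] = (
    ("Headache", "Nervous system disorders", 0.20),
    ("Nausea", "Gastrointestinal disorders", 0.18),
    ("Fatigue", "General disorders and administration site conditions", 0.16),
    ("Diarrhoea", "Gastrointestinal disorders", 0.14),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.12),
    ("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.10),
    ("Pyrexia", "General disorders and administration site conditions", 0.10),
    ("Vomiting", "Gastrointestinal disorders", 0.09),
    ("Dizziness", "Nervous system disorders", 0.08),
    ("Pruritus", "Skin and subcutaneous tissue disorders", 0.07),
    ("Insomnia", "Psychiatric disorders", 0.06),
    ("Cough", "Respiratory, thoracic and mediastinal disorders", 0.06),
    ("Abdominal pain", "Gastrointestinal disorders", 0.05),
    ("Anxiety", "Psychiatric disorders", 0.05),
    ("Back pain", "Musculoskeletal and connective tissue disorders", 0.05),
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.04),
    ("Constipation", "Gastrointestinal disorders", 0.04),
    ("Oedema peripheral", "General disorders and administration site conditions", 0.03),
    ("Acne", "Skin and subcutaneous tissue disorders", 0.03),
    ("Haematochezia", "Gastrointestinal disorders", 0.02),
    ("Nasopharyngitis", "Infections and infestations", 0.02),
    ("Flatulence", "Gastrointestinal disorders", 0.02),
    ("Herpes zoster", "Infections and infestations", 0.01),
    ("Frequent bowel movements", "Gastrointestinal disorders", 0.01),
    ("Blood cholesterol increased", "Investigations", 0.008),
    ("Pulmonary embolism", "Respiratory, thoracic and mediastinal disorders", 0.008),
    ("Product residue present", "Investigations", 0.004),
)

WINDOW_START = date(2019, 7, 1)
WINDOW_END = date(2024, 3, 31)


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults describe a mid-sized spontaneous
    reporting database with a ~10% target-cohort share.

    ``planted_signals`` maps PT → reporting-rate ratio applied inside the
    target cohort (its reporting probability becomes min(1, ratio·p)); all
    other terms keep their background probability, i.e. ratio 1.
    """

    seed: int = 0
    n_cases: int = 5000
    target_share: float = 0.12          # P(case names the target drug as PS)
    indication_share: float = 0.85      # P(IBD indication | target PS case)
    background_indication_share: float = 0.05
    target_ss_rate: float = 0.02        # P(bg case also lists target as SS)
    pt_catalog: tuple[tuple[str, str, float], ...] = DEFAULT_PT_CATALOG
    planted_signals: dict[str, float] = field(default_factory=dict)
    duplicate_rate: float = 0.05
    missing_age_rate: float = 0.20
    age_anomaly_rate: float = 0.01
    missing_date_rate: float = 0.30
    imprecise_date_rate: float = 0.05
    onset_mu: float = 3.7               # log-days; exp(3.7) ~ 40-day median
    onset_sigma: float = 1.9
    sex_probs: dict[str, float] = field(default_factory=lambda: {"F": 0.45, "M": 0.42, "": 0.13})
    country_probs: dict[str, float] = field(
        default_factory=lambda: {"US": 0.70, "JP": 0.06, "DE": 0.05, "GB": 0.05,
                                 "FR": 0.05, "CA": 0.05, "BR": 0.04}
    )
    reporter_probs: dict[str, float] = field(
        default_factory=lambda: {"CN": 0.55, "MD": 0.25, "PH": 0.15, "OT": 0.04, "": 0.01}
    )
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: {"HO": 0.35, "OT": 0.40, "DE": 0.08, "LT": 0.07,
                                 "DS": 0.05, "RI": 0.03, "CA": 0.02}
    )
    quarter_label: str = "SYN"

    def validate(self) -> list[str]:
        warnings = []
        for name in ("target_share", "indication_share", "duplicate_rate",
                     "missing_age_rate", "missing_date_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        catalog_pts = {pt for pt, _, _ in self.pt_catalog}
        for pt, ratio in self.planted_signals.items():
            if ratio <= 0:
                raise ValueError(f"planted ratio for {pt} must be > 0")
            if pt not in catalog_pts:
                raise ValueError(f"planted PT '{pt}' not in pt_catalog")
            p = next(p for name, _, p in self.pt_catalog if name == pt)
            if ratio * p > 1.0:
                warnings.append(f"planted probability for {pt} clamped to 1 (ratio {ratio} x p {p})")
        return warnings

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pt_catalog" in raw:
            raw["pt_catalog"] = tuple(tuple(row) for row in raw["pt_catalog"])
        return cls(**raw)


@dataclass
class Manifest:
    """Ground truth recorded at generation time."""

    n_cases: int
    n_unique_cases: int
    n_duplicates: int
    n_target_ps: int              # cases with target drug as PS (any indication)
    n_cohort_target: int          # PS + IBD indication: the analysis target
    target_pairs: int             # distinct (case, PT) pairs in the target cohort
    background_pairs: int
    per_pt: dict[str, dict[str, int]]   # pt -> {a, b, c, d}
    onset_days: list[int]               # truth for cases with recoverable onset
    table_rows: dict[str, int]
    per_case: list[dict]
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path, include_case_truth: bool = True) -> None:
        payload = asdict(self)
        if not include_case_truth:
            payload["per_case"] = []
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "Manifest":
        return cls(**json.loads(Path(path).read_text()))


def _categorical(rng: np.random.Generator, probs: dict[str, float], n: int) -> np.ndarray:
    labels = list(probs)
    p = np.asarray([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=n, p=p)


def _fmt_date(d: date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> Manifest:
    """Generate one synthetic quarterly extract and write the seven ASCII
    tables plus ``manifest.json`` into ``out_dir``."""
    warnings = config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    K = len(config.pt_catalog)
    pts = [pt for pt, _, _ in config.pt_catalog]
    p_bg = np.array([p for _, _, p in config.pt_catalog], dtype=float)

    # --- latent case-level draws (fixed order for determinism) ------------
    is_target_ps = rng.random(n) < config.target_share
    has_ind = is_target_ps & (rng.random(n) < config.indication_share)
    bg_ind = ~is_target_ps & (rng.random(n) < config.background_indication_share)
    target_ss = ~is_target_ps & (rng.random(n) < config.target_ss_rate)
    cohort = is_target_ps & has_ind

    probs = np.tile(p_bg, (n, 1))
    for pt, ratio in config.planted_signals.items():
        j = pts.index(pt)
        probs[cohort, j] = min(1.0, ratio * p_bg[j])
    react = rng.random((n, K)) < probs

    fda_offsets = rng.integers(0, (WINDOW_END - WINDOW_START).days + 1, n)
    dup = rng.random(n) < config.duplicate_rate
    dup_delta = rng.integers(1, 91, n)

    true_age = np.clip(rng.normal(47.0, 17.0, n), 1.0, 95.0)
    age_missing = rng.random(n) < config.missing_age_rate
    age_anomal = ~age_missing & (rng.random(n) < config.age_anomaly_rate)
    age_code_pick = rng.random(n)

    sex = _categorical(rng, config.sex_probs, n)
    country = _categorical(rng, config.country_probs, n)
    occp = _categorical(rng, config.reporter_probs, n)
    n_outc = rng.choice([0, 1, 2], size=n, p=[0.45, 0.45, 0.10])

    onset_draw = np.floor(rng.lognormal(config.onset_mu, config.onset_sigma, n)).astype(int)
    report_delay = rng.integers(0, 61, n)
    has_start = cohort & (rng.random(n) >= config.missing_date_rate)
    imprecise = has_start & (rng.random(n) < config.imprecise_date_rate)
    verbatim_pick = rng.integers(0, len(TARGET_VERBATIMS), n)
    ind_pick = rng.integers(0, len(IBD_INDICATIONS), n)
    bg_drug_pick = rng.integers(0, len(BACKGROUND_DRUGS), n)
    concomitant = rng.random(n) < 0.3
    outc_labels = list(config.outcome_probs)
    outc_p = np.asarray([config.outcome_probs[k] for k in outc_labels], dtype=float)
    outc_p /= outc_p.sum()
    rpsr = _categorical(rng, {"FGN": 0.3, "HLP": 0.4, "OTH": 0.3}, n)

    # --- assemble rows ----------------------------------------------------
    rows: dict[str, list[str]] = {t: [] for t in
                                  ("demo", "drug", "reac", "outc", "rpsr", "ther", "indi")}
    per_case: list[dict] = []
    onset_truth: list[int] = []

    for i in range(n):
        caseid = 100000 + i
        fda = WINDOW_START + timedelta(days=int(fda_offsets[i]))
        versions = [(str(caseid * 10 + 1), "1", fda)]
        if dup[i]:
            versions.append((str(caseid * 10 + 2), "2", fda + timedelta(days=int(dup_delta[i]))))

        if age_missing[i]:
            age_str, age_cod, age_truth = "", "", None
        elif age_anomal[i]:
            age_str, age_cod, age_truth = "250", "YR", None
        elif age_code_pick[i] < 0.8:
            v = int(round(true_age[i]))
            age_str, age_cod, age_truth = str(v), "YR", float(v)
        elif age_code_pick[i] < 0.9:
            months = int(round(true_age[i] * 12))
            age_str, age_cod, age_truth = str(months), "MON", months / 12.0
        else:
            dec = round(float(true_age[i]) / 10.0, 2)
            age_str, age_cod, age_truth = repr(dec), "DEC", dec * 10.0

        pt_idx = np.nonzero(react[i])[0]
        case_pts = [pts[j] for j in pt_idx]

        event_str = ""
        start_str = ""
        onset_ok = None
        if cohort[i] and has_start[i]:
            start = fda - timedelta(days=int(onset_draw[i]) + int(report_delay[i]))
            event = start + timedelta(days=int(onset_draw[i]))
            event_str = _fmt_date(event)
            if imprecise[i]:
                start_str = f"{start.year:04d}{start.month:02d}"
            else:
                start_str = _fmt_date(start)
                onset_ok = int(onset_draw[i])
                onset_truth.append(onset_ok)

        if n_outc[i] > 0:
            codes = list(rng.choice(outc_labels, size=int(n_outc[i]), replace=False, p=outc_p))
        else:
            codes = []

        for pid, version, vdate in versions:
            rows["demo"].append(
                "$".join([pid, str(caseid), version, _fmt_date(vdate), sex[i],
                          age_str, age_cod, "", "", country[i], occp[i], event_str])
            )
            if is_target_ps[i]:
                rows["drug"].append("$".join([pid, str(caseid), "1", "PS",
                                              TARGET_VERBATIMS[verbatim_pick[i]]]))
                if concomitant[i]:
                    rows["drug"].append("$".join([pid, str(caseid), "2", "C", "MESALAZINE"]))
                if has_ind[i]:
                    rows["indi"].append("$".join([pid, str(caseid), "1",
                                                  IBD_INDICATIONS[ind_pick[i]]]))
                else:
                    rows["indi"].append("$".join([pid, str(caseid), "1", NON_IBD_INDICATION]))
                if start_str:
                    rows["ther"].append("$".join([pid, str(caseid), "1", start_str, ""]))
            else:
                rows["drug"].append("$".join([pid, str(caseid), "1", "PS",
                                              BACKGROUND_DRUGS[bg_drug_pick[i]]]))
                if target_ss[i]:
                    rows["drug"].append("$".join([pid, str(caseid), "2", "SS",
                                                  TARGET_VERBATIMS[verbatim_pick[i]]]))
                if bg_ind[i]:
                    rows["indi"].append("$".join([pid, str(caseid), "1",
                                                  IBD_INDICATIONS[ind_pick[i]]]))
            for pt in case_pts:
                rows["reac"].append("$".join([pid, str(caseid), pt]))
            for code in codes:
                rows["outc"].append("$".join([pid, str(caseid), code]))
            rows["rpsr"].append("$".join([pid, str(caseid), rpsr[i]]))

        per_case.append(
            {
                "caseid": str(caseid),
                "is_target_ps": bool(is_target_ps[i]),
                "is_cohort_target": bool(cohort[i]),
                "indication": (IBD_INDICATIONS[ind_pick[i]] if (has_ind[i] or bg_ind[i])
                               else (NON_IBD_INDICATION if is_target_ps[i] else None)),
                "pts": case_pts,
                "age_years": age_truth,
                "onset_days": onset_ok,
            }
        )

    # --- realized fourfold truth -------------------------------------------
    a_counts = react[cohort].sum(axis=0)
    c_counts = react[~cohort].sum(axis=0)
    target_pairs = int(react[cohort].sum())
    background_pairs = int(react[~cohort].sum())
    per_pt = {
        pts[j]: {
            "a": int(a_counts[j]),
            "b": target_pairs - int(a_counts[j]),
            "c": int(c_counts[j]),
            "d": background_pairs - int(c_counts[j]),
        }
        for j in range(K)
    }

    headers = {
        "demo": "primaryid$caseid$caseversion$fda_dt$sex$age$age_cod$wt$wt_cod$occr_country$occp_cod$event_dt",
        "drug": "primaryid$caseid$drug_seq$role_cod$drugname",
        "reac": "primaryid$caseid$pt",
        "outc": "primaryid$caseid$outc_cod",
        "rpsr": "primaryid$caseid$rpsr_cod",
        "ther": "primaryid$caseid$dsg_drug_seq$start_dt$end_dt",
        "indi": "primaryid$caseid$indi_drug_seq$indi_pt",
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, lines in rows.items():
        path = out_dir / f"{name.upper()}{config.quarter_label}.txt"
        path.write_text("\n".join([headers[name]] + lines) + "\n")

    manifest = Manifest(
        n_cases=n,
        n_unique_cases=n,
        n_duplicates=int(dup.sum()),
        n_target_ps=int(is_target_ps.sum()),
        n_cohort_target=int(cohort.sum()),
        target_pairs=target_pairs,
        background_pairs=background_pairs,
        per_pt=per_pt,
        onset_days=onset_truth,
        table_rows={name: len(lines) for name, lines in rows.items()},
        per_case=per_case,
        warnings=warnings,
    )
    manifest.write(out_dir / "manifest.json", include_case_truth=n <= 20000)
    return manifest


def null_calibration_config(seed: int = 0) -> SyntheticConfig:
    """Study conditions for null calibration: no planted signals, ~50,000
    (case, PT) pairs, so every disproportionality estimate should scatter
    around its null value."""
    return SyntheticConfig(n_cases=29_000, seed=seed)


def recovery_benchmark_config(seed: int = 0) -> SyntheticConfig:
    """Study conditions for planted-signal recovery, mirroring the regime of
    a real spontaneous-reporting database where the target cohort is ~0.5%
    of all reports (at larger shares the unshrunk EBGM self-masks, because
    the target's own reports dominate the event's column margin).

    The strongest planted term has background probability 0.004 and ratio
    10, giving an expected target count a ≈ 100.
    """
    return SyntheticConfig(
        n_cases=470_000,
        target_share=0.0063,
        seed=seed,
        planted_signals={"Product residue present": 10.0, "Haematochezia": 3.0},
    )


def expected_tables(config: SyntheticConfig) -> dict[str, dict[str, float]]:
    """Closed-form expected fourfold counts per PT under the config.

    E[a] = n_t·min(1, ratio·p), E[c] = n_b·p with n_t the expected target
    cohort size and n_b its complement; b and d follow from the expected
    pair totals.  Used by parameter-recovery tests.
    """
    n_t = config.n_cases * config.target_share * config.indication_share
    n_b = config.n_cases - n_t
    p_target = {
        pt: min(1.0, config.planted_signals.get(pt, 1.0) * p)
        for pt, _, p in config.pt_catalog
    }
    e_target_pairs = n_t * sum(p_target.values())
    e_bg_pairs = n_b * sum(p for _, _, p in config.pt_catalog)
    out = {}
    for pt, _, p in config.pt_catalog:
        ea = n_t * p_target[pt]
        ec = n_b * p
        out[pt] = {"a": ea, "b": e_target_pairs - ea, "c": ec, "d": e_bg_pairs - ec}
    return out
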