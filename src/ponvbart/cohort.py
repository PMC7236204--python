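"""Cohort loading, inclusion filtering, covariate encoding, descriptives.

The unit of analysis is one anesthetic case.  The encoded covariate set is
the a-priori PONV risk set: age < 50, ASA class (dummies vs ASA 1),
nitrous-oxide exposure (> 5% of surgical time), potent volatile exposure
(age-adjusted MAC > 0.5 for > 15% of surgical time), log surgical
duration, female sex, history of PONV or motion sickness, non-smoking
status, PACU opioid receipt, and the count of prophylactic antiemetics.
The simplified Apfel score is the 0–4 count of female sex, prior
PONV/motion sickness, non-smoking status, and PACU opioid receipt.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectRecord",
    "FeatureMatrix",
    "ColumnDialect",
    "ConfigurationError",
    "RowError",
    "load_cohort",
    "load_cohort_detailed",
    "apply_inclusion_filters",
    "build_feature_matrix",
    "summarize_cohort",
    "summarize_aggregate",
    "load_table1_fixture",
    "FEATURE_COLUMNS",
    "N2O_TIME_THRESHOLD",
    "VOLATILE_TIME_THRESHOLD",
]

# Exposure dichotomization thresholds (fractions of surgical time)
N2O_TIME_THRESHOLD = 0.05
VOLATILE_TIME_THRESHOLD = 0.15

FEATURE_COLUMNS = [
    "age_lt_50", "asa_2", "asa_3", "n2o_exposed", "volatile_exposed",
    "log_duration", "female", "prior_ponv", "nonsmoker", "pacu_opioids",
    "n_prophylactic_antiemetics", "cannabis_current", "cannabis_daily",
]

CANNABIS_LEVELS = ("none", "current", "daily")


class ConfigurationError(ValueError):
    """A column mapping or config problem that stops the whole load."""


@dataclass(frozen=True)
class RowError:
    row_index: int
    field: str
    message: str


@dataclass
class SubjectRecord:
    """One anesthetic case with raw pre/intra/postoperative fields."""

    subject_id: str
    age_years: float
    sex: str                       # "female" | "male"
    asa_class: int
    smoker: bool                   # patient-reported tobacco use
    prior_ponv_or_motion_sickness: bool
    outpatient: bool
    cannabis_use: str              # "none" | "current" | "daily"
    duration_min: float            # surgical duration, minutes
    n2o_time_fraction: float       # fraction of surgical time on nitrous
    volatile_mac_time_fraction: float  # fraction of time with MAC > 0.5
    surgery_high_risk_nausea: bool
    n_prophylactic_antiemetics: int
    pacu_opioids: bool
    ponv_observed: bool            # composite outcome (any severity or rescue)

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female/male, got {self.sex!r}")
        if self.cannabis_use not in CANNABIS_LEVELS:
            raise ValueError(
                f"cannabis_use must be one of {CANNABIS_LEVELS}, "
                f"got {self.cannabis_use!r}")
        if not self.age_years > 0:
            raise ValueError("age_years must be positive")
        if not self.duration_min > 0:
            raise ValueError("duration_min must be positive")
        for name in ("n2o_time_fraction", "volatile_mac_time_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_prophylactic_antiemetics < 0:
            raise ValueError("n_prophylactic_antiemetics must be >= 0")

    @property
    def apfel(self) -> int:
        """Simplified Apfel score: count of the four classical PONV risks."""
        return (int(self.sex == "female")
                + int(self.prior_ponv_or_motion_sickness)
                + int(not self.smoker)
                + int(self.pacu_opioids))


_BOOL_FIELDS = {"smoker", "prior_ponv_or_motion_sickness", "outpatient",
                "surgery_high_risk_nausea", "pacu_opioids", "ponv_observed"}
_FLOAT_FIELDS = {"age_years", "duration_min", "n2o_time_fraction",
                 "volatile_mac_time_fraction"}
_INT_FIELDS = {"asa_class", "n_prophylactic_antiemetics"}

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


@dataclass
class ColumnDialect:
    """How to read a cohort CSV whose headers differ from the field names.

    ``columns`` maps SubjectRecord field name -> CSV column name (identity
    for unmapped fields).  ``cannabis_values`` maps raw cell values to the
    three analysis levels; past use collapses to "none" by default.
    """

    columns: dict = field(default_factory=dict)
    cannabis_values: dict = field(default_factory=lambda: {"past": "none"})

    def column_for(self, field_name: str) -> str:
        return self.columns.get(field_name, field_name)


def _parse_cell(name: str, raw: str, dialect: ColumnDialect):
    raw = raw.strip()
    if name in _BOOL_FIELDS:
        low = raw.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise ValueError(f"cannot parse boolean from {raw!r}")
    if name in _FLOAT_FIELDS:
        return float(raw)
    if name in _INT_FIELDS:
        return int(float(raw))
    if name == "sex":
        return raw.lower()
    if name == "cannabis_use":
        low = raw.lower()
        return dialect.cannabis_values.get(low, low)
    return raw


def load_cohort_detailed(path, dialect: ColumnDialect | None = None):
    """Read a cohort CSV; return (records, row_errors), input order preserved.

    Rows failing type or invariant validation are rejected individually and
    reported (and logged at warning level); a missing mapped column aborts
    the load with a :class:`ConfigurationError` naming the column.
    """
    dialect = dialect or ColumnDialect()
    field_names = [f.name for f in dc_fields(SubjectRecord)]
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [dialect.column_for(f) for f in field_names
                   if dialect.column_for(f) not in header]
        if missing:
            raise ConfigurationError(
                f"cohort file {path} is missing mapped column(s): "
                f"{', '.join(missing)}")
        records, errors = [], []
        for i, row in enumerate(reader):
            try:
                kwargs = {}
                bad_field = None
                for f in field_names:
                    bad_field = f
                    kwargs[f] = _parse_cell(f, row[dialect.column_for(f)],
                                            dialect)
                bad_field = None
                records.append(SubjectRecord(**kwargs))
            except (ValueError, TypeError) as exc:
                err = RowError(i, bad_field or "<record>", str(exc))
                errors.append(err)
                logger.warning("rejected row %d (%s): %s", i, err.field,
                               err.message)
    return records, errors


def load_cohort(path, dialect: ColumnDialect | None = None):
    """Read a cohort CSV and return the validated records (see detailed variant)."""
    records, _ = load_cohort_detailed(path, dialect)
    return records


# --- inclusion / exclusion -------------------------------------------------

_CRITERIA = ("age", "asa", "duration", "anesthesia_type", "obstetric",
             "cardiac", "pacu_recovery")


def apply_inclusion_filters(records, raw_flags=None):
    """Apply the cohort's inclusion criteria; return (kept, exclusion_tally).

    Retains adults (age >= 18), ASA 1–3, general anesthesia lasting >= 30
    minutes (both boundaries inclusive), recovered in the PACU, excluding
    obstetric and cardiac cases.  ``raw_flags`` is an optional per-row
    sequence of dicts with keys ``anesthesia_type`` ("general" passes),
    ``is_obstetric``, ``is_cardiac``, ``pacu_recovery``; omitted flags are
    treated as passing.  A row tripping several criteria is tallied under
    every one of them.
    """
    if raw_flags is None:
        raw_flags = [{}] * len(records)
    if len(raw_flags) != len(records):
        raise ValueError("raw_flags must align with records")
    tally = {c: 0 for c in _CRITERIA}
    kept = []
    for rec, flags in zip(records, raw_flags):
        tripped = []
        if rec.age_years < 18:
            tripped.append("age")
        if rec.asa_class > 3:
            tripped.append("asa")
        if rec.duration_min < 30:
            tripped.append("duration")
        if flags.get("anesthesia_type", "general") != "general":
            tripped.append("anesthesia_type")
        if flags.get("is_obstetric", False):
            tripped.append("obstetric")
        if flags.get("is_cardiac", False):
            tripped.append("cardiac")
        if not flags.get("pacu_recovery", True):
            tripped.append("pacu_recovery")
        if tripped:
            for c in tripped:
                tally[c] += 1
        else:
            kept.append(rec)
    return kept, tally


# --- feature encoding ------------------------------------------------------

class FeatureMatrix:
    """Encoded modelling table: covariate block, outcome, Apfel stratum.

    ``data`` holds one row per subject with the covariate columns of
    :data:`FEATURE_COLUMNS` plus ``y`` (0/1 outcome) and ``apfel`` (0–4).
    """

    def __init__(self, data: pd.DataFrame):
        expected = FEATURE_COLUMNS + ["y", "apfel"]
        missing = [c for c in expected if c not in data.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        self.data = data[expected].reset_index(drop=True)

    @property
    def X(self) -> pd.DataFrame:
        return self.data[FEATURE_COLUMNS]

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy(dtype=int)

    @property
    def apfel(self) -> np.ndarray:
        return self.data["apfel"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)


def build_feature_matrix(records) -> FeatureMatrix:
    """Encode records into the modelling covariates (deterministic)."""
    rows = []
    for i, rec in enumerate(records):
        if rec.duration_min <= 0:
            raise ValueError(
                f"row {i}: duration_min must be positive to take its log")
        rows.append({
            "age_lt_50": int(rec.age_years < 50),
            "asa_2": int(rec.asa_class == 2),
            "asa_3": int(rec.asa_class == 3),
            "n2o_exposed": int(rec.n2o_time_fraction > N2O_TIME_THRESHOLD),
            "volatile_exposed": int(
                rec.volatile_mac_time_fraction > VOLATILE_TIME_THRESHOLD),
            "log_duration": float(np.log(rec.duration_min)),
            "female": int(rec.sex == "female"),
            "prior_ponv": int(rec.prior_ponv_or_motion_sickness),
            "nonsmoker": int(not rec.smoker),
            "pacu_opioids": int(rec.pacu_opioids),
            "n_prophylactic_antiemetics": int(rec.n_prophylactic_antiemetics),
            "cannabis_current": int(rec.cannabis_use == "current"),
            "cannabis_daily": int(rec.cannabis_use == "daily"),
            "y": int(rec.ponv_observed),
            "apfel": rec.apfel,
        })
    return FeatureMatrix(pd.DataFrame(rows))


# --- descriptive summaries -------------------------------------------------

def _pct(count, denom):
    return round(100.0 * count / denom, 1) if denom else float("nan")


def summarize_cohort(records) -> dict:
    """Table-1-style descriptives keyed by cannabis level.

    Continuous variables as mean (sd), categorical as n (within-level %),
    ordinal as median [IQR].  Percentages are column percentages within
    each cannabis level, rounded to one decimal.
    """
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    total = len(records)
    out = {"total_n": total, "levels": {}}
    for level in CANNABIS_LEVELS:
        grp = [r for r in records if r.cannabis_use == level]
        if not grp:
            continue
        n = len(grp)
        ages = np.array([r.age_years for r in grp])
        durs = np.array([r.duration_min for r in grp])
        proph = np.array([r.n_prophylactic_antiemetics for r in grp])
        apfel = np.array([r.apfel for r in grp])

        def n_pct(pred):
            c = sum(1 for r in grp if pred(r))
            return {"n": c, "pct": _pct(c, n)}

        def med_iqr(arr):
            return {"median": float(np.median(arr)),
                    "iqr": [float(np.percentile(arr, 25)),
                            float(np.percentile(arr, 75))]}

        out["levels"][level] = {
            "n": n,
            "pct_of_total": _pct(n, total),
            "age": {"mean": round(float(ages.mean()), 1),
                    "sd": round(float(ages.std(ddof=1)) if n > 1 else 0.0, 1)},
            "asa": {str(k): n_pct(lambda r, k=k: r.asa_class == k)
                    for k in (1, 2, 3)},
            "outpatient": n_pct(lambda r: r.outpatient),
            "male": n_pct(lambda r: r.sex == "male"),
            "nonsmoker": n_pct(lambda r: not r.smoker),
            "prior_ponv": n_pct(lambda r: r.prior_ponv_or_motion_sickness),
            "duration": {"mean": round(float(durs.mean()), 1),
                         "sd": round(float(durs.std(ddof=1)) if n > 1 else 0.0,
                                     1)},
            "n2o_exposed": n_pct(
                lambda r: r.n2o_time_fraction > N2O_TIME_THRESHOLD),
            "high_risk_surgery": n_pct(lambda r: r.surgery_high_risk_nausea),
            "prophylactic_antiemetics": med_iqr(proph),
            "pacu_opioids": n_pct(lambda r: r.pacu_opioids),
            "apfel": med_iqr(apfel),
            "ponv_observed": n_pct(lambda r: r.ponv_observed),
        }
    used = sum(lv["n"] for lv in out["levels"].values())
    any_use = sum(out["levels"][l]["n"] for l in ("current", "daily")
                  if l in out["levels"])
    out["any_cannabis"] = {"n": any_use, "pct": _pct(any_use, used)}
    return out


def summarize_aggregate(agg: dict) -> dict:
    """Descriptive summary from pre-aggregated per-level counts.

    Test/reporting entry point for aggregate tables (stratum sizes and
    event counts rather than row-level data).  ``agg`` maps each cannabis
    level to a dict with at least ``n`` plus count entries; count entries
    are converted to within-level percentages rounded to one decimal.
    """
    total = sum(v["n"] for v in agg.values())
    out = {"total_n": total, "levels": {}}
    for level, vals in agg.items():
        n = vals["n"]
        entry = {"n": n, "pct_of_total": _pct(n, total)}
        for key, val in vals.items():
            if key == "n":
                continue
            if isinstance(val, dict):       # e.g. asa: {"1": c1, ...}
                entry[key] = {k: {"n": c, "pct": _pct(c, n)}
                              for k, c in val.items()}
            elif isinstance(val, (int, np.integer)):
                entry[key] = {"n": val, "pct": _pct(val, n)}
            else:
                entry[key] = val
        out["levels"][level] = entry
    any_use = sum(agg[l]["n"] for l in ("current", "daily") if l in agg)
    out["any_cannabis"] = {"n": any_use, "pct": _pct(any_use, total)}
    return out


def load_table1_fixture() -> dict:
    """Packaged per-level aggregate counts of the UWMC descriptive table."""
    ref = importlib.resources.files("ponvbart.data") / "table1_uwmc_counts.json"
    return json.loads(ref.read_text())
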