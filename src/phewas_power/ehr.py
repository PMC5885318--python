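"""ICD-9 case definition and case-count tabulation for EHR phenotype selection.

Longitudinal EHR diagnosis data are sparse: a code appearing once in a
patient's record may be a rule-out or a coding error.  The "rule of three"
case definition counts a patient as a case for a code only when the code
appears on three or more independent visits; independence is read here as
distinct calendar dates for that patient/code pair.  Tabulating the number
of codes that clear successive case-count thresholds shows how a minimum
case requirement (e.g. >= 200 cases for common-variant PheWAS) prunes the
phenome and the multiple-testing burden.

Visit records are plain delimited text with columns patient_id, code, date
(ISO-8601).  Matching is on the exact code string — no ICD-9 hierarchy
rollup or phecode grouping.  A synthetic record generator emulating sparse
longitudinal coding (per-patient code carriage ~ Bernoulli(prevalence),
visit counts ~ Poisson(rate), distinct dates uniform over a study window)
makes the procedure testable without patient data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CodeSpec",
    "DEFAULT_CATALOG",
    "validate_code",
    "read_visit_records",
    "define_cases",
    "case_counts_by_code",
    "tabulate_codes_by_threshold",
    "synth_ehr",
]

# ICD-9-CM lexical shape: 3-digit rubric (or V2d / E3d) with optional
# 1-2 digit decimal extension
_ICD9_RE = re.compile(r"^(?:\d{3}|V\d{2}|E\d{3})(?:\.\d{1,2})?$")

_COLUMNS = ("patient_id", "code", "date")


def validate_code(code: str) -> str:
    """Check an ICD-9 code string against the 3-to-5-digit dotted form."""
    if not isinstance(code, str) or not _ICD9_RE.match(code):
        raise ValueError(f"not a valid ICD-9 code: {code!r}")
    return code


@dataclass(frozen=True)
class CodeSpec:
    """Synthetic-generator parameters for one ICD-9 code.

    ``prevalence`` is the fraction of patients carrying the diagnosis;
    ``visit_rate`` is the Poisson mean number of visits at which a carrier's
    record shows the code over the study window.
    """

    code: str
    prevalence: float
    visit_rate: float

    def __post_init__(self) -> None:
        validate_code(self.code)
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError(f"prevalence must lie in [0, 1], got {self.prevalence}")
        if self.visit_rate < 0:
            raise ValueError(f"visit_rate must be >= 0, got {self.visit_rate}")


#: A realistic sparse-EHR mix: common chronic diagnoses carried by 10-30% of
#: patients with frequent coding, down to rare diagnoses near 1%.
DEFAULT_CATALOG: tuple[CodeSpec, ...] = (
    CodeSpec("401.1", 0.25, 6.0),    # essential hypertension, benign
    CodeSpec("272.4", 0.20, 5.0),    # hyperlipidemia
    CodeSpec("530.81", 0.18, 3.0),   # GERD
    CodeSpec("311", 0.15, 4.0),      # depressive disorder NEC
    CodeSpec("715.90", 0.12, 3.0),   # osteoarthrosis, unspecified
    CodeSpec("250.00", 0.10, 8.0),   # type 2 diabetes without complication
    CodeSpec("493.90", 0.08, 3.0),   # asthma, unspecified
    CodeSpec("414.01", 0.07, 4.0),   # coronary atherosclerosis
    CodeSpec("585.3", 0.04, 4.0),    # chronic kidney disease, stage III
    CodeSpec("174.9", 0.015, 6.0),   # malignant neoplasm of breast
    CodeSpec("038.9", 0.010, 1.5),   # unspecified septicemia
    CodeSpec("V70.0", 0.30, 2.0),    # routine general medical examination
)


def _as_records(records) -> pd.DataFrame:
    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"visit records missing columns: {missing}")
    return df


def read_visit_records(path, sep: str | None = None) -> pd.DataFrame:
    """Read visit records from headered CSV/TSV with columns
    patient_id, code, date (ISO-8601).

    The delimiter is inferred from the extension (.tsv -> tab) unless given.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str, "code": str})
    df = _as_records(df)
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.normalize()
    return df


def define_cases(records, code: str, min_visits: int = 3) -> set:
    """Patients who are cases for ``code``: >= ``min_visits`` distinct dates
    on which the exact code appears in their record."""
    validate_code(code)
    if min_visits < 1:
        raise ValueError(f"min_visits must be >= 1, got {min_visits}")
    df = _as_records(records)
    sub = df.loc[df["code"] == code, ["patient_id", "date"]].drop_duplicates()
    counts = sub.groupby("patient_id").size()
    return set(counts.index[counts >= min_visits])


def case_counts_by_code(records, min_visits: int = 3) -> pd.DataFrame:
    """Case counts per distinct code under the rule-of-``min_visits``.

    Duplicate (patient, code, date) rows collapse to one visit.  Returns a
    DataFrame with columns ``code`` and ``n_cases`` (codes with zero cases
    included), sorted by code.
    """
    if min_visits < 1:
        raise ValueError(f"min_visits must be >= 1, got {min_visits}")
    df = _as_records(records)
    dedup = df[["patient_id", "code", "date"]].drop_duplicates()
    visits = dedup.groupby(["code", "patient_id"]).size()
    n_cases = (visits >= min_visits).groupby(level="code").sum()
    out = n_cases.reindex(sorted(df["code"].unique()), fill_value=0)
    return out.rename("n_cases").rename_axis("code").reset_index()


def tabulate_codes_by_threshold(table: pd.DataFrame, thresholds) -> pd.DataFrame:
    """Number of codes whose case count meets each threshold (>= t).

    Monotone non-increasing in the threshold by construction.
    """
    thresholds = [int(t) for t in thresholds]
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    counts = np.asarray(table["n_cases"], dtype=int)
    rows = [{"threshold": t, "n_codes": int((counts >= t).sum())} for t in thresholds]
    return pd.DataFrame(rows)


def synth_ehr(
    n_patients: int,
    catalog=DEFAULT_CATALOG,
    rng: np.random.Generator | None = None,
    start: str = "1996-01-01",
    end: str = "2015-12-31",
) -> pd.DataFrame:
    """Generate a synthetic longitudinal visit-record set.

    For each code in the catalog, each patient carries the diagnosis with
    probability ``prevalence``; a carrier's record shows the code at
    Poisson(``visit_rate``) visits on distinct dates drawn uniformly over the
    study window.  The expected case count under the rule of three is
    therefore n_patients * prevalence * P(Poisson(rate) >= 3) in closed
    form, which test oracles exploit.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    if rng is None:
        rng = np.random.default_rng()
    days = pd.date_range(start=start, end=end, freq="D")
    n_days = len(days)
    patients = np.array([f"P{i:06d}" for i in range(n_patients)])
    frames = []
    for spec in catalog:
        if spec.prevalence == 0.0:
            continue
        carriers = patients[rng.random(n_patients) < spec.prevalence]
        if carriers.size == 0:
            continue
        n_visits = rng.poisson(spec.visit_rate, carriers.size)
        pid_col = np.repeat(carriers, n_visits)
        date_idx = np.concatenate(
            [rng.choice(n_days, size=v, replace=False) for v in n_visits if v > 0]
        ) if n_visits.sum() else np.empty(0, dtype=int)
        frames.append(
            pd.DataFrame(
                {"patient_id": pid_col, "code": spec.code, "date": days[date_idx]}
            )
        )
    if not frames:
        return pd.DataFrame(columns=list(_COLUMNS))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(list(_COLUMNS), ignore_index=True)
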