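"""Prognostic scores for ER-positive breast cancer from IHC markers and clinical factors.

Implements the IHC4 score of Cuzick and colleagues, the companion clinical
score, their sum (IHC4+C), and the refitted "IHC4 + Clinical PathIES" score
estimated on the endocrine-switch (tamoxifen -> exemestane) population, plus
cohort-level quartile risk grouping and the ER-positivity eligibility filter.

All scores live on a log-hazard scale multiplied by 100 for readability:
a difference of 100 score points corresponds to a hazard ratio of e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Her2Category",
    "NodalCategory",
    "Grade",
    "Treatment",
    "MarkerPanel",
    "ClinicalProfile",
    "ScoreSet",
    "MissingDataError",
    "compute_ihc4",
    "compute_clinical_score",
    "compute_pathies_score",
    "assign_risk_groups",
    "eligibility_filter",
    "score_cohort",
    "tumour_size_category",
]


class MissingDataError(ValueError):
    """A required field is missing; the record must be excluded, not scored."""


class Her2Category(str, Enum):
    """HER2 immunohistochemistry category. Only 3+ counts as positive;
    0/1+/2+ are negative (no ISH reflex testing)."""

    ZERO = "0"
    ONE_PLUS = "1+"
    TWO_PLUS = "2+"
    THREE_PLUS = "3+"

    @classmethod
    def parse(cls, value: "Her2Category | str") -> "Her2Category":
        if isinstance(value, cls):
            return value
        v = str(value).strip()
        aliases = {"0": cls.ZERO, "1": cls.ONE_PLUS, "2": cls.TWO_PLUS, "3": cls.THREE_PLUS}
        try:
            return cls(v)
        except ValueError:
            if v in aliases:
                return aliases[v]
            raise ValueError(f"her2_ihc must be one of 0/1+/2+/3+, got {value!r}") from None


class NodalCategory(str, Enum):
    N0 = "N0"
    N1to3 = "N1to3"
    Ngt3 = "Ngt3"


class Grade(str, Enum):
    G1 = "G1"
    G2 = "G2"
    G3 = "G3"
    NOT_ASSESSABLE = "not_assessable"
    UNKNOWN = "unknown"


class Treatment(str, Enum):
    TAMOXIFEN = "tamoxifen_only"
    EXEMESTANE = "switch_to_exemestane"


def _check_range(name: str, value: float, lo: float, hi: float) -> float:
    value = float(value)
    if not math.isfinite(value) or not (lo <= value <= hi):
        raise ValueError(f"{name} must be in [{lo}, {hi}], got {value!r}")
    return value


@dataclass(frozen=True)
class MarkerPanel:
    """One patient's four immunohistochemical marker measurements.

    Parameters
    ----------
    er_hscore : ER H-score, 0-300 (intensity-weighted percent positive nuclei).
    pgr_percent : PgR percent positive tumour nuclei, 0-100.
    her2_ihc : HER2 IHC category (0, 1+, 2+, 3+).
    ki67_percent : Ki67 percent positive, 0-100.
    """

    er_hscore: float
    pgr_percent: float
    her2_ihc: Her2Category
    ki67_percent: float

    def __post_init__(self) -> None:
        _check_range("er_hscore", self.er_hscore, 0, 300)
        _check_range("pgr_percent", self.pgr_percent, 0, 100)
        _check_range("ki67_percent", self.ki67_percent, 0, 100)
        object.__setattr__(self, "her2_ihc", Her2Category.parse(self.her2_ihc))


@dataclass(frozen=True)
class ClinicalProfile:
    """Clinical covariates entering the clinical and PathIES scores."""

    age_years: float
    nodal_category: NodalCategory | None
    tumour_size_cm: float | None
    grade: Grade | None
    treatment: Treatment = Treatment.TAMOXIFEN

    def __post_init__(self) -> None:
        if self.age_years is not None and not (0 < float(self.age_years) < 130):
            raise ValueError(f"age_years must be positive, got {self.age_years!r}")
        if self.tumour_size_cm is not None and not float(self.tumour_size_cm) > 0:
            raise ValueError(f"tumour_size_cm must be > 0, got {self.tumour_size_cm!r}")


@dataclass(frozen=True)
class ScoreSet:
    """The four scores for one patient (risk group is assigned cohort-wise)."""

    ihc4: float
    clinical: float | None
    combined_ihc4c: float | None
    pathies: float | None


# --- IHC4 -------------------------------------------------------------------

IHC4_SCALE = 94.7
IHC4_COEF = {"er10": -0.100, "pgr10": -0.079, "her2": 0.586, "ki67": 0.240}


def compute_ihc4(panel: MarkerPanel, *, ki67_as_fraction: bool = False) -> float:
    """IHC4 = 94.7 x [-0.100 ER10 - 0.079 PgR10 + 0.586 HER2 + 0.240 ln(1 + 4 Ki67)].

    ER10 is the H-score / 30, PgR10 the percent positive / 10 (both on 0-10),
    HER2 the indicator of IHC 3+, and Ki67 the percent positive (0-100 scale
    by default; ``ki67_as_fraction`` rescales to 0-1 for sensitivity checks).
    """
    ki67 = panel.ki67_percent / 100.0 if ki67_as_fraction else panel.ki67_percent
    her2_pos = 1.0 if panel.her2_ihc is Her2Category.THREE_PLUS else 0.0
    return IHC4_SCALE * (
        IHC4_COEF["er10"] * (panel.er_hscore / 30.0)
        + IHC4_COEF["pgr10"] * (panel.pgr_percent / 10.0)
        + IHC4_COEF["her2"] * her2_pos
        + IHC4_COEF["ki67"] * math.log1p(4.0 * ki67)
    )


# --- Clinical score ---------------------------------------------------------

def tumour_size_category(size_cm: float) -> str:
    """Map continuous size to the score categories T0 (<1), T1-2, T2-3, T>3 cm."""
    size_cm = float(size_cm)
    if size_cm <= 0:
        raise ValueError(f"tumour size must be positive, got {size_cm}")
    if size_cm < 1.0:
        return "T0"
    if size_cm <= 2.0:
        return "T1-2"
    if size_cm <= 3.0:
        return "T2-3"
    return "T>3"


CLINICAL_COEF = {
    "N1to3": 0.417,
    "Ngt3": 1.566,
    "shrink": 0.93,
    "T1-2": 0.497,
    "T2-3": 0.882,
    "T>3": 1.838,
    "G2": 0.559,
    "G3": 0.970,
    "age65": 0.130,
}


def compute_clinical_score(profile: ClinicalProfile) -> float:
    """Clinical score = 100 x [0.417 N1-3 + 1.566 N>3
    + 0.93 x (0.497 T1-2 + 0.882 T2-3 + 1.838 T>3 + 0.559 Gr2 + 0.970 Gr3 + 0.130 Age>=65)].

    Requires assessable grade, nodal status and tumour size; records missing
    any of these are excluded upstream rather than silently scored.
    The age indicator switches on at 65 (boundary included).
    """
    if profile.grade is None or profile.grade in (Grade.NOT_ASSESSABLE, Grade.UNKNOWN):
        raise MissingDataError("grade is missing or not assessable")
    if profile.nodal_category is None:
        raise MissingDataError("nodal_category is missing")
    if profile.tumour_size_cm is None:
        raise MissingDataError("tumour_size_cm is missing")
    if profile.age_years is None:
        raise MissingDataError("age_years is missing")
    c = CLINICAL_COEF
    tcat = tumour_size_category(profile.tumour_size_cm)
    nodes = (
        c["N1to3"] * (profile.nodal_category is NodalCategory.N1to3)
        + c["Ngt3"] * (profile.nodal_category is NodalCategory.Ngt3)
    )
    inner = (
        c["T1-2"] * (tcat == "T1-2")
        + c["T2-3"] * (tcat == "T2-3")
        + c["T>3"] * (tcat == "T>3")
        + c["G2"] * (profile.grade is Grade.G2)
        + c["G3"] * (profile.grade is Grade.G3)
        + c["age65"] * (float(profile.age_years) >= 65.0)
    )
    return 100.0 * (nodes + c["shrink"] * inner)


# --- PathIES refitted combined score ---------------------------------------

PATHIES_COEF = {
    "exe": -0.13,
    "N1to3": 0.46,
    "Ngt3": 1.45,
    "T1-2": 1.37,
    # Printed with a duplicated T1-2 label; read as the (otherwise absent)
    # 2-3 cm category so coefficients increase with size.
    "T2-3": 1.65,
    "T>3": 2.21,
    "ihc4": 0.0048,
}


def compute_pathies_score(ihc4: float, profile: ClinicalProfile) -> float:
    """IHC4 + Clinical PathIES score
    = 100 x (-0.13 exe + 0.46 N1-3 + 1.45 N>3 + 1.37 T1-2 + 1.65 T2-3 + 2.21 T>3 + 0.0048 IHC4).

    The refit on the switch-trial population: grade and age drop out, the
    treatment arm (exemestane indicator) enters, and IHC4 enters continuously.
    """
    if not math.isfinite(float(ihc4)):
        raise ValueError(f"ihc4 must be finite, got {ihc4!r}")
    if profile.nodal_category is None:
        raise MissingDataError("nodal_category is missing")
    if profile.tumour_size_cm is None:
        raise MissingDataError("tumour_size_cm is missing")
    c = PATHIES_COEF
    tcat = tumour_size_category(profile.tumour_size_cm)
    return 100.0 * (
        c["exe"] * (profile.treatment is Treatment.EXEMESTANE)
        + c["N1to3"] * (profile.nodal_category is NodalCategory.N1to3)
        + c["Ngt3"] * (profile.nodal_category is NodalCategory.Ngt3)
        + c["T1-2"] * (tcat == "T1-2")
        + c["T2-3"] * (tcat == "T2-3")
        + c["T>3"] * (tcat == "T>3")
        + c["ihc4"] * float(ihc4)
    )


# --- Quartile risk groups ---------------------------------------------------

RISK_GROUPS = ("Q1", "Q2Q3", "Q4")


def assign_risk_groups(scores: Sequence[float]) -> tuple[np.ndarray, tuple[float, float]]:
    """Label each score Q1 (< 25th percentile), Q2Q3 (25th-75th) or Q4 (>= 75th).

    Cutpoints are the empirical type-7 (linear-interpolation) quantiles of the
    supplied scores; a score exactly at a cutpoint goes to the upper group.

    Returns
    -------
    labels : ndarray of {"Q1", "Q2Q3", "Q4"}
    cutpoints : (q25, q75)

    Raises
    ------
    ValueError
        If fewer than 4 scores are supplied or the quartiles are degenerate
        (identical cutpoints, or no score strictly below the 25th percentile).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 1 or arr.size < 4:
        raise ValueError(f"need at least 4 scores to form quartile groups, got {arr.size}")
    if np.isnan(arr).any():
        raise ValueError("scores contain missing values; filter before grouping")
    q25, q75 = np.quantile(arr, [0.25, 0.75])
    if q25 == q75:
        raise ValueError("degenerate quartiles: 25th and 75th percentiles coincide")
    labels = np.where(arr < q25, "Q1", np.where(arr >= q75, "Q4", "Q2Q3"))
    if not (labels == "Q1").any():
        raise ValueError("degenerate lower quartile: no score below the 25th percentile")
    return labels, (float(q25), float(q75))


# --- Eligibility and cohort-level scoring -----------------------------------

MARKER_COLUMNS = ("er_hscore", "pgr_percent", "her2_ihc", "ki67_percent")
CLINICAL_COLUMNS = ("age_years", "nodal_category", "tumour_size_cm", "grade")


def eligibility_filter(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the ER-positivity and marker-completeness eligibility rules.

    A row is ER positive if ANY of: er_percent >= 1, er_hscore >= 1,
    er_allred >= 3 (central-review criteria). Rows with no ER measure at all
    are excluded as unassessable. Eligible rows must additionally carry all
    four IHC4 markers. Rows kept for IHC4 analyses but missing any
    clinical-score component (age, nodes, size, assessable grade) are flagged
    ``clinical_complete = False`` rather than dropped, reproducing the
    IHC4-set vs complete-case-set split.

    Returns
    -------
    kept : eligible rows with a ``clinical_complete`` boolean column appended.
    exclusions : DataFrame with columns (index of original row, reason).
    """
    df = cohort.copy()
    er_cols = [c for c in ("er_percent", "er_hscore", "er_allred") if c in df.columns]
    if not er_cols:
        raise ValueError("cohort has no ER measure column (er_percent/er_hscore/er_allred)")

    er_measures = df[er_cols].apply(pd.to_numeric, errors="coerce")
    unassessable = er_measures.isna().all(axis=1)
    thresholds = {"er_percent": 1.0, "er_hscore": 1.0, "er_allred": 3.0}
    er_positive = pd.Series(False, index=df.index)
    for c in er_cols:
        er_positive |= er_measures[c] >= thresholds[c]

    marker_missing = pd.Series(False, index=df.index)
    for c in MARKER_COLUMNS:
        if c not in df.columns:
            raise ValueError(f"cohort is missing marker column {c!r}")
        marker_missing |= df[c].isna() | (df[c].astype(str).str.strip() == "")

    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    reason[marker_missing] = "incomplete_markers"
    reason[~er_positive] = "er_negative"
    reason[unassessable] = "er_unassessable"

    excluded = reason.notna()
    exclusions = pd.DataFrame({"row": df.index[excluded], "reason": reason[excluded].to_numpy()})

    kept = df.loc[~excluded].copy()
    clinical_complete = pd.Series(True, index=kept.index)
    for c in CLINICAL_COLUMNS:
        if c not in kept.columns:
            raise ValueError(f"cohort is missing clinical column {c!r}")
        missing = kept[c].isna() | (kept[c].astype(str).str.strip() == "")
        if c == "grade":
            missing |= kept[c].astype(str).isin([Grade.NOT_ASSESSABLE.value, Grade.UNKNOWN.value])
        clinical_complete &= ~missing
    kept["clinical_complete"] = clinical_complete
    return kept, exclusions


def _row_profile(row: pd.Series) -> ClinicalProfile:
    def _opt(value, conv):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        s = str(value).strip()
        if s == "" or s == "nan":
            return None
        return conv(value)

    return ClinicalProfile(
        age_years=float(row["age_years"]),
        nodal_category=_opt(row.get("nodal_category"), lambda v: NodalCategory(str(v))),
        tumour_size_cm=_opt(row.get("tumour_size_cm"), float),
        grade=_opt(row.get("grade"), lambda v: Grade(str(v))),
        treatment=Treatment(str(row["treatment"])) if "treatment" in row else Treatment.TAMOXIFEN,
    )


def score_cohort(cohort: pd.DataFrame, *, ki67_as_fraction: bool = False) -> pd.DataFrame:
    """Append ihc4 / clinical / ihc4c / pathies score columns to a cohort table.

    Vectorised over rows; agrees exactly with the per-record functions.
    IHC4 is computed for every row (markers are required inputs); the
    clinical, combined and PathIES scores are left missing where their
    clinical components are absent.
    """
    out = cohort.copy()
    n = len(out)

    er = pd.to_numeric(out["er_hscore"], errors="raise").to_numpy(float)
    pgr = pd.to_numeric(out["pgr_percent"], errors="raise").to_numpy(float)
    ki67 = pd.to_numeric(out["ki67_percent"], errors="raise").to_numpy(float)
    for name, arr, hi in (("er_hscore", er, 300), ("pgr_percent", pgr, 100),
                          ("ki67_percent", ki67, 100)):
        bad = ~np.isfinite(arr) | (arr < 0) | (arr > hi)
        if bad.any():
            raise ValueError(f"{name} out of range [0, {hi}] in {int(bad.sum())} row(s)")
    her2 = out["her2_ihc"].map(lambda v: Her2Category.parse(v).value).to_numpy()
    her2_pos = (her2 == Her2Category.THREE_PLUS.value).astype(float)
    k = ki67 / 100.0 if ki67_as_fraction else ki67
    ihc4 = IHC4_SCALE * (
        IHC4_COEF["er10"] * (er / 30.0)
        + IHC4_COEF["pgr10"] * (pgr / 10.0)
        + IHC4_COEF["her2"] * her2_pos
        + IHC4_COEF["ki67"] * np.log1p(4.0 * k)
    )

    def _strcol(name: str) -> np.ndarray:
        return out[name].fillna("").astype(str).str.strip().to_numpy()

    nodes = _strcol("nodal_category")
    grade = _strcol("grade")
    size = pd.to_numeric(out["tumour_size_cm"], errors="coerce").to_numpy(float)
    age = pd.to_numeric(out["age_years"], errors="coerce").to_numpy(float)
    if "treatment" in out.columns:
        exe = (_strcol("treatment") == Treatment.EXEMESTANE.value).astype(float)
    else:
        exe = np.zeros(n)

    with np.errstate(invalid="ignore"):
        t12 = (size >= 1.0) & (size <= 2.0)
        t23 = (size > 2.0) & (size <= 3.0)
        tgt3 = size > 3.0
    n13 = nodes == NodalCategory.N1to3.value
    ngt3 = nodes == NodalCategory.Ngt3.value

    c = CLINICAL_COEF
    clinical = 100.0 * (
        c["N1to3"] * n13
        + c["Ngt3"] * ngt3
        + c["shrink"]
        * (c["T1-2"] * t12 + c["T2-3"] * t23 + c["T>3"] * tgt3
           + c["G2"] * (grade == Grade.G2.value) + c["G3"] * (grade == Grade.G3.value)
           + c["age65"] * (age >= 65.0))
    )
    clinical_missing = (
        (nodes == "") | (grade == "") | np.isin(grade, [Grade.NOT_ASSESSABLE.value,
                                                        Grade.UNKNOWN.value])
        | ~np.isfinite(size) | ~np.isfinite(age)
    )
    clinical = np.where(clinical_missing, np.nan, clinical)

    p = PATHIES_COEF
    pathies = 100.0 * (
        p["exe"] * exe
        + p["N1to3"] * n13
        + p["Ngt3"] * ngt3
        + p["T1-2"] * t12
        + p["T2-3"] * t23
        + p["T>3"] * tgt3
        + p["ihc4"] * ihc4
    )
    pathies_missing = (nodes == "") | ~np.isfinite(size)
    pathies = np.where(pathies_missing, np.nan, pathies)

    out["ihc4"] = ihc4
    out["clinical"] = clinical
    out["ihc4c"] = ihc4 + clinical
    out["pathies"] = pathies
    return out
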