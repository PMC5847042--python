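"""Data dictionary for the patient-level cohort table.

One row per patient; missing values are empty fields. ``validate_schema``
checks presence and basic ranges and raises naming the offending column.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["COLUMNS", "ColumnSpec", "validate_schema", "data_dictionary_markdown"]


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: str
    units: str
    description: str
    required: bool = True
    allowed: tuple[str, ...] | None = None
    lo: float | None = None
    hi: float | None = None


COLUMNS: tuple[ColumnSpec, ...] = (
    ColumnSpec("patient_id", "str", "", "unique patient identifier", required=False),
    ColumnSpec("er_hscore", "float", "H-score 0-300",
               "ER intensity-weighted percent positive nuclei", lo=0, hi=300),
    ColumnSpec("er_percent", "float", "%", "ER percent positive cells (eligibility)",
               required=False, lo=0, hi=100),
    ColumnSpec("er_allred", "int", "0-8", "ER Allred score (eligibility)",
               required=False, lo=0, hi=8),
    ColumnSpec("pgr_percent", "float", "%", "PgR percent positive tumour nuclei",
               lo=0, hi=100),
    ColumnSpec("her2_ihc", "category", "", "HER2 IHC category",
               allowed=("0", "1+", "2+", "3+")),
    ColumnSpec("ki67_percent", "float", "%", "Ki67 percent positive", lo=0, hi=100),
    ColumnSpec("age_years", "float", "years", "age at randomisation", lo=18, hi=110),
    ColumnSpec("nodal_category", "category", "", "positive axillary nodes",
               allowed=("N0", "N1to3", "Ngt3")),
    ColumnSpec("tumour_size_cm", "float", "cm", "pathological tumour size", lo=0, hi=30),
    ColumnSpec("grade", "category", "", "histological grade",
               allowed=("G1", "G2", "G3", "not_assessable", "unknown")),
    ColumnSpec("treatment", "category", "", "randomised arm",
               allowed=("tamoxifen_only", "switch_to_exemestane")),
    ColumnSpec("time_months", "float", "months", "follow-up from randomisation", lo=0, hi=400),
    ColumnSpec("event_type", "category", "", "terminal follow-up event",
               allowed=("none", "distant_recurrence", "local_or_regional_recurrence",
                        "contralateral", "death_breast_cancer", "death_unknown_cause",
                        "death_other_cause")),
)


def validate_schema(df: pd.DataFrame) -> None:
    """Raise ValueError naming the first missing or out-of-range column."""
    for spec in COLUMNS:
        if spec.name not in df.columns:
            if spec.required:
                raise ValueError(f"input is missing required column {spec.name!r}")
            continue
        col = df[spec.name]
        nonmissing = col[col.notna() & (col.astype(str).str.strip() != "")]
        if nonmissing.empty:
            continue
        if spec.allowed is not None:
            bad = set(nonmissing.astype(str).str.strip()) - set(spec.allowed)
            if bad:
                raise ValueError(
                    f"column {spec.name!r} contains invalid values {sorted(bad)!r}; "
                    f"allowed: {spec.allowed}"
                )
        elif spec.lo is not None:
            vals = pd.to_numeric(nonmissing, errors="coerce")
            if vals.isna().any():
                raise ValueError(f"column {spec.name!r} contains non-numeric values")
            if ((vals < spec.lo) | (vals > spec.hi)).any():
                raise ValueError(
                    f"column {spec.name!r} has values outside [{spec.lo}, {spec.hi}]"
                )


def data_dictionary_markdown() -> str:
    lines = [
        "| column | type | units | required | description |",
        "|---|---|---|---|---|",
    ]
    for s in COLUMNS:
        extra = f" (allowed: {', '.join(s.allowed)})" if s.allowed else ""
        lines.append(
            f"| {s.name} | {s.dtype} | {s.units} | {'yes' if s.required else 'no'} "
            f"| {s.description}{extra} |"
        )
    return "\n".join(lines)
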