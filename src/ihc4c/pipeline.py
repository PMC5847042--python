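"""End-to-end analysis pipeline: filter -> score -> stratify -> survival -> calibration.

Produces a :class:`ReportBundle` of journal-style tables (cohort
characteristics; hazard ratios by score quartile; univariable and
forced-treatment backward-stepwise multivariable Cox models; calibration by
score decile; Kaplan-Meier and prediction-curve plot data) plus a run log
whose row counts reconcile input rows to analysed rows.
"""

from __future__ import annotations

import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import calibration as cal
from . import scores as sc
from . import survival as sv
from .datadict import validate_schema
from .synthetic import GeneratorConfig, SyntheticCohort, generate_cohort

__all__ = ["AnalysisConfig", "ReportBundle", "run_pipeline", "make_fixture",
           "SCORE_VARIANTS"]

SCORE_VARIANTS = ("ihc4", "ihc4c", "pathies")


@dataclass
class AnalysisConfig:
    """Run-level options for the full analysis."""

    input_path: str | Path
    out_dir: str | Path | None = None
    score_variants: tuple[str, ...] = SCORE_VARIANTS
    quartile_groups: bool = True
    horizon_months: float = cal.DEFAULT_HORIZON_MONTHS
    baseline_mode: str = "internal"  # "internal" or "external:<csv path>"
    alpha: float = 0.10
    seed: int = 0
    interaction_method: str = "lr"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")
        if isinstance(self.score_variants, str):
            v = self.score_variants
            self.score_variants = SCORE_VARIANTS if v == "all" else (v,)
        unknown = set(self.score_variants) - set(SCORE_VARIANTS)
        if unknown:
            raise ValueError(f"unknown score variants {sorted(unknown)}")


@dataclass
class ReportBundle:
    """All pipeline outputs, as DataFrames keyed the way the reports are written."""

    characteristics: pd.DataFrame
    quartile_hr: pd.DataFrame
    km_curves: pd.DataFrame
    logrank: pd.DataFrame
    univariable: pd.DataFrame
    multivariable: pd.DataFrame
    interaction: pd.DataFrame
    calibration_table: pd.DataFrame
    predicted_risk: dict
    prediction_curves: pd.DataFrame
    scored_cohort: pd.DataFrame
    exclusions: pd.DataFrame
    run_log: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "characteristics.csv": self.characteristics,
            "quartile_hr.csv": self.quartile_hr,
            "km_curves.csv": self.km_curves,
            "logrank.csv": self.logrank,
            "cox_univariable.csv": self.univariable,
            "cox_multivariable.csv": self.multivariable,
            "interaction.csv": self.interaction,
            "calibration.csv": self.calibration_table,
            "prediction_curves.csv": self.prediction_curves,
            "scored_cohort.csv": self.scored_cohort,
            "exclusions.csv": self.exclusions,
        }
        for name, df in tables.items():
            df.to_csv(out / name, index=False)
        log_lines = [f"{k}: {v}" for k, v in self.run_log.items()]
        log_lines.append(f"predicted_risk: {self.predicted_risk}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        return out


def _characteristics(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    n = len(df)

    def add(factor: str, level: str, count: int) -> None:
        rows.append((factor, level, count, round(100.0 * count / n, 1)))

    for arm in ("tamoxifen_only", "switch_to_exemestane"):
        add("treatment", arm, int((df["treatment"] == arm).sum()))
    age = pd.to_numeric(df["age_years"])
    for label, mask in (("<60", age < 60), ("60-69", (age >= 60) & (age < 70)),
                        ("70+", age >= 70)):
        add("age_years", label, int(mask.sum()))
    for factor in ("grade", "nodal_category"):
        col = df[factor].fillna("").astype(str).str.strip()
        for level in sorted(v for v in col.unique() if v):
            add(factor, level, int((col == level).sum()))
        add(factor, "missing", int((col == "").sum()))
    size = pd.to_numeric(df["tumour_size_cm"], errors="coerce")
    for label, mask in (("<=2", size <= 2), (">2-<=5", (size > 2) & (size <= 5)),
                        (">5", size > 5)):
        add("tumour_size_cm", label, int(mask.sum()))
    add("tumour_size_cm", "missing", int(size.isna().sum()))
    return pd.DataFrame(rows, columns=["factor", "level", "n", "percent"])


def _analysis_frame(scored: pd.DataFrame, variant: str) -> pd.DataFrame:
    """Rows with the variant's score available, with TTDR columns."""
    df = scored[scored[variant].notna()].copy()
    return df


def _quartile_analyses(
    scored: pd.DataFrame, variants: tuple[str, ...], method: str
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    hr_rows, km_rows, lr_rows, int_rows = [], [], [], []
    for variant in variants:
        df = _analysis_frame(scored, variant)
        labels, (q25, q75) = sc.assign_risk_groups(df[variant].to_numpy(float))
        df = df.assign(risk_group=labels)
        scored.loc[df.index, f"risk_group_{variant}"] = labels

        stat, dof, p_lr = sv.logrank_test(df["time_months"], df["event"], labels)
        lr_rows.append((variant, len(df), stat, dof, p_lr, q25, q75))

        design = pd.DataFrame(
            {
                "time_months": df["time_months"].to_numpy(float),
                "event": df["event"].to_numpy(int),
                "Q2Q3": (labels == "Q2Q3").astype(float),
                "Q4": (labels == "Q4").astype(float),
            }
        )
        fit = sv.cox_fit(design, ["Q2Q3", "Q4"])
        hr_rows.append((variant, "Q1", int((labels == "Q1").sum()),
                        int(df.loc[labels == "Q1", "event"].sum()),
                        1.0, np.nan, np.nan, np.nan))
        for term in ("Q2Q3", "Q4"):
            i = fit.terms.index(term)
            hr_rows.append(
                (variant, term, int((labels == term).sum()),
                 int(df.loc[labels == term, "event"].sum()),
                 fit.hr[i], fit.ci_low[i], fit.ci_high[i], fit.p[i])
            )

        for grp in sc.RISK_GROUPS:
            sub = df[labels == grp]
            km = sv.km_estimate(sub[["time_months", "event"]])
            for t, s, r, lo, hi in zip(km.event_times, km.survival_prob,
                                       km.n_at_risk, km.ci_low, km.ci_high):
                km_rows.append((variant, grp, t, s, int(r), lo, hi))

        try:
            p_int, _ = sv.interaction_test(
                df.assign(risk_group=labels), "risk_group", "treatment", method=method
            )
            int_rows.append((variant, len(df), p_int, method))
        except (sv.CoxFitError, ValueError) as exc:
            int_rows.append((variant, len(df), np.nan, f"failed: {exc}"))

    quartile_hr = pd.DataFrame(
        hr_rows, columns=["score", "group", "n", "events", "hr", "ci_low", "ci_high", "p"]
    )
    km_curves = pd.DataFrame(
        km_rows, columns=["score", "group", "time_months", "survival",
                          "n_at_risk", "ci_low", "ci_high"]
    )
    logrank = pd.DataFrame(
        lr_rows, columns=["score", "n", "chi2", "df", "p", "q25", "q75"]
    )
    interaction = pd.DataFrame(int_rows, columns=["score", "n", "p", "method"])
    return quartile_hr, km_curves, logrank, interaction


def _design_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded factors for the Cox tables (reference levels per journal layout)."""
    out = pd.DataFrame(index=df.index)
    out["age65"] = (pd.to_numeric(df["age_years"]) >= 65).astype(float)
    nodes = df["nodal_category"].fillna("").astype(str).str.strip()
    out["nodes_1to3"] = np.where(nodes == "", np.nan, (nodes == "N1to3").astype(float))
    out["nodes_gt3"] = np.where(nodes == "", np.nan, (nodes == "Ngt3").astype(float))
    size = pd.to_numeric(df["tumour_size_cm"], errors="coerce")
    tcat = size.map(lambda s: sc.tumour_size_category(s) if np.isfinite(s) else None)
    for lab, col in (("T1-2", "size_1to2"), ("T2-3", "size_2to3"), ("T>3", "size_gt3")):
        out[col] = tcat.map(lambda v, lab=lab: np.nan if v is None else float(v == lab))
    grade = df["grade"].fillna("").astype(str).str.strip()
    grade_known = ~grade.isin(["", "not_assessable", "unknown"])
    out["grade_2"] = np.where(grade_known, (grade == "G2").astype(float), np.nan)
    out["grade_3"] = np.where(grade_known, (grade == "G3").astype(float), np.nan)
    out["ihc4_cont"] = pd.to_numeric(df["ihc4"])
    out["treat_exe"] = (df["treatment"].astype(str) == sc.Treatment.EXEMESTANE.value).astype(float)
    return out


COX_TERMS: dict[str, list[str]] = {
    "age": ["age65"],
    "nodes": ["nodes_1to3", "nodes_gt3"],
    "size": ["size_1to2", "size_2to3", "size_gt3"],
    "grade": ["grade_2", "grade_3"],
    "ihc4": ["ihc4_cont"],
    "treatment": ["treat_exe"],
}


def _cox_tables(scored: pd.DataFrame, alpha: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    design = pd.concat(
        [_design_columns(scored), scored[["time_months", "event"]]], axis=1
    )
    uni_rows = []
    for term, cols in COX_TERMS.items():
        sub = design[cols + ["time_months", "event"]].dropna()
        try:
            fit = sv.cox_fit(sub, cols)
            for c in cols:
                i = fit.terms.index(c)
                uni_rows.append((term, c, fit.n, fit.hr[i], fit.ci_low[i],
                                 fit.ci_high[i], fit.p[i]))
        except sv.CoxFitError as exc:
            uni_rows.append((term, cols[0], len(sub), np.nan, np.nan, np.nan, np.nan))
    univariable = pd.DataFrame(
        uni_rows, columns=["factor", "term", "n", "hr", "ci_low", "ci_high", "p"]
    )

    complete = design.dropna()
    fit = sv.stepwise_backward(complete, COX_TERMS, forced_terms=["treatment"], alpha=alpha)
    multi = fit.to_frame()
    multi.insert(0, "removed_terms", ", ".join(fit.removal_log) or "(none)")
    return univariable, multi


def _prediction_curves(
    scored: pd.DataFrame, baseline: cal.BaselineSurvival, horizon: float
) -> pd.DataFrame:
    """Predicted DR probability at the horizon vs PathIES score, by nodal status."""
    rows = []
    df = scored[scored["pathies"].notna()]
    for nodal, sub in df.groupby(df["nodal_category"].astype(str)):
        lo, hi = sub["pathies"].min(), sub["pathies"].max()
        if not np.isfinite(lo) or lo == hi:
            continue
        grid = np.linspace(lo, hi, 50)
        pred = cal.predict_dr_probability(grid, horizon, baseline)
        rows.extend((nodal, s, p) for s, p in zip(grid, pred))
    return pd.DataFrame(rows, columns=["nodal_category", "pathies_score", "predicted"])


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Execute the full analysis and (optionally) write the report bundle."""
    raw = pd.read_csv(config.input_path, dtype={"her2_ihc": str})
    validate_schema(raw)
    n_input = len(raw)
    if n_input == 0:
        raise ValueError("input cohort is empty")

    kept, exclusions = sc.eligibility_filter(raw)
    if kept.empty:
        raise ValueError("no analysable rows after eligibility filtering")
    scored = sc.score_cohort(kept)
    scored = sv.derive_ttdr_frame(scored)

    characteristics = _characteristics(scored)
    quartile_hr, km_curves, logrank, interaction = _quartile_analyses(
        scored, tuple(config.score_variants), config.interaction_method
    )
    univariable, multivariable = _cox_tables(scored, config.alpha)

    calib_df = scored[scored["ihc4c"].notna()]
    if config.baseline_mode.startswith("external:"):
        table = pd.read_csv(config.baseline_mode.split(":", 1)[1])
        baseline = cal.BaselineSurvival.from_table(table)
    else:
        baseline = cal.BaselineSurvival.internal_breslow(
            calib_df["ihc4c"], calib_df["time_months"], calib_df["event"]
        )
    horizon = min(config.horizon_months, float(baseline.times[-1]))
    calibration_table = cal.calibration_deciles(
        calib_df["ihc4c"].to_numpy(float),
        calib_df["time_months"].to_numpy(float),
        calib_df["event"].to_numpy(int),
        horizon_months=horizon,
        baseline=baseline,
    )
    predictions = cal.predict_dr_probability(
        calib_df["ihc4c"].to_numpy(float), horizon, baseline
    )
    predicted_risk = cal.predicted_risk_summary(predictions)
    nine_year = min(108.0, horizon)
    prediction_curves = _prediction_curves(scored, baseline, nine_year)

    reasons = exclusions["reason"].value_counts().to_dict() if len(exclusions) else {}
    run_log = {
        "package_version": __version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "input_rows": n_input,
        "excluded_rows": int(len(exclusions)),
        "exclusions_by_reason": reasons,
        "analysed_rows": int(len(scored)),
        "clinical_complete_rows": int(scored["clinical_complete"].sum()),
        "ttdr_events": int(scored["event"].sum()),
        "horizon_months": horizon,
        "baseline_mode": baseline.mode,
        "stepwise_alpha": config.alpha,
    }
    assert run_log["input_rows"] == run_log["analysed_rows"] + run_log["excluded_rows"]

    bundle = ReportBundle(
        characteristics=characteristics,
        quartile_hr=quartile_hr,
        km_curves=km_curves,
        logrank=logrank,
        univariable=univariable,
        multivariable=multivariable,
        interaction=interaction,
        calibration_table=calibration_table,
        predicted_risk=predicted_risk,
        prediction_curves=prediction_curves,
        scored_cohort=scored,
        exclusions=exclusions,
        run_log=run_log,
    )
    if config.out_dir is not None:
        bundle.write(config.out_dir)
    return bundle


def make_fixture(config: GeneratorConfig, out_dir: str | Path) -> SyntheticCohort:
    """Generate a synthetic cohort fixture and write cohort + truth CSVs."""
    cohort = generate_cohort(config)
    cohort.write(out_dir)
    return cohort
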