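"""Time-to-distant-recurrence endpoint and survival analyses.

The endpoint (TTDR) runs from randomisation to distant recurrence or death
from breast cancer or unknown cause without prior recurrence; any other
outcome censors. Kaplan-Meier estimation, log-rank tests and Cox
proportional-hazards models (Efron tie handling) are provided through
lifelines, wrapped to the report shapes used throughout the package, together
with forced-term backward stepwise selection and the treatment-by-risk-group
interaction test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "EventType",
    "TTDR_EVENT_TYPES",
    "FollowUpRecord",
    "SurvivalOutcome",
    "KMCurve",
    "CoxModelFit",
    "CoxFitError",
    "derive_ttdr",
    "derive_ttdr_frame",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "stepwise_backward",
    "interaction_test",
]

_Z95 = float(stats.norm.ppf(0.975))


class EventType(str, Enum):
    NONE = "none"
    DISTANT_RECURRENCE = "distant_recurrence"
    LOCAL_OR_REGIONAL = "local_or_regional_recurrence"
    CONTRALATERAL = "contralateral"
    DEATH_BREAST_CANCER = "death_breast_cancer"
    DEATH_UNKNOWN_CAUSE = "death_unknown_cause"
    DEATH_OTHER_CAUSE = "death_other_cause"


#: Event types that count as TTDR events; everything else censors.
TTDR_EVENT_TYPES = frozenset(
    {EventType.DISTANT_RECURRENCE, EventType.DEATH_BREAST_CANCER, EventType.DEATH_UNKNOWN_CAUSE}
)


@dataclass(frozen=True)
class FollowUpRecord:
    time_months: float
    event_type: EventType

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_months) or self.time_months < 0:
            raise ValueError(f"time_months must be finite and >= 0, got {self.time_months!r}")
        object.__setattr__(self, "event_type", EventType(self.event_type))


@dataclass(frozen=True)
class SurvivalOutcome:
    time_months: float
    event: int


def derive_ttdr(record: FollowUpRecord) -> SurvivalOutcome:
    """Map a follow-up record to the TTDR outcome (event or censoring)."""
    return SurvivalOutcome(
        time_months=float(record.time_months),
        event=int(record.event_type in TTDR_EVENT_TYPES),
    )


def derive_ttdr_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`derive_ttdr`: appends a binary ``event`` column."""
    out = cohort.copy()
    times = pd.to_numeric(out["time_months"], errors="raise")
    if (times < 0).any() or not np.isfinite(times).all():
        raise ValueError("time_months must be finite and >= 0")
    types = out["event_type"].map(lambda v: EventType(str(v)))
    out["event"] = types.isin(TTDR_EVENT_TYPES).astype(int)
    return out


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate with Greenwood pointwise intervals."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (1 before the first event)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        return float(self.ci_low[idx]), float(self.ci_high[idx])


def km_estimate(outcomes: Sequence[SurvivalOutcome] | pd.DataFrame) -> KMCurve:
    """Kaplan-Meier estimate over the distinct event/censoring times.

    Subjects censored exactly at an event time are counted at risk for that
    time (the usual convention). Confidence bands are Greenwood with the
    log(-log) transform.
    """
    if isinstance(outcomes, pd.DataFrame):
        times = outcomes["time_months"].to_numpy(float)
        events = outcomes["event"].to_numpy(int)
    else:
        times = np.array([o.time_months for o in outcomes], float)
        events = np.array([o.event for o in outcomes], int)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one outcome")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tbl = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    grid = tbl.index.to_numpy(float)
    return KMCurve(
        event_times=grid,
        survival_prob=sf.to_numpy(float),
        n_at_risk=tbl["at_risk"].to_numpy(int),
        ci_low=ci.iloc[:, 0].to_numpy(float),
        ci_high=ci.iloc[:, 1].to_numpy(float),
    )


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence
) -> tuple[float, int, float]:
    """Log-rank test across >= 2 groups; returns (chi2, df, p)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("logrank_test requires at least two groups")
    if (counts == 0).any():
        raise ValueError("every group must contain at least one subject")
    res = multivariate_logrank_test(times, groups, events)
    df = int(labels.size - 1)
    return float(res.test_statistic), df, float(res.p_value)


class CoxFitError(RuntimeError):
    """Cox partial-likelihood maximisation failed (degenerate design,
    monotone likelihood / complete separation, or non-convergence)."""


@dataclass(frozen=True)
class CoxModelFit:
    """A fitted Cox proportional-hazards model.

    Hazard ratios are exp(coef) with Wald 95% intervals
    exp(coef +/- 1.96 SE); ``p`` are Wald p-values.
    """

    terms: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    log_likelihood: float
    n: int
    n_events: int
    removal_log: tuple[str, ...] = field(default=())

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coef - _Z95 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coef + _Z95 * self.se)

    def to_frame(self) -> pd.DataFrame:
        """Report table: term, N, HR, CI bounds, p (the journal layout)."""
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "n": self.n,
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            }
        )

    def term_p(self, term: str) -> float:
        return float(self.p[self.terms.index(term)])


def cox_fit(
    data: pd.DataFrame,
    covariates: Sequence[str],
    *,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> CoxModelFit:
    """Fit a Cox PH model by Efron-ties partial likelihood on ``covariates``.

    Raises
    ------
    CoxFitError
        If a covariate is constant, events are fewer than terms, or the
        likelihood is monotone / the optimiser fails to converge.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("cox_fit requires at least one covariate")
    cols = covariates + [duration_col, event_col]
    df = data[cols].dropna()
    n_events = int(df[event_col].sum())
    for c in covariates:
        if df[c].nunique() <= 1:
            raise CoxFitError(f"covariate {c!r} is constant across all subjects")
    if n_events < len(covariates):
        raise CoxFitError(
            f"{n_events} events cannot support {len(covariates)} model terms"
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise CoxFitError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary
    coef = summ["coef"].to_numpy(float)
    se = summ["se(coef)"].to_numpy(float)
    if not np.isfinite(coef).all() or (np.abs(coef) > 10).any() or (se > 50).any():
        raise CoxFitError("monotone likelihood suspected: diverging coefficient")
    return CoxModelFit(
        terms=tuple(summ.index),
        coef=coef,
        se=se,
        p=summ["p"].to_numpy(float),
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(df)),
        n_events=n_events,
    )


def _block_p(
    data: pd.DataFrame,
    current: dict[str, list[str]],
    name: str,
    fit: CoxModelFit,
    duration_col: str,
    event_col: str,
) -> float:
    """Wald p for single-column terms, likelihood-ratio p for blocks."""
    cols = current[name]
    if len(cols) == 1:
        return fit.term_p(cols[0])
    reduced_cols = [c for t, cc in current.items() if t != name for c in cc]
    if not reduced_cols:
        # null model: partial log-likelihood with all coefficients zero
        reduced_ll = _null_partial_loglik(data, duration_col, event_col)
    else:
        reduced_ll = cox_fit(
            data, reduced_cols, duration_col=duration_col, event_col=event_col
        ).log_likelihood
    lr = 2.0 * (fit.log_likelihood - reduced_ll)
    return float(stats.chi2.sf(max(lr, 0.0), df=len(cols)))


def _null_partial_loglik(data: pd.DataFrame, duration_col: str, event_col: str) -> float:
    # Efron and Breslow coincide at beta = 0 up to tie terms; use Efron's form.
    df = data[[duration_col, event_col]].dropna().sort_values(duration_col)
    t = df[duration_col].to_numpy(float)
    e = df[event_col].to_numpy(int)
    ll = 0.0
    for ti in np.unique(t[e == 1]):
        d = int(((t == ti) & (e == 1)).sum())
        r = int((t >= ti).sum())
        # at beta = 0 the Efron denominators reduce to r, r-1, ..., r-d+1
        ll -= float(np.sum(np.log(r - np.arange(d))))
    return ll


def stepwise_backward(
    data: pd.DataFrame,
    candidate_terms: Mapping[str, Sequence[str]],
    forced_terms: Sequence[str],
    alpha: float = 0.10,
    *,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> CoxModelFit:
    """Backward stepwise Cox selection with forced (never-removed) terms.

    ``candidate_terms`` maps term names to their design columns; grouped
    categorical factors (e.g. the two nodal indicators) form one block and
    are judged by the block likelihood-ratio p-value, single columns by the
    Wald p-value. Each iteration refits and removes the non-forced term with
    the largest p exceeding ``alpha``; selection stops when all remaining
    non-forced terms have p <= alpha. The removal order is logged on the
    returned fit.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    current = {t: list(cols) for t, cols in candidate_terms.items()}
    forced = set(forced_terms)
    if not forced <= set(current):
        raise ValueError("forced terms must be a subset of candidate terms")
    removed: list[str] = []
    while True:
        cols = [c for cc in current.values() for c in cc]
        fit = cox_fit(data, cols, duration_col=duration_col, event_col=event_col)
        droppable = [t for t in current if t not in forced]
        if not droppable:
            break
        pvals = {
            t: _block_p(data, current, t, fit, duration_col, event_col) for t in droppable
        }
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha:
            break
        del current[worst]
        removed.append(worst)
    return CoxModelFit(
        terms=fit.terms,
        coef=fit.coef,
        se=fit.se,
        p=fit.p,
        log_likelihood=fit.log_likelihood,
        n=fit.n,
        n_events=fit.n_events,
        removal_log=tuple(removed),
    )


def interaction_test(
    data: pd.DataFrame,
    group_col: str,
    treatment_col: str,
    *,
    duration_col: str = "time_months",
    event_col: str = "event",
    method: str = "lr",
) -> tuple[float, CoxModelFit]:
    """Treatment-by-risk-group interaction in the multivariable Cox model.

    Compares main effects (risk group + treatment) against the model adding
    group x treatment products, by likelihood ratio (default) or Wald test.
    """
    if method not in ("lr", "wald"):
        raise ValueError("method must be 'lr' or 'wald'")
    df = data[[group_col, treatment_col, duration_col, event_col]].dropna().copy()
    groups = sorted(df[group_col].astype(str).unique())
    arms = sorted(df[treatment_col].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("risk group factor does not vary")
    if len(arms) < 2:
        raise ValueError("treatment factor does not vary")
    cell = pd.crosstab(df[group_col], df[treatment_col])
    if (cell == 0).any().any():
        raise CoxFitError("empty risk-group x treatment cell; interaction not estimable")

    treat = (df[treatment_col].astype(str) == arms[-1]).astype(float)
    design = pd.DataFrame({duration_col: df[duration_col], event_col: df[event_col]})
    design["treat"] = treat
    main_cols = ["treat"]
    inter_cols = []
    for g in groups[1:]:
        gcol = f"group_{g}"
        design[gcol] = (df[group_col].astype(str) == g).astype(float)
        main_cols.append(gcol)
        icol = f"treat_x_{g}"
        design[icol] = design[gcol] * treat
        inter_cols.append(icol)
    fit_main = cox_fit(design, main_cols, duration_col=duration_col, event_col=event_col)
    fit_full = cox_fit(
        design, main_cols + inter_cols, duration_col=duration_col, event_col=event_col
    )
    if method == "lr":
        lr = 2.0 * (fit_full.log_likelihood - fit_main.log_likelihood)
        p = float(stats.chi2.sf(max(lr, 0.0), df=len(inter_cols)))
    else:
        # Wald chi-square on the interaction subvector
        idx = [fit_full.terms.index(c) for c in inter_cols]
        w = np.sum((fit_full.coef[idx] / fit_full.se[idx]) ** 2)
        p = float(stats.chi2.sf(w, df=len(inter_cols)))
    return p, fit_full
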