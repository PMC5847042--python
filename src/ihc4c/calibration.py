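"""Predicted 10-year distant-recurrence probabilities and calibration by decile.

The combined score is a Cox linear predictor scaled by 100, so the predicted
probability of a distant-recurrence event by time t is

    P(t | score) = 1 - S0(t) ** exp(score / 100)

where S0 is a baseline survival function: either supplied externally as a
(time, S0) table, or estimated internally by the Breslow estimator treating
score/100 as a fixed offset (no coefficient refitting). Calibration compares
mean predicted probabilities with observed Kaplan-Meier estimates within
score-decile groups; perfect calibration lies on the 45-degree line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .survival import km_estimate

__all__ = [
    "BaselineSurvival",
    "predict_dr_probability",
    "calibration_deciles",
    "predicted_risk_summary",
    "DEFAULT_HORIZON_MONTHS",
]

DEFAULT_HORIZON_MONTHS = 120.0


@dataclass(frozen=True)
class BaselineSurvival:
    """Baseline survival S0(t) as a right-continuous step function.

    ``mode`` records provenance: ``internal_breslow`` (estimated from the
    cohort with the score as a fixed offset) or ``external_table`` (user
    supplied, e.g. from an external derivation cohort).
    """

    times: np.ndarray
    s0: np.ndarray
    mode: str = "external_table"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        s = np.asarray(self.s0, float)
        if t.ndim != 1 or t.size == 0 or t.size != s.size:
            raise ValueError("baseline table must be two equal-length columns")
        if (np.diff(t) <= 0).any():
            raise ValueError("baseline times must be strictly increasing")
        if (s <= 0).any() or (s > 1).any():
            raise ValueError("S0 values must lie in (0, 1]")
        if (np.diff(s) > 1e-12).any():
            raise ValueError("S0 must be non-increasing in time")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "s0", s)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "BaselineSurvival":
        """Build from a 2-column table (time_months, s0)."""
        return cls(
            times=table.iloc[:, 0].to_numpy(float),
            s0=table.iloc[:, 1].to_numpy(float),
            mode="external_table",
        )

    @classmethod
    def internal_breslow(
        cls,
        scores: Sequence[float],
        times: Sequence[float],
        events: Sequence[int],
    ) -> "BaselineSurvival":
        """Breslow baseline with score/100 as a fixed, known linear predictor.

        H0(t) = sum over event times t_i <= t of d_i / sum_{j at risk} exp(lp_j),
        S0(t) = exp(-H0(t)). No coefficient is estimated.
        """
        lp = np.asarray(scores, float) / 100.0
        t = np.asarray(times, float)
        e = np.asarray(events, int)
        if not (lp.size == t.size == e.size) or lp.size == 0:
            raise ValueError("scores, times and events must be equal-length and non-empty")
        risk = np.exp(lp)
        order = np.argsort(t)
        t, e, risk = t[order], e[order], risk[order]
        event_times = np.unique(t[e == 1])
        if event_times.size == 0:
            raise ValueError("no events: Breslow baseline is undefined")
        # cumulative risk from the right gives the at-risk denominator
        rev_cumsum = np.cumsum(risk[::-1])[::-1]
        h0 = np.zeros(event_times.size)
        for i, ti in enumerate(event_times):
            d = int(((t == ti) & (e == 1)).sum())
            at_risk = rev_cumsum[np.searchsorted(t, ti, side="left")]
            h0[i] = d / at_risk
        s0 = np.exp(-np.cumsum(h0))
        return cls(times=event_times, s0=s0, mode="internal_breslow")

    def s0_at(self, t: float) -> float:
        if t < 0:
            raise ValueError("time must be non-negative")
        if t > self.times[-1]:
            raise ValueError(
                f"horizon {t} exceeds baseline support (max {self.times[-1]})"
            )
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.s0[idx])

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "s0": self.s0})


def predict_dr_probability(
    score: float | np.ndarray,
    horizon_months: float,
    baseline: BaselineSurvival,
) -> float | np.ndarray:
    """Predicted probability of distant recurrence by ``horizon_months``.

    ``1 - S0(horizon) ** exp(score / 100)``; monotone increasing in both the
    score and the horizon, bounded in [0, 1].
    """
    s0 = baseline.s0_at(float(horizon_months))
    out = 1.0 - np.power(s0, np.exp(np.asarray(score, float) / 100.0))
    return float(out) if np.ndim(score) == 0 else out


def calibration_deciles(
    scores: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
    baseline: BaselineSurvival | None = None,
) -> pd.DataFrame:
    """Predicted vs observed event probability within score-decile groups.

    Patients are split into ten groups at the empirical 10th percentiles of
    the score. Within each group the mean predicted probability at the
    horizon is compared with the observed Kaplan-Meier event probability
    1 - S(horizon) and its Greenwood (log-log) 95% interval. A group with no
    events and nobody under observation at the horizon gets a missing
    observed value rather than a fabricated one.

    Returns a plot-ready table with columns
    (decile, n, score_min, score_max, predicted, observed, ci_low, ci_high).
    """
    s = np.asarray(scores, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if not (s.size == t.size == e.size):
        raise ValueError("scores and outcomes must be aligned")
    if s.size < 10:
        raise ValueError("calibration requires at least 10 subjects")
    edges = np.quantile(s, np.linspace(0.1, 0.9, 9))
    if np.unique(edges).size < 9:
        raise ValueError("degenerate deciles: tied 10th-percentile cutpoints")
    if baseline is None:
        baseline = BaselineSurvival.internal_breslow(s, t, e)
    bins = np.searchsorted(edges, s, side="right")  # boundary scores move up
    pred = predict_dr_probability(s, horizon_months, baseline)
    rows = []
    for b in range(10):
        mask = bins == b
        n = int(mask.sum())
        if n == 0:
            rows.append((b + 1, 0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        tb, eb = t[mask], e[mask]
        any_events = (eb[tb <= horizon_months] == 1).any()
        at_risk_at_h = (tb >= horizon_months).any()
        if not any_events and not at_risk_at_h:
            obs = ci_lo = ci_hi = np.nan
        else:
            km = km_estimate(pd.DataFrame({"time_months": tb, "event": eb}))
            obs = 1.0 - km.survival_at(horizon_months)
            lo, hi = km.ci_at(horizon_months)
            ci_lo, ci_hi = 1.0 - hi, 1.0 - lo
        rows.append(
            (b + 1, n, float(s[mask].min()), float(s[mask].max()),
             float(np.mean(pred[mask])), obs, ci_lo, ci_hi)
        )
    return pd.DataFrame(
        rows,
        columns=["decile", "n", "score_min", "score_max",
                 "predicted", "observed", "ci_low", "ci_high"],
    )


def predicted_risk_summary(
    predictions: Sequence[float],
    quantiles: Sequence[float] = (0.1, 0.25, 0.5, 0.75, 0.9),
) -> dict:
    """Median, 75th percentile and a full quantile grid of predicted risks.

    Quantiles use the empirical (inverted-CDF) convention: the reported
    median is an observed prediction with at least half the cohort at or
    below it — the natural reading of statements like "fifty per cent of
    patients had predicted risk <= 10%".
    """
    p = np.asarray(predictions, float)
    if p.size == 0:
        raise ValueError("predicted_risk_summary requires at least one prediction")

    def q(frac: float) -> float:
        return float(np.quantile(p, frac, method="inverted_cdf"))

    return {
        "median": q(0.5),
        "q75": q(0.75),
        "quantiles": {float(f): q(f) for f in quantiles},
    }
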