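"""Endpoint derivation, Kaplan-Meier, log-rank, Cox models and selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ihc4c import survival as sv


def make_outcomes(times, events):
    return pd.DataFrame({"time_months": times, "event": events})


class TestDeriveTTDR:
    @pytest.mark.parametrize(
        "time,etype,expected_event",
        [
            (30, "distant_recurrence", 1),
            (55, "death_breast_cancer", 1),
            (72, "death_unknown_cause", 1),
            (40, "death_other_cause", 0),
            (18, "local_or_regional_recurrence", 0),
            (64, "contralateral", 0),
            (120, "none", 0),
        ],
    )
    def test_endpoint_rule(self, time, etype, expected_event):
        out = sv.derive_ttdr(sv.FollowUpRecord(time, sv.EventType(etype)))
        assert out.time_months == time and out.event == expected_event

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            sv.FollowUpRecord(-1.0, sv.EventType.NONE)

    def test_frame_version_matches_scalar(self):
        df = pd.DataFrame(
            {
                "time_months": [30.0, 40.0, 120.0],
                "event_type": ["distant_recurrence", "death_other_cause", "none"],
            }
        )
        out = sv.derive_ttdr_frame(df)
        assert list(out["event"]) == [1, 0, 0]


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        km = sv.km_estimate(make_outcomes([1.0, 2.0, 3.0], [1, 1, 0]))
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.0) == pytest.approx(1 / 3)
        assert km.survival_at(2.5) == pytest.approx(1 / 3)

    def test_all_censored_stays_at_one(self):
        km = sv.km_estimate(make_outcomes([5.0, 8.0, 12.0], [0, 0, 0]))
        assert km.survival_at(12.0) == 1.0

    def test_single_event_drops_to_zero(self):
        km = sv.km_estimate(make_outcomes([5.0], [1]))
        assert km.survival_at(5.0) == 0.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sv.km_estimate(make_outcomes([], []))

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(50, size=300).round(3)
        km = sv.km_estimate(make_outcomes(t, np.ones_like(t, dtype=int)))
        for q in (10, 30, 60, 100):
            assert km.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = [5.0, 10.0, 15.0, 20.0]
        e = [1, 0, 1, 1]
        stat, dof, p = sv.logrank_test(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_three_groups_have_two_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 30)
        _, dof, _ = sv.logrank_test(t, np.ones(30, int), np.repeat(["a", "b", "c"], 10))
        assert dof == 2

    def test_detects_planted_rate_ratio_three(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            t = np.concatenate([rng.exponential(60, 500), rng.exponential(20, 500)])
            g = np.repeat(["tam", "exe"], 500)
            _, _, p = sv.logrank_test(t, np.ones(1000, int), g)
            assert p < 0.001

    def test_invariance_to_labels_and_time_rescaling(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(30, 80)
        e = rng.integers(0, 2, 80)
        g = rng.choice(["x", "y"], 80)
        s1, _, p1 = sv.logrank_test(t, e, g)
        s2, _, p2 = sv.logrank_test(t, e, np.where(g == "x", "y", "x"))
        s3, _, p3 = sv.logrank_test(t * 7.3, e, g)
        assert s1 == pytest.approx(s2) and s1 == pytest.approx(s3)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            sv.logrank_test([1, 2], [1, 1], ["a", "a"])


def brute_force_cox_beta(x, t, e):
    """Grid/1-d maximisation of the (tie-free) Cox partial likelihood."""

    def neg_pl(beta):
        ll = 0.0
        for i in np.flatnonzero(e):
            at_risk = t >= t[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
        return -ll

    res = optimize.minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                                   options={"xatol": 1e-8})
    return res.x


class TestCoxFit:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_brute_force_partial_likelihood(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(40 / np.exp(0.7 * x))  # continuous -> no ties
        e = (rng.random(n) < 0.8).astype(int)
        if e.sum() < 5 or len(set(x)) < 2:
            pytest.skip("degenerate draw")
        df = pd.DataFrame({"x": x, "time_months": t, "event": e})
        fit = sv.cox_fit(df, ["x"])
        assert fit.coef[0] == pytest.approx(brute_force_cox_beta(x, t, e), abs=1e-3)

    def test_recovers_planted_hazard_ratio_two(self):
        """HR within [1.8, 2.2] in nearly all replicates (the ~95% band)."""
        rng = np.random.default_rng(12)
        inside = 0
        for _ in range(10):
            n = 2000
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(50 / np.exp(np.log(2.0) * x))
            c = rng.uniform(30, 120, n)
            df = pd.DataFrame(
                {"x": x, "time_months": np.minimum(t, c), "event": (t <= c).astype(int)}
            )
            fit = sv.cox_fit(df, ["x"])
            inside += 1.8 <= fit.hr[0] <= 2.2
        assert inside >= 8

    def test_hazard_ratio_and_ci_are_exp_of_coef(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=200),
                "time_months": rng.exponential(30, 200),
                "event": rng.integers(0, 2, 200),
            }
        )
        fit = sv.cox_fit(df, ["x"])
        assert fit.hr[0] == pytest.approx(np.exp(fit.coef[0]))
        assert fit.ci_low[0] == pytest.approx(np.exp(fit.coef[0] - 1.96 * fit.se[0]), rel=1e-4)
        assert fit.ci_high[0] == pytest.approx(np.exp(fit.coef[0] + 1.96 * fit.se[0]), rel=1e-4)

    def test_constant_covariate_raises(self):
        df = pd.DataFrame(
            {"x": np.ones(20), "time_months": np.arange(1, 21), "event": [1] * 20}
        )
        with pytest.raises(sv.CoxFitError, match="constant"):
            sv.cox_fit(df, ["x"])

    def test_more_terms_than_events_raises(self):
        df = pd.DataFrame(
            {
                "x1": [0, 1, 0, 1], "x2": [1, 1, 0, 0],
                "time_months": [1.0, 2.0, 3.0, 4.0], "event": [1, 0, 0, 0],
            }
        )
        with pytest.raises(sv.CoxFitError):
            sv.cox_fit(df, ["x1", "x2"])

    def test_complete_separation_is_diagnosed(self):
        # all events in one arm, observed before every other-arm time
        df = pd.DataFrame(
            {
                "x": [1.0] * 10 + [0.0] * 10,
                "time_months": list(range(1, 11)) + list(range(20, 30)),
                "event": [1] * 10 + [0] * 10,
            }
        )
        with pytest.raises(sv.CoxFitError):
            sv.cox_fit(df, ["x"])


def _selection_data(rng, n=800):
    """Planted effects on nodes and size; grade, age carry none."""
    nodes = rng.choice([0, 1, 2], n, p=[0.45, 0.36, 0.19])
    size = rng.choice([0, 1, 2, 3], n, p=[0.14, 0.44, 0.25, 0.17])
    grade = rng.choice([0, 1, 2], n, p=[0.25, 0.55, 0.20])
    age65 = rng.integers(0, 2, n).astype(float)
    treat = rng.integers(0, 2, n).astype(float)
    lp = 0.65 * (nodes == 1) + 1.6 * (nodes == 2) + 0.5 * size
    t = rng.exponential(1.0, n) / (0.012 * np.exp(lp))
    c = rng.uniform(60, 120, n)
    return pd.DataFrame(
        {
            "nodes_1to3": (nodes == 1).astype(float),
            "nodes_gt3": (nodes == 2).astype(float),
            "size_1to2": (size == 1).astype(float),
            "size_2to3": (size == 2).astype(float),
            "size_gt3": (size == 3).astype(float),
            "grade_2": (grade == 1).astype(float),
            "grade_3": (grade == 2).astype(float),
            "age65": age65,
            "treat_exe": treat,
            "time_months": np.minimum(t, c),
            "event": (t <= c).astype(int),
        }
    )


CANDIDATES = {
    "nodes": ["nodes_1to3", "nodes_gt3"],
    "size": ["size_1to2", "size_2to3", "size_gt3"],
    "grade": ["grade_2", "grade_3"],
    "age": ["age65"],
    "treatment": ["treat_exe"],
}


class TestStepwiseBackward:
    def test_planted_truth_selection(self):
        rng = np.random.default_rng(31)
        df = _selection_data(rng)
        fit = sv.stepwise_backward(df, CANDIDATES, forced_terms=["treatment"], alpha=0.10)
        retained = set(fit.terms)
        assert {"nodes_1to3", "nodes_gt3", "size_1to2", "size_2to3", "size_gt3",
                "treat_exe"} <= retained
        assert "grade_2" not in retained and "age65" not in retained
        assert set(fit.removal_log) == {"grade", "age"}

    def test_alpha_one_removes_nothing(self):
        rng = np.random.default_rng(32)
        df = _selection_data(rng, n=400)
        fit = sv.stepwise_backward(df, CANDIDATES, forced_terms=["treatment"], alpha=1.0)
        assert fit.removal_log == ()
        assert len(fit.terms) == 9

    def test_only_forced_terms_is_identity(self):
        rng = np.random.default_rng(33)
        df = _selection_data(rng, n=400)
        fit = sv.stepwise_backward(
            df, {"treatment": ["treat_exe"]}, forced_terms=["treatment"], alpha=0.10
        )
        direct = sv.cox_fit(df, ["treat_exe"])
        assert fit.terms == direct.terms
        assert fit.coef[0] == pytest.approx(direct.coef[0])

    def test_smaller_alpha_never_retains_more(self):
        rng = np.random.default_rng(34)
        df = _selection_data(rng, n=600)
        loose = sv.stepwise_backward(df, CANDIDATES, forced_terms=["treatment"], alpha=0.5)
        strict = sv.stepwise_backward(df, CANDIDATES, forced_terms=["treatment"], alpha=0.05)
        assert set(strict.terms) <= set(loose.terms)

    def test_forced_must_be_candidate(self):
        rng = np.random.default_rng(35)
        df = _selection_data(rng, n=200)
        with pytest.raises(ValueError):
            sv.stepwise_backward(df, {"age": ["age65"]}, forced_terms=["treatment"])


def _interaction_data(rng, n, hr_by_group=(1.0, 1.0, 1.0)):
    """Treatment halves/doubles the hazard per risk group as configured."""
    group = rng.choice(["Q1", "Q2Q3", "Q4"], n, p=[0.25, 0.5, 0.25])
    treat = rng.choice(["tamoxifen_only", "switch_to_exemestane"], n)
    hr = dict(zip(["Q1", "Q2Q3", "Q4"], hr_by_group))
    lp = np.where(treat == "switch_to_exemestane",
                  np.log([hr[g] for g in group]), 0.0)
    base = 0.02 * np.exp(0.4 * (group == "Q2Q3") + 0.9 * (group == "Q4"))
    t = rng.exponential(1.0, n) / (base * np.exp(lp))
    c = rng.uniform(60, 120, n)
    return pd.DataFrame(
        {
            "risk_group": group,
            "treatment": treat,
            "time_months": np.minimum(t, c),
            "event": (t <= c).astype(int),
        }
    )


class TestInteractionTest:
    def test_detects_planted_qualitative_interaction(self):
        rng = np.random.default_rng(41)
        detected = 0
        for _ in range(5):
            df = _interaction_data(rng, 2000, hr_by_group=(0.5, 1.0, 2.0))
            p, _ = sv.interaction_test(df, "risk_group", "treatment")
            detected += p < 0.01
        assert detected >= 4

    def test_wald_and_lr_agree_roughly(self):
        rng = np.random.default_rng(42)
        df = _interaction_data(rng, 1500, hr_by_group=(0.6, 1.0, 1.8))
        p_lr, _ = sv.interaction_test(df, "risk_group", "treatment", method="lr")
        p_wald, _ = sv.interaction_test(df, "risk_group", "treatment", method="wald")
        assert p_lr == pytest.approx(p_wald, abs=0.05)

    def test_single_arm_raises(self):
        rng = np.random.default_rng(43)
        df = _interaction_data(rng, 200)
        df["treatment"] = "tamoxifen_only"
        with pytest.raises(ValueError, match="treatment"):
            sv.interaction_test(df, "risk_group", "treatment")

    def test_empty_cell_raises(self):
        rng = np.random.default_rng(44)
        df = _interaction_data(rng, 300)
        df = df[~((df["risk_group"] == "Q4") & (df["treatment"] == "tamoxifen_only"))]
        with pytest.raises(sv.CoxFitError, match="empty"):
            sv.interaction_test(df, "risk_group", "treatment")
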