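"""Error-zeroing sensitivity analysis and the variance-ratio F-test."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from synchromargin import error_model as em, margins as mg, sensitivity as sdt
from synchromargin.log_io import AXES


def test_zeroing_an_already_zero_source_is_neutral():
    budget = em.analytic_budget("Liver", "SI")
    zeroed_once = sdt.zero_source(budget, "correlation")
    res = sdt.zero_and_recompute(zeroed_once, "correlation")
    assert res.interaction_level_mm == pytest.approx(0.0, abs=1e-12)
    assert res.impact_class == "low"


@pytest.mark.parametrize("method", ["van_herk", "uncertainty"])
def test_pair_interaction_superadditive(method):
    """Concavity of the quadrature margin makes pair interactions
    superadditive: zeroing both tracking sources removes at least as much as
    the two single-source effects combined, and at least as much as either."""
    for site in ("Lung LLL", "Liver", "Retroperitoneum"):
        for axis in AXES:
            budget = em.analytic_budget(site, axis)
            corr = sdt.zero_and_recompute(budget, "correlation", method).interaction_level_mm
            pred = sdt.zero_and_recompute(budget, "prediction", method).interaction_level_mm
            pair = sdt.zero_and_recompute(budget, "correlation+prediction", method).interaction_level_mm
            assert pair >= max(corr, pred) - 1e-12
            assert pair >= corr + pred - 1e-12


def test_interaction_matches_bruteforce_recompute():
    """Zero-and-recompute equals editing the inputs and recomputing directly."""
    budget = em.analytic_budget("Pancreas", "AP")
    res = sdt.zero_and_recompute(budget, "prediction", method="van_herk")
    sigma_sys = {s: budget.sources[s].sigma_systematic_mm for s in em.SOURCES}
    sigma_sys["prediction"] = 0.0
    manual = mg.van_herk_extended(
        mg.MarginInputs(
            sigma_sys=sigma_sys,
            sigma_rand={
                "correlation": budget.sources["correlation"].sigma_random_mm,
                "prediction": 0.0,
            },
        )
    )
    assert res.recalculated_margin_mm == pytest.approx(manual, abs=1e-12)
    assert res.interaction_level_mm == pytest.approx(
        res.original_margin_mm - manual, abs=1e-12
    )


@pytest.mark.parametrize("method", ["van_herk", "uncertainty"])
def test_zeroing_everything_gives_zero_margin(method):
    budget = em.analytic_budget("Lung LUL", "SI")
    for hyp in ("segmentation+deformation", "correlation+prediction", "robot"):
        budget = sdt.zero_source(budget, hyp)
    compute = (
        mg.van_herk_margin_from_budget if method == "van_herk" else mg.uncertainty_margin_from_budget
    )
    assert compute(budget) == pytest.approx(0.0, abs=1e-12)


def test_robot_impact_low_tracking_impact_high():
    """Zeroing the robot (targeting) term moves the margin less than zeroing
    the tracking pair at published-cohort scale, except where the published
    tracking residuals are themselves below the fixed 0.3-mm targeting SD
    (retroperitoneum), where both impacts are in the low class."""
    robots, pairs = [], []
    for site in em.reference.SITE_TRACKING:
        for axis in AXES:
            budget = em.analytic_budget(site, axis)
            robot = sdt.zero_and_recompute(budget, "robot").interaction_level_mm
            pair = sdt.zero_and_recompute(budget, "correlation+prediction").interaction_level_mm
            robots.append(robot)
            pairs.append(pair)
            if site == "Retroperitoneum":
                assert sdt.classify_impact(robot) == "low"
                assert sdt.classify_impact(pair) == "low"
            else:
                assert robot < pair
    assert np.mean(robots) < np.mean(pairs)


def test_impact_classes_on_high_motion_budget():
    """At a large-motion lung site, robot impact classifies low while the
    correlation impact is moderate to very high."""
    budget = em.analytic_budget("Lung LLL", "SI")
    robot = sdt.zero_and_recompute(budget, "robot")
    corr = sdt.zero_and_recompute(budget, "correlation")
    assert robot.impact_class == "low"
    assert corr.impact_class in ("moderate", "high", "very_high")


def test_sdt_is_pure_function_of_budget():
    budget = em.analytic_budget("Lung RLL", "LR")
    r1 = sdt.zero_and_recompute(budget, "deformation")
    r2 = sdt.zero_and_recompute(budget, "deformation")
    assert r1 == r2


def test_unknown_hypothesis_rejected():
    budget = em.analytic_budget("Liver", "SI")
    with pytest.raises(ValueError):
        sdt.zero_source(budget, "latency")


def test_classify_impact_bins_and_monotonicity():
    assert sdt.classify_impact(0.0) == "low"
    assert sdt.classify_impact(0.5) == "moderate"
    assert sdt.classify_impact(1.5) == "high"
    assert sdt.classify_impact(5.0) == "very_high"
    order = {"low": 0, "moderate": 1, "high": 2, "very_high": 3}
    deltas = np.linspace(0, 3, 61)
    classes = [order[sdt.classify_impact(d)] for d in deltas]
    assert all(a <= b for a, b in zip(classes, classes[1:]))
    with pytest.raises(ValueError):
        sdt.classify_impact(-0.1)


def test_f_test_identical_samples_not_significant():
    res = sdt.variance_ratio_f_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert res.f_value == pytest.approx(1.0)
    assert not res.significant
    assert res.p_value == pytest.approx(1.0)


def test_f_test_matches_independent_arithmetic():
    """F, critical value and p agree with direct scipy.stats.f arithmetic."""
    a = [2.1, 2.9, 3.4, 1.7, 2.6, 3.1]
    b = [2.0, 2.2, 2.1, 1.9, 2.05, 2.15]
    res = sdt.variance_ratio_f_test(a, b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    f = max(va, vb) / min(va, vb)
    assert res.f_value == pytest.approx(f, abs=1e-12)
    assert res.p_value == pytest.approx(min(1.0, 2 * stats.f.sf(f, 5, 5)), abs=1e-12)
    assert res.f_critical == pytest.approx(stats.f.ppf(0.975, 5, 5), abs=1e-12)
    assert res.significant == (res.f_value > res.f_critical and res.p_value < 0.05)


def test_f_test_power_on_ninefold_variance():
    """N(0,1) vs N(0,9) at n=50 is detected in >= 95% of seeded replicates."""
    rng = np.random.default_rng(0)
    hits = 0
    n_rep = 1000
    for _ in range(n_rep):
        a = rng.standard_normal(50)
        b = 3.0 * rng.standard_normal(50)
        if sdt.variance_ratio_f_test(a, b).significant:
            hits += 1
    assert hits / n_rep >= 0.95


def test_f_test_degenerate_inputs():
    with pytest.raises(ValueError):
        sdt.variance_ratio_f_test([1.0, 1.0], [2.0, 2.0])
    with pytest.raises(ValueError):
        sdt.variance_ratio_f_test([1.0], [1.0, 2.0])
    res = sdt.variance_ratio_f_test([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
    assert np.isinf(res.f_value) and res.significant
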