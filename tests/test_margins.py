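"""Margin recipes: formula values, monotonicity, limits, cohort behaviour."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from synchromargin import error_model as em, margins as mg, synthetic_data as sd


def _inputs(sigma_sys, sigma_c=0.0, sigma_p=0.0, rho=6.4, beta=0.84):
    keys = ("segmentation", "deformation", "correlation", "prediction", "targeting")
    return mg.MarginInputs(
        sigma_sys=dict(zip(keys, sigma_sys)),
        sigma_rand={"correlation": sigma_c, "prediction": sigma_p},
        penumbra_sd_mm=rho,
        beta=beta,
    )


@pytest.mark.parametrize(
    "sys_tot, rand_tot, expected",
    [(1.0, 1.0, 3.2), (0.0, 0.0, 0.0), (0.54, 0.9, 1.98)],
)
def test_van_herk_classic(sys_tot, rand_tot, expected):
    assert mg.van_herk_classic(sys_tot, rand_tot) == pytest.approx(expected, abs=1e-9)


def test_van_herk_extended_zero_limit():
    """With all SDs zero the penumbra terms cancel exactly."""
    assert mg.van_herk_extended(_inputs((0, 0, 0, 0, 0))) == 0.0


def test_van_herk_extended_frozen_arithmetic():
    """Matches the hand-computed value 2.5*sqrt(3.1941) + 0.84*(sqrt(42.21)-6.4)."""
    val = mg.van_herk_extended(_inputs((0.54, 1.25, 1.0, 0.5, 0.3), sigma_c=1.0, sigma_p=0.5))
    assert val == pytest.approx(4.549429, abs=1e-4)


def test_van_herk_extended_strictly_monotone():
    base = _inputs((0.5, 0.75, 0.4, 0.3, 0.3), sigma_c=0.8, sigma_p=0.5)
    m0 = mg.van_herk_extended(base)
    for source in ("segmentation", "deformation", "correlation", "prediction", "targeting"):
        sys2 = dict(base.sigma_sys)
        sys2[source] += 0.1
        assert mg.van_herk_extended(
            mg.MarginInputs(sigma_sys=sys2, sigma_rand=base.sigma_rand)
        ) > m0
    for source in ("correlation", "prediction"):
        rand2 = dict(base.sigma_rand)
        rand2[source] += 0.1
        assert mg.van_herk_extended(
            mg.MarginInputs(sigma_sys=base.sigma_sys, sigma_rand=rand2)
        ) > m0


def test_van_herk_extended_dominates_systematic_term():
    rng = np.random.default_rng(2)
    for _ in range(50):
        sys = rng.uniform(0, 2, size=5)
        inputs = _inputs(sys, *rng.uniform(0, 2, size=2))
        assert mg.van_herk_extended(inputs) >= 2.5 * np.sqrt(np.sum(sys**2)) - 1e-12


def test_wide_penumbra_absorbs_random_term():
    """As the penumbra SD grows the random (blurring) term vanishes."""
    sys = (0.5, 0.75, 0.4, 0.3, 0.3)
    wide = mg.van_herk_extended(_inputs(sys, sigma_c=2.0, sigma_p=1.5, rho=1e6))
    assert wide == pytest.approx(2.5 * np.sqrt(np.sum(np.array(sys) ** 2)), abs=1e-5)


def test_permutation_invariance_within_quadrature_groups():
    a = mg.van_herk_extended(_inputs((0.2, 0.4, 0.6, 0.8, 1.0), sigma_c=0.3, sigma_p=0.9))
    b = mg.van_herk_extended(_inputs((1.0, 0.8, 0.6, 0.4, 0.2), sigma_c=0.9, sigma_p=0.3))
    assert a == pytest.approx(b, abs=1e-12)


def test_combined_standard_uncertainty_values():
    assert mg.combined_standard_uncertainty([3, 4, 0, 0, 0]) == pytest.approx(5.0)
    assert mg.combined_standard_uncertainty([0, 0, 0, 0, 0]) == 0.0
    with pytest.raises(ValueError):
        mg.combined_standard_uncertainty([1, 2, 3])
    # published apex-left SI column; independent arithmetic: sqrt(sum U^2) = 3.8063
    u = [1.46, 2.5, 1.99, 1.24, 0.78]
    assert mg.expanded_combined_uncertainty(u) == pytest.approx(3.8063, abs=1e-4)
    assert mg.expanded_combined_uncertainty(u) == pytest.approx(
        2 * mg.combined_standard_uncertainty([x / 2 for x in u])
    )


def test_formalisms_agree_within_1mm_over_published_grid():
    """Across budgets spanning the published tracking-error ranges (equal
    inter/intra-fraction variance split) the two margin formalisms differ by
    less than 1 mm, mirroring their observed statistical equivalence."""
    worst = 0.0
    for mu_c, st_c, mu_p, st_p, cls in itertools.product(
        [0.0, 0.1, 0.2, 0.32, 0.4],
        [0.24, 0.6, 1.0, 1.5, 2.05],
        [0.08, 0.3, 0.6, 0.83],
        [0.11, 0.5, 0.9, 1.14],
        [1.5, 2.5],
    ):
        tau_c, sig_c = st_c / np.sqrt(2), st_c / np.sqrt(2)
        tau_p, sig_p = st_p / np.sqrt(2), st_p / np.sqrt(2)
        vh = mg.van_herk_extended(
            _inputs(
                (0.54, cls / 2, np.hypot(mu_c, tau_c), np.hypot(mu_p, tau_p), 0.3),
                sigma_c=sig_c,
                sigma_p=sig_p,
            )
        )
        un = mg.expanded_combined_uncertainty(
            [
                em.expanded_uncertainty(0.38, 0.54),
                cls,
                em.expanded_uncertainty(mu_c, st_c),
                em.expanded_uncertainty(mu_p, st_p),
                em.expanded_uncertainty(0.5, 0.3),
            ]
        )
        worst = max(worst, abs(vh - un))
    assert worst < 1.0


def _zero_tracking_cohort(seed=13):
    cfg = sd.CohortConfig(
        sites=(("Liver", 1, 4),), samples_per_fraction=40, seed=seed, dense_duration_s=30.0
    )
    return sd.simulate_cohort(cfg, inject_by_site={"Liver": sd.ErrorInjection()})


def test_cohort_margins_zero_tracking_constant_margins():
    """With no tracking error every per-fraction margin is the constant-only
    value and the SD over fractions is zero."""
    cohort = _zero_tracking_cohort()
    for method in ("van_herk", "uncertainty"):
        res = mg.cohort_margins(
            cohort.bundles, "Liver", "SI", deformation_uncertainty_mm=1.5, method=method
        )
        assert res.sd_mm == pytest.approx(0.0, abs=1e-12)
        assert np.all(res.per_fraction_mm == res.per_fraction_mm[0])
    vh = mg.cohort_margins(cohort.bundles, "Liver", "SI", 1.5, method="van_herk")
    expected = mg.van_herk_extended(_inputs((0.54, 0.75, 0.0, 0.0, 0.3)))
    assert vh.mean_mm == pytest.approx(expected, abs=1e-12)


def test_cohort_margins_deterministic_under_seed():
    a = _zero_tracking_cohort(seed=21)
    b = _zero_tracking_cohort(seed=21)
    ra = mg.cohort_margins(a.bundles, "Liver", "AP", 1.5, method="uncertainty")
    rb = mg.cohort_margins(b.bundles, "Liver", "AP", 1.5, method="uncertainty")
    np.testing.assert_array_equal(ra.per_fraction_mm, rb.per_fraction_mm)
    assert ra.mean_mm == rb.mean_mm and ra.sd_mm == rb.sd_mm


def test_cohort_margins_pooled_mode_uses_budget(small_cohort):
    bundles = small_cohort.by_site("Pancreas")
    res = mg.cohort_margins(
        bundles, "Pancreas", "SI", 1.5, method="van_herk", mode="pooled"
    )
    budget = em.build_budget(bundles, "Pancreas", 1.5)["SI"]
    assert res.mean_mm == pytest.approx(mg.van_herk_margin_from_budget(budget))
    assert res.per_fraction_mm.size == 0


def test_invalid_margin_inputs_rejected():
    with pytest.raises(ValueError):
        mg.MarginInputs(sigma_sys={"segmentation": -0.1}, sigma_rand={})
    with pytest.raises(ValueError):
        mg.MarginInputs(sigma_sys={}, sigma_rand={}, beta=3.0)
    with pytest.raises(ValueError):
        mg.van_herk_classic(-1.0, 0.0)
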