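"""Shared fixtures: tiny simulated bundles and hand-built budgets."""

from __future__ import annotations

import numpy as np
import pytest

from synchromargin import error_model, synthetic_data as sd
from synchromargin.log_io import (
    ERsiStream,
    FractionLogBundle,
    MarkerStream,
    ModelPointStream,
    ModelerStream,
    PredictorStream,
)


def make_bundle_with_errors(
    corr: np.ndarray | None = None,
    pred: np.ndarray | None = None,
    robot: np.ndarray | None = None,
    site: str = "Lung LUL",
    patient_id: str = "P0",
    fraction_index: int = 1,
) -> FractionLogBundle:
    """A minimal valid bundle whose residual streams are given verbatim.

    Each argument is (n,) — broadcast to all three axes — or (n, 3).
    """

    def as_3col(x, default_n=3):
        if x is None:
            x = np.zeros(default_n)
        x = np.asarray(x, dtype=float)
        return np.tile(x[:, None], (1, 3)) if x.ndim == 1 else x

    corr = as_3col(corr)
    pred = as_3col(pred)
    robot = as_3col(robot)
    n_c, n_p, n_r = len(corr), len(pred), len(robot)
    t_c, t_p, t_r = np.arange(1.0, n_c + 1), np.arange(1.0, n_p + 1), np.arange(1.0, n_r + 1)
    return FractionLogBundle(
        patient_id=patient_id,
        tumor_site=site,
        fraction_index=fraction_index,
        modelpoints=ModelPointStream(
            t=t_c,
            fiducial=np.zeros((n_c, 3)),
            leds=np.zeros((n_c, 3, 3)),
            correlation_error=corr,
        ),
        predictor=PredictorStream(t=t_p, predicted=np.zeros((n_p, 3)), prediction_error=pred),
        ersidata=ERsiStream(
            t=t_r,
            robot_position=np.zeros((n_r, 3)),
            commanded_offset=np.zeros((n_r, 3)),
            robotic_error=robot,
        ),
        markers=MarkerStream(t=np.arange(2.0), leds=np.zeros((2, 3, 3))),
        modeler=ModelerStream(t=np.arange(2.0), estimate=np.zeros((2, 3))),
    )


@pytest.fixture()
def simulated_bundle() -> FractionLogBundle:
    """One generator fraction with moderate noise and injections."""
    breathing = sd.BreathingModel(amplitude_cm=(1.5, 0.05, 0.3), period_mean_s=3.8, period_sd_s=0.5)
    inject = sd.ErrorInjection(
        correlation=sd.SourceInjection(mean=(0.1, 0.0, -0.05), sd=(0.8, 0.5, 0.7)),
        prediction=sd.SourceInjection(mean=(0.3, 0.2, 0.2), sd=(0.5, 0.4, 0.4)),
        robotic=sd.SourceInjection(mean=(-0.5, 0.2, 0.3), sd=(1.0, 1.2, 1.1)),
    )
    cfg = sd.CohortConfig(sites=(("Lung LUL", 1, 1),), seed=42, dense_duration_s=120.0)
    bundle, _ = sd.simulate_fraction(breathing, inject, cfg, 0)
    return bundle


@pytest.fixture()
def small_cohort() -> sd.CohortSim:
    """A 6-fraction single-site cohort with known injections."""
    inject = {
        "Pancreas": sd.ErrorInjection(
            correlation=sd.SourceInjection(mean=(0.07, 0.0, 0.01), sd=(0.7, 0.65, 0.7), shift_sd=(0.65, 0.6, 0.65)),
            prediction=sd.SourceInjection(mean=(0.32, 0.51, 0.49), sd=(0.3, 0.4, 0.37), shift_sd=(0.3, 0.4, 0.37)),
            robotic=sd.SourceInjection(mean=(-0.18, -0.54, -0.06), sd=(1.1, 1.9, 1.8)),
        )
    }
    cfg = sd.CohortConfig(
        sites=(("Pancreas", 2, 6),), samples_per_fraction=48, seed=7, dense_duration_s=120.0
    )
    return sd.simulate_cohort(cfg, inject_by_site=inject)


def published_budget(site: str, axis: str, **kwargs) -> error_model.ErrorBudget:
    """Analytic budget at published-cohort scale (equal variance split)."""
    return error_model.analytic_budget(site, axis, **kwargs)
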