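"""Synthetic tracking-log cohorts with known injected error parameters.

The downstream pipeline consumes only what the logs record: a quasi-periodic
fiducial-centroid trace sampled sparsely by radiographs, and per-record
residual streams for the correlation model, the latency predictor and the
robot.  The generator therefore emulates exactly those observables:

* breathing motion per axis is an asymmetric quartic-cosine waveform
  (long dwell at exhale, brief excursion to inhale) with Gaussian per-cycle
  period jitter and optional linear baseline drift;
* sparse radiographic localizations (default 62 per fraction at a mean
  interval of 66 s, the clinical cadence) with configurable observation
  noise;
* correlation / prediction / robotic residuals drawn per record from
  per-axis normal distributions.  Each fraction additionally draws a
  per-axis mean shift from a zero-mean normal whose SD is configurable per
  source — this inter-fraction shift is what a systematic-error estimator
  should recover.

Residuals are injected as additive streams rather than derived from a
mechanistic surrogate model: the analysis only ever reads the logged
residuals, so distributional control is what makes the pipeline testable.

Randomness uses one root seed; every fraction derives a child generator from
``(root_seed, fraction_counter)`` so any single fraction is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .log_io import (
    ERsiStream,
    FractionLogBundle,
    MarkerStream,
    ModelPointStream,
    ModelerStream,
    PredictorStream,
    TUMOR_SITES,
    write_bundle,
)
from .log_io import _pat_to_rob_rows

__all__ = [
    "BreathingModel",
    "SourceInjection",
    "ErrorInjection",
    "CohortConfig",
    "GroundTruth",
    "CohortSim",
    "breathing_waveform",
    "simulate_fraction",
    "simulate_cohort",
    "default_breathing",
    "default_injection",
    "default_cohort_config",
]


@dataclass(frozen=True)
class BreathingModel:
    """Quasi-periodic 3-axis breathing motion of the fiducial centroid.

    Parameters
    ----------
    amplitude_cm
        Half peak-to-peak motion per axis (SI, LR, AP), cm.
    period_mean_s, period_sd_s
        Mean and SD of the per-cycle breathing period, s.
    baseline_drift_rate_cm_min
        Linear baseline drift applied along the SI axis, cm/min.
    observation_noise_sd_mm
        Isotropic radiographic localization noise added to observed
        fiducial positions, mm.
    """

    amplitude_cm: tuple[float, float, float] = (1.0, 0.0, 0.25)
    period_mean_s: float = 3.8
    period_sd_s: float = 0.7
    baseline_drift_rate_cm_min: float = 0.0
    observation_noise_sd_mm: float = 0.5

    def __post_init__(self):
        if any(a < 0 for a in self.amplitude_cm):
            raise ValueError("amplitude components must be >= 0")
        if self.period_mean_s <= 0:
            raise ValueError("period_mean_s must be positive")
        if self.period_sd_s < 0 or self.observation_noise_sd_mm < 0:
            raise ValueError("spreads must be >= 0")


@dataclass(frozen=True)
class SourceInjection:
    """Residual distribution for one error source.

    Per-record residuals on axis ``a`` are drawn from
    ``Normal(mean[a] + shift[a], sd[a])`` where ``shift`` is redrawn once per
    fraction from ``Normal(0, shift_sd[a])`` — the inter-fraction systematic
    component.
    """

    mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shift_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(s < 0 for s in self.sd) or any(s < 0 for s in self.shift_sd):
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class ErrorInjection:
    """Injected residual distributions for the three logged error streams."""

    correlation: SourceInjection = SourceInjection()
    prediction: SourceInjection = SourceInjection()
    robotic: SourceInjection = SourceInjection()


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout and sampling cadence.

    ``sites`` lists ``(tumor_site, n_patients, n_fractions)``.  Sparse
    radiographic localizations default to 62 per fraction at a mean interval
    of 66 s (the clinical cadence); dense streams (markers, modeler,
    predictor, robot) run at ``dense_rate_hz`` for ``dense_duration_s``.
    """

    sites: tuple[tuple[str, int, int], ...]
    samples_per_fraction: int = 62
    sampling_interval_mean_s: float = 66.0
    dense_rate_hz: float = 5.0
    dense_duration_s: float = 240.0
    seed: int = 0

    def __post_init__(self):
        for site, n_pat, n_frac in self.sites:
            if site not in TUMOR_SITES:
                raise ValueError(f"unknown tumor site {site!r}")
            if n_pat <= 0 or n_frac <= 0:
                raise ValueError("patient and fraction counts must be positive")
        if not (1 <= self.samples_per_fraction):
            raise ValueError("samples_per_fraction must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Everything injected into one simulated fraction."""

    breathing: BreathingModel
    injection: ErrorInjection
    fraction_shift: dict  # source -> (3,) drawn per-axis mean shift, mm
    seed_counter: int


@dataclass
class CohortSim:
    """A simulated cohort: bundles, ground truths and a manifest table."""

    bundles: list[FractionLogBundle]
    ground_truths: list[GroundTruth]
    manifest: pd.DataFrame
    config: CohortConfig

    def by_site(self, site: str) -> list[FractionLogBundle]:
        return [b for b in self.bundles if b.tumor_site == site]

    def write(self, directory) -> Path:
        """Write every bundle plus manifest and ground-truth JSON files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        records = []
        for bundle, truth in zip(self.bundles, self.ground_truths):
            sub = directory / f"{bundle.patient_id}_fx{bundle.fraction_index:02d}"
            write_bundle(bundle, sub)
            records.append(
                {
                    "bundle_dir": sub.name,
                    "tumor_site": bundle.tumor_site,
                    "patient_id": bundle.patient_id,
                    "fraction_index": bundle.fraction_index,
                    "fraction_shift": {
                        k: list(np.round(v, 9)) for k, v in truth.fraction_shift.items()
                    },
                }
            )
        self.manifest.to_csv(directory / "manifest.csv", index=False)
        import json

        with open(directory / "ground_truth.json", "w") as fh:
            json.dump(records, fh, indent=1)
        return directory


def _cycle_boundaries(rng: np.random.Generator, duration_s: float, model: BreathingModel) -> np.ndarray:
    """Cumulative inhale-peak times covering [0, duration]."""
    n_guess = int(duration_s / model.period_mean_s * 1.5) + 8
    periods = rng.normal(model.period_mean_s, model.period_sd_s, size=n_guess)
    periods = np.clip(periods, 0.3 * model.period_mean_s, None)
    bounds = np.concatenate([[0.0], np.cumsum(periods)])
    while bounds[-1] < duration_s:
        extra = np.clip(
            rng.normal(model.period_mean_s, model.period_sd_s, size=8),
            0.3 * model.period_mean_s,
            None,
        )
        bounds = np.concatenate([bounds, bounds[-1] + np.cumsum(extra)])
    return bounds


def breathing_waveform(t: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Dimensionless waveform in [-1, 1] with inhale peaks at *bounds*.

    ``w(c) = 2 cos^4(pi c) - 1`` in cycle-fraction coordinates ``c``: value
    +1 at each cycle boundary (inhale) and a quartically flat dwell at -1
    mid-cycle (exhale), reproducing the asymmetric shape of free breathing.
    """
    c = np.interp(t, bounds, np.arange(bounds.size, dtype=float))
    return 2.0 * np.cos(np.pi * c) ** 4 - 1.0


def _positions_mm(
    t: np.ndarray, bounds: np.ndarray, model: BreathingModel
) -> np.ndarray:
    """True fiducial-centroid trajectory (n, 3) in mm, patient frame."""
    w = breathing_waveform(t, bounds)
    amp_mm = 10.0 * np.asarray(model.amplitude_cm)
    pos = np.outer(w, amp_mm)
    pos[:, 0] += 10.0 * model.baseline_drift_rate_cm_min * (t / 60.0)
    return pos


_LED_OFFSETS_MM = np.array(
    [[120.0, -40.0, 80.0], [140.0, 0.0, 85.0], [120.0, 40.0, 80.0]]
)
_LED_GAINS_MM = np.array([[1.0, 0.0, 3.0], [1.2, 0.0, 4.0], [0.8, 0.0, 3.5]])


def _led_positions(t: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Chest-surrogate LED positions (n, 3 LEDs, 3 axes) in mm."""
    w = breathing_waveform(t, bounds)
    return _LED_OFFSETS_MM[None, :, :] + w[:, None, None] * _LED_GAINS_MM[None, :, :]


def _draw_residuals(
    rng: np.random.Generator, inj: SourceInjection, shift: np.ndarray, n: int
) -> np.ndarray:
    out = np.empty((n, 3))
    mean = np.asarray(inj.mean) + shift
    sd = np.asarray(inj.sd)
    for a in range(3):
        out[:, a] = rng.normal(mean[a], sd[a], size=n) if sd[a] > 0 else mean[a]
    return out


def simulate_fraction(
    breathing: BreathingModel,
    inject: ErrorInjection,
    config: CohortConfig,
    seed_counter: int,
    patient_id: str = "P000",
    tumor_site: str = "Lung LUL",
    fraction_index: int = 1,
) -> tuple[FractionLogBundle, GroundTruth]:
    """Simulate one treatment fraction's five log streams.

    The child generator is derived from ``(config.seed, seed_counter)`` so a
    fraction is reproducible independently of the rest of its cohort.
    """
    rng = np.random.default_rng([int(config.seed), int(seed_counter)])

    # Sparse radiographic sampling times (strictly increasing).
    intervals = config.sampling_interval_mean_s * rng.uniform(
        0.5, 1.5, size=config.samples_per_fraction
    )
    t_sparse = np.cumsum(intervals)
    duration = max(float(t_sparse[-1]), config.dense_duration_s) + 10.0
    bounds = _cycle_boundaries(rng, duration, breathing)

    shifts = {
        source: np.asarray(getattr(inject, source).shift_sd) * rng.standard_normal(3)
        for source in ("correlation", "prediction", "robotic")
    }

    # ModelPoints: imaged fiducial centroid + correlation residuals.
    fid_true = _positions_mm(t_sparse, bounds, breathing)
    noise = (
        rng.normal(0.0, breathing.observation_noise_sd_mm, size=fid_true.shape)
        if breathing.observation_noise_sd_mm > 0
        else 0.0
    )
    modelpoints = ModelPointStream(
        t=t_sparse,
        fiducial=fid_true + noise,
        leds=_led_positions(t_sparse, bounds),
        correlation_error=_draw_residuals(
            rng, inject.correlation, shifts["correlation"], len(t_sparse)
        ),
    )

    # Dense streams.
    t_dense = np.arange(0.5, config.dense_duration_s, 1.0 / config.dense_rate_hz)
    pos_dense = _positions_mm(t_dense, bounds, breathing)
    markers = MarkerStream(t=t_dense, leds=_led_positions(t_dense, bounds))
    modeler = ModelerStream(
        t=t_dense, estimate=pos_dense + rng.normal(0.0, 0.1, size=pos_dense.shape)
    )
    pred_err = _draw_residuals(rng, inject.prediction, shifts["prediction"], len(t_dense))
    predictor = PredictorStream(
        t=t_dense, predicted=pos_dense + pred_err, prediction_error=pred_err
    )
    rob_err = _draw_residuals(rng, inject.robotic, shifts["robotic"], len(t_dense))
    robot_pos = _pat_to_rob_rows(pos_dense)
    ersidata = ERsiStream(
        t=t_dense,
        robot_position=robot_pos,
        commanded_offset=rng.normal(0.0, 0.1, size=(len(t_dense), 3)),
        robotic_error=rob_err,
    )

    bundle = FractionLogBundle(
        patient_id=patient_id,
        tumor_site=tumor_site,
        fraction_index=fraction_index,
        modelpoints=modelpoints,
        predictor=predictor,
        ersidata=ersidata,
        markers=markers,
        modeler=modeler,
    )
    truth = GroundTruth(
        breathing=breathing,
        injection=inject,
        fraction_shift=shifts,
        seed_counter=seed_counter,
    )
    return bundle, truth


def default_breathing(site: str) -> BreathingModel:
    """Site breathing model parameterized from the published cohort summary."""
    motion = reference.SITE_MOTION[site]
    return BreathingModel(
        amplitude_cm=tuple(s / 2.0 for s in motion.span_mean_cm),
        period_mean_s=motion.period_mean_s,
        period_sd_s=motion.period_sd_s,
    )


def default_injection(site: str, variance_split: float = 0.5) -> ErrorInjection:
    """Site residual injections from the published pooled (mean, SD) table.

    The published table pools inter- and intra-fraction variability into one
    SD per axis; ``variance_split`` is the fraction of that pooled variance
    assigned to the inter-fraction mean shift (default: equal split).
    """
    if not 0.0 <= variance_split < 1.0:
        raise ValueError("variance_split must be in [0, 1)")
    stats = reference.SITE_TRACKING[site]

    def split(src: reference.SourceStats) -> SourceInjection:
        total = np.asarray(src.sd)
        return SourceInjection(
            mean=tuple(src.mean),
            sd=tuple(total * np.sqrt(1.0 - variance_split)),
            shift_sd=tuple(total * np.sqrt(variance_split)),
        )

    return ErrorInjection(
        correlation=split(stats["correlation"]),
        prediction=split(stats["prediction"]),
        robotic=split(stats["robotic"]),
    )


def default_cohort_config(seed: int = 0, sites: Sequence[str] | None = None) -> CohortConfig:
    """Cohort layout mirroring the published case mix (45 patients, 159 fx)."""
    names = tuple(sites) if sites is not None else tuple(reference.SITE_COHORT)
    return CohortConfig(
        sites=tuple((s, *reference.SITE_COHORT[s]) for s in names),
        seed=seed,
    )


def simulate_cohort(
    config: CohortConfig,
    breathing_by_site: Mapping[str, BreathingModel] | None = None,
    inject_by_site: Mapping[str, ErrorInjection] | None = None,
) -> CohortSim:
    """Simulate every configured fraction; deterministic under a fixed seed.

    Fractions are assigned to patients round-robin within each site.  When a
    site's models are not supplied they default to the published-cohort
    parameterization (:func:`default_breathing`, :func:`default_injection`).
    """
    bundles: list[FractionLogBundle] = []
    truths: list[GroundTruth] = []
    rows = []
    counter = 0
    for site, n_patients, n_fractions in config.sites:
        breathing = (
            breathing_by_site[site]
            if breathing_by_site is not None and site in breathing_by_site
            else default_breathing(site)
        )
        inject = (
            inject_by_site[site]
            if inject_by_site is not None and site in inject_by_site
            else default_injection(site)
        )
        site_tag = site.replace(" ", "-")
        for k in range(n_fractions):
            patient = k % n_patients
            patient_id = f"{site_tag}_pt{patient:02d}"
            fraction_index = k // n_patients + 1
            bundle, truth = simulate_fraction(
                breathing,
                inject,
                config,
                seed_counter=counter,
                patient_id=patient_id,
                tumor_site=site,
                fraction_index=fraction_index,
            )
            bundles.append(bundle)
            truths.append(truth)
            rows.append(
                {
                    "tumor_site": site,
                    "patient_id": patient_id,
                    "fraction_index": fraction_index,
                    "seed_counter": counter,
                    "n_modelpoints": len(bundle.modelpoints),
                }
            )
            counter += 1
    manifest = pd.DataFrame(rows)
    return CohortSim(bundles=bundles, ground_truths=truths, manifest=manifest, config=config)
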