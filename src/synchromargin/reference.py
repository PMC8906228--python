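"""Published per-site summary statistics of a clinical tracking-log cohort.

These tables summarize a published clinical cohort of 45 patients / 159
treatment fractions treated with a robotic radiosurgery respiratory tracking
system.  They serve two roles here:

1. defaults for the synthetic cohort generator, so simulated fractions match
   the clinical conditions (fraction counts, motion amplitudes, breathing
   periods, tracking-residual scales);
2. inputs for desk-scale arithmetic checks (motion-span norm, step-one
   expanded uncertainties) and for the deformation-class discrepancy report.

Units follow the originals: motion spans and the span norm (CoM metric) in
cm, breathing periods in s, error statistics in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SEGMENTATION_MEAN_MM",
    "SEGMENTATION_SD_MM",
    "TARGETING_MEAN_MM",
    "TARGETING_SD_MM",
    "PENUMBRA_SD_MM",
    "BETA",
    "DEFORMATION_THRESHOLD_CM",
    "DEFORMATION_CLASS_SMALL_MM",
    "DEFORMATION_CLASS_LARGE_MM",
    "SiteMotion",
    "SourceStats",
    "SITE_COHORT",
    "SITE_MOTION",
    "SITE_TRACKING",
    "TABLE5_DEFORMATION_CLASS",
]

# Segmentation error assumed isotropic from phantom tracking studies (mm).
SEGMENTATION_MEAN_MM = 0.38
SEGMENTATION_SD_MM = 0.54

# Targeting (end-to-end delivery) error from phantom E2E tests (mm), isotropic.
TARGETING_MEAN_MM = 0.5
TARGETING_SD_MM = 0.3

# Beam-penumbra SD and dose-level coefficient for the extended margin recipe,
# chosen for lung SBRT at an 80% prescription isodose.
PENUMBRA_SD_MM = 6.4
BETA = 0.84

# Motion-span-norm threshold splitting the deformation-uncertainty classes.
DEFORMATION_THRESHOLD_CM = 2.0
DEFORMATION_CLASS_SMALL_MM = 1.5
DEFORMATION_CLASS_LARGE_MM = 2.5


#: site -> (number of patients, number of treatment fractions)
SITE_COHORT: dict[str, tuple[int, int]] = {
    "Lung apex left": (1, 3),
    "Lung hilum": (1, 4),
    "Lung hilum left": (1, 3),
    "Lung hilum right": (2, 8),
    "Lung LLL": (2, 10),
    "Lung LUL": (11, 33),
    "Lung RLL": (5, 15),
    "Lung RML": (4, 13),
    "Lung RUL": (4, 15),
    "Liver": (2, 6),
    "Pancreas": (9, 28),
    "Retroperitoneum": (3, 10),
    "Chest wall": (2, 6),
    "Internal mammary nodes": (1, 5),
}


@dataclass(frozen=True)
class SiteMotion:
    """Per-site breathing/motion summary.

    ``span_mean``/``span_sd`` are the per-axis motion spans (SI, LR, AP) in
    cm estimated from cluster centers of the fiducial trace; ``com`` the
    printed Euclidean norm of the mean spans; ``stated_class_mm`` the
    deformation-uncertainty class the original analysis assigned (mm).
    """

    period_mean_s: float
    period_sd_s: float
    span_mean_cm: tuple[float, float, float]
    span_sd_cm: tuple[float, float, float]
    com_cm: float
    stated_class_mm: float


SITE_MOTION: dict[str, SiteMotion] = {
    "Lung apex left": SiteMotion(3.81, 0.67, (0.09, 0.0, 0.03), (0.02, 0.01, 0.01), 0.094, 1.5),
    "Lung hilum": SiteMotion(4.49, 0.89, (0.72, 0.09, 0.39), (0.10, 0.08, 0.09), 0.823, 1.5),
    "Lung hilum left": SiteMotion(3.41, 0.72, (2.23, 0.02, 0.42), (0.21, 0.05, 0.11), 2.269, 2.5),
    "Lung hilum right": SiteMotion(3.71, 0.67, (3.95, 0.04, 0.74), (0.33, 0.15, 0.24), 4.018, 2.5),
    "Lung LLL": SiteMotion(3.14, 0.60, (4.02, 0.0, 0.87), (0.30, 0.10, 0.18), 4.11, 2.5),
    "Lung LUL": SiteMotion(3.73, 0.69, (2.90, 0.0, 0.36), (0.21, 0.06, 0.12), 2.92, 2.5),
    "Lung RLL": SiteMotion(3.56, 0.74, (4.62, 0.0, 0.38), (0.73, 0.04, 0.16), 4.63, 2.5),
    "Lung RML": SiteMotion(4.04, 0.96, (4.62, 0.07, 0.73), (0.38, 0.18, 0.26), 4.677, 2.5),
    "Lung RUL": SiteMotion(4.19, 0.80, (4.09, 0.0, 0.54), (0.46, 0.06, 0.17), 4.125, 2.5),
    "Liver": SiteMotion(3.96, 0.71, (0.52, 0.0, 0.15), (0.09, 0.01, 0.04), 0.541, 1.5),
    "Pancreas": SiteMotion(3.12, 0.61, (0.60, 0.0, 0.13), (0.13, 0.04, 0.06), 0.613, 1.5),
    "Retroperitoneum": SiteMotion(3.74, 0.80, (0.65, 0.01, 0.15), (0.07, 0.02, 0.05), 0.667, 1.5),
    "Chest wall": SiteMotion(3.81, 0.67, (0.09, 0.0, 0.03), (0.02, 0.01, 0.01), 0.094, 2.5),
    "Internal mammary nodes": SiteMotion(5.25, 1.12, (1.69, 0.0, 0.87), (0.31, 0.12, 0.21), 1.9, 1.5),
}


@dataclass(frozen=True)
class SourceStats:
    """Pooled per-axis (mean, SD) in mm for one error source at one site."""

    mean: tuple[float, float, float]  # (SI, LR, AP)
    sd: tuple[float, float, float]


#: site -> {"correlation" | "prediction" | "robotic": SourceStats}
SITE_TRACKING: dict[str, dict[str, SourceStats]] = {
    "Lung apex left": {
        "correlation": SourceStats((-0.02, -0.08, 0.12), (0.98, 0.34, 1.00)),
        "prediction": SourceStats((0.18, 0.14, 0.14), (0.53, 0.35, 0.40)),
        "robotic": SourceStats((-1.90, -0.82, -1.13), (0.62, 0.66, 0.62)),
    },
    "Lung hilum": {
        "correlation": SourceStats((-0.20, -0.17, -0.32), (1.38, 2.05, 1.49)),
        "prediction": SourceStats((0.32, 0.58, 0.58), (0.60, 0.88, 0.78)),
        "robotic": SourceStats((0.25, -0.13, 0.11), (1.25, 2.31, 2.54)),
    },
    "Lung hilum left": {
        "correlation": SourceStats((-0.10, 0.09, 0.10), (0.58, 0.60, 0.84)),
        "prediction": SourceStats((0.26, 0.27, 0.24), (0.21, 0.27, 0.24)),
        "robotic": SourceStats((0.25, -0.13, 0.11), (1.25, 2.31, 2.54)),
    },
    "Lung hilum right": {
        "correlation": SourceStats((-0.09, 0.16, 0.05), (0.44, 0.71, 0.61)),
        "prediction": SourceStats((0.16, 0.43, 0.42), (0.15, 0.45, 0.46)),
        "robotic": SourceStats((-0.27, -2.04, -1.06), (0.78, 1.56, 1.61)),
    },
    "Lung LLL": {
        "correlation": SourceStats((-0.09, 0.03, -0.07), (1.81, 1.39, 1.42)),
        "prediction": SourceStats((0.56, 0.60, 0.59), (0.76, 0.86, 0.93)),
        "robotic": SourceStats((-1.80, 0.92, 2.24), (2.33, 2.20, 2.12)),
    },
    "Lung LUL": {
        "correlation": SourceStats((-0.09, 0.00, 0.00), (1.12, 0.90, 0.90)),
        "prediction": SourceStats((0.40, 0.35, 0.41), (0.56, 0.45, 0.51)),
        "robotic": SourceStats((-0.14, -0.13, -0.51), (1.83, 1.56, 1.85)),
    },
    "Lung RLL": {
        "correlation": SourceStats((-0.12, 0.17, -0.03), (0.69, 1.23, 0.71)),
        "prediction": SourceStats((0.29, 0.83, 0.73), (0.43, 1.14, 0.79)),
        "robotic": SourceStats((-1.74, -1.96, -0.97), (1.27, 2.80, 2.55)),
    },
    "Lung RML": {
        "correlation": SourceStats((0.01, 0.02, 0.03), (0.65, 0.64, 0.62)),
        "prediction": SourceStats((0.29, 0.41, 0.33), (0.43, 0.41, 0.36)),
        "robotic": SourceStats((-0.63, -1.28, 0.95), (0.93, 1.48, 1.01)),
    },
    "Lung RUL": {
        "correlation": SourceStats((-0.01, 0.09, 0.14), (1.05, 1.23, 1.16)),
        "prediction": SourceStats((0.37, 0.49, 0.41), (0.51, 0.63, 0.62)),
        "robotic": SourceStats((-0.03, -2.49, 1.30), (1.25, 2.08, 1.87)),
    },
    "Liver": {
        "correlation": SourceStats((0.06, 0.13, -0.40), (0.49, 1.02, 1.08)),
        "prediction": SourceStats((0.56, 0.71, 0.50), (0.65, 0.71, 0.54)),
        "robotic": SourceStats((-1.00, 0.39, -1.98), (2.10, 2.71, 2.26)),
    },
    "Pancreas": {
        "correlation": SourceStats((0.07, 0.00, 0.01), (0.96, 0.93, 0.96)),
        "prediction": SourceStats((0.32, 0.51, 0.49), (0.43, 0.56, 0.52)),
        "robotic": SourceStats((-0.18, -0.54, -0.06), (1.14, 1.94, 1.88)),
    },
    "Retroperitoneum": {
        "correlation": SourceStats((0.00, 0.03, -0.02), (0.25, 0.40, 0.24)),
        "prediction": SourceStats((0.08, 0.11, 0.13), (0.11, 0.13, 0.16)),
        "robotic": SourceStats((-0.12, 0.71, 0.30), (0.34, 0.57, 0.59)),
    },
    "Chest wall": {
        "correlation": SourceStats((-0.01, -0.15, 0.07), (0.59, 0.50, 0.49)),
        "prediction": SourceStats((0.23, 0.16, 0.16), (0.33, 0.42, 0.52)),
        "robotic": SourceStats((-0.66, -0.89, 0.96), (1.18, 1.21, 1.18)),
    },
    "Internal mammary nodes": {
        "correlation": SourceStats((-0.10, 0.07, -0.16), (0.83, 0.44, 0.77)),
        "prediction": SourceStats((0.11, 0.11, 0.08), (0.15, 0.16, 0.11)),
        "robotic": SourceStats((-2.90, 3.03, -0.49), (0.94, 0.94, 0.58)),
    },
}


#: Deformation-uncertainty class (mm) as printed in the published uncertainty
#: table, which disagrees with the motion-summary table for several sites;
#: kept separately so the discrepancy report can surface both.
TABLE5_DEFORMATION_CLASS: dict[str, float] = {
    "Lung apex left": 2.5,
    "Lung hilum": 2.5,
    "Lung hilum left": 2.5,
    "Lung hilum right": 2.5,
    "Lung LLL": 2.5,
    "Lung LUL": 2.5,
    "Lung RLL": 1.5,
    "Lung RML": 1.5,
    "Lung RUL": 1.5,
    "Liver": 1.5,
    "Pancreas": 2.5,
    "Retroperitoneum": 1.5,
    "Chest wall": 1.5,
    "Internal mammary nodes": 1.5,
}
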