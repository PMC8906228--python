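"""PTV margin recipes: extended Van Herk formula and uncertainty budget.

Two formalisms, fed by the five-source error budget:

* Van Herk recipe.  Classic form ``M = 2.5 Sigma + 0.7 sigma``; extended for
  five sources and a finite beam penumbra::

      M = 2.5 sqrt(Sigma_S^2 + Sigma_D^2 + Sigma_C^2 + Sigma_P^2 + Sigma_T^2)
          + beta (sqrt(sigma_C^2 + sigma_P^2 + sigma_rho^2) - sigma_rho)

  with penumbra SD ``sigma_rho = 6.4`` mm and ``beta = 0.84`` (80%
  prescription isodose in lung SBRT).  The random (blurring) term vanishes
  both when the random errors vanish and in the wide-penumbra limit.

* Uncertainty-estimation method.  Each source contributes an expanded
  uncertainty ``U = |mu| + 2 sigma`` (coverage k = 2); standard
  uncertainties ``U/2`` add in quadrature and the margin is the expanded
  combined uncertainty ``2 sqrt(sum (U_s/2)^2) = sqrt(sum U_s^2)``.

Cohort margins are reported fraction by fraction (mean +/- SD over
fractions, each fraction contributing its own tracking statistics while the
constant sources stay fixed) or pooled into a single cohort-level margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import reference
from .error_model import (
    SOURCES,
    BudgetConstants,
    ErrorBudget,
    expanded_uncertainty,
    standard_uncertainty,
    summarize_fraction,
)
from .log_io import AXES, FractionLogBundle

__all__ = [
    "MarginInputs",
    "MarginResult",
    "van_herk_classic",
    "van_herk_extended",
    "combined_standard_uncertainty",
    "expanded_combined_uncertainty",
    "margin_inputs_from_budget",
    "uncertainty_margin_from_budget",
    "van_herk_margin_from_budget",
    "cohort_margins",
]


@dataclass(frozen=True)
class MarginInputs:
    """Per-source SDs (mm) feeding the extended Van Herk recipe.

    ``sigma_sys`` holds the five systematic SDs keyed by source;
    ``sigma_rand`` the random SDs of the tracking sources (correlation,
    prediction).
    """

    sigma_sys: Mapping[str, float]
    sigma_rand: Mapping[str, float]
    penumbra_sd_mm: float = reference.PENUMBRA_SD_MM
    beta: float = reference.BETA

    def __post_init__(self):
        if any(v < 0 for v in self.sigma_sys.values()):
            raise ValueError("systematic SDs must be >= 0")
        if any(v < 0 for v in self.sigma_rand.values()):
            raise ValueError("random SDs must be >= 0")
        if self.penumbra_sd_mm < 0:
            raise ValueError("penumbra SD must be >= 0")
        if not 0.0 < self.beta < 2.6:
            raise ValueError("beta out of range (0, 2.6)")


@dataclass(frozen=True)
class MarginResult:
    """Cohort margin for one site/axis under one formalism."""

    tumor_site: str
    axis: str
    method: str  # "van_herk" | "uncertainty"
    mode: str  # "per_fraction" | "pooled"
    per_fraction_mm: np.ndarray  # empty in pooled mode
    mean_mm: float
    sd_mm: float


def van_herk_classic(sigma_sys_total_mm: float, sigma_rand_total_mm: float) -> float:
    """Classic recipe ``2.5 Sigma + 0.7 sigma`` (mm)."""
    if sigma_sys_total_mm < 0 or sigma_rand_total_mm < 0:
        raise ValueError("inputs must be >= 0")
    return 2.5 * sigma_sys_total_mm + 0.7 * sigma_rand_total_mm


def van_herk_extended(inputs: MarginInputs) -> float:
    """Extended five-source recipe with penumbra correction (mm)."""
    sigma_sys_sq = sum(v**2 for v in inputs.sigma_sys.values())
    sigma_rand_sq = sum(v**2 for v in inputs.sigma_rand.values())
    rho = inputs.penumbra_sd_mm
    return 2.5 * math.sqrt(sigma_sys_sq) + inputs.beta * (
        math.sqrt(sigma_rand_sq + rho**2) - rho
    )


def combined_standard_uncertainty(standards_mm: Sequence[float]) -> float:
    """Quadrature of the five standard uncertainties (mm)."""
    s = np.asarray(standards_mm, dtype=float)
    if s.size != len(SOURCES):
        raise ValueError(f"expected {len(SOURCES)} standard uncertainties, got {s.size}")
    if np.any(s < 0):
        raise ValueError("standard uncertainties must be >= 0")
    return float(np.sqrt(np.sum(s**2)))


def expanded_combined_uncertainty(expanded_mm: Sequence[float]) -> float:
    """Expanded combined uncertainty: quadrature of the five expanded terms.

    Equal to twice the combined standard uncertainty, and the PTV margin of
    the uncertainty-estimation method.
    """
    u = np.asarray(expanded_mm, dtype=float)
    if u.size != len(SOURCES):
        raise ValueError(f"expected {len(SOURCES)} expanded uncertainties, got {u.size}")
    return 2.0 * combined_standard_uncertainty(u / 2.0)


def margin_inputs_from_budget(
    budget: ErrorBudget,
    penumbra_sd_mm: float = reference.PENUMBRA_SD_MM,
    beta: float = reference.BETA,
) -> MarginInputs:
    """Extract Van Herk inputs from a five-source budget."""
    budget.require_complete()
    return MarginInputs(
        sigma_sys={s: budget.sources[s].sigma_systematic_mm for s in SOURCES},
        sigma_rand={s: budget.sources[s].sigma_random_mm for s in ("correlation", "prediction")},
        penumbra_sd_mm=penumbra_sd_mm,
        beta=beta,
    )


def van_herk_margin_from_budget(
    budget: ErrorBudget,
    penumbra_sd_mm: float = reference.PENUMBRA_SD_MM,
    beta: float = reference.BETA,
) -> float:
    return van_herk_extended(margin_inputs_from_budget(budget, penumbra_sd_mm, beta))


def uncertainty_margin_from_budget(budget: ErrorBudget) -> float:
    budget.require_complete()
    return expanded_combined_uncertainty([budget.sources[s].expanded_mm for s in SOURCES])


def _per_fraction_margin(
    bundle: FractionLogBundle,
    axis: str,
    deformation_uncertainty_mm: float,
    constants: BudgetConstants,
    method: str,
    penumbra_sd_mm: float,
    beta: float,
) -> float:
    """Margin of one fraction: its own tracking statistics, fixed constants.

    For the Van Herk recipe the fraction's systematic tracking component is
    the magnitude of its mean shift and the random component its SD; for the
    uncertainty method each tracking term is |mean| + 2 SD of that fraction.
    """
    corr = summarize_fraction(bundle, "correlation", axis)
    pred = summarize_fraction(bundle, "prediction", axis)
    def_std = standard_uncertainty(deformation_uncertainty_mm)
    if method == "van_herk":
        inputs = MarginInputs(
            sigma_sys={
                "segmentation": constants.segmentation_sd_mm,
                "deformation": def_std,
                "correlation": abs(corr.mean_shift_mm),
                "prediction": abs(pred.mean_shift_mm),
                "targeting": constants.targeting_sd_mm,
            },
            sigma_rand={"correlation": corr.sd_mm, "prediction": pred.sd_mm},
            penumbra_sd_mm=penumbra_sd_mm,
            beta=beta,
        )
        return van_herk_extended(inputs)
    if method == "uncertainty":
        u_t = (
            constants.targeting_expanded_mm
            if constants.targeting_expanded_mm is not None
            else expanded_uncertainty(constants.targeting_mean_mm, constants.targeting_sd_mm)
        )
        expanded = [
            expanded_uncertainty(constants.segmentation_mean_mm, constants.segmentation_sd_mm),
            deformation_uncertainty_mm,
            expanded_uncertainty(corr.mean_shift_mm, corr.sd_mm),
            expanded_uncertainty(pred.mean_shift_mm, pred.sd_mm),
            u_t,
        ]
        return expanded_combined_uncertainty(expanded)
    raise ValueError(f"unknown method {method!r}")


def cohort_margins(
    bundles: Sequence[FractionLogBundle],
    tumor_site: str,
    axis: str,
    deformation_uncertainty_mm: float,
    method: str = "van_herk",
    mode: str = "per_fraction",
    constants: BudgetConstants = BudgetConstants(),
    budget: ErrorBudget | None = None,
    penumbra_sd_mm: float = reference.PENUMBRA_SD_MM,
    beta: float = reference.BETA,
) -> MarginResult:
    """Cohort PTV margin for one site/axis.

    ``mode="per_fraction"`` (default) computes one margin per fraction and
    reports their mean +/- SD; ``mode="pooled"`` computes a single margin
    from the cohort-level budget (supply ``budget`` to avoid recomputation).
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}")
    site_bundles = [b for b in bundles if b.tumor_site == tumor_site]
    if not site_bundles:
        raise ValueError(f"no fractions for site {tumor_site!r}")
    if mode == "per_fraction":
        values = np.array(
            [
                _per_fraction_margin(
                    b, axis, deformation_uncertainty_mm, constants, method, penumbra_sd_mm, beta
                )
                for b in site_bundles
            ]
        )
        return MarginResult(
            tumor_site=tumor_site,
            axis=axis,
            method=method,
            mode=mode,
            per_fraction_mm=values,
            mean_mm=float(values.mean()),
            sd_mm=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        )
    if mode == "pooled":
        if budget is None:
            from .error_model import build_budget

            budget = build_budget(
                site_bundles, tumor_site, deformation_uncertainty_mm, constants
            )[axis]
        value = (
            van_herk_margin_from_budget(budget, penumbra_sd_mm, beta)
            if method == "van_herk"
            else uncertainty_margin_from_budget(budget)
        )
        return MarginResult(
            tumor_site=tumor_site,
            axis=axis,
            method=method,
            mode=mode,
            per_fraction_mm=np.empty(0),
            mean_mm=value,
            sd_mm=0.0,
        )
    raise ValueError(f"unknown mode {mode!r}")
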