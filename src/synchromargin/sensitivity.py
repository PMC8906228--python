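"""Error-zeroing sensitivity analysis (systematic design test).

Each hypothesis zeroes one error source — or one of the stated pairs — in a
five-source budget, recomputes the PTV margin under both formalisms, and
reports the interaction level (original minus recalculated margin).  Both
margin formalisms are concave (square-root-of-quadrature) functions of the
per-source variances, i.e. submodular over the source set, so interaction
levels are superadditive: zeroing a pair removes at least as much margin as
the two single-source effects combined — small contributors hide behind
large ones until the large ones are removed too.

Interaction levels are binned into qualitative impact classes.  The class
thresholds are not part of the published recipe; the defaults (0.5 / 1.0 /
2.0 mm) span the margin deltas implied by clinical-scale budgets and are a
configuration knob, not a claim.

The F-test compares two per-fraction margin samples by their variance ratio
(two-sided, larger variance in the numerator); significance requires both
``F > F_critical`` and ``p < alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .error_model import ErrorBudget, SourceBudget
from .margins import uncertainty_margin_from_budget, van_herk_margin_from_budget

__all__ = [
    "HYPOTHESES",
    "DEFAULT_IMPACT_THRESHOLDS",
    "SDTResult",
    "FTestResult",
    "zero_source",
    "zero_and_recompute",
    "classify_impact",
    "variance_ratio_f_test",
]

#: The error-zeroing hypotheses: five singles and the two stated pairs.
#: "robot" denotes the targeting (delivery-accuracy) term.
HYPOTHESES = (
    "segmentation",
    "deformation",
    "correlation",
    "prediction",
    "robot",
    "segmentation+deformation",
    "correlation+prediction",
)

_HYPOTHESIS_SOURCES = {
    "segmentation": ("segmentation",),
    "deformation": ("deformation",),
    "correlation": ("correlation",),
    "prediction": ("prediction",),
    "robot": ("targeting",),
    "segmentation+deformation": ("segmentation", "deformation"),
    "correlation+prediction": ("correlation", "prediction"),
}

DEFAULT_IMPACT_THRESHOLDS = (0.5, 1.0, 2.0)  # mm: low / moderate / high / very_high
_IMPACT_CLASSES = ("low", "moderate", "high", "very_high")


@dataclass(frozen=True)
class SDTResult:
    """One hypothesis's effect on the margin of one site/axis."""

    tumor_site: str
    axis: str
    hypothesis: str
    method: str
    original_margin_mm: float
    recalculated_margin_mm: float
    interaction_level_mm: float
    impact_class: str


@dataclass(frozen=True)
class FTestResult:
    f_value: float
    f_critical: float
    p_value: float
    significant: bool
    df: tuple[int, int]


def zero_source(budget: ErrorBudget, hypothesis: str) -> ErrorBudget:
    """A copy of the budget with the hypothesis's source(s) set to zero.

    Zeroing clears the systematic and random SDs and the uncertainty terms
    of the named source(s); all other sources are untouched.
    """
    try:
        names = _HYPOTHESIS_SOURCES[hypothesis]
    except KeyError:
        raise ValueError(
            f"unknown hypothesis {hypothesis!r}; expected one of {HYPOTHESES}"
        ) from None
    sources = dict(budget.sources)
    for name in names:
        s = sources[name]
        sources[name] = SourceBudget(
            source=s.source,
            axis=s.axis,
            mu_mm=0.0,
            sigma_mm=0.0,
            sigma_systematic_mm=0.0,
            sigma_random_mm=0.0,
            expanded_mm=0.0,
            standard_mm=0.0,
        )
    return ErrorBudget(
        tumor_site=budget.tumor_site,
        axis=budget.axis,
        sources=sources,
        n_fractions=budget.n_fractions,
    )


def zero_and_recompute(
    budget: ErrorBudget,
    hypothesis: str,
    method: str = "van_herk",
    thresholds: Sequence[float] = DEFAULT_IMPACT_THRESHOLDS,
    **margin_kwargs,
) -> SDTResult:
    """Zero the hypothesis's source(s) and recompute the margin.

    The interaction level is original minus recalculated; it is nonnegative
    because both formalisms are monotone in every source.
    """
    budget.require_complete()
    compute = (
        van_herk_margin_from_budget if method == "van_herk" else uncertainty_margin_from_budget
    )
    if method not in ("van_herk", "uncertainty"):
        raise ValueError(f"unknown method {method!r}")
    original = compute(budget, **margin_kwargs)
    recalculated = compute(zero_source(budget, hypothesis), **margin_kwargs)
    delta = original - recalculated
    return SDTResult(
        tumor_site=budget.tumor_site,
        axis=budget.axis,
        hypothesis=hypothesis,
        method=method,
        original_margin_mm=original,
        recalculated_margin_mm=recalculated,
        interaction_level_mm=delta,
        impact_class=classify_impact(delta, thresholds),
    )


def classify_impact(
    delta_mm: float, thresholds: Sequence[float] = DEFAULT_IMPACT_THRESHOLDS
) -> str:
    """Bin an interaction level (mm) into low/moderate/high/very_high."""
    if delta_mm < 0:
        raise ValueError("interaction level must be >= 0")
    t = list(thresholds)
    if len(t) != 3 or sorted(t) != t:
        raise ValueError("thresholds must be three increasing values")
    for cls, bound in zip(_IMPACT_CLASSES, t):
        if delta_mm < bound:
            return cls
    return _IMPACT_CLASSES[-1]


def variance_ratio_f_test(
    sample_a: Sequence[float], sample_b: Sequence[float], alpha: float = 0.05
) -> FTestResult:
    """Two-sided variance-ratio F-test between two margin samples.

    The larger sample variance goes in the numerator; the critical value is
    the upper alpha/2 quantile of the F distribution at the corresponding
    degrees of freedom.  Significance requires both ``F > F_critical`` and
    ``p < alpha``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("both samples have zero variance; F undefined")
    if va >= vb:
        num, den, dfn, dfd = va, vb, a.size - 1, b.size - 1
    else:
        num, den, dfn, dfd = vb, va, b.size - 1, a.size - 1
    if den == 0.0:
        f_value = math.inf
        p_value = 0.0
    else:
        f_value = num / den
        p_value = min(1.0, 2.0 * stats.f.sf(f_value, dfn, dfd))
    f_critical = stats.f.ppf(1.0 - alpha / 2.0, dfn, dfd)
    return FTestResult(
        f_value=float(f_value),
        f_critical=float(f_critical),
        p_value=float(p_value),
        significant=bool(f_value > f_critical and p_value < alpha),
        df=(dfn, dfd),
    )
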