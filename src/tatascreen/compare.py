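"""Allele comparison: Fisher Z statistic and expression-change call.

Two affinity estimates (ancestral vs. minor allele) are compared with the
standardized absolute difference

    Z = |x_wt - x_mut| / sqrt(delta_wt^2 + delta_mut^2)

where x is -ln(K_D) and delta its standard deviation.  The two-sided
standard-normal tail of Z gives the p-value, binned into the conventional
significance grid {1e-6, 1e-3, 1e-2, 0.05}.  A significant call is oriented
by the sign of the K_D change: tighter binding of the minor allele (lower
K_D) predicts over-expression of the downstream gene ("up"), weaker binding
predicts under-expression ("down").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .affinity import AffinityEstimate

#: Significance bins as printed in candidate-marker reports, finest first.
ALPHA_BINS = (1e-6, 1e-3, 1e-2, 0.05)

UP, DOWN, INSIGNIFICANT = "up", "down", "insignificant"


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one wt-vs-mut affinity comparison."""

    z: float
    p_value: float
    alpha_bin: float | None  # one of ALPHA_BINS, or None when insignificant
    direction: str  # up | down | insignificant
    wt: AffinityEstimate
    mut: AffinityEstimate


def z_score(wt: AffinityEstimate, mut: AffinityEstimate) -> float:
    """Absolute standardized difference of two affinity estimates.

    Symmetric in its arguments.  When both standard deviations are zero and
    the means differ, the statistic is saturated and ``math.inf`` is
    returned; identical means give 0 regardless of the deltas.
    """
    diff = abs(wt.neg_ln_kd - mut.neg_ln_kd)
    if diff == 0.0:
        return 0.0
    denom = math.hypot(wt.delta, mut.delta)
    if denom == 0.0:
        return math.inf
    return diff / denom


def p_value(z: float) -> float:
    """Two-sided standard-normal tail probability of an absolute Z."""
    if math.isinf(z):
        return 0.0
    return float(2.0 * norm.sf(z))


def classify(z: float, wt_kd: float, mut_kd: float) -> tuple[str, float | None, float]:
    """Call the predicted expression change for one allele comparison.

    Returns ``(direction, alpha_bin, p)`` where ``alpha_bin`` is the smallest
    bin of :data:`ALPHA_BINS` that is >= p (``None`` when p > 0.05, in which
    case the direction is ``insignificant``).  A significant Z with equal K_D
    values cannot be oriented and is a contract violation.
    """
    if z < 0:
        raise ValueError("z must be non-negative")
    if wt_kd <= 0 or mut_kd <= 0:
        raise ValueError("K_D values must be positive")
    p = p_value(z)
    bin_ = next((a for a in ALPHA_BINS if p <= a), None)
    if bin_ is None:
        return INSIGNIFICANT, None, p
    if mut_kd == wt_kd:
        raise ValueError("significant comparison with equal K_D values cannot be oriented")
    return (UP if mut_kd < wt_kd else DOWN), bin_, p


def compare_estimates(wt: AffinityEstimate, mut: AffinityEstimate) -> ComparisonResult:
    """Full comparison of two affinity estimates (Z, p, bin, direction)."""
    z = z_score(wt, mut)
    direction, alpha_bin, p = classify(z, wt.kd_nM, mut.kd_nM)
    return ComparisonResult(z=z, p_value=p, alpha_bin=alpha_bin, direction=direction, wt=wt, mut=mut)
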