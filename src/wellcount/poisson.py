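"""Poisson limiting-dilution quantification.

With particles loaded at random, the number per well is Poisson with mean
``lambda = density * V_well``, so the probability that a well is occupied
(holds at least one particle) is ``p = 1 - exp(-lambda)``. Observing k
occupied wells out of n inverts this:

    p_hat      = k / n
    lambda_hat = -ln(1 - p_hat)
    density    = lambda_hat / V_well        [particles per uL]

The confidence interval is a binomial interval on p (Wilson score by
default, Clopper-Pearson exact as an option) with both endpoints mapped
through the same monotone transform; coverage on p therefore carries over
to the density. At k = n the transform diverges — every well is occupied
and the data only support a lower bound — which is raised as a
:class:`~wellcount.errors.SaturationError` carrying that one-sided bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import DomainError, SaturationError

_CI_METHODS = {"wilson": "wilson", "clopper-pearson": "beta"}


def occupancy_probability(density_per_ul: float, well_volume_ul: float) -> float:
    """Probability that a well is occupied at the given number density:
    ``1 - exp(-density * V)``."""
    if density_per_ul < 0:
        raise DomainError(f"density must be >= 0, got {density_per_ul}")
    if well_volume_ul <= 0:
        raise DomainError("well_volume_ul must be > 0")
    return -math.expm1(-density_per_ul * well_volume_ul)


@dataclass(frozen=True)
class CountEstimate:
    """Density estimate from a digital occupancy count."""

    k: int
    n: int
    p_hat: float
    lambda_hat: float
    density_per_ul: float
    ci_low_per_ul: float
    ci_high_per_ul: float
    confidence_level: float
    well_volume_ul: float

    def to_dict(self) -> dict:
        return {
            "k": self.k, "n": self.n, "p_hat": self.p_hat,
            "lambda_hat": self.lambda_hat,
            "density_per_ul": self.density_per_ul,
            "ci_low_per_ul": self.ci_low_per_ul,
            "ci_high_per_ul": self.ci_high_per_ul,
            "confidence_level": self.confidence_level,
            "well_volume_ul": self.well_volume_ul,
        }


def _p_interval(k: float, n: int, confidence_level: float, method: str):
    try:
        sm_method = _CI_METHODS[method]
    except KeyError:
        raise DomainError(
            f"unknown CI method {method!r}; choose from {sorted(_CI_METHODS)}"
        )
    return proportion_confint(k, n, alpha=1 - confidence_level, method=sm_method)


def estimate_density(
    k: float,
    n: int,
    well_volume_ul: float,
    confidence_level: float = 0.95,
    ci_method: str = "wilson",
) -> CountEstimate:
    """Estimate number density from k occupied wells out of n.

    ``k`` may be fractional (useful for analytic design curves where the
    expected occupancy n*p is evaluated directly). k = 0 returns density 0
    with the upper confidence bound from the binomial interval; k = n
    raises :class:`SaturationError` carrying the one-sided lower density
    bound at ``confidence_level``.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if not (0 <= k <= n):
        raise DomainError(f"k must lie in [0, n], got k={k}, n={n}")
    if well_volume_ul <= 0:
        raise DomainError("well_volume_ul must be > 0")
    if not (0 < confidence_level < 1):
        raise DomainError("confidence_level must be in (0, 1)")

    if k == n:
        # one-sided lower bound at confidence_level
        p_lo, _ = _p_interval(k, n, 1 - 2 * (1 - confidence_level), ci_method)
        lower = -math.log1p(-float(p_lo)) / well_volume_ul
        raise SaturationError(
            f"all {n} wells occupied: density unidentifiable, "
            f">= {lower:.4g} per uL at {confidence_level:.0%} confidence",
            density_lower_bound=lower,
        )

    p_hat = k / n
    lambda_hat = -math.log1p(-p_hat)
    density = lambda_hat / well_volume_ul
    p_lo, p_hi = _p_interval(k, n, confidence_level, ci_method)
    if k == 0:
        p_lo = 0.0  # interval endpoints can carry float noise at the boundary
    ci_low = -math.log1p(-float(np.clip(p_lo, 0.0, 1.0))) / well_volume_ul
    ci_high = -math.log1p(-float(min(p_hi, 1 - 1e-15))) / well_volume_ul
    return CountEstimate(
        k=int(k) if float(k).is_integer() else k,  # type: ignore[arg-type]
        n=int(n),
        p_hat=p_hat,
        lambda_hat=lambda_hat,
        density_per_ul=density,
        ci_low_per_ul=ci_low,
        ci_high_per_ul=ci_high,
        confidence_level=confidence_level,
        well_volume_ul=well_volume_ul,
    )


def ci_percent_of_mean(estimate: CountEstimate) -> float:
    """Confidence-interval half-width as a percentage of the estimated
    density: ``100 * (ci_high - ci_low) / (2 * density)``."""
    if estimate.density_per_ul <= 0:
        raise DomainError("CI percentage undefined at zero density")
    return (
        100.0
        * (estimate.ci_high_per_ul - estimate.ci_low_per_ul)
        / (2.0 * estimate.density_per_ul)
    )
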