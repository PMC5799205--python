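"""Design-space analysis for microwell digital counting.

Two trade-offs govern an array design:

* the number of wells n sets the precision — the confidence interval on
  the density shrinks like 1/sqrt(n) at fixed occupancy;
* the well volume V sets the measurable density range — at a usable
  occupied fraction f the density is -ln(1-f)/V, so smaller wells reach
  proportionally higher densities.

Both curves are available analytically (expected occupancy plugged into
the estimator) and by Monte Carlo (binomial occupancy draws), plus an
end-to-end recovery harness that pushes a fully synthetic device through
the whole imaging-and-counting pipeline and compares the estimate with
the ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import classification, detection, poisson, synthetic
from .errors import DomainError
from .geometry import ArrayGeometry
from .synthetic import Modality, NoiseSpec


@dataclass
class DesignCurve:
    """One simulated design curve: y(x) plus the parameters held fixed."""

    x_values: np.ndarray
    y_values: np.ndarray
    x_label: str
    y_label: str
    fixed_params: dict
    method: str  # "analytic" | "monte_carlo" | "closed_form"
    rng_seed: int | None = None
    y_stderr: np.ndarray | None = None

    def __post_init__(self):
        self.x_values = np.asarray(self.x_values, dtype=float)
        self.y_values = np.asarray(self.y_values, dtype=float)
        assert self.x_values.shape == self.y_values.shape
        if self.method == "monte_carlo" and self.rng_seed is None:
            raise DomainError("monte_carlo curves require an rng_seed")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({self.x_label: self.x_values, self.y_label: self.y_values})
        df["method"] = self.method
        for key, val in self.fixed_params.items():
            df[key] = val
        return df


def ci_vs_well_count(
    density_per_ul: float,
    geometry: ArrayGeometry,
    well_counts: Sequence[int],
    method: str = "analytic",
    reps: int = 1000,
    rng_seed: int | None = None,
    confidence_level: float = 0.95,
) -> DesignCurve:
    """CI half-width as % of the mean vs the number of wells analysed.

    analytic: the expected occupancy k = n*p is plugged straight into the
    estimator. monte_carlo: k ~ Binomial(n, p) is drawn ``reps`` times and
    the mean CI% reported (draws with k = 0 or k = n carry no finite
    interval and are dropped with a saturation warning).
    """
    if density_per_ul <= 0:
        raise DomainError("density must be > 0")
    if method not in {"analytic", "monte_carlo"}:
        raise DomainError(f"unknown method {method!r}")
    V = geometry.well_volume_ul
    p = poisson.occupancy_probability(density_per_ul, V)
    ys, errs = [], []
    rng = np.random.default_rng(rng_seed)
    for n in well_counts:
        n = int(n)
        if n < 1:
            raise DomainError("well counts must be positive")
        if p >= 1 - 1e-12 or n * (1 - p) < 1e-9:
            warnings.warn(
                f"occupancy saturates at n={n}: CI% undefined", stacklevel=2
            )
            ys.append(np.nan)
            errs.append(np.nan)
            continue
        if method == "analytic":
            est = poisson.estimate_density(n * p, n, V, confidence_level)
            ys.append(poisson.ci_percent_of_mean(est))
            errs.append(0.0)
        else:
            ks = rng.binomial(n, p, size=reps)
            valid = (ks > 0) & (ks < n)
            vals = [
                poisson.ci_percent_of_mean(
                    poisson.estimate_density(int(k), n, V, confidence_level)
                )
                for k in ks[valid]
            ]
            ys.append(float(np.mean(vals)))
            errs.append(float(np.std(vals, ddof=1) / np.sqrt(len(vals))))
    return DesignCurve(
        x_values=np.asarray(well_counts, dtype=float),
        y_values=np.asarray(ys),
        x_label="n_wells",
        y_label="ci_percent_of_mean",
        fixed_params={
            "density_per_ul": density_per_ul,
            "well_volume_ul": V,
            "confidence_level": confidence_level,
        },
        method=method,
        rng_seed=rng_seed,
        y_stderr=np.asarray(errs) if method == "monte_carlo" else None,
    )


def density_vs_volume(
    occupied_fractions: Sequence[float],
    volumes_ul: Sequence[float],
) -> list[DesignCurve]:
    """Measurable density vs well volume, one closed-form curve per
    occupied fraction: density = -ln(1 - f) / V (slope -1 in log-log)."""
    volumes = np.asarray(volumes_ul, dtype=float)
    if np.any(volumes <= 0):
        raise DomainError("well volumes must be > 0")
    curves = []
    for f in occupied_fractions:
        if not (0 < f < 1):
            raise DomainError(f"occupied fraction must be in (0, 1), got {f}")
        curves.append(
            DesignCurve(
                x_values=volumes,
                y_values=-np.log1p(-f) / volumes,
                x_label="well_volume_ul",
                y_label="density_per_ul",
                fixed_params={"occupied_fraction": f},
                method="closed_form",
            )
        )
    return curves


@dataclass
class RecoveryResult:
    """End-to-end pipeline estimate next to the generating truth."""

    estimate: poisson.CountEstimate
    true_density_per_ul: float
    true_occupied: int
    detected_circles: int = 0
    panels_used: int = 1

    @property
    def relative_error(self) -> float:
        if self.true_density_per_ul == 0:
            return 0.0 if self.estimate.density_per_ul == 0 else np.inf
        return (
            self.estimate.density_per_ul - self.true_density_per_ul
        ) / self.true_density_per_ul

    @property
    def covered(self) -> bool:
        """True density inside the estimate's confidence interval."""
        return (
            self.estimate.ci_low_per_ul
            <= self.true_density_per_ul
            <= self.estimate.ci_high_per_ul
        )


def end_to_end_recovery(
    density_per_ul: float,
    geometry: ArrayGeometry,
    noise: NoiseSpec | None = None,
    aggregation: float = 0.0,
    rng_seed: int = 0,
    modality: Modality | str = Modality.BRIGHTFIELD,
    panels: int = 1,
) -> RecoveryResult:
    """Generate ``panels`` synthetic panels at a known density and run the
    full chain: seed -> render -> denoise -> Hough -> grid fit -> well
    intensities -> auto threshold -> classify -> Poisson estimate.

    Intensities are pooled across panels into one device-level histogram
    before thresholding. Returns the estimate alongside the truth.
    """
    noise = noise or NoiseSpec()
    root = np.random.default_rng(rng_seed)
    all_int: list[np.ndarray] = []
    true_occ = 0
    n_circles = 0
    for _ in range(panels):
        seed_t, seed_r = (int(s) for s in root.integers(0, 2**31 - 1, size=2))
        truth = synthetic.seed_particles(
            geometry, density_per_ul, aggregation=aggregation, rng_seed=seed_t
        )
        true_occ += truth.n_occupied
        img = synthetic.render_panel(
            geometry, truth, modality=modality,
            noise=NoiseSpec(noise.additive_sigma, noise.illumination_gradient, seed_r),
        )
        img = detection.denoise(img)
        circles = detection.find_wells(img, geometry)
        n_circles += len(circles)
        grid = detection.fit_grid(circles, geometry)
        all_int.append(classification.well_intensities(img, grid))
    pooled = np.concatenate(all_int)
    thr = classification.auto_threshold(pooled, modality)
    occ = classification.classify(pooled, thr, modality)
    est = poisson.estimate_density(
        occ.k_occupied, occ.n_total, geometry.well_volume_ul
    )
    return RecoveryResult(
        estimate=est,
        true_density_per_ul=density_per_ul,
        true_occupied=true_occ,
        detected_circles=n_circles,
        panels_used=panels,
    )
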