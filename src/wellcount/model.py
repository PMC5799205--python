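"""Model/results front end for the counting pipeline.

:class:`MicrowellCounter` is built from panel images plus an array
geometry; ``fit()`` runs recognition, classification and Poisson
estimation and returns a :class:`MicrowellCountResults` carrying the
density estimate, its confidence interval, per-panel diagnostics and a
``summary()`` table. The underlying stages remain available as plain
functions in :mod:`wellcount.detection`, :mod:`wellcount.classification`
and :mod:`wellcount.poisson` for piecewise use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classification, detection, poisson
from .errors import WellcountError
from .geometry import ArrayGeometry
from .synthetic import Modality, PanelImage, load_image


class MicrowellCounter:
    """Digital particle/cell counter over one device's panel images.

    Parameters
    ----------
    panels : sequence of PanelImage
        One image per panel of the device.
    geometry : ArrayGeometry
        Physical description of the array (grid shape, well radius, pitch,
        pixel scale, per-well volume).
    modality : Modality, optional
        Overrides the modality recorded on the images.
    kernel_size, radius_tol_um, interior_fraction, hough_threshold
        Pipeline tuning knobs passed to the respective stages.
    """

    def __init__(
        self,
        panels: Sequence[PanelImage],
        geometry: ArrayGeometry,
        modality: Modality | str | None = None,
        kernel_size: int = 3,
        radius_tol_um: float = 1.0,
        interior_fraction: float = 0.8,
        hough_threshold: float = 0.5,
    ):
        if not panels:
            raise WellcountError("need at least one panel image")
        self.panels = list(panels)
        self.geometry = geometry
        self.modality = Modality(modality) if modality else self.panels[0].modality
        self.kernel_size = kernel_size
        self.radius_tol_um = radius_tol_um
        self.interior_fraction = interior_fraction
        self.hough_threshold = hough_threshold

    @classmethod
    def from_images(
        cls,
        paths: Sequence[str | Path],
        geometry: ArrayGeometry,
        modality: Modality | str = Modality.BRIGHTFIELD,
        **kwargs,
    ) -> "MicrowellCounter":
        panels = [
            load_image(p, modality, geometry.pixel_scale_um_per_px) for p in paths
        ]
        return cls(panels, geometry, modality=modality, **kwargs)

    def fit(
        self,
        threshold: float | None = None,
        pooling: str = "device",
        on_panel_error: str = "drop",
    ) -> "MicrowellCountResults":
        """Run the full pipeline and estimate the number density.

        pooling "device" thresholds one pooled histogram over all panels
        (the default; a single illumination setting per device), "panel"
        thresholds each panel separately. Panels whose grid fit fails are
        dropped with a record (``on_panel_error="drop"``) or abort the fit
        (``"raise"``). A manual ``threshold`` bypasses auto-thresholding.
        """
        if pooling not in {"device", "panel"}:
            raise WellcountError(f"unknown pooling {pooling!r}")
        per_panel_int: dict[int, np.ndarray] = {}
        grids: dict[int, detection.WellGrid] = {}
        circles_per_panel: dict[int, int] = {}
        failures: dict[int, str] = {}
        for i, panel in enumerate(self.panels):
            try:
                img = detection.denoise(panel, self.kernel_size)
                circles = detection.find_wells(
                    img, self.geometry,
                    radius_tol_um=self.radius_tol_um,
                    hough_threshold=self.hough_threshold,
                )
                grid = detection.fit_grid(circles, self.geometry)
                per_panel_int[i] = classification.well_intensities(
                    img, grid, self.interior_fraction
                )
                grids[i] = grid
                circles_per_panel[i] = len(circles)
            except WellcountError as exc:
                if on_panel_error == "raise":
                    raise
                failures[i] = f"{type(exc).__name__}: {exc}"
        if not per_panel_int:
            raise WellcountError(
                f"every panel failed: {failures}"
            )

        if pooling == "device":
            pooled = np.concatenate([per_panel_int[i] for i in sorted(per_panel_int)])
            thr = (
                float(threshold)
                if threshold is not None
                else classification.auto_threshold(pooled, self.modality)
            )
            thresholds = {i: thr for i in per_panel_int}
        else:
            thresholds = {
                i: (
                    float(threshold)
                    if threshold is not None
                    else classification.auto_threshold(v, self.modality)
                )
                for i, v in per_panel_int.items()
            }
        occs = {
            i: classification.classify(per_panel_int[i], thresholds[i], self.modality)
            for i in per_panel_int
        }
        k = sum(o.k_occupied for o in occs.values())
        n = sum(o.n_total for o in occs.values())
        estimate = poisson.estimate_density(k, n, self.geometry.well_volume_ul)
        pooled_all = np.concatenate([per_panel_int[i] for i in sorted(per_panel_int)])
        device_occ = classification.classify(
            pooled_all, float(np.median(list(thresholds.values()))), self.modality
        )
        return MicrowellCountResults(
            model=self,
            estimate=estimate,
            occupancy=device_occ,
            panel_occupancies=occs,
            grids=grids,
            circles_per_panel=circles_per_panel,
            failures=failures,
            pooling=pooling,
        )


@dataclass
class MicrowellCountResults:
    """Fit outcome: density estimate, CI, and per-panel diagnostics."""

    model: MicrowellCounter
    estimate: poisson.CountEstimate
    occupancy: classification.OccupancyResult
    panel_occupancies: dict[int, classification.OccupancyResult]
    grids: dict[int, detection.WellGrid]
    circles_per_panel: dict[int, int]
    failures: dict[int, str] = field(default_factory=dict)
    pooling: str = "device"

    @property
    def density_per_ul(self) -> float:
        return self.estimate.density_per_ul

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.estimate.ci_low_per_ul, self.estimate.ci_high_per_ul)

    def per_panel_frame(self) -> pd.DataFrame:
        rows = []
        for i, occ in sorted(self.panel_occupancies.items()):
            rows.append(
                dict(
                    panel=i,
                    detected_circles=self.circles_per_panel[i],
                    fitted_wells=occ.n_total,
                    k_occupied=occ.k_occupied,
                    threshold=occ.threshold,
                    rms_residual_px=self.grids[i].rms_residual_px,
                )
            )
        for i, msg in sorted(self.failures.items()):
            rows.append(dict(panel=i, error=msg))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        e = self.estimate
        g = self.model.geometry
        ci_pct = (
            poisson.ci_percent_of_mean(e) if e.density_per_ul > 0 else float("nan")
        )
        lines = [
            "Microwell digital count",
            "=" * 58,
            f"{'Panels analysed':<32}{len(self.panel_occupancies):>26}",
            f"{'Panels dropped':<32}{len(self.failures):>26}",
            f"{'Wells analysed (n)':<32}{e.n:>26}",
            f"{'Occupied wells (k)':<32}{e.k:>26}",
            f"{'Occupied fraction p^':<32}{e.p_hat:>26.4f}",
            f"{'Mean occupancy lambda^':<32}{e.lambda_hat:>26.4f}",
            f"{'Well volume [uL]':<32}{e.well_volume_ul:>26.4g}",
            "-" * 58,
            f"{'Number density [1/uL]':<32}{e.density_per_ul:>26.4g}",
            f"{f'{e.confidence_level:.0%} CI low [1/uL]':<32}{e.ci_low_per_ul:>26.4g}",
            f"{f'{e.confidence_level:.0%} CI high [1/uL]':<32}{e.ci_high_per_ul:>26.4g}",
            f"{'CI half-width [% of mean]':<32}{ci_pct:>26.2f}",
            "=" * 58,
            f"Modality: {self.model.modality.value}; pooling: {self.pooling}; "
            f"grid {g.rows}x{g.cols} per panel",
        ]
        return "\n".join(lines)

    def plot_histogram(self, ax=None):
        """Well-intensity histogram with the threshold marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        edges, counts = self.occupancy.histogram
        ax.stairs(counts, edges, fill=True, alpha=0.6)
        ax.axvline(self.occupancy.threshold, color="red", ls="--", label="threshold")
        ax.set_xlabel("mean well intensity")
        ax.set_ylabel("wells")
        ax.legend()
        return ax
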