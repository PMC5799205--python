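"""Per-well mean intensity, bimodal threshold selection, and binary
occupied/unoccupied classification.

Occupancy is read from the well-intensity histogram: unoccupied wells form
one narrow mode (bright in bright-field, dim in fluorescence) and occupied
wells a second mode on the other side, possibly spread over sub-modes when
wells hold different particle numbers. The threshold is placed at the
density minimum between the unoccupied mode and the nearest occupied mode.
Polarity: bright-field occupied wells are *below* threshold (particles
block transmission), fluorescence occupied wells are *above* it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .detection import WellGrid
from .errors import BoundsError, DomainError
from .synthetic import Modality, PanelImage


@dataclass
class OccupancyResult:
    """Classification outcome for one panel (or a pooled device).

    ``k_occupied`` counts wells past the threshold on the occupied side of
    the modality's polarity; ties sit with the unoccupied class (strict
    inequality), the conservative choice for a density estimate.
    """

    intensities: np.ndarray
    threshold: float
    modality: Modality
    histogram: tuple[np.ndarray, np.ndarray]  # (bin_edges, bin_counts)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.modality = Modality(self.modality)

    @property
    def occupied_mask(self) -> np.ndarray:
        if self.modality is Modality.BRIGHTFIELD:
            return self.intensities < self.threshold
        return self.intensities > self.threshold

    @property
    def k_occupied(self) -> int:
        return int(self.occupied_mask.sum())

    @property
    def n_total(self) -> int:
        return int(self.intensities.size)

    def to_frame(self, grid: WellGrid | None = None, panel: int = 0) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "panel": panel,
                "mean_intensity": self.intensities,
                "occupied": self.occupied_mask,
            }
        )
        if grid is not None:
            rr, cc = np.mgrid[0 : grid.rows, 0 : grid.cols]
            df.insert(1, "row", rr.ravel())
            df.insert(2, "col", cc.ravel())
        return df


def well_intensities(
    image: PanelImage, grid: WellGrid, interior_fraction: float = 0.8
) -> np.ndarray:
    """Mean pixel intensity inside each fitted well, row-major.

    The averaging disk has radius ``interior_fraction * radius_px`` so the
    dark rim contributes as little as possible to the unoccupied-well mean.
    Raises :class:`BoundsError`, naming the wells, if any disk leaves the
    image.
    """
    if not (0 < interior_fraction <= 1):
        raise DomainError("interior_fraction must be in (0, 1]")
    h, w = image.pixels.shape
    r = grid.radius_px * interior_fraction
    bad = [
        (ri, ci)
        for ri in range(grid.rows)
        for ci in range(grid.cols)
        if not (
            r <= grid.centers[ri, ci, 0] <= w - 1 - r
            and r <= grid.centers[ri, ci, 1] <= h - 1 - r
        )
    ]
    if bad:
        raise BoundsError(
            f"{len(bad)} wells extend outside the {h}x{w} image "
            f"(first: {bad[:5]})",
            wells=bad,
        )
    # one shared offset stencil, shifted to each (rounded) centre
    rad = int(np.ceil(r))
    dy, dx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    out = np.empty(grid.rows * grid.cols)
    flat_centers = grid.centers.reshape(-1, 2)
    for i, (cx, cy) in enumerate(flat_centers):
        ix, iy = int(round(cx)), int(round(cy))
        mask = (dx + ix - cx) ** 2 + (dy + iy - cy) ** 2 <= r**2
        patch = image.pixels[iy - rad : iy + rad + 1, ix - rad : ix + rad + 1]
        out[i] = patch[mask].mean()
    return out


def _histogram(intensities: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Freedman-Diaconis binning with a floor of 16 bins."""
    x = np.asarray(intensities, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        edges = np.linspace(lo - 0.5, hi + 0.5, 17)
    else:
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        width = 2 * iqr / len(x) ** (1 / 3) if iqr > 0 else 0.0
        nbins = int(np.ceil((hi - lo) / width)) if width > 0 else 16
        edges = np.linspace(lo, hi, max(nbins, 16) + 1)
    counts, edges = np.histogram(x, bins=edges)
    return edges, counts


def auto_threshold(
    intensities: np.ndarray,
    modality: Modality | str,
    min_prominence: float = 0.05,
) -> float:
    """Place the occupancy threshold at the valley of the smoothed
    well-intensity density.

    The density (Gaussian KDE, Scott bandwidth) is scanned for significant
    modes (prominence >= ``min_prominence`` of the density maximum). The
    unoccupied mode is the extreme mode on the modality's unoccupied side —
    the brightest mode in bright-field, the dimmest in fluorescence — and
    the threshold is the density minimum between it and the neighbouring
    significant mode. If the density is unimodal there is no evidence of
    occupancy and a sentinel threshold classifying every well as
    unoccupied is returned (below the minimum intensity in bright-field,
    above the maximum in fluorescence).
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise DomainError("cannot threshold an empty intensity list")
    modality = Modality(modality)

    def sentinel() -> float:
        if modality is Modality.BRIGHTFIELD:
            return float(x.min()) - 1e-9
        return float(x.max()) + 1e-9

    if x.size < 2 or np.ptp(x) < 1e-12:
        return sentinel()

    pad = 0.05 * np.ptp(x)
    grid = np.linspace(x.min() - pad, x.max() + pad, 512)
    try:
        density = gaussian_kde(x)(grid)
    except np.linalg.LinAlgError:
        return sentinel()
    peaks, _ = find_peaks(density, prominence=min_prominence * density.max())
    if len(peaks) < 2:
        return sentinel()

    if modality is Modality.BRIGHTFIELD:
        unocc, neighbour = peaks[-1], peaks[-2]
    else:
        unocc, neighbour = peaks[0], peaks[1]
    lo, hi = sorted((unocc, neighbour))
    valley = lo + int(np.argmin(density[lo : hi + 1]))
    return float(grid[valley])


def classify(
    intensities: np.ndarray,
    threshold: float,
    modality: Modality | str,
) -> OccupancyResult:
    """Apply the polarity rule at ``threshold`` and assemble the result
    (counts plus a Freedman-Diaconis histogram of the intensities)."""
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise DomainError("cannot classify an empty intensity list")
    if not np.isfinite(threshold):
        raise DomainError("threshold must be finite")
    return OccupancyResult(
        intensities=x,
        threshold=float(threshold),
        modality=Modality(modality),
        histogram=_histogram(x),
    )
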