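"""Well recognition: mean-kernel denoising, radius-bounded Hough circle
detection, and reconstruction of the full rows x cols well lattice from a
partial set of detections.

The detection chain deliberately looks only for the wells — circular
objects of known, fabrication-defined radius — never for the particles
inside them. That is what makes the downstream occupancy count robust to
aggregates and irregularly shaped samples: whatever sits inside a well can
neither create nor destroy a well detection, because its radius falls
outside the accepted band and any residual response lies within the
merge distance of the (stronger) rim response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import DetectionError, GridFitError, ParameterError
from .geometry import ArrayGeometry
from .synthetic import PanelImage


@dataclass(frozen=True)
class DetectedCircle:
    """One Hough detection: centre (x, y) in pixels plus radius and the
    normalised accumulator strength of the peak."""

    x_px: float
    y_px: float
    radius_px: float
    strength: float = 1.0


@dataclass
class WellGrid:
    """The fitted rows x cols lattice of well centres.

    ``centers`` always holds rows x cols positions, however many circles
    were actually detected: wells missed by the detector still get a fitted
    centre, so the number of analysed wells never depends on occupancy or
    filling defects. The lattice is parameterised by an origin (well (0,0))
    and independent x/y pitches with small shear terms absorbing residual
    camera rotation.
    """

    origin: tuple[float, float]
    pitch_x_px: float
    pitch_y_px: float
    rows: int
    cols: int
    radius_px: float
    centers: np.ndarray  # (rows, cols, 2) -> (x_px, y_px)
    rms_residual_px: float = 0.0

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        assert self.centers.shape == (self.rows, self.cols, 2)

    def to_frame(self, detected: set[tuple[int, int]] | None = None, panel: int = 0) -> pd.DataFrame:
        rows = []
        for r in range(self.rows):
            for c in range(self.cols):
                x, y = self.centers[r, c]
                rows.append(
                    dict(
                        panel=panel, row=r, col=c, x_px=x, y_px=y,
                        radius_px=self.radius_px,
                        detected_flag=(detected is None) or ((r, c) in detected),
                    )
                )
        return pd.DataFrame(rows)


def denoise(image: PanelImage, kernel_size: int = 3) -> PanelImage:
    """Mean-kernel noise removal: each pixel becomes the average of its
    kernel_size x kernel_size neighbourhood (reflect padding at edges).

    kernel_size must be odd, >= 1 and smaller than both image dimensions;
    kernel_size 1 is the identity.
    """
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ParameterError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    h, w = image.pixels.shape
    if kernel_size >= h or kernel_size >= w:
        raise ParameterError(
            f"kernel_size {kernel_size} too large for image {h}x{w}"
        )
    if kernel_size == 1:
        smooth = image.pixels.copy()
    else:
        smooth = ndimage.uniform_filter(image.pixels, size=kernel_size, mode="reflect")
        np.clip(smooth, 0.0, 1.0, out=smooth)
    return PanelImage(
        pixels=smooth, modality=image.modality,
        pixel_scale_um_per_px=image.pixel_scale_um_per_px,
    )


def find_wells(
    image: PanelImage,
    geometry: ArrayGeometry,
    radius_tol_um: float = 1.0,
    hough_threshold: float = 0.5,
    canny_sigma: float = 1.0,
) -> list[DetectedCircle]:
    """Detect well rims as circles of near-nominal radius via Hough transform.

    Only circles with radii within ``radius_tol_um`` of the nominal well
    radius are accepted (plus half a pixel of quantisation slack), which
    rejects responses from structured clutter of the wrong size. Peaks
    closer than half a pitch are merged to the stronger accumulator peak,
    so at most one detection survives per well.

    ``hough_threshold`` is the minimal normalised accumulator value (1.0 =
    a complete circle of edge pixels) for a peak to count as a well.
    """
    if radius_tol_um <= 0:
        raise ParameterError("radius_tol_um must be > 0")
    scale = image.pixel_scale_um_per_px
    r_nominal = geometry.well_radius_um / scale
    r_lo = (geometry.well_radius_um - radius_tol_um) / scale
    r_hi = (geometry.well_radius_um + radius_tol_um) / scale
    h, w = image.pixels.shape
    if h < 2 * r_nominal or w < 2 * r_nominal:
        raise DetectionError(
            f"image {h}x{w} px cannot hold a well of radius {r_nominal:.1f} px"
        )
    pitch_px = geometry.pitch_px

    edges = canny(image.pixels, sigma=canny_sigma)
    radii = np.arange(max(int(np.floor(r_lo)), 1), int(np.ceil(r_hi)) + 1)
    accum = hough_circle(edges, radii, normalize=True)
    n_max = 4 * geometry.rows * geometry.cols
    strengths, cx, cy, found_r = hough_circle_peaks(
        accum, radii,
        min_xdistance=max(int(pitch_px / 2), 1),
        min_ydistance=max(int(pitch_px / 2), 1),
        threshold=hough_threshold,
        total_num_peaks=n_max,
    )

    # radius band with half-pixel quantisation slack
    keep = (found_r >= r_lo - 0.5) & (found_r <= r_hi + 0.5)
    circles = sorted(
        (
            DetectedCircle(float(x), float(y), float(r), float(s))
            for s, x, y, r in zip(strengths[keep], cx[keep], cy[keep], found_r[keep])
        ),
        key=lambda c: -c.strength,
    )

    # greedy Euclidean merge: hough_circle_peaks suppresses per-axis, this
    # enforces the pitch/2 minimum centre separation exactly
    out: list[DetectedCircle] = []
    min_d2 = (pitch_px / 2.0) ** 2
    for c in circles:
        if all((c.x_px - o.x_px) ** 2 + (c.y_px - o.y_px) ** 2 >= min_d2 for o in out):
            out.append(c)
    return out


# -- lattice fitting ---------------------------------------------------------

def _cluster_1d(values: np.ndarray, gap: float) -> list[float]:
    """Sort values and split where the gap to the predecessor exceeds
    ``gap``; return the median of each cluster."""
    v = np.sort(values)
    splits = np.where(np.diff(v) > gap)[0]
    meds = [float(np.median(part)) for part in np.split(v, splits + 1)]
    return meds


def _axis_fit(meds: list[float], n_expected: int, nominal_pitch: float, axis: str):
    """Assign lattice indices to cluster medians and regress position on
    index; returns (offset, pitch)."""
    if len(meds) < 2:
        raise GridFitError(f"single {axis} detected: cannot fit lattice")
    idx = np.round((np.asarray(meds) - meds[0]) / nominal_pitch).astype(int)
    if len(np.unique(idx)) != len(idx):
        raise GridFitError(
            f"{axis} clusters collapse onto the same lattice index: "
            "inconsistent spacing"
        )
    if idx.max() > n_expected - 1:
        raise GridFitError(
            f"detections span {idx.max() + 1} {axis}s but the array has "
            f"{n_expected}"
        )
    coeffs = np.polyfit(idx, meds, 1)
    return float(coeffs[1]), float(coeffs[0])  # offset, pitch


def fit_grid(
    circles: list[DetectedCircle],
    geometry: ArrayGeometry,
    residual_tol_frac: float = 0.25,
) -> WellGrid:
    """Fit the known rows x cols lattice to the detected circles.

    Detected x (and y) coordinates are clustered into columns (rows) with a
    gap threshold of half a pitch, cluster medians are assigned lattice
    indices via the nominal pitch, and a least-squares regression of
    position on index gives origin and pitch per axis. A second pass
    assigns every circle to its nearest lattice site and re-solves the
    lattice with shear terms, absorbing small camera rotation. Every well
    gets a centre whether or not it was detected.

    Raises :class:`GridFitError` when fewer than two distinct rows or
    columns are detected, or when the fit residuals exceed
    ``residual_tol_frac`` of a pitch (inconsistent lattice).
    """
    if len(circles) < 4:
        raise GridFitError(f"only {len(circles)} circles: too few to fit a lattice")
    xs = np.array([c.x_px for c in circles])
    ys = np.array([c.y_px for c in circles])
    pitch = geometry.pitch_px

    x0, px = _axis_fit(_cluster_1d(xs, pitch / 2), geometry.cols, pitch, "column")
    y0, py = _axis_fit(_cluster_1d(ys, pitch / 2), geometry.rows, pitch, "row")

    # refinement with shear terms: x = x0 + c*px + r*sx ; y = y0 + r*py + c*sy
    col_idx = np.round((xs - x0) / px).astype(int)
    row_idx = np.round((ys - y0) / py).astype(int)
    ok = (
        (col_idx >= 0) & (col_idx < geometry.cols)
        & (row_idx >= 0) & (row_idx < geometry.rows)
    )
    if ok.sum() < 4:
        raise GridFitError("detections do not land on the expected lattice")
    A = np.column_stack([np.ones(ok.sum()), col_idx[ok], row_idx[ok]])
    bx, *_ = np.linalg.lstsq(A, xs[ok], rcond=None)
    by, *_ = np.linalg.lstsq(A, ys[ok], rcond=None)
    x0, px, sx = bx
    y0, sy, py = by[0], by[1], by[2]

    rr, cc = np.mgrid[0 : geometry.rows, 0 : geometry.cols]
    centers = np.stack(
        [x0 + cc * px + rr * sx, y0 + rr * py + cc * sy], axis=-1
    )
    fit_x = x0 + col_idx[ok] * px + row_idx[ok] * sx
    fit_y = y0 + row_idx[ok] * py + col_idx[ok] * sy
    resid = np.hypot(xs[ok] - fit_x, ys[ok] - fit_y)
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms > residual_tol_frac * pitch or resid.max() > 2 * residual_tol_frac * pitch:
        raise GridFitError(
            f"lattice fit residuals too large (rms {rms:.2f} px, max "
            f"{resid.max():.2f} px vs pitch {pitch:.1f} px): detections are "
            "not consistent with a single lattice"
        )
    radius = float(np.median([c.radius_px for c in circles]))
    return WellGrid(
        origin=(float(x0), float(y0)),
        pitch_x_px=float(px), pitch_y_px=float(py),
        rows=geometry.rows, cols=geometry.cols,
        radius_px=radius, centers=centers, rms_residual_px=rms,
    )
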