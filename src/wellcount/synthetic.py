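"""Synthetic microwell-panel micrographs with known ground truth.

Two stages, both deterministic given their seed:

* :func:`seed_particles` distributes particles into the wells of one panel.
  With ``aggregation = 0`` the per-well counts are i.i.d. Poisson with mean
  ``lambda = density * well_volume`` — the random-loading model digital
  counting relies on. With ``aggregation > 0`` particles arrive in clumps
  of geometric size landing in a single well, so at high density fewer
  wells are occupied than Poisson loading predicts (the under-counting
  failure mode seen with aggregating microparticles).
* :func:`render_panel` draws the panel as a bright-field or fluorescence
  micrograph: well rims, dark (bright-field) or bright (fluorescence)
  particle disks, additive Gaussian noise and a slow illumination tilt.

The generator emulates what the counting algorithm actually consumes —
contrast between occupied and unoccupied well interiors on a regular
lattice — not the optics (no point-spread function, no 3-D rendering).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DomainError
from .geometry import ArrayGeometry


class Modality(str, Enum):
    BRIGHTFIELD = "brightfield"
    FLUORESCENCE = "fluorescence"


@dataclass(frozen=True)
class NoiseSpec:
    """Imaging imperfections applied by the renderer.

    additive_sigma
        Std. dev. of zero-mean Gaussian pixel noise (intensity units).
    illumination_gradient
        Maximal fractional intensity change across the frame (a linear
        multiplicative tilt along the image diagonal), in [0, 0.5].
    rng_seed
        Seed for the renderer's random draws (noise, particle placement).
    """

    additive_sigma: float = 0.02
    illumination_gradient: float = 0.10
    rng_seed: int = 0

    def __post_init__(self):
        if self.additive_sigma < 0:
            raise DomainError("additive_sigma must be >= 0")
        if not (0 <= self.illumination_gradient <= 0.5):
            raise DomainError("illumination_gradient must be in [0, 0.5]")


@dataclass(frozen=True)
class RenderSettings:
    """Contrast constants of the renderer (intensity units in [0, 1]).

    These stand in for the light source and shutter settings that are
    adjusted per device on a real microscope; defaults give a cleanly
    bimodal well-intensity histogram in both modalities.
    """

    # bright-field: bright background, dark rims, dark particles
    bf_background: float = 0.85
    bf_interior: float = 0.78
    bf_rim: float = 0.35
    bf_particle: float = 0.15
    # fluorescence: dark background, faint unoccupied wells, bright particles
    fl_background: float = 0.05
    fl_interior: float = 0.22
    fl_rim: float = 0.30
    fl_particle: float = 0.85
    rim_width_px: float = 2.0
    #: particle radius as a fraction of the well radius (a 10 um bead in a
    #: 20 um well -> 0.5)
    particle_radius_frac: float = 0.5
    #: particles are centred within this fraction of the well radius
    particle_offset_frac: float = 0.45


@dataclass
class PanelImage:
    """One panel's intensity raster plus imaging metadata.

    ``pixels`` is a 2-D float array in [0, 1], row-major, origin top-left;
    x is the column index and y the row index.
    """

    pixels: np.ndarray
    modality: Modality
    pixel_scale_um_per_px: float

    def __post_init__(self):
        self.modality = Modality(self.modality)
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 3:  # RGB -> luminance
            px = px @ np.array([0.2126, 0.7152, 0.0722])
        if px.ndim != 2:
            raise ConsistencyError("pixels must be a 2-D intensity array")
        if px.size and (px.min() < 0 or px.max() > 1):
            raise ConsistencyError("intensities must lie in [0, 1]")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class GroundTruth:
    """Known content of one synthetic panel, for testing the pipeline.

    ``particles`` and ``occupied`` are rows x cols arrays over the full
    lattice; ``centers`` lists (row, col, x_px, y_px) for wells actually
    rendered (missing wells have no entry and always carry 0 particles).
    """

    geometry: ArrayGeometry
    particles: np.ndarray  # int, rows x cols
    missing_wells: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self):
        self.particles = np.asarray(self.particles, dtype=int)
        if self.particles.shape != (self.geometry.rows, self.geometry.cols):
            raise ConsistencyError(
                f"particles shape {self.particles.shape} does not match grid "
                f"{(self.geometry.rows, self.geometry.cols)}"
            )
        for r, c in self.missing_wells:
            if not (0 <= r < self.geometry.rows and 0 <= c < self.geometry.cols):
                raise ConsistencyError(f"missing well ({r},{c}) outside grid")
            if self.particles[r, c] != 0:
                raise ConsistencyError("missing wells cannot hold particles")

    @property
    def occupied(self) -> np.ndarray:
        return self.particles >= 1

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.sum())

    @property
    def centers(self) -> list[tuple[int, int, float, float]]:
        g = self.geometry
        out = []
        for r in range(g.rows):
            for c in range(g.cols):
                if (r, c) in self.missing_wells:
                    continue
                x, y = well_center_px(g, r, c)
                out.append((r, c, x, y))
        return out

    def to_frame(self, panel: int = 0) -> pd.DataFrame:
        g = self.geometry
        rows = []
        for r in range(g.rows):
            for c in range(g.cols):
                x, y = well_center_px(g, r, c)
                rows.append(
                    dict(
                        panel=panel, row=r, col=c, x_px=x, y_px=y,
                        particles=int(self.particles[r, c]),
                        occupied=bool(self.particles[r, c] >= 1),
                        missing=(r, c) in self.missing_wells,
                    )
                )
        return pd.DataFrame(rows)


# -- panel layout ------------------------------------------------------------

def panel_shape_px(geometry: ArrayGeometry) -> tuple[int, int]:
    """Image height, width in pixels: one pitch of margin around the lattice."""
    p = geometry.pitch_px
    return int(round(p * geometry.rows)), int(round(p * geometry.cols))


def well_center_px(geometry: ArrayGeometry, row: int, col: int) -> tuple[float, float]:
    """Ground-truth centre (x_px, y_px) of well (row, col); origin top-left."""
    p = geometry.pitch_px
    return p / 2.0 + col * p, p / 2.0 + row * p


# -- particle seeding --------------------------------------------------------

def seed_particles(
    geometry: ArrayGeometry,
    density_per_ul: float,
    aggregation: float = 0.0,
    rng_seed: int = 0,
    missing_wells: int | Iterable[tuple[int, int]] = (),
) -> GroundTruth:
    """Distribute particles of a sample at ``density_per_ul`` into one panel.

    The clump model: clumps arrive in each well as Poisson with mean
    ``lambda * (1 - aggregation)`` and each clump holds Geometric(1 -
    aggregation) particles (support 1, 2, ...), so the expected particles
    per well is exactly ``lambda = density * well_volume`` for every
    aggregation level, while the occupied fraction drops from
    ``1 - exp(-lambda)`` at aggregation 0 to ``1 - exp(-lambda (1 - a))``.

    ``missing_wells`` marks wells rendered absent (fabrication defects):
    either an iterable of (row, col) indices or an integer count drawn
    uniformly without replacement.
    """
    if density_per_ul < 0:
        raise DomainError(f"density must be >= 0, got {density_per_ul}")
    if not (0 <= aggregation < 1):
        raise DomainError("aggregation must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    lam = density_per_ul * geometry.well_volume_ul
    shape = (geometry.rows, geometry.cols)

    if isinstance(missing_wells, (int, np.integer)):
        k = int(missing_wells)
        flat = rng.choice(geometry.wells_per_panel, size=k, replace=False)
        missing = frozenset(
            (int(i // geometry.cols), int(i % geometry.cols)) for i in flat
        )
    else:
        missing = frozenset((int(r), int(c)) for r, c in missing_wells)

    keep = 1.0 - aggregation
    clumps = rng.poisson(lam * keep, size=shape)
    if aggregation == 0:
        particles = clumps  # geometric(1) clump size == 1: plain Poisson
    else:
        # sum of iid Geometric(keep) sizes per well == negative binomial
        particles = np.zeros(shape, dtype=int)
        nz = clumps > 0
        particles[nz] = clumps[nz] + rng.negative_binomial(
            clumps[nz], keep
        )
    for r, c in missing:
        particles[r, c] = 0
    return GroundTruth(geometry=geometry, particles=particles, missing_wells=missing)


# -- rendering ---------------------------------------------------------------

def _disk_patch(img, cx, cy, radius, value):
    """Paint a filled disk; clipped at image borders."""
    h, w = img.shape
    x0, x1 = max(int(cx - radius) - 1, 0), min(int(cx + radius) + 2, w)
    y0, y1 = max(int(cy - radius) - 1, 0), min(int(cy + radius) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    img[y0:y1, x0:x1][mask] = value


def _annulus_patch(img, cx, cy, r_in, r_out, value):
    h, w = img.shape
    x0, x1 = max(int(cx - r_out) - 1, 0), min(int(cx + r_out) + 2, w)
    y0, y1 = max(int(cy - r_out) - 1, 0), min(int(cy + r_out) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    mask = (d2 >= r_in**2) & (d2 <= r_out**2)
    img[y0:y1, x0:x1][mask] = value


def render_panel(
    geometry: ArrayGeometry,
    truth: GroundTruth,
    modality: Modality | str = Modality.BRIGHTFIELD,
    noise: NoiseSpec | None = None,
    settings: RenderSettings | None = None,
) -> PanelImage:
    """Draw one panel micrograph from a :class:`GroundTruth`.

    Bright-field: bright background, darker rim annulus per well, dark
    particle disks in occupied wells. Fluorescence: dark background, faintly
    visible well interiors, bright particle disks. An illumination tilt is
    applied multiplicatively along the image diagonal, Gaussian noise is
    added, and intensities are clipped to [0, 1].
    """
    if truth.geometry != geometry:
        raise ConsistencyError("ground truth was built for a different geometry")
    modality = Modality(modality)
    noise = noise or NoiseSpec()
    s = settings or RenderSettings()
    rng = np.random.default_rng(noise.rng_seed)

    h, w = panel_shape_px(geometry)
    R = geometry.well_radius_px
    rim_in = R - s.rim_width_px / 2.0
    rim_out = R + s.rim_width_px / 2.0
    r_particle = s.particle_radius_frac * R
    max_off = s.particle_offset_frac * R

    if modality is Modality.BRIGHTFIELD:
        bg, interior, rim, particle = s.bf_background, s.bf_interior, s.bf_rim, s.bf_particle
    else:
        bg, interior, rim, particle = s.fl_background, s.fl_interior, s.fl_rim, s.fl_particle

    img = np.full((h, w), bg, dtype=float)
    for r in range(geometry.rows):
        for c in range(geometry.cols):
            if (r, c) in truth.missing_wells:
                continue
            cx, cy = well_center_px(geometry, r, c)
            _annulus_patch(img, cx, cy, rim_in, rim_out, rim)
            _disk_patch(img, cx, cy, rim_in, interior)
            for _ in range(int(truth.particles[r, c])):
                rho = max_off * np.sqrt(rng.uniform())
                theta = rng.uniform(0.0, 2.0 * np.pi)
                _disk_patch(
                    img,
                    cx + rho * np.cos(theta),
                    cy + rho * np.sin(theta),
                    r_particle,
                    particle,
                )

    if noise.illumination_gradient > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        u = (xx / max(w - 1, 1) + yy / max(h - 1, 1)) / 2.0  # 0..1 along diagonal
        img *= 1.0 + noise.illumination_gradient * (u - 0.5)
    if noise.additive_sigma > 0:
        img = img + rng.normal(0.0, noise.additive_sigma, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return PanelImage(
        pixels=img, modality=modality,
        pixel_scale_um_per_px=geometry.pixel_scale_um_per_px,
    )


# -- image / truth I/O -------------------------------------------------------

def save_image(image: PanelImage, path: str | Path) -> None:
    """Write as 16-bit grayscale TIFF (.tif/.tiff) or 8-bit PNG (.png)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, (image.pixels * 65535).round().astype(np.uint16))
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, (image.pixels * 255).round().astype(np.uint8))
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def load_image(
    path: str | Path,
    modality: Modality | str,
    pixel_scale_um_per_px: float,
) -> PanelImage:
    """Read a PNG/TIFF panel image; integer types are rescaled to [0, 1] and
    RGB is converted to grayscale by luminance weighting."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        raw = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raw = iio.imread(path)
    raw = np.asarray(raw)
    if np.issubdtype(raw.dtype, np.integer):
        raw = raw.astype(float) / np.iinfo(raw.dtype).max
    else:
        raw = raw.astype(float)
    return PanelImage(
        pixels=raw, modality=Modality(modality),
        pixel_scale_um_per_px=pixel_scale_um_per_px,
    )


def save_ground_truth(
    truths: dict[int, GroundTruth], csv_path: str | Path, json_path: str | Path | None = None
) -> None:
    """Write per-well ground truth for one or more panels as CSV (and JSON)."""
    frames = [t.to_frame(panel=p) for p, t in sorted(truths.items())]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            str(p): {
                "particles": t.particles.tolist(),
                "missing_wells": sorted(map(list, t.missing_wells)),
            }
            for p, t in sorted(truths.items())
        }
        Path(json_path).write_text(json.dumps(payload, indent=1))
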