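"""Physical description of a microwell array and its config file format.

The array is a device of ``panels`` identical panels, each a rectangular
``rows x cols`` lattice of circular wells. All lengths are in micrometres,
volumes in microlitres, and ``pixel_scale`` converts between image pixels
and physical length. The per-well volume defaults to the cylinder volume
computed from diameter and depth; a config may override it explicitly,
e.g. to reproduce a previously published figure that used a different
per-well volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import ConfigError, GeometryError

UM3_PER_UL = 1e9  # 1 uL = 1e9 um^3


def cylinder_volume(diameter_um: float, depth_um: float) -> float:
    """Volume of a cylindrical well in microlitres.

    Parameters
    ----------
    diameter_um, depth_um : float
        Well diameter and depth in micrometres; both must be positive.

    Returns
    -------
    float
        pi * (d/2)^2 * depth, converted from um^3 to uL.
    """
    if not (diameter_um > 0) or not (depth_um > 0):
        raise GeometryError(
            f"cylinder dimensions must be positive, got diameter={diameter_um}, "
            f"depth={depth_um}"
        )
    return math.pi * (diameter_um / 2.0) ** 2 * depth_um / UM3_PER_UL


@dataclass(frozen=True)
class ArrayGeometry:
    """Physical/optical description of a microwell array device.

    Defaults describe a PDMS chip of 36 panels, each a 30 x 30 square
    arrangement of circular wells 20 um in diameter and 25 um deep
    (14,400 wells per device). The centre-to-centre pitch and the pixel
    scale are imaging/fabrication free parameters.

    ``well_volume_ul`` is the cylinder volume unless overridden.
    """

    well_diameter_um: float = 20.0
    well_depth_um: float = 25.0
    pitch_um: float = 40.0
    rows: int = 30
    cols: int = 30
    panels: int = 36
    pixel_scale_um_per_px: float = 1.0
    well_volume_ul: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not (self.well_diameter_um > 0):
            raise GeometryError("well_diameter_um must be > 0")
        if not (self.well_depth_um > 0):
            raise GeometryError("well_depth_um must be > 0")
        if self.pitch_um < self.well_diameter_um:
            raise GeometryError(
                f"pitch_um ({self.pitch_um}) must be >= well_diameter_um "
                f"({self.well_diameter_um})"
            )
        if self.rows < 2 or self.cols < 2:
            raise GeometryError("rows and cols must both be >= 2")
        if self.panels < 1:
            raise GeometryError("panels must be >= 1")
        if not (self.pixel_scale_um_per_px > 0):
            raise GeometryError("pixel_scale_um_per_px must be > 0")
        if self.well_volume_ul is None:
            object.__setattr__(
                self,
                "well_volume_ul",
                cylinder_volume(self.well_diameter_um, self.well_depth_um),
            )
        if not (self.well_volume_ul > 0):
            raise GeometryError("well_volume_ul must be > 0")

    # -- derived quantities ------------------------------------------------
    @property
    def wells_per_panel(self) -> int:
        return self.rows * self.cols

    @property
    def wells_per_device(self) -> int:
        return self.rows * self.cols * self.panels

    @property
    def total_well_volume_ul(self) -> float:
        """Combined volume of every well on the device."""
        return self.wells_per_device * self.well_volume_ul

    @property
    def well_radius_um(self) -> float:
        return self.well_diameter_um / 2.0

    @property
    def well_radius_px(self) -> float:
        return self.well_radius_um / self.pixel_scale_um_per_px

    @property
    def pitch_px(self) -> float:
        return self.pitch_um / self.pixel_scale_um_per_px

    def with_override(self, **kwargs) -> "ArrayGeometry":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# -- config I/O --------------------------------------------------------------

_CONFIG_KEYS = {
    "well_diameter_um": float,
    "well_depth_um": float,
    "pitch_um": float,
    "rows": int,
    "cols": int,
    "panels": int,
    "pixel_scale_um_per_px": float,
    "well_volume_ul": float,  # optional override
}
_REQUIRED = [k for k in _CONFIG_KEYS if k != "well_volume_ul"]


def load_config(path: str | Path) -> ArrayGeometry:
    """Parse a flat ``key = value`` config document into an :class:`ArrayGeometry`.

    Lines starting with ``#`` and blank lines are ignored. All keys except
    ``well_volume_ul`` are required; unknown keys are an error. Units are
    fixed: micrometres for lengths, microlitres for volumes.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    values: dict[str, float | int] = {}
    bad: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, val = line.partition("=")
        elif ":" in line:
            key, _, val = line.partition(":")
        else:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = key.strip(), val.strip()
        if key not in _CONFIG_KEYS:
            bad.append(key)
            continue
        try:
            values[key] = _CONFIG_KEYS[key](val)
        except ValueError:
            raise ConfigError(f"{path}:{lineno}: cannot parse {key}={val!r}", [key])
    missing = [k for k in _REQUIRED if k not in values]
    if bad or missing:
        raise ConfigError(
            f"invalid config {path}: unknown keys {bad or 'none'}, "
            f"missing keys {missing or 'none'}",
            bad + missing,
        )
    try:
        return ArrayGeometry(**values)  # type: ignore[arg-type]
    except GeometryError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def write_config(geometry: ArrayGeometry, path: str | Path) -> None:
    """Write a geometry as a flat key = value document (round-trips with
    :func:`load_config`)."""
    path = Path(path)
    lines = ["# microwell array geometry (lengths um, volumes uL)"]
    for key in _CONFIG_KEYS:
        lines.append(f"{key} = {getattr(geometry, key)!r}")
    path.write_text("\n".join(lines) + "\n")


#: Per-well volume quoted for the original 20 um x 25 um PDMS device
#: (14,400 wells -> 0.18 uL total). It does not equal the cylinder volume of
#: that geometry (7.854e-6 uL; it instead matches pi * 20^2 * 10 um^3) and is
#: kept as an explicit override for reproducing the published arithmetic.
PRINTED_WELL_VOLUME_UL = 1.257e-5

#: Well count quoted for the original device. The stated layout (36 panels
#: of 30 x 30 wells) multiplies out to 32,400, so the quoted 14,400 does not
#: follow from it; it is, however, the value whose product with
#: :data:`PRINTED_WELL_VOLUME_UL` reproduces the quoted 0.18 uL total.
#: Both published numbers are kept verbatim rather than reconciled.
PRINTED_WELLS_PER_DEVICE = 14_400
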