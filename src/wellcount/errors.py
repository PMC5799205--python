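"""Exception hierarchy.

Each public failure mode has its own class so the CLI can map them to
distinct exit codes and callers can catch precisely.
"""

from __future__ import annotations


class WellcountError(Exception):
    """Base class for all package errors."""


class GeometryError(WellcountError, ValueError):
    """Invalid physical array description (non-positive length, bad grid shape...)."""


class ConfigError(WellcountError, ValueError):
    """Config document missing, unparsable, or carrying invalid keys/values."""

    def __init__(self, message: str, bad_keys: list[str] | None = None):
        super().__init__(message)
        self.bad_keys = list(bad_keys or [])


class DomainError(WellcountError, ValueError):
    """Argument outside its mathematical domain (negative density, fraction >= 1...)."""


class ParameterError(WellcountError, ValueError):
    """Invalid algorithm parameter (even kernel, oversized kernel...)."""


class ConsistencyError(WellcountError, ValueError):
    """Ground truth and geometry disagree (shape mismatch, out-of-range indices)."""


class DetectionError(WellcountError, RuntimeError):
    """Circle detection cannot run (image smaller than one well...)."""


class GridFitError(WellcountError, RuntimeError):
    """Lattice fit impossible or inconsistent; message names the deficiency."""


class BoundsError(WellcountError, ValueError):
    """Fitted grid extends outside the image; carries the offending wells."""

    def __init__(self, message: str, wells: list[tuple[int, int]] | None = None):
        super().__init__(message)
        self.wells = list(wells or [])


class SaturationError(WellcountError, RuntimeError):
    """All wells occupied: the mean occupancy is unidentifiable.

    Carries the one-sided lower density bound that the data still support.
    """

    def __init__(self, message: str, density_lower_bound: float):
        super().__init__(message)
        self.density_lower_bound = density_lower_bound
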