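"""Exception hierarchy for the SRH toolkit.

The command-line layer maps these onto distinct exit codes; library users
catch :class:`SRHError` for anything raised by the package itself.
"""


class SRHError(Exception):
    """Base class for all srhkit errors."""


class ManifestError(SRHError):
    """Tile manifest is internally inconsistent (duplicate or missing grid cells)."""


class FormatError(SRHError):
    """An on-disk image does not match the expected two-channel layout."""


class DegenerateFieldError(SRHError):
    """Flat-field estimation produced a non-positive gain somewhere."""


class CalibrationError(SRHError):
    """No usable pixels for unmixing-coefficient calibration."""


class StitchError(SRHError):
    """Tile grid cannot be assembled into a mosaic."""


class PlacementError(SRHError):
    """Hard-core nucleus placement could not reach the requested density."""

    def __init__(self, message: str, achieved_density: float | None = None):
        super().__init__(message)
        self.achieved_density = achieved_density


class ConfigError(SRHError):
    """Pipeline configuration failed validation."""
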