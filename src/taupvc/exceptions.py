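"""Exception hierarchy for taupvc.

All package-specific failures derive from :class:`TauPVCError` so callers
can catch pipeline problems without masking programming errors.
"""


class TauPVCError(Exception):
    """Base class for all taupvc errors."""


class ParameterError(TauPVCError, ValueError):
    """A model or simulation parameter violates its constraints."""


class GeometryError(TauPVCError, ValueError):
    """Phantom region geometry is invalid (out of bounds, empty, ...)."""


class ConfigurationError(TauPVCError, ValueError):
    """A configuration object is inconsistent or incomplete."""


class DegenerateInputError(TauPVCError, ValueError):
    """An input is degenerate for the requested operation (e.g. all-zero
    composite image for HYPR denoising)."""


class EmptyRegionError(TauPVCError, ValueError):
    """A volume of interest is empty where a non-empty one is required."""


class IrreversibleModelError(TauPVCError, ValueError):
    """k4 = 0 with k3 > 0: the distribution volume is undefined."""


class FitError(TauPVCError, RuntimeError):
    """Non-linear regression failed to converge from every start."""


class InsufficientDataError(TauPVCError, ValueError):
    """Too few observations for the requested statistical test."""
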