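"""Package-specific error types."""


class MusmbError(Exception):
    """Base class for all package errors."""


class IntegrationError(MusmbError, RuntimeError):
    """The column ODE integrator failed to converge."""


class UndefinedMomentError(MusmbError, ValueError):
    """A chromatogram moment was requested on an (all-zero) empty trace."""


class EstimationError(MusmbError, ValueError):
    """Tracer-based porosity estimation produced an out-of-range value."""


class InfeasibleFlowError(MusmbError, ValueError):
    """A flow balance or zone flow came out nonpositive / inconsistent."""


class InconsistentConfigError(MusmbError, ValueError):
    """An SMB configuration violates the overall liquid mass balance."""


class NoSeparationRegionError(MusmbError, ValueError):
    """Triangle design requested for species without a separation region."""


class InsufficientDataError(MusmbError, ValueError):
    """Not enough cycles / scans to perform the requested analysis."""
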