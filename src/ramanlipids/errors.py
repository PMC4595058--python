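"""Exception hierarchy for the pipeline.

Every error raised by this package derives from :class:`RamanLipidsError`,
so callers (and the CLI, which maps subclasses to exit codes) can catch one
base class.
"""


class RamanLipidsError(Exception):
    """Base class for all package errors."""


class ValidationError(RamanLipidsError, ValueError):
    """Invalid domain value (bad fatty-acid code, negative weight, ...)."""


class FormatError(RamanLipidsError, ValueError):
    """Malformed input file; message names the offending line/pixel."""


class FitError(RamanLipidsError, RuntimeError):
    """Peak or calibration fit failed to converge after restarts."""


class QCError(RamanLipidsError, RuntimeError):
    """Spectrum failed a quality-control gate (protein contamination,
    inadequate photobleach, undefined ratio)."""


class LocalizationError(RamanLipidsError, RuntimeError):
    """Lipid-body localization found no pixel above the noise floor."""


class RangeError(RamanLipidsError, ValueError):
    """Inversion requested outside a calibration model's invertible range."""
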