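"""Exception hierarchy for famseg.

Every error raised intentionally by this package derives from
:class:`FamsegError`, so callers (and the CLI) can distinguish pipeline
failures from programming errors.
"""


class FamsegError(Exception):
    """Base class for all famseg errors."""


class ParseError(FamsegError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(FamsegError):
    """Structurally parseable input that violates a model invariant."""


class MissingDataError(FamsegError):
    """A required measurement (e.g. a BMD Z-score) is absent."""


class VcfFormatError(FamsegError):
    """The VCF lacks a required feature (e.g. the GT FORMAT field)."""


class ConfigurationError(FamsegError):
    """The pipeline configuration is inconsistent with the input data."""


class SimulationError(FamsegError):
    """A simulation request is unsatisfiable (e.g. fate/carrier conflict)."""
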