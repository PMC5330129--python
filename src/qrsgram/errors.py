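"""Exception hierarchy shared across the pipeline."""


class QRSGramError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QRSGramError):
    """A parameter set violates its invariants (e.g. cutoff above Nyquist)."""


class InputError(QRSGramError):
    """An input signal, file or argument is malformed for the operation."""


class DegenerateSignalError(InputError):
    """Signal has no usable structure (constant / zero / too short)."""


class FeatureUnavailableError(QRSGramError):
    """An optional feature's dependency is not installed."""
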