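"""Exception hierarchy.

``ConfigurationError`` and ``ValidationError`` indicate bad user input and
map to CLI exit code 2; everything else maps to exit code 1.
"""


class SebumetricsError(Exception):
    """Base class for package errors."""


class ConfigurationError(SebumetricsError, ValueError):
    """Invalid configuration (bad parameter values, malformed config file)."""


class ValidationError(SebumetricsError, ValueError):
    """Inputs that fail a contract check (mismatched metadata, bad labels)."""


class ParseError(SebumetricsError, ValueError):
    """A spectra or table file could not be parsed."""


class UnsupportedContentError(ParseError):
    """The file parsed but holds content the pipeline cannot use
    (profile-mode spectra, MS2-only files)."""


class StageError(SebumetricsError, ValueError):
    """A feature-matrix operation applied at the wrong processing stage."""
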