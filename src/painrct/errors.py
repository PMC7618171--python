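"""Exception hierarchy shared across the package."""


class PainRCTError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(PainRCTError, ValueError):
    """An argument violates a documented precondition."""


class ConfigError(PainRCTError, ValueError):
    """A configuration value is inconsistent or out of range."""


class MissingDataError(PainRCTError):
    """A required score component or data cell is absent; scores are never imputed."""


class FlaggedInputError(PainRCTError):
    """An artefact-flagged epoch was passed to a scorer that refuses flagged input."""


class EmptyAnalysisError(PainRCTError):
    """No complete cases remain for the requested analysis."""


class WeakInstrumentError(PainRCTError):
    """The randomisation instrument carries no information about exposure."""


class ParseError(PainRCTError):
    """A dataset file on disk is malformed; the message names the file (and column/row)."""
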