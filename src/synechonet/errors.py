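"""Exception types shared across the package."""


class SynechonetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SynechonetError):
    """A file could not be parsed; the message names the offending row/column."""


class UndefinedAgreementError(SynechonetError):
    """Two profiles share no experiment where both states are present."""


class ImpossibleEvidenceError(SynechonetError):
    """Evidence has probability zero under the model."""


class NotExtendableError(SynechonetError):
    """A partially directed graph admits no consistent DAG extension."""
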