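"""Exception hierarchy.

``ConfigurationError`` flags problems in how a design was set up (bad
groups, missing oracles, malformed configs); ``ProtocolError`` flags
illegal sequence edits (mutating an immutable residue, emptying a
chain); ``OracleError`` wraps failures inside a predictor adapter so the
offending input is always visible.
"""


class FoldscapeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FoldscapeError):
    """A design, binding or run configuration is invalid."""


class ProtocolError(FoldscapeError):
    """A mutation proposal violated the rules of the sequence model."""


class OracleError(FoldscapeError):
    """An oracle failed to produce output for a sequence tuple."""

    def __init__(self, message: str, sequences=None):
        if sequences is not None:
            message = f"{message} (input sequences: {sequences!r})"
        super().__init__(message)
        self.sequences = sequences
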