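"""Exception hierarchy.

CLI exit-code mapping: UsageError -> 1, data/format errors -> 2.
"""


class BnsmotifError(Exception):
    """Base class for all package errors."""


class UsageError(BnsmotifError):
    """A call violated an operation's precondition (bad arguments)."""


class FormatError(BnsmotifError):
    """An input file is malformed; message names the offending line where known."""


class GenerationError(BnsmotifError):
    """A synthetic-data request cannot be satisfied under the given parameters."""


class StageError(BnsmotifError):
    """A pipeline stage failed on otherwise well-formed inputs."""
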