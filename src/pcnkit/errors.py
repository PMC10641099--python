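"""Exception hierarchy for pcnkit.

Every error raised by the library derives from :class:`PCNError`, so callers
(and the CLI) can distinguish domain failures from programming errors.
"""


class PCNError(Exception):
    """Base class for all pcnkit errors."""


class ParseError(PCNError):
    """A PDB or adjacency file could not be parsed."""


class StructureError(PCNError):
    """A structure is empty or yields no usable residue nodes."""


class MatrixFormatError(PCNError):
    """An adjacency matrix violates the binary/symmetric/square contract."""


class ParameterError(PCNError):
    """Invalid build or analysis parameters."""


class ConvergenceError(PCNError):
    """An iterative solver failed to converge within its iteration budget."""


class FetchError(PCNError):
    """A remote structure download failed."""
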