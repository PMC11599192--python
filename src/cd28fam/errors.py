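"""Exception hierarchy for cd28fam.

Each error class maps to one CLI exit code (see :mod:`cd28fam.cli`).
"""


class Cd28FamError(Exception):
    """Base class for all package errors."""


class MotifParseError(Cd28FamError):
    """Malformed consensus-motif notation (carries token and position)."""

    def __init__(self, message: str, token: str = "", position: int = -1):
        super().__init__(message)
        self.token = token
        self.position = position


class SequenceError(Cd28FamError):
    """Invalid residue or malformed protein record."""


class SegmentationError(Cd28FamError):
    """Protein could not be segmented into a type-I membrane architecture."""


class TableError(Cd28FamError):
    """Malformed gene-order table or lookup failure."""


class CatalogError(Cd28FamError):
    """Family catalog schema violation or uncompilable pattern."""


class PhyloError(Cd28FamError):
    """Invalid input to an alignment or tree operation."""
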