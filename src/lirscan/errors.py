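"""Typed exceptions raised across the package."""


class LirScanError(Exception):
    """Base class for all lirscan errors."""


class InvalidWindowError(LirScanError, ValueError):
    """A candidate window has the wrong length."""


class InvalidResidueError(LirScanError, ValueError):
    """A sequence contains a character outside the 20 standard amino acids.

    The offending character is stored on ``residue``.
    """

    def __init__(self, residue: str, context: str = ""):
        self.residue = residue
        msg = f"non-standard residue {residue!r}"
        if context:
            msg += f" in {context!r}"
        super().__init__(msg)


class NotAMotifError(LirScanError, ValueError):
    """Subtype was requested for a window that matches neither consensus."""


class EmptySequenceError(LirScanError, ValueError):
    """A protein record has an empty sequence."""


class DuplicateIdError(LirScanError, ValueError):
    """Two records in one scan share an accession."""


class IntervalError(LirScanError, ValueError):
    """Disorder intervals are unsorted, overlapping, or out of bounds."""


class TrainingSetError(LirScanError, ValueError):
    """The PSSM training set is empty or contains an invalid window."""


class BackgroundError(LirScanError, ValueError):
    """A residue background frequency is zero, negative, or unnormalised."""


class EnrichmentBoundsError(LirScanError, ValueError):
    """Hypergeometric urn parameters violate 0 <= k <= min(n, K) <= N."""


class GroupError(LirScanError, ValueError):
    """An enrichment group is empty or not contained in the universe."""


class TaxonomyError(LirScanError, ValueError):
    """Invalid taxonomy query or malformed species list."""


class FixtureError(LirScanError, ValueError):
    """A synthetic-fixture specification is internally inconsistent."""


class FileFormatError(LirScanError, ValueError):
    """A malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
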