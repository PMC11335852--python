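"""Exception hierarchy shared across the package."""


class GroundvecError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GroundvecError):
    """A file does not conform to its expected text dialect."""


class EmptyInputError(GroundvecError):
    """An input that must be nonempty is empty."""


class MissingReferenceError(GroundvecError):
    """A record refers to an identifier that cannot be resolved."""


class VocabularyError(GroundvecError, KeyError):
    """A word is absent from an embedding table or vocabulary."""


class ShapeError(GroundvecError, ValueError):
    """Array dimensions are inconsistent with the operation's contract."""


class DegenerateInputError(GroundvecError, ValueError):
    """Input is numerically degenerate (zero vector, constant scores, ...)."""


class CoverageError(GroundvecError):
    """Too few scorable items remain to compute a statistic."""
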