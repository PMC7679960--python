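"""Exception hierarchy shared across the package.

Every error a user can trigger through bad input derives from
:class:`ConsmutError`, so the CLI can catch one type and print a one-line
diagnostic instead of a stack trace.
"""


class ConsmutError(Exception):
    """Base class for all user-facing errors."""


class RaggedAlignmentError(ConsmutError):
    """Alignment records have unequal lengths."""


class DuplicateIdError(ConsmutError):
    """Two records in one alignment share an identifier."""


class AlphabetError(ConsmutError):
    """A residue character outside the accepted alphabet."""


class UnknownReferenceError(ConsmutError):
    """The requested reference id is not in the alignment."""


class EmptyColumnError(ConsmutError):
    """An all-gap column was used where a residue distribution is required."""


class MaskError(ConsmutError):
    """Malformed or out-of-range region mask."""


class ReferenceMismatchError(ConsmutError):
    """A mutation's stated wild-type residue disagrees with the reference."""


class DuplicateMutationError(ConsmutError):
    """Two mutations target the same reference position."""


class NotationError(ConsmutError):
    """A mutation string does not parse as wtPOSnew (e.g. ``V123L``)."""


class EmptyPanelError(ConsmutError):
    """A panel report was requested for an empty construct list."""


class ConfigError(ConsmutError):
    """Invalid synthetic-MSA or run configuration."""
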