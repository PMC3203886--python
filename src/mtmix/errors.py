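"""Exception and warning types shared across the package."""


class MtmixError(Exception):
    """Base class for all package-specific errors."""


class ProfileFormatError(MtmixError, ValueError):
    """A profile or stain token does not match the position-list grammar."""


class PositionRangeError(MtmixError, ValueError):
    """A variant position falls outside the declared sequence range."""


class DuplicatePositionError(MtmixError, ValueError):
    """The same position occurs more than once in a profile."""


class DatabaseError(MtmixError, ValueError):
    """A haplotype database file could not be read."""


class EmptyDatabaseError(DatabaseError):
    """The database file contains no profile rows."""


class ProfileNotFoundError(MtmixError, KeyError):
    """Frequency lookup for a profile absent from the database (ERROR policy)."""


class DegenerateModelError(MtmixError, ValueError):
    """The two contributor profiles are identical over the model sites, so the
    mixture fraction is unidentifiable."""


class ParameterError(MtmixError, ValueError):
    """An operation was called with an out-of-domain parameter."""


class NormalizationError(MtmixError, ValueError):
    """A frequency vector does not sum to one."""


class ReferenceMismatchWarning(UserWarning):
    """An IUPAC ambiguity code is inconsistent with the rCRS base at that
    position (neither decoded base equals the reference base)."""
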