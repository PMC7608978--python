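"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`ColocError`; the CLI
maps subclasses onto distinct exit codes.
"""


class ColocError(Exception):
    """Base class for all sscoloc errors."""


class ConfigurationError(ColocError):
    """A required column mapping or option is missing or inconsistent."""


class ParseError(ColocError):
    """A token or file line could not be parsed."""


class EmptyInputError(ColocError):
    """No valid rows survived parsing/validation."""


class RegionError(ColocError):
    """Region coordinates are malformed (start > end, bad chromosome)."""


class RegionTooLargeError(RegionError):
    """Region span exceeds the 2 Mbp cap."""


class NoOverlapError(ColocError):
    """Variant intersection across datasets/LD is empty."""


class FormatError(ColocError):
    """A matrix or file does not match its expected dialect."""


class AlignmentError(ColocError):
    """Dimensions or builds of two inputs do not agree."""


class NoLeadSnpError(ColocError):
    """No dataset variant is present in the LD panel."""


class DegenerateError(ColocError):
    """A statistic is undefined for the given input (all-zero weights, ...)."""


class DomainError(ColocError):
    """A numeric argument is outside its mathematical domain."""


class UndefinedEntryError(ColocError):
    """A pairwise LD entry has fewer than two complete observations."""
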