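"""Exception hierarchy for capsidprof.

Every error raised by the library derives from :class:`CapsidProfError`,
so callers (and the CLI) can catch one type and report a one-line message.
"""


class CapsidProfError(Exception):
    """Base class for all capsidprof errors."""


class InputError(CapsidProfError):
    """Invalid argument, missing entity, or malformed input content."""


class FormatError(InputError):
    """A structure or table file could not be parsed under its format."""


class DegenerateGeometryError(CapsidProfError):
    """Coincident Cα pair: the inverse-square contact sum is singular."""


class DegenerateProfileError(CapsidProfError):
    """A profile is constant (or too short) and cannot be z-normalized."""


class MappingError(CapsidProfError):
    """Conservation sites disagree with structure residues beyond tolerance."""


class InsufficientOverlapError(CapsidProfError):
    """Fewer than 3 residues shared between two profiles."""


class GenerationError(CapsidProfError):
    """Synthetic structure generation could not satisfy its constraints."""


class BatchError(CapsidProfError):
    """Every job in a batch failed."""
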