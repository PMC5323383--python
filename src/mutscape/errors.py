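"""Exception hierarchy shared across the package.

Every error raised by mutscape derives from :class:`MutscapeError`, so
pipeline code can distinguish our domain failures from programming errors.
"""


class MutscapeError(Exception):
    """Base class for all mutscape errors."""


class FormatError(MutscapeError):
    """An input file does not conform to its declared format."""


class LabelError(MutscapeError):
    """A sequence is missing from, or inconsistent in, the group-label file."""


class ReferenceMappingError(MutscapeError):
    """A residue or position cannot be resolved in the reference numbering."""


class CorrespondenceError(MutscapeError):
    """Two poses do not share an identical atom-label set."""


class DegenerateInputError(MutscapeError):
    """The input is too degenerate for the requested computation."""


class ComparisonError(MutscapeError):
    """A wild-type/mutant comparison cannot be carried out (e.g. no group III)."""


class ConfigError(MutscapeError):
    """A configuration file or parameter set is invalid."""
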