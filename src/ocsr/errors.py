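"""Exception hierarchy for the recognition pipeline.

Each pipeline failure mode gets its own class so the CLI can map them to
distinct exit codes.
"""


class OcsrError(Exception):
    """Base class for all recognition errors."""

    exit_code = 1


class UnreadableImageError(OcsrError):
    """The input file could not be opened or decoded as an image."""

    exit_code = 2


class BlankImageError(OcsrError):
    """The input image contains no ink pixels after binarization."""

    exit_code = 3


class EmptyGraphError(OcsrError):
    """Recognition finished but no molecule graph could be assembled."""

    exit_code = 4


class MolfileError(OcsrError):
    """The molecule graph cannot be serialized (e.g. V2000 atom limit)."""

    exit_code = 5
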