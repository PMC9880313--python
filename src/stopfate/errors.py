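"""Exception hierarchy.

Every failure mode a caller may want to catch separately gets its own type;
the CLI maps these onto per-variant error columns instead of aborting a run.
"""


class StopfateError(Exception):
    """Base class for all package errors."""


class FixtureError(StopfateError):
    """Malformed fixture JSON (missing/ill-typed field)."""


class ValidationError(StopfateError):
    """A domain invariant is violated (e.g. CDS length not divisible by 3)."""


class NotFoundError(StopfateError):
    """Requested transcript absent from the annotation source."""


class DomainError(StopfateError):
    """Coordinate outside its legal range."""


class HgvsParseError(StopfateError):
    """Malformed HGVS expression.

    ``offset`` is the 0-based character position at which parsing failed,
    relative to the string after any reference prefix was split off.
    """

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class UnsupportedRegionError(StopfateError):
    """Syntactically valid HGVS that addresses a region outside the CDS
    (intronic offsets, 5'/3' UTR positions) or a span outside the CDS.

    Distinct from a parse error so callers can report rather than
    misannotate."""


class ReferenceMismatchError(StopfateError):
    """Variant's stated reference bases disagree with the transcript."""

    def __init__(self, message: str, expected: str, found: str):
        super().__init__(message)
        self.expected = expected
        self.found = found


class ScanAbortedError(StopfateError):
    """Translation scan hit a codon containing N; refusing to guess."""


class NoBoundaryError(StopfateError):
    """A rule-boundary sweep never observed the named rule firing."""
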