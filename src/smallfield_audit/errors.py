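"""Exception hierarchy for the audit pipeline.

Every failure mode of the pipeline raises a named subclass of
:class:`AuditError` so that callers (and the CLI's ``--keep-going`` mode)
can attribute a failure to an institution/file without string matching.
"""

from __future__ import annotations


class AuditError(Exception):
    """Base class for all errors raised by smallfield_audit."""


# ---------------------------------------------------------------- scan_io
class ParseError(AuditError):
    """Malformed file content; carries the offending path and line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ValidationError(AuditError):
    """A domain-type invariant was violated; message names the field."""


# ----------------------------------------------------------- scan_metrics
class DegenerateCurveError(AuditError):
    """Curve span too short for the requested resampling step."""


class AmbiguousPeakError(AuditError):
    """Two or more non-adjacent samples tie for the PDD maximum."""


class OutOfRangeError(AuditError):
    """A required position (e.g. the central axis) lies outside the scan."""


class CrossingNotFoundError(AuditError):
    """A requested dose level is never crossed on the requested side."""


class MultipleCrossingError(AuditError):
    """Noise produced well-separated repeated crossings of one level."""


class IncompatibleCurveError(AuditError):
    """Curves differ in axis/energy/filter/field size or do not overlap."""


class NoPenumbraSamplesError(AuditError):
    """No evaluated sample falls in the 20-80% penumbra region."""


# --------------------------------------------------------- output_factors
class MissingReferenceError(AuditError):
    """Output-factor series lacks the 100 mm reference entry."""


class UnknownDetectorError(AuditError):
    """Correction table has no rows for the requested detector/quality."""


class MissingIntermediateError(AuditError):
    """Correction table lacks the 20 or 40 mm renormalization entries."""


class InsufficientEnsembleError(AuditError):
    """Fewer than three institutions contribute to an ensemble statistic."""


# ------------------------------------------------------------------ stats
class EmptySampleError(AuditError):
    """All paired differences are zero; the signed-rank test is undefined."""


class SampleTooSmallError(AuditError):
    """Too few observations for a nonparametric CI at the requested level."""


class CorrectionMagnitudeWarning(UserWarning):
    """|k - 1| exceeds 5%, beyond the range codes of practice endorse."""
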