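"""Exception hierarchy for the digital atlasing infrastructure.

Every error raised by the package derives from :class:`DAIError` so callers
(and the WPS service layer, which maps errors onto ExceptionReport documents)
can catch a single base class.
"""

from __future__ import annotations


class DAIError(Exception):
    """Base class for all atlasing-infrastructure errors."""

    #: short machine-readable token used in ExceptionReport documents
    code = "DAIError"


# --- registry ---------------------------------------------------------------

class NotFound(DAIError):
    code = "NotFound"


class DuplicateCode(DAIError):
    code = "DuplicateCode"


class DuplicateName(DAIError):
    code = "DuplicateName"


class ValidationError(DAIError):
    """Raised when a record fails validation; carries field-level messages."""

    code = "ValidationError"

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(str(v) for v in self.violations))


class ComplexAxisError(DAIError):
    """Transformation fitting over an SRS with a free-text "complex" axis."""

    code = "ComplexAxisError"


# --- transforms -------------------------------------------------------------

class Underdetermined(DAIError):
    code = "Underdetermined"


class DegenerateConfiguration(DAIError):
    code = "DegenerateConfiguration"


class SingularSystem(DAIError):
    code = "SingularSystem"


class SingularMatrix(DAIError):
    code = "SingularMatrix"


class InvalidLambda(DAIError):
    code = "InvalidLambda"


class DimensionMismatch(DAIError):
    code = "DimensionMismatch"


class SRSMismatch(DAIError):
    code = "SRSMismatch"


class InvalidSampleCount(DAIError):
    code = "InvalidSampleCount"


# --- chain resolution -------------------------------------------------------

class ChainMismatch(DAIError):
    code = "ChainMismatch"


class NoPathFound(DAIError):
    code = "NoPathFound"


class UnknownSRS(DAIError):
    code = "UnknownSRS"


# --- WaxML ------------------------------------------------------------------

class MalformedXML(DAIError):
    code = "MalformedXML"


class MissingSRSName(DAIError):
    code = "MissingSRSName"


class BadCoordinateCount(DAIError):
    code = "BadCoordinateCount"


# --- WPS / hub services -----------------------------------------------------

class MissingService(DAIError):
    code = "MissingService"


class MissingIdentifier(DAIError):
    code = "MissingIdentifier"


class MalformedDataInputs(DAIError):
    code = "MalformedDataInputs"


class UnsupportedAsync(DAIError):
    """Asynchronous WPS execution clauses are parsed but rejected."""

    code = "UnsupportedAsync"


class UnknownProcess(DAIError):
    code = "UnknownProcess"


class NoSegmentation(DAIError):
    code = "NoSegmentation"


# --- registration workflow --------------------------------------------------

class UnreadableImage(DAIError):
    code = "UnreadableImage"


class NonInvertibleOverGrid(DAIError):
    code = "NonInvertibleOverGrid"


class EmptyCollection(DAIError):
    code = "EmptyCollection"


class UnknownTargetSRS(DAIError):
    code = "UnknownTargetSRS"


# --- synthetic fixtures -----------------------------------------------------

class TooManyStructures(DAIError):
    code = "TooManyStructures"
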