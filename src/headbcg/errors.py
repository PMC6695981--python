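"""Exception hierarchy for the head-BCG pipeline.

Every failure mode that the CLI maps to a distinct exit code derives from
:class:`BcgError`.  The ``exit_code`` attribute is stable across releases.
"""

from __future__ import annotations


class BcgError(Exception):
    """Base class for all pipeline errors."""

    exit_code: int = 1


# --- tracking -------------------------------------------------------------

class NoFaceFound(BcgError):
    exit_code = 10


class DegenerateBox(BcgError):
    exit_code = 11


class NoTrackablePoints(BcgError):
    exit_code = 12


class AllPointsLost(BcgError):
    exit_code = 13


# --- cardiac --------------------------------------------------------------

class SignalTooShort(BcgError):
    exit_code = 20


class NyquistViolation(BcgError):
    exit_code = 21


class InsufficientPoints(BcgError):
    exit_code = 22


class EmptyBand(BcgError):
    exit_code = 23


# --- features -------------------------------------------------------------

class EmptySignal(BcgError):
    exit_code = 30


class ZeroBandPower(BcgError):
    exit_code = 31


class TooFewBeats(BcgError):
    exit_code = 32


class AlignmentError(BcgError):
    exit_code = 33


# --- model ----------------------------------------------------------------

class DimensionMismatch(BcgError):
    exit_code = 40


class TooFewSamples(BcgError):
    exit_code = 41


class EmptyModel(BcgError):
    exit_code = 42


class SerializationError(BcgError):
    exit_code = 43


class SchemaMismatch(BcgError):
    exit_code = 44


# --- estimate -------------------------------------------------------------

class EmptyValidation(BcgError):
    exit_code = 50


class TooFewPeaks(BcgError):
    exit_code = 51


# --- evaluate -------------------------------------------------------------

class RecordingTooShort(BcgError):
    exit_code = 60


class LengthMismatch(BcgError):
    exit_code = 61


class DegenerateVariance(BcgError):
    exit_code = 62


class SingleSubject(BcgError):
    exit_code = 63


# --- synthetic ------------------------------------------------------------

class InvalidSpec(BcgError):
    exit_code = 70
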