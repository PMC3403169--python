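"""Quality flags and exception hierarchy shared across the package."""

from __future__ import annotations

import enum


class Flag(str, enum.Enum):
    """Per-peptide quality flags attached to redox-state results.

    Flags annotate results; they never alter the numeric values, which are
    reported unclamped (negative or over-unity fractions are meaningful
    diagnostics of reference-channel underestimation, e.g. pre-lysis
    overoxidation of the control sample).
    """

    #: Free-thiol fraction came out negative (test revox ratio exceeds the
    #: test total ratio).
    NEGATIVE_FREE = "NEGATIVE_FREE"
    #: A channel ratio relative to the control-total reference exceeds 1.
    OVER_UNITY_RATIO = "OVER_UNITY_RATIO"
    #: Peptide carries two or more cysteines; the partition cannot attribute
    #: the redox state to an individual residue.
    MULTI_CYS_AMBIGUOUS = "MULTI_CYS_AMBIGUOUS"
    #: No reporter-area errors were supplied and only one replicate group is
    #: available, so fraction uncertainties are zero by construction.
    NO_ERROR_ESTIMATE = "NO_ERROR_ESTIMATE"
    #: One or more reporter channels required by the design are missing or
    #: the reference channel is zero.
    INCOMPLETE_CHANNELS = "INCOMPLETE_CHANNELS"

    def __str__(self) -> str:  # so ';'.join(flags) prints bare codes
        return self.value


def format_flags(flags) -> str:
    """Render a flag set as a stable semicolon-joined string."""
    return ";".join(sorted(f.value for f in flags))


def parse_flags(text: str) -> frozenset[Flag]:
    if not text:
        return frozenset()
    return frozenset(Flag(tok) for tok in text.split(";") if tok)


class RedoxQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(RedoxQuantError):
    """Invalid input values or an inconsistent channel design."""


class FormatError(RedoxQuantError):
    """Malformed tabular input (missing column, non-numeric field...)."""


class IncompleteChannelsError(RedoxQuantError):
    """Reference channel missing or zero; no ratios can be formed."""
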