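"""Shared helpers: alphabets, rounding, error types."""

from __future__ import annotations

import math

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in input sequences (standard codes plus the unknown code X).
VALID_AA = STANDARD_AA + "X"


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class ConsistencyError(ValueError):
    """Raised when two inputs that must agree (e.g. a composition and its
    catalog) reference each other inconsistently."""


def check_sequence(aa_seq: str, *, name: str = "sequence") -> str:
    """Validate an amino-acid string against the allowed alphabet.

    Returns the upper-cased sequence; raises :class:`ValidationError` on an
    empty string or a residue outside the 20 standard codes plus X.
    """
    if not aa_seq:
        raise ValidationError(f"{name} is empty")
    seq = aa_seq.upper()
    bad = set(seq) - set(VALID_AA)
    if bad:
        raise ValidationError(
            f"{name} contains invalid residue(s): {''.join(sorted(bad))}"
        )
    return seq


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up.

    Used for the printed clone-abundance percentages, which follow the
    half-up convention rather than banker's rounding.
    """
    return int(math.floor(x + 0.5))
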