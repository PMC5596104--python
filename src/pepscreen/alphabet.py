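"""Amino-acid alphabet validation shared across the package.

Only the 20 standard one-letter codes are accepted. Ambiguity and
non-standard codes (B, Z, X, U, O, J) are rejected rather than guessed:
a digestion-resistance call on a sequence containing an unknown residue
would otherwise silently pass.
"""

from __future__ import annotations

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """Raised for an empty sequence or a non-standard residue."""


def validate_sequence(sequence: str, *, what: str = "sequence") -> str:
    """Check that *sequence* is non-empty uppercase standard amino acids.

    Returns the sequence unchanged so it can be used inline. Raises
    :class:`SequenceError` naming the offending residue and its 1-based
    position otherwise.
    """
    if not isinstance(sequence, str) or not sequence:
        raise SequenceError(f"{what} must be a non-empty string")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in AMINO_ACIDS:
            raise SequenceError(
                f"{what} contains non-standard residue {aa!r} at position {pos}; "
                "only the 20 standard one-letter codes are accepted"
            )
    return sequence


def validate_residue_codes(codes, *, what: str = "residue set") -> frozenset:
    """Validate an iterable of one-letter residue codes, returning a frozenset."""
    out = frozenset(codes)
    bad = sorted(c for c in out if c not in AMINO_ACIDS)
    if bad:
        raise SequenceError(f"{what} contains non-standard residue code(s): {', '.join(map(repr, bad))}")
    return out
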