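"""Candidate encrypted-peptide enumeration and filtering.

Bioactive peptides hidden ("encrypted") inside larger bacterial proteins
need not coincide with natural digestion boundaries, so the default
mining mode slides a window of 10-19 residues (the length span of the
synthesized peptide set) over each source protein. Digestion-fragment
mining is available as an alternative mode for workflows that only
consider proteolytic products. Each candidate is annotated with its
endoprotease-resistance call; the screening filter keeps candidates
with no internal cleavage site for the configured cocktail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .alphabet import validate_sequence
from .proteolysis import ProteaseCocktail, digest, intestinal_cocktail, is_resistant

__all__ = [
    "PeptideCandidate",
    "MiningConfig",
    "enumerate_windows",
    "mine_peptides",
    "CANDIDATE_COLUMNS",
]

CANDIDATE_COLUMNS = [
    "candidate_id",
    "sequence",
    "parent_id",
    "start",
    "end",
    "resistant",
    "offending_sites",
]


@dataclass(frozen=True)
class PeptideCandidate:
    """A subsequence of a source protein with provenance coordinates."""

    sequence: str
    parent_id: str
    start: int
    end: int
    resistant: Optional[bool] = None
    bioactivity_score: Optional[float] = None
    best_reference: Optional[str] = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"candidate {self.parent_id}:{self.start}-{self.end}: coordinates span "
                f"{self.end - self.start + 1} residues but sequence has {len(self.sequence)}"
            )


@dataclass(frozen=True)
class MiningConfig:
    """Length bounds, cocktail and filter switches for :func:`mine_peptides`.

    Default length bounds 10-19 residues; ``mode`` is ``"windows"``
    (every contiguous subsequence) or ``"fragments"`` (digestion
    products of the cocktail, with ``fragment_missed_cleavages``).
    """

    min_length: int = 10
    max_length: int = 19
    cocktail: ProteaseCocktail = field(default_factory=intestinal_cocktail)
    require_resistance: bool = False
    deduplicate: bool = False
    mode: str = "windows"
    fragment_missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.min_length <= self.max_length):
            raise ValueError(
                f"length bounds must satisfy 1 <= min <= max, got "
                f"[{self.min_length}, {self.max_length}]"
            )
        if self.mode not in ("windows", "fragments"):
            raise ValueError(f"mode must be 'windows' or 'fragments', got {self.mode!r}")


def enumerate_windows(sequence: str, min_length: int, max_length: int) -> list:
    """All contiguous subsequences with length in ``[min_length, max_length]``.

    Returned as ``(start, end, subsequence)`` triples with 1-based
    inclusive coordinates, ordered by start then length. A protein of
    length L contributes ``max(0, L - k + 1)`` windows of length k.
    """
    if not (1 <= min_length <= max_length):
        raise ValueError(
            f"length bounds must satisfy 1 <= min <= max, got [{min_length}, {max_length}]"
        )
    validate_sequence(sequence)
    L = len(sequence)
    out = []
    for start in range(1, L + 1):
        for k in range(min_length, max_length + 1):
            end = start + k - 1
            if end > L:
                break
            out.append((start, end, sequence[start - 1 : end]))
    return out


def _format_offending(offending: dict) -> str:
    parts = [
        f"{name}:{','.join(map(str, sites))}" for name, sites in offending.items() if sites
    ]
    return ";".join(parts)


def mine_peptides(proteome: Iterable, config: MiningConfig = MiningConfig()) -> pd.DataFrame:
    """Enumerate, annotate and filter candidates from a proteome.

    *proteome* is an iterable of ``(protein_id, sequence)`` pairs (as
    returned by :func:`pepscreen.io.read_fasta`) or a mapping. Records
    must have unique ids and the proteome must be non-empty. Each window
    (or digestion fragment) within the length bounds becomes one row,
    annotated with its resistance call under ``config.cocktail``; with
    ``require_resistance`` the non-resistant rows are dropped, and with
    ``deduplicate`` one row is kept per distinct sequence with all
    provenance entries joined into ``candidate_id``-style tokens.
    """
    if isinstance(proteome, dict):
        records = list(proteome.items())
    else:
        records = [(str(rid), str(seq)) for rid, seq in proteome]
    if not records:
        raise ValueError("proteome is empty: at least one protein record is required")
    ids = [rid for rid, _ in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate protein id(s): {', '.join(dupes)}")

    rows = []
    for rid, seq in records:
        validate_sequence(seq, what=f"protein {rid}")
        if config.mode == "windows":
            pieces = enumerate_windows(seq, config.min_length, config.max_length)
        else:
            result = digest(seq, config.cocktail, config.fragment_missed_cleavages)
            pieces = [
                (f.start, f.end, f.sequence)
                for f in result.fragments
                if config.min_length <= len(f.sequence) <= config.max_length
            ]
        for start, end, sub in pieces:
            flag, offending = is_resistant(sub, config.cocktail)
            if config.require_resistance and not flag:
                continue
            rows.append(
                {
                    "candidate_id": f"{rid}:{start}-{end}",
                    "sequence": sub,
                    "parent_id": rid,
                    "start": start,
                    "end": end,
                    "resistant": flag,
                    "offending_sites": _format_offending(offending),
                }
            )

    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    if config.deduplicate and not df.empty:
        grouped = []
        for seq, grp in df.groupby("sequence", sort=False):
            first = grp.iloc[0].to_dict()
            first["candidate_id"] = ";".join(grp["candidate_id"])
            grouped.append(first)
        df = pd.DataFrame(grouped, columns=CANDIDATE_COLUMNS)
        df = df.sort_values(["parent_id", "start", "end"], kind="stable").reset_index(drop=True)
    return df
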