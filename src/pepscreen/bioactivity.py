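"""Similarity-based bioactivity scoring against a curated reference set.

A candidate peptide's bioactivity score is the query-normalized identity
of its best local alignment to any peptide in a curated set of known
immunomodulatory peptides:

    percent = 100 * identities / len(query),  maximized over references.

Normalizing by query length (rather than alignment length) means a
short spurious match on a long query scores low, and a query present
verbatim in the reference set scores exactly 100. Alignment uses
affine-gap Smith-Waterman (identity matrix +1/-1 by default, gap open
-2, gap extend -1 per additional gapped residue); a substitution matrix
(e.g. BLOSUM62 from ``Bio.Align.substitution_matrices``) may be passed
for the raw score, while identities always count exact residue matches.

Ties are broken deterministically: among maximal-scoring local
alignments, the one with the smallest query start wins, then smallest
reference start, then fewest alignment columns, then most identities.
Alignments never start or end with a gap, and a gap in one sequence is
never immediately followed by a gap in the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .alphabet import validate_sequence

__all__ = [
    "ReferencePeptide",
    "AlignmentParams",
    "AlignmentOutcome",
    "BioactivityScore",
    "local_align",
    "score_bioactivity",
    "rank_candidates",
]


@dataclass(frozen=True)
class ReferencePeptide:
    """One curated immunomodulatory peptide used as a scoring target."""

    ref_id: str
    sequence: str
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.ref_id:
            raise ValueError("ref_id must be non-empty")
        validate_sequence(self.sequence, what=f"reference {self.ref_id}")


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for :func:`local_align`.

    ``gap_open`` is the cost of the first residue of a gap run and
    ``gap_extend`` the cost of each additional one. ``matrix``, if
    given, is a substitution matrix indexable as ``matrix[a, b]`` (e.g.
    a Biopython ``substitution_matrices`` array) and overrides
    match/mismatch for the raw score.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    matrix: Optional[object] = None

    def __post_init__(self) -> None:
        if self.matrix is None and self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap penalties must be <= 0")

    def substitution(self, a: str, b: str) -> float:
        if self.matrix is not None:
            return float(self.matrix[a, b])
        return self.match if a == b else self.mismatch


@dataclass(frozen=True)
class AlignmentOutcome:
    """Best local alignment summary: raw score, identities and spans.

    Spans are 1-based inclusive ``(start, end)`` intervals; they are
    ``None`` for the empty alignment (no positive-scoring pair).
    """

    raw_score: float
    identities: int
    query_span: Optional[tuple] = None
    ref_span: Optional[tuple] = None


@dataclass(frozen=True)
class BioactivityScore:
    """Query-normalized identity percent and the best-scoring reference."""

    percent: float
    best_reference: str
    outcome: AlignmentOutcome


_EMPTY = AlignmentOutcome(raw_score=0.0, identities=0)

# DP cell payload: (score, qstart, rstart, ncols, identities). The
# tie-break key (qstart, rstart, ncols, -identities) is minimized among
# equal-score candidates; lexicographic order is preserved under path
# extension, so greedy per-cell selection yields the global tie-break.


def _better(a, b):
    """Pick the higher-scoring cell payload, breaking ties on the key."""
    if b is None:
        return a
    if a is None:
        return b
    if a[0] != b[0]:
        return a if a[0] > b[0] else b
    ka = (a[1], a[2], a[3], -a[4])
    kb = (b[1], b[2], b[3], -b[4])
    return a if ka <= kb else b


def local_align(query: str, reference: str, params: AlignmentParams = AlignmentParams()) -> AlignmentOutcome:
    """Maximal-scoring affine-gap local alignment of *query* vs *reference*.

    Returns the empty :class:`AlignmentOutcome` (score 0) when no local
    alignment has positive score. Deterministic under the tie-break
    documented in the module docstring.
    """
    validate_sequence(query, what="query")
    validate_sequence(reference, what="reference")
    n, m = len(query), len(reference)
    open_, ext = params.gap_open, params.gap_extend

    # H: ends with q[i] aligned to r[j]; E: ends with gap in reference
    # (consumes query); F: ends with gap in query (consumes reference).
    H = [[None] * (m + 1) for _ in range(n + 1)]
    E = [[None] * (m + 1) for _ in range(n + 1)]
    F = [[None] * (m + 1) for _ in range(n + 1)]
    best = None
    best_end = None

    for i in range(1, n + 1):
        qi = query[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Ei1 = E[i], E[i - 1]
        Fi, Fi1 = F[i], F[i - 1]
        for j in range(1, m + 1):
            rj = reference[j - 1]
            s = params.substitution(qi, rj)
            ident = 1 if qi == rj else 0

            # States with negative running score are never part of an
            # optimal local alignment (trimming the prefix scores
            # strictly higher), so they are pruned to None; zero-score
            # states are kept because a continuation through them can
            # tie the trimmed alignment and win on query start.
            cand = (s, i, j, 1, ident)  # fresh local start at (i, j)
            for prev in (Hi1[j - 1], Ei1[j - 1], Fi1[j - 1]):
                if prev is not None:
                    cand = _better(
                        cand, (prev[0] + s, prev[1], prev[2], prev[3] + 1, prev[4] + ident)
                    )
            Hi[j] = cand if cand[0] >= 0 else None

            e = None
            prev = Hi1[j]
            if prev is not None:
                e = (prev[0] + open_, prev[1], prev[2], prev[3] + 1, prev[4])
            prev = Ei1[j]
            if prev is not None:
                e = _better(e, (prev[0] + ext, prev[1], prev[2], prev[3] + 1, prev[4]))
            Ei[j] = e if e is not None and e[0] >= 0 else None

            f = None
            prev = Hi[j - 1]
            if prev is not None:
                f = (prev[0] + open_, prev[1], prev[2], prev[3] + 1, prev[4])
            prev = Fi[j - 1]
            if prev is not None:
                f = _better(f, (prev[0] + ext, prev[1], prev[2], prev[3] + 1, prev[4]))
            Fi[j] = f if f is not None and f[0] >= 0 else None

            # local alignments end on an aligned pair, i.e. in state H
            if cand[0] > 0:
                merged = _better(best, cand)
                if merged is not best:
                    best, best_end = merged, (i, j)

    if best is None or best[0] <= 0:
        return _EMPTY
    score, qstart, rstart, _, identities = best
    qend, rend = best_end
    return AlignmentOutcome(
        raw_score=float(score),
        identities=int(identities),
        query_span=(qstart, qend),
        ref_span=(rstart, rend),
    )


def score_bioactivity(
    query: str,
    references: Sequence[ReferencePeptide],
    params: AlignmentParams = AlignmentParams(),
) -> BioactivityScore:
    """Best query-normalized identity percent over a reference set.

    ``percent = 100 * identities / len(query)`` of the best local
    alignment; ties between references go to the lexicographically
    smallest ``ref_id``. An empty reference set is an error, never a
    silent zero.
    """
    refs = list(references)
    if not refs:
        raise ValueError("reference set is empty; scoring requires at least one reference peptide")
    validate_sequence(query, what="query")
    best: Optional[BioactivityScore] = None
    for ref in sorted(refs, key=lambda r: r.ref_id):
        outcome = local_align(query, ref.sequence, params)
        percent = min(100.0, 100.0 * outcome.identities / len(query))
        if best is None or percent > best.percent:
            best = BioactivityScore(percent=percent, best_reference=ref.ref_id, outcome=outcome)
    return best


def rank_candidates(
    candidates: pd.DataFrame,
    references: Sequence[ReferencePeptide],
    params: AlignmentParams = AlignmentParams(),
    threshold_percent: Optional[float] = None,
) -> pd.DataFrame:
    """Score and rank a candidate table against the reference set.

    *candidates* is a table with at least ``candidate_id`` and
    ``sequence`` columns (the mining output). Rows gain ``percent``,
    ``best_reference``, ``identities``, ``query_span`` and ``ref_span``
    columns and are sorted by percent descending (ties: longer query
    first, then candidate_id); rows below *threshold_percent* are
    dropped when a threshold is given. An empty candidate table yields
    an empty ranked table without error.
    """
    refs = list(references)
    if not refs:
        raise ValueError("reference set is empty; scoring requires at least one reference peptide")
    out = candidates.copy()
    extra = ["percent", "best_reference", "identities", "query_span", "ref_span"]
    if out.empty:
        for col in extra:
            out[col] = pd.Series(dtype=object)
        return out.reset_index(drop=True)

    cache: dict = {}
    records = []
    for seq in out["sequence"]:
        if seq not in cache:
            cache[seq] = score_bioactivity(seq, refs, params)
        records.append(cache[seq])
    out["percent"] = [round(s.percent, 6) for s in records]
    out["best_reference"] = [s.best_reference for s in records]
    out["identities"] = [s.outcome.identities for s in records]
    out["query_span"] = [
        "" if s.outcome.query_span is None else f"{s.outcome.query_span[0]}-{s.outcome.query_span[1]}"
        for s in records
    ]
    out["ref_span"] = [
        "" if s.outcome.ref_span is None else f"{s.outcome.ref_span[0]}-{s.outcome.ref_span[1]}"
        for s in records
    ]
    if threshold_percent is not None:
        out = out[out["percent"] >= threshold_percent]
    out = out.assign(_len=out["sequence"].str.len())
    out = out.sort_values(
        ["percent", "_len", "candidate_id"], ascending=[False, False, True], kind="stable"
    ).drop(columns="_len")
    return out.reset_index(drop=True)
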