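"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity by the most transparent route
available — position-by-position scanning, full-matrix DP with explicit
backtrack enumeration — independently of the library code paths it
checks.
"""

from __future__ import annotations

import math

NEG = float("-inf")


def scan_cleavage_sites(sequence: str, p1: set, blockers: set) -> list:
    """Naive position-by-position cut-site scan."""
    sites = []
    for i in range(1, len(sequence)):  # cut between residues i and i+1 (1-based)
        if sequence[i - 1] in p1 and sequence[i] not in blockers:
            sites.append(i)
    return sites


def oracle_local_align(
    query: str,
    reference: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
    path_cap: int = 200_000,
):
    """Affine-gap Smith-Waterman by full-matrix DP with explicit
    enumeration of every optimal traceback.

    Returns ``(score, identities, query_span, ref_span)`` for the
    alignment selected by the tie-break: smallest query start, then
    smallest reference start, then fewest columns, then most
    identities, then smallest end coordinates. Spans are None for the
    empty alignment. Alignments start and end on an aligned pair and a
    gap in one sequence never directly follows a gap in the other.
    """
    n, m = len(query), len(reference)

    def sub(i, j):
        return match if query[i - 1] == reference[j - 1] else mismatch

    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            H[i][j] = sub(i, j) + max(0.0, H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)

    best = max((H[i][j] for i in range(1, n + 1) for j in range(1, m + 1)), default=NEG)
    if best <= 0:
        return 0.0, 0, None, None

    memo = {}
    counter = [0]

    def paths(state, i, j):
        """All (qstart, rstart, ncols, identities) prefixes ending at state."""
        key = (state, i, j)
        if key in memo:
            return memo[key]
        counter[0] += 1
        if counter[0] > path_cap:
            raise RuntimeError("oracle path enumeration exceeded cap")
        out = []
        if state == "H":
            s = sub(i, j)
            ident = 1 if query[i - 1] == reference[j - 1] else 0
            prev_best = max(0.0, H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            if prev_best == 0.0:
                out.append((i, j, 1, ident))
            for st, val in (("H", H[i - 1][j - 1]), ("E", E[i - 1][j - 1]), ("F", F[i - 1][j - 1])):
                if val == prev_best and val > NEG and val >= 0.0:
                    for qs, rs, nc, ids in paths(st, i - 1, j - 1):
                        out.append((qs, rs, nc + 1, ids + ident))
        elif state == "E":
            val = E[i][j]
            if H[i - 1][j] + gap_open == val:
                for qs, rs, nc, ids in paths("H", i - 1, j):
                    out.append((qs, rs, nc + 1, ids))
            if E[i - 1][j] + gap_extend == val:
                for qs, rs, nc, ids in paths("E", i - 1, j):
                    out.append((qs, rs, nc + 1, ids))
        else:
            val = F[i][j]
            if H[i][j - 1] + gap_open == val:
                for qs, rs, nc, ids in paths("H", i, j - 1):
                    out.append((qs, rs, nc + 1, ids))
            if F[i][j - 1] + gap_extend == val:
                for qs, rs, nc, ids in paths("F", i, j - 1):
                    out.append((qs, rs, nc + 1, ids))
        memo[key] = out
        return out

    candidates = []
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if H[i][j] == best:
                for qs, rs, nc, ids in paths("H", i, j):
                    candidates.append((qs, rs, nc, -ids, i, j))
    qs, rs, nc, neg_ids, qend, rend = min(candidates)
    return best, -neg_ids, (qs, qend), (rs, rend)


def exhaustive_mwu_p(a, b) -> float:
    """Two-sided permutation p-value by direct enumeration of label
    assignments, using midranks and |U - n1*n2/2| extremeness."""
    import itertools

    from scipy.stats import rankdata

    pooled = list(a) + list(b)
    ranks = rankdata(pooled)
    n1, n = len(a), len(pooled)
    mu = n1 * (n - n1) / 2.0
    d_obs = abs(sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0 - mu)
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        u = sum(ranks[k] for k in combo) - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= d_obs - 1e-9:
            count += 1
    return count / total
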