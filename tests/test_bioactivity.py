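"""Local alignment and reference-set bioactivity scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepscreen.bioactivity import (
    AlignmentParams,
    ReferencePeptide,
    local_align,
    rank_candidates,
    score_bioactivity,
)

short_seqs = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12)
low_alpha_seqs = st.text(alphabet="ACDE", min_size=1, max_size=10)


class TestLocalAlign:
    def test_substring_match(self):
        outcome = local_align("PEPTIDE", "TIDE")
        assert outcome.raw_score == 4
        assert outcome.identities == 4
        assert outcome.query_span == (4, 7)
        assert outcome.ref_span == (1, 4)

    def test_self_match(self):
        outcome = local_align("AAAA", "AAAA")
        assert outcome.raw_score == 4 and outcome.identities == 4
        assert outcome.query_span == (1, 4)

    def test_disjoint_alphabets_empty_alignment(self):
        outcome = local_align("AAAA", "CCCC")
        assert outcome.raw_score == 0 and outcome.identities == 0
        assert outcome.query_span is None and outcome.ref_span is None

    def test_gapped_alignment_beats_split_matches(self):
        # ACDEFGH vs ACDFGH: one deletion bridges two exact blocks.
        outcome = local_align("ACDEFGH", "ACDFGH")
        assert outcome.raw_score == 4  # 6 matches - gap open 2
        assert outcome.identities == 6

    def test_equal_score_tie_prefers_shorter_alignment(self):
        # ACDEFG vs ACDFG: the 6-column gapped alignment (5 matches -
        # gap open 2) ties the plain ACD prefix at score 3; the
        # tie-break keeps the shorter alignment.
        outcome = local_align("ACDEFG", "ACDFG")
        assert outcome.raw_score == 3
        assert outcome.identities == 3
        assert outcome.query_span == (1, 3)

    def test_tie_break_prefers_smallest_query_start(self):
        outcome = local_align("ACAC", "AC")
        assert outcome.query_span == (1, 2)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AlignmentParams(match=0.0)
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=1.0)

    def test_invalid_residues_rejected(self):
        with pytest.raises(ValueError):
            local_align("ACDX", "ACD")

    @given(q=short_seqs, r=short_seqs)
    def test_agrees_with_backtrack_enumeration_oracle(self, q, r):
        from oracles import oracle_local_align

        expected = oracle_local_align(q, r)
        outcome = local_align(q, r)
        assert (outcome.raw_score, outcome.identities, outcome.query_span, outcome.ref_span) == expected

    @given(q=low_alpha_seqs, r=low_alpha_seqs)
    def test_agrees_with_oracle_on_repetitive_sequences(self, q, r):
        from oracles import oracle_local_align

        expected = oracle_local_align(q, r)
        outcome = local_align(q, r)
        assert (outcome.raw_score, outcome.identities, outcome.query_span, outcome.ref_span) == expected

    @given(q=short_seqs, r=short_seqs)
    def test_score_agrees_with_biopython(self, q, r):
        from Bio import Align

        aligner = Align.PairwiseAligner(
            mode="local", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-1,
        )
        outcome = local_align(q, r)
        assert outcome.raw_score == max(0.0, aligner.score(q, r))

    def test_substitution_matrix_scoring(self):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        params = AlignmentParams(matrix=blosum, gap_open=-11, gap_extend=-1)
        outcome = local_align("PEPTIDE", "PEPTIDE", params)
        expected = sum(blosum[a, a] for a in "PEPTIDE")
        assert outcome.raw_score == expected
        assert outcome.identities == 7


class TestScoreBioactivity:
    REFS = [
        ReferencePeptide("R1", "TIDE"),
        ReferencePeptide("R2", "PEPTIDE"),
        ReferencePeptide("R3", "WWWW"),
    ]

    def test_verbatim_query_scores_100(self):
        score = score_bioactivity("PEPTIDE", self.REFS)
        assert score.percent == 100.0
        assert score.best_reference == "R2"

    def test_partial_match_normalized_by_query_length(self):
        score = score_bioactivity("PEPTIDE", [ReferencePeptide("R1", "TIDE")])
        assert score.percent == pytest.approx(100 * 4 / 7)

    def test_disjoint_reference_scores_zero(self):
        score = score_bioactivity("AAAA", [ReferencePeptide("R1", "CCCC")])
        assert score.percent == 0.0

    def test_empty_reference_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            score_bioactivity("PEPTIDE", [])

    def test_ties_go_to_lexicographically_smallest_ref(self):
        refs = [ReferencePeptide("B", "TIDE"), ReferencePeptide("A", "TIDE")]
        assert score_bioactivity("TIDE", refs).best_reference == "A"

    @given(q=short_seqs)
    def test_adding_query_to_references_gives_100(self, q):
        refs = [ReferencePeptide("R1", "WWWW"), ReferencePeptide("SELF", q)]
        assert score_bioactivity(q, refs).percent == 100.0

    @given(q=short_seqs, extra=short_seqs)
    def test_monotone_in_reference_set(self, q, extra):
        base = [ReferencePeptide("R1", "ACDEFG")]
        bigger = base + [ReferencePeptide("R2", extra)]
        assert score_bioactivity(q, bigger).percent >= score_bioactivity(q, base).percent


class TestRankCandidates:
    def _table(self, seqs):
        return pd.DataFrame(
            {"candidate_id": [f"c{i}" for i in range(len(seqs))], "sequence": seqs}
        )

    def test_ranking_and_threshold(self):
        refs = [ReferencePeptide("R1", "ACDEFGHIKL")]
        table = self._table(["ACDEFGHIKL", "ACDEFAAAAA", "WWWWWWWWWW"])
        ranked = rank_candidates(table, refs)
        assert list(ranked["percent"]) == sorted(ranked["percent"], reverse=True)
        assert ranked.iloc[0]["sequence"] == "ACDEFGHIKL"
        only_exact = rank_candidates(table, refs, threshold_percent=100.0)
        assert list(only_exact["sequence"]) == ["ACDEFGHIKL"]

    def test_empty_candidates_yield_empty_table(self):
        ranked = rank_candidates(self._table([]), [ReferencePeptide("R1", "ACDE")])
        assert ranked.empty
        assert "percent" in ranked.columns

    def test_deterministic_byte_identical(self):
        refs = [ReferencePeptide("R1", "ACDEFGHIKL"), ReferencePeptide("R2", "MKTAYIAKQR")]
        table = self._table(["ACDEFGHIKL", "MKTAYIAKQR", "ACDEFAAAAA"])
        a = rank_candidates(table, refs).to_csv(sep="\t", index=False)
        b = rank_candidates(table, refs).to_csv(sep="\t", index=False)
        assert a == b
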