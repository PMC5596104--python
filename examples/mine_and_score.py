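"""Mine candidate encrypted peptides from a toy proteome and score them.

Slides 10-16 residue windows over two proteins, keeps the candidates
with no internal cleavage site for trypsin, and ranks them by
query-normalized identity against a small reference set. A candidate
identical to a reference scores 100 and ranks first.
"""

from pepscreen.bioactivity import ReferencePeptide, rank_candidates
from pepscreen.mining import MiningConfig, mine_peptides
from pepscreen.proteolysis import ProteaseCocktail, parse_cleavage_rule

trypsin = ProteaseCocktail((parse_cleavage_rule("trypsin: after {K,R} unless before {P}"),))
proteome = [
    ("secA_frag", "GGFAIVDEVDSILIDEAGGG"),   # hides an acidic 16-mer
    ("mystery", "MSTAYIAQQSQISFVQSHFS"),
]
references = [
    ReferencePeptide("REF1", "FAIVDEVDSILIDEAG", "known immunomodulatory peptide"),
    ReferencePeptide("REF2", "STPPQVSNEVLKAH", "known immunomodulatory peptide"),
]

config = MiningConfig(min_length=10, max_length=16, cocktail=trypsin, require_resistance=True)
candidates = mine_peptides(proteome, config)
print(f"{len(candidates)} trypsin-resistant candidate windows mined")

ranked = rank_candidates(candidates, references, threshold_percent=50.0)
print(f"{len(ranked)} candidates at >= 50% identity to a reference:")
cols = ["candidate_id", "sequence", "percent", "best_reference", "identities"]
print(ranked[cols].head(5).to_string(index=False))
# percent = 100 * identities / query length of the best local
# alignment; the verbatim REF1 window tops the ranking at 100.
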