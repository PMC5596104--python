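"""In-silico digestion and endoprotease-resistance calls.

Digests a small bacterial protein with the default intestinal cocktail
(simplified pepsin/trypsin/chymotrypsin rules) and screens two of the
shipped synthesized peptides for digestion resistance.
"""

from pepscreen.proteolysis import digest, intestinal_cocktail, is_resistant
from pepscreen.synthdata import table1_fixture

cocktail = intestinal_cocktail()
protein = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"

result = digest(protein, cocktail, missed_cleavages=0)
print(f"protein ({len(protein)} aa) -> {len(result.fragments)} fragments, "
      f"cut sites at {list(result.sites)}")
for frag in result.fragments:
    print(f"  {frag.start:>3}-{frag.end:<3} {frag.sequence}")

# Resistance means no internal cut site for any protease in the
# cocktail; offending sites are reported per protease for diagnostics.
by_name = {row.peptide_name: row for row in table1_fixture()}
for name in ("LR17", "QE14"):
    seq = by_name[name].sequence
    flag, offending = is_resistant(seq, cocktail)
    sites = {p: s for p, s in offending.items() if s}
    print(f"{name} ({seq}): resistant={flag} offending={sites or 'none'}")
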