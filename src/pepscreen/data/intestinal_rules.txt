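# Simplified cleavage specificities for the major intestinal endoproteases.
# Grammar: NAME: after {P1 residues} [unless before {P1' blockers}]
# These one-line rules are deliberate simplifications of the full Keil
# exception tables; supply your own rules file for exact specificities.
pepsin: after {F,L}
trypsin: after {K,R} unless before {P}
chymotrypsin: after {F,Y,W} unless before {P}
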