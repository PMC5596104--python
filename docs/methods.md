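# Methods

## Cleavage rules and digestion resistance

A protease's specificity is stated in P1/P1′ terms: it cuts the bond
C-terminal to any residue in its P1 set unless the residue immediately
C-terminal to the bond is in its blocker set. Cut positions are
1-based (position *i* = the bond between residues *i* and *i* + 1), so
a terminal P1 residue never yields a site — this matches how the
protease literature indexes P1. Sequences are restricted to the 20
standard one-letter codes; ambiguity codes (B, Z, X, U, …) are
rejected rather than guessed, because a resistance call that silently
passed an unknown residue would be meaningless.

The default "intestinal" cocktail is three deliberately simplified
one-line rules — pepsin after {F, L}; trypsin after {K, R} unless
before P; chymotrypsin after {F, Y, W} unless before P — covering the
proteases that dominate gastrointestinal digestion. The full Keil
exception tables are not encoded; the rule grammar
(`NAME: after {…} unless before {…}`) lets users supply exact
PeptideCutter-style rule sets where that matters. Under this full
default cocktail most of the 15 shipped peptides carry at least one
internal site (several contain internal F/L); the fixture tests
therefore assert rule-engine behaviour (e.g. QE14's single tryptic
site at position 7, LR17's trypsin resistance), not a biological
resistance claim for any particular cocktail. *Resistance* is defined
as "no internal cut position for any rule", which is provably
equivalent to zero-missed-cleavage digestion returning a single
fragment; both forms are tested. Missed cleavages default to 0
because the screening criterion is resistance, not coverage.
Exopeptidases, pH-dependent kinetics and partial-digestion
probabilities are out of scope.

## Candidate mining

Encrypted peptides are internal subsequences whose boundaries need not
coincide with cut sites, so the default mining mode slides windows of
10–19 residues (the length span of the shipped peptide set) over each
protein; digestion-fragment mining is available as an alternative
mode. Every candidate keeps provenance (parent id, 1-based start/end)
that re-slices to its sequence; duplicate sequences from redundant
(meta)proteomes are retained with multi-provenance rather than
dropped, and deduplication only merges rows, never changes the set of
distinct sequences.

## Bioactivity scoring

No public definition exists for the percent scale used by upstream
peptide-bioactivity databases (identity-, similarity- or hit-count
based), so the shipped fixture's prediction column is treated as
metadata, not as a reproduction target. This package defines its own
transparent, oracle-checkable score: the query-normalized identity of
the best affine-gap Smith–Waterman local alignment,

    percent = 100 · identities / |query|,   maximized over references.

Defaults: match +1, mismatch −1, gap open −2 (first gapped residue),
gap extend −1 (each additional); a substitution matrix (e.g. BLOSUM62)
may replace match/mismatch for the raw score while identities always
count exact matches. Query-length normalization (not alignment-length)
makes short spurious matches on long queries score low and puts a
verbatim reference hit at exactly 100.

Determinism: among maximal-scoring alignments the winner has the
smallest query start, then smallest reference start, then fewest
columns, then most identities, then smallest end coordinates.
Alignments start and end on an aligned pair; a gap in one sequence
never directly follows a gap in the other; prefixes with negative
running score are excluded (trimming them scores strictly higher),
while zero-score prefixes are kept because they tie the trimmed
alignment and win on query start. The test suite checks the
implementation cell-by-cell against a brute-force DP oracle with
explicit backtrack enumeration, and its raw scores against Biopython's
`PairwiseAligner`.

## Panel analysis

The panel vocabulary is the fixed 18-analyte set; common aliases
(IL17 → IL-17A, TNFa → TNFα, …) are canonicalized on load and unknown
analytes are an error listing the vocabulary. The default subset map
pools inducing and signature cytokines: Th1 {IL-12p70, IL-18, IFNγ},
Th2 {IL-4, IL-5, IL-13}, Th9 {IL-9}, Th17 {IL-1β, IL-6, IL-23, IL-21,
IL-17A}, Th22 {IL-22}, Treg {IL-10}; GM-CSF, IL-2, IL-27 and TNFα stay
unassigned and are used only where a ratio names them directly (TGFβ
and TNFβ are outside the measured panel). The map is configurable and
user maps are validated against the vocabulary.

A subset aggregate is the arithmetic mean of member concentrations
(so subsets of different sizes are comparable; sum and geometric mean
are available) plus a pseudocount ε = 0.01 pg/mL. Ratios sum their
term aggregates in numerator and denominator; rows whose denominator
was held up only by ε are flagged. The default ratio file contains
exactly the 17 published polarization ratios. With ε = 0 the ratios
are exactly scale-invariant per donor × condition, and an all-equal
panel gives every pure-subset ratio 1; both identities are tested.

### Permutation Mann–Whitney test

U is the first group's statistic computed with midranks;
two-sided extremeness is |U − n₁n₂/2|. When the number of label
assignments C(n₁+n₂, n₁) is at most 200,000 the permutation
distribution is enumerated exhaustively and the p-value is exact
(fully separated 5v5 groups give p = 2/252 ≈ 0.0079; 3v3 give 0.1);
otherwise n = 99,999 Monte-Carlo reshuffles are drawn and
p = (1 + #extreme) / (1 + n), whose upward bias (< 10⁻⁵ at that n) is
negligible against the Monte-Carlo standard error. Only the two-sided
alternative is offered. Condition contrasts treat donors as
independent samples (no pairing), the comparison is always against the
activation control by default, and multiple-testing correction is
deliberately not applied by default — stars reflect unadjusted
p-values — with an optional Benjamini–Hochberg q-value column.

## Synthetic panels

Concentrations are log-normal:
`concentration(d, t, c) = 10^(μ_c + δ_d + log10 β_{c,t} + ε)` with
per-cytokine baseline μ_c (log10 pg/mL, order-of-magnitude choices for
5-day anti-CD3-stimulated PBMC supernatants: IFNγ/IL-6 ≈ 10³, TNFα ≈
500, IL-17A/IL-22/IL-10 ≈ 10², Th2/Th9 channels ≈ 10–50, IL-12p70 ≈
10), donor effect δ_d ~ N(0, τ = 0.1), noise ε ~ N(0, σ = 0.2), and
multiplicative condition fold changes β. Multiplex cytokine data are
right-skewed and analyzed by rank-based nonparametrics, which makes
the log-normal a natural free choice. The default layout mirrors the
emulated experiment: 5 donors; conditions basal (all channels ×0.2
relative to activation), activated, lps (innate channels IL-1β, IL-6,
TNFα, IL-10, IL-23, GM-CSF ×2.5) and two peptide co-cultures. The
programmed-effect scenario raises IL-6, IL-17A, IL-12p70, IL-22,
IL-23 and TNFα 3-fold under both peptide conditions, which by the
subset-aggregate algebra raises Th17/Th1 roughly 2.6-fold while
leaving the IFNγ-dominated Th1 aggregate nearly unchanged.

What the generator does *not* emulate: detection limits/censoring,
plate and bead effects, heavy-tailed outliers, and donor-specific
responsiveness to stimulation. Passing tests therefore demonstrate
the correctness and calibration of the analysis code under its own
assumptions, not the effect sizes of any real co-culture experiment.

### Calibration and power studies

Type-I error is measured under the no-effect scenario with
*independent* donor groups (each comparison splits a fresh null
panel's activated condition into two groups of 10, exhaustive
permutation distribution), i.e. under the test's own independence
assumptions; the rejection fraction at α = 0.05 over 1,000 comparisons
sits near 0.04–0.06 (the permutation distribution is discrete, so the
attainable level just below 0.05 is ≈ 0.043 at 10v10). In the
in-study design, conditions share donors and positive intra-donor
correlation makes the unpaired test slightly conservative — a known
limitation of the Mann–Whitney choice, not corrected here. Power uses
the programmed 3-fold scenario at 20 donors per group — a scaled-up
synthetic experiment, since 5 donors per group cannot resolve p < 0.05
beyond 0.0079 — with 9,999 Monte-Carlo permutations per replicate over
200 replicates; IL-17A is flagged in essentially every replicate and
the Th17/Th1 ratio median is elevated in all of them.

## Numerical conventions

Rank computations use scipy midranks; permutation-count comparisons
use a 10⁻⁹ tolerance so midrank arithmetic never drops tied-extreme
permutations. Seeds: every stochastic routine takes an explicit seed;
study drivers derive child seeds from a master generator, and
per-test generators inside `compare_conditions` come from spawned
`SeedSequence` children so adding a measure never perturbs another's
p-value. Fixed seeds give byte-identical panels, reports and ranked
tables.

## Known limitations

- The shipped endoprotease presets are simplified; real resistance
  screening should supply full exception tables through the grammar.
- The bioactivity percent is this package's own definition; it is
  shaped like, but not numerically comparable to, the prediction
  column of the shipped fixture.
- The packaged reference set is synthetic demonstration data, not a
  curated immunomodulatory-peptide database.
- Donor pairing is ignored by design in the test; a paired
  (signed-rank) alternative would be more powerful on real panels.
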