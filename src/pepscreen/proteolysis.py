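"""Cleavage-rule grammar, in-silico digestion, and digestion resistance.

A protease's cut specificity is stated in P1/P1' terms: it cleaves the
bond C-terminal to any residue in its P1 set, unless the residue
immediately C-terminal to the bond (P1') is in its blocker set. Cut
positions are 1-based: position ``i`` is the bond between residues ``i``
and ``i + 1``, so a sequence of length L has candidate positions
``1 .. L - 1`` and a terminal P1 residue never yields a site.

The shipped intestinal presets are deliberately simplified one-line
rules (pepsin after F/L; trypsin after K/R unless before P; chymotrypsin
after F/Y/W unless before P) that dominate gastrointestinal digestion;
the grammar lets users supply exact PeptideCutter-style rule sets where
the full exception tables matter. A peptide is called *resistant* to a
cocktail when no rule yields any internal cut position — equivalently,
zero-missed-cleavage digestion returns it as a single fragment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .alphabet import SequenceError, validate_residue_codes, validate_sequence

__all__ = [
    "CleavageRule",
    "ProteaseCocktail",
    "DigestionResult",
    "Fragment",
    "RuleParseError",
    "parse_cleavage_rule",
    "format_cleavage_rule",
    "parse_rules_text",
    "intestinal_cocktail",
    "find_cleavage_sites",
    "digest",
    "is_resistant",
]


class RuleParseError(ValueError):
    """Raised when rule text does not match the documented grammar."""


@dataclass(frozen=True)
class CleavageRule:
    """One protease's cut specificity.

    Parameters
    ----------
    protease_name:
        Short label, unique within a cocktail.
    p1_residues:
        Residues N-terminal to the cut bond (non-empty).
    p1prime_blockers:
        Residues that suppress the cut when immediately C-terminal to
        the bond. May be empty and may overlap ``p1_residues``.
    """

    protease_name: str
    p1_residues: frozenset = field(default_factory=frozenset)
    p1prime_blockers: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.protease_name or not str(self.protease_name).strip():
            raise ValueError("protease_name must be non-empty")
        p1 = validate_residue_codes(self.p1_residues, what=f"{self.protease_name} P1 set")
        if not p1:
            raise ValueError(f"{self.protease_name}: P1 residue set must be non-empty")
        blockers = validate_residue_codes(
            self.p1prime_blockers, what=f"{self.protease_name} P1' blocker set"
        )
        object.__setattr__(self, "p1_residues", p1)
        object.__setattr__(self, "p1prime_blockers", blockers)


@dataclass(frozen=True)
class ProteaseCocktail:
    """An ordered collection of cleavage rules with unique names.

    May be empty, in which case digestion is a no-op and every peptide
    is vacuously resistant.
    """

    rules: tuple = ()

    def __post_init__(self) -> None:
        rules = tuple(self.rules)
        names = [r.protease_name for r in rules]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise ValueError(f"duplicate protease name(s) in cocktail: {', '.join(dupes)}")
        object.__setattr__(self, "rules", rules)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)


@dataclass(frozen=True)
class Fragment:
    """One digestion fragment with 1-based inclusive parent coordinates."""

    sequence: str
    start: int
    end: int


@dataclass(frozen=True)
class DigestionResult:
    """Fragments and cut sites produced by :func:`digest`.

    ``sites`` holds every cut position found on the parent; with zero
    missed cleavages the fragment sequences concatenate exactly to the
    parent and ``len(fragments) == len(sites) + 1``.
    """

    fragments: tuple
    sites: tuple


_RULE_RE = re.compile(
    r"^\s*(?P<name>\S+?)\s*:\s*after\s*\{(?P<p1>[^{}]*)\}"
    r"(?:\s+unless\s+before\s*\{(?P<blockers>[^{}]*)\})?\s*$"
)


def _split_codes(group: str, what: str) -> frozenset:
    codes = [tok.strip() for tok in re.split(r"[,\s]+", group) if tok.strip()]
    bad = [c for c in codes if len(c) != 1]
    if bad:
        raise RuleParseError(f"{what}: expected one-letter residue codes, got {bad[0]!r}")
    return frozenset(codes)


def parse_cleavage_rule(spec: str) -> CleavageRule:
    """Parse rule text of the form ``NAME: after {K,R} unless before {P}``.

    The ``unless before`` clause is optional; ``{}`` denotes an empty
    set. Raises :class:`RuleParseError` on malformed grammar and
    :class:`~pepscreen.alphabet.SequenceError` on invalid residue codes.
    """
    m = _RULE_RE.match(spec)
    if m is None:
        raise RuleParseError(
            f"cannot parse cleavage rule {spec!r}; expected "
            "'NAME: after {residues} [unless before {residues}]'"
        )
    name = m.group("name")
    p1 = _split_codes(m.group("p1"), f"{name} P1 set")
    blockers = _split_codes(m.group("blockers") or "", f"{name} P1' set")
    return CleavageRule(protease_name=name, p1_residues=p1, p1prime_blockers=blockers)


def format_cleavage_rule(rule: CleavageRule) -> str:
    """Render a rule in the grammar accepted by :func:`parse_cleavage_rule`."""
    text = f"{rule.protease_name}: after {{{','.join(sorted(rule.p1_residues))}}}"
    if rule.p1prime_blockers:
        text += f" unless before {{{','.join(sorted(rule.p1prime_blockers))}}}"
    return text


def parse_rules_text(text: str) -> ProteaseCocktail:
    """Parse a rules file: one rule per line, ``#`` comments and blanks ignored."""
    rules = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            rules.append(parse_cleavage_rule(line))
    return ProteaseCocktail(rules=tuple(rules))


def intestinal_cocktail() -> ProteaseCocktail:
    """The default simplified pepsin/trypsin/chymotrypsin cocktail."""
    text = resources.files("pepscreen.data").joinpath("intestinal_rules.txt").read_text()
    return parse_rules_text(text)


def find_cleavage_sites(sequence: str, rule: CleavageRule) -> list:
    """Cut positions of *rule* on *sequence*, sorted ascending.

    Position ``i`` is reported iff ``1 <= i <= L - 1``, residue ``i`` is
    in the P1 set and residue ``i + 1`` is not a P1' blocker.
    """
    validate_sequence(sequence)
    p1, blockers = rule.p1_residues, rule.p1prime_blockers
    return [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in p1 and sequence[i] not in blockers
    ]


def digest(sequence: str, cocktail: ProteaseCocktail, missed_cleavages: int = 0) -> DigestionResult:
    """In-silico digestion of *sequence* by every rule in *cocktail*.

    ``sites`` is the union of cut positions over all rules. With
    ``missed_cleavages = m`` the fragment list contains every run of at
    most ``m + 1`` consecutive zero-missed fragments, ordered by start
    coordinate then length.
    """
    validate_sequence(sequence)
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be non-negative")
    sites: set = set()
    for rule in cocktail:
        sites.update(find_cleavage_sites(sequence, rule))
    bounds = [0, *sorted(sites), len(sequence)]
    fragments = []
    n_base = len(bounds) - 1
    for i in range(n_base):
        for span in range(1, min(missed_cleavages + 1, n_base - i) + 1):
            start, end = bounds[i] + 1, bounds[i + span]
            fragments.append(Fragment(sequence[start - 1 : end], start, end))
    fragments.sort(key=lambda f: (f.start, f.end - f.start))
    return DigestionResult(fragments=tuple(fragments), sites=tuple(sorted(sites)))


def is_resistant(peptide: str, cocktail: ProteaseCocktail):
    """Whether *peptide* contains no internal cut site for any rule.

    Returns ``(flag, offending)`` where ``offending`` maps each protease
    name to its (possibly empty) sorted list of cut positions. The flag
    is true iff every list is empty, which is equivalent to zero-missed
    digestion returning the peptide as a single fragment.
    """
    validate_sequence(peptide, what="peptide")
    offending = {rule.protease_name: find_cleavage_sites(peptide, rule) for rule in cocktail}
    flag = not any(offending.values())
    return flag, offending
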