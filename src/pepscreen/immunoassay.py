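"""Cytokine-panel analysis: T-cell-subset ratios and permutation tests.

The panel is an 18-analyte multiplex measurement of PBMC supernatants
(GM-CSF, IFNγ, IL-1β, IL-2, IL-4, IL-5, IL-6, IL-9, IL-10, IL-12p70,
IL-13, IL-17A, IL-18, IL-21, IL-22, IL-23, IL-27, TNFα) per donor and
stimulation condition (basal, anti-CD3 activated, LPS, or an added
peptide). Cytokines map to CD4+ T-helper subsets (Th1/Th2/Th9/Th17/
Th22/Treg) through a configurable subset map pooling inducing and
signature cytokines; polarization is summarized by named ratios of
subset aggregates such as Th17/Th1, with compound sums like
Th1+Th2+Th17/Treg allowed.

Condition contrasts use a two-sided Mann-Whitney U test whose p-value
is computed by Monte Carlo permutation of the group labels (default
n = 99,999 reshuffles) or by exhaustive enumeration of all label
assignments when that is tractable. Donors are treated as independent
samples by the test even though conditions share donors. Significance
stars follow the p < 0.05 / 0.01 / 0.001 convention.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, rankdata

__all__ = [
    "CYTOKINES",
    "DEFAULT_SUBSET_MAP",
    "DEFAULT_RATIOS",
    "CytokinePanel",
    "RatioDefinition",
    "TestConfig",
    "MWUResult",
    "canonical_cytokine",
    "load_panel",
    "panel_from_dataframe",
    "subset_aggregate",
    "compute_ratios",
    "mwu_permutation_test",
    "significance_stars",
    "compare_conditions",
    "boxplot_summary",
]

CYTOKINES = (
    "GM-CSF", "IFNγ", "IL-1β", "IL-2", "IL-4", "IL-5", "IL-6", "IL-9",
    "IL-10", "IL-12p70", "IL-13", "IL-17A", "IL-18", "IL-21", "IL-22",
    "IL-23", "IL-27", "TNFα",
)

PANEL_COLUMNS = ["donor_id", "condition", "cytokine", "concentration_pg_ml"]

_GREEK = str.maketrans({"α": "A", "β": "B", "γ": "G", "Α": "A", "Β": "B", "Γ": "G"})


def _norm(name: str) -> str:
    return re.sub(r"[\s_\-/]+", "", str(name).translate(_GREEK)).upper()


_ALIASES = {_norm(c): c for c in CYTOKINES}
_ALIASES.update(
    {
        "IFNGAMMA": "IFNγ",
        "INTERFERONGAMMA": "IFNγ",
        "TNF": "TNFα",
        "TNFALPHA": "TNFα",
        "IL1BETA": "IL-1β",
        "IL17": "IL-17A",
        "IL12": "IL-12p70",
    }
)


def canonical_cytokine(name: str) -> str:
    """Map a cytokine name or common alias (IL17, TNFa, IFN-gamma, ...)
    to its canonical panel spelling, or raise listing the vocabulary."""
    key = _norm(name)
    if key not in _ALIASES:
        raise ValueError(
            f"unknown cytokine {name!r}; the panel vocabulary is: {', '.join(CYTOKINES)}"
        )
    return _ALIASES[key]


_CONDITION_RE = re.compile(r"^(basal|activated|lps|peptide:[A-Za-z0-9_.\-]+)$")

# Inducing and signature cytokines pooled per subset. GM-CSF, IL-2,
# IL-27 and TNFα stay unassigned and are used only where a ratio names
# them directly; TGFβ and TNFβ are outside the measured panel.
DEFAULT_SUBSET_MAP: Mapping[str, tuple] = {
    "Th1": ("IL-12p70", "IL-18", "IFNγ"),
    "Th2": ("IL-4", "IL-5", "IL-13"),
    "Th9": ("IL-9",),
    "Th17": ("IL-1β", "IL-6", "IL-23", "IL-21", "IL-17A"),
    "Th22": ("IL-22",),
    "Treg": ("IL-10",),
}


@dataclass(frozen=True)
class RatioDefinition:
    """A named quotient of summed term aggregates.

    Each term in ``numerator``/``denominator`` is a subset label or a
    single cytokine; term values (mean member concentration plus the
    pseudocount) are summed within numerator and denominator.
    """

    name: str
    numerator: tuple
    denominator: tuple

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise ValueError(f"ratio {self.name!r}: numerator and denominator must be non-empty")
        object.__setattr__(self, "numerator", tuple(self.numerator))
        object.__setattr__(self, "denominator", tuple(self.denominator))


DEFAULT_RATIOS = (
    RatioDefinition("IL10/TNFα", ("IL-10",), ("TNFα",)),
    RatioDefinition("IL10/IFNγ", ("IL-10",), ("IFNγ",)),
    RatioDefinition("IL10/IL17", ("IL-10",), ("IL-17A",)),
    RatioDefinition("IL10/IL4", ("IL-10",), ("IL-4",)),
    RatioDefinition("IFNγ/IL17", ("IFNγ",), ("IL-17A",)),
    RatioDefinition("Th1/Th2", ("Th1",), ("Th2",)),
    RatioDefinition("Th17/Th1", ("Th17",), ("Th1",)),
    RatioDefinition("Th17/Th2", ("Th17",), ("Th2",)),
    RatioDefinition("Th1/Treg", ("Th1",), ("Treg",)),
    RatioDefinition("Th2/Treg", ("Th2",), ("Treg",)),
    RatioDefinition("Th1+Th2+Th17/Treg", ("Th1", "Th2", "Th17"), ("Treg",)),
    RatioDefinition("Th17/Treg", ("Th17",), ("Treg",)),
    RatioDefinition("Th22/Th1", ("Th22",), ("Th1",)),
    RatioDefinition("Th22/Th2", ("Th22",), ("Th2",)),
    RatioDefinition("Th22/Th17", ("Th22",), ("Th17",)),
    RatioDefinition("Th22/Treg", ("Th22",), ("Treg",)),
    RatioDefinition("Th22+Th17/Th1+Th2", ("Th22", "Th17"), ("Th1", "Th2")),
)


@dataclass(frozen=True)
class CytokinePanel:
    """A validated long-format panel of cytokine concentrations (pg/mL)."""

    data: pd.DataFrame

    @property
    def donors(self) -> list:
        return sorted(self.data["donor_id"].unique())

    @property
    def conditions(self) -> list:
        return sorted(self.data["condition"].unique())

    @property
    def cytokines(self) -> list:
        return [c for c in CYTOKINES if c in set(self.data["cytokine"])]

    def missing_cells(self) -> list:
        """(donor, condition, cytokine) grid cells without a measurement."""
        have = set(map(tuple, self.data[["donor_id", "condition", "cytokine"]].itertuples(index=False)))
        return [
            (d, t, c)
            for d in self.donors
            for t in self.conditions
            for c in CYTOKINES
            if (d, t, c) not in have
        ]

    def value(self, donor, condition, cytokine) -> float:
        cytokine = canonical_cytokine(cytokine)
        sel = self.data[
            (self.data["donor_id"] == donor)
            & (self.data["condition"] == condition)
            & (self.data["cytokine"] == cytokine)
        ]
        if sel.empty:
            raise KeyError(f"no measurement for donor {donor!r}, condition {condition!r}, {cytokine}")
        return float(sel["concentration_pg_ml"].iloc[0])

    def values(self, condition, cytokine) -> np.ndarray:
        """Per-donor concentrations for one condition x cytokine, donor-sorted."""
        cytokine = canonical_cytokine(cytokine)
        sel = self.data[(self.data["condition"] == condition) & (self.data["cytokine"] == cytokine)]
        if sel.empty:
            raise KeyError(f"no measurements for condition {condition!r}, {cytokine}")
        return sel.sort_values("donor_id")["concentration_pg_ml"].to_numpy(dtype=float)


def panel_from_dataframe(df: pd.DataFrame) -> CytokinePanel:
    """Validate a long-format dataframe into a :class:`CytokinePanel`.

    Accepts cytokine aliases, requires the documented header, rejects
    unknown cytokines, malformed conditions, negative or non-finite
    concentrations, duplicate (donor, condition, cytokine) keys, and
    empty input.
    """
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel is missing column(s): {', '.join(missing)}; expected {PANEL_COLUMNS}")
    if df.empty:
        raise ValueError("panel file contains no measurements")
    out = df[PANEL_COLUMNS].copy()
    out["donor_id"] = out["donor_id"].astype(str)
    out["condition"] = out["condition"].astype(str)
    out["cytokine"] = [canonical_cytokine(c) for c in out["cytokine"]]
    bad = sorted(set(out["condition"]) - {c for c in out["condition"] if _CONDITION_RE.match(c)})
    if bad:
        raise ValueError(
            f"invalid condition(s) {bad}; expected basal, activated, lps or peptide:<name>"
        )
    conc = pd.to_numeric(out["concentration_pg_ml"], errors="coerce")
    if conc.isna().any() or not np.isfinite(conc).all():
        raise ValueError("concentrations must be finite numbers (pg/mL)")
    if (conc < 0).any():
        raise ValueError("concentrations must be non-negative (pg/mL)")
    out["concentration_pg_ml"] = conc.astype(float)
    dup = out.duplicated(subset=["donor_id", "condition", "cytokine"])
    if dup.any():
        row = out[dup].iloc[0]
        raise ValueError(
            f"duplicate measurement for donor {row['donor_id']!r}, "
            f"condition {row['condition']!r}, {row['cytokine']}"
        )
    return CytokinePanel(data=out.reset_index(drop=True))


def load_panel(path) -> CytokinePanel:
    """Read and validate a long-format panel TSV
    (columns donor_id, condition, cytokine, concentration_pg_ml)."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"panel file {path} contains no measurements")
    return panel_from_dataframe(df)


def _term_members(term: str, subset_map: Mapping[str, tuple]) -> tuple:
    if term in subset_map:
        members = tuple(subset_map[term])
        if not members:
            raise ValueError(f"subset {term!r} has no member cytokines")
        return tuple(canonical_cytokine(c) for c in members)
    return (canonical_cytokine(term),)  # raises for unresolvable terms


_AGG = {
    "mean": lambda v: float(np.mean(v)),
    "sum": lambda v: float(np.sum(v)),
    "geomean": lambda v: float(np.exp(np.mean(np.log(np.asarray(v, dtype=float) + 1e-12)))),
}


def subset_aggregate(
    panel: CytokinePanel,
    donor,
    condition,
    subset: str,
    subset_map: Mapping[str, tuple] = DEFAULT_SUBSET_MAP,
    *,
    eps: float = 0.01,
    method: str = "mean",
) -> float:
    """Aggregate of a subset's member cytokines for one donor x condition.

    Arithmetic mean by default (so subsets of different sizes are
    comparable; ``sum`` and ``geomean`` available), plus the pseudocount
    ``eps`` in pg/mL. A missing member measurement is an error naming
    the gap, never a silent drop.
    """
    if method not in _AGG:
        raise ValueError(f"unknown aggregation method {method!r}; choose from {sorted(_AGG)}")
    members = _term_members(subset, subset_map)
    values = [panel.value(donor, condition, c) for c in members]
    return _AGG[method](values) + eps


def compute_ratios(
    panel: CytokinePanel,
    ratios: Sequence[RatioDefinition] = DEFAULT_RATIOS,
    subset_map: Mapping[str, tuple] = DEFAULT_SUBSET_MAP,
    *,
    eps: float = 0.01,
    method: str = "mean",
) -> pd.DataFrame:
    """One ratio value per donor x condition x ratio definition.

    Numerator and denominator each sum their terms' aggregates
    (``agg(term) + eps``); ``denominator_floored`` flags rows whose
    denominator consisted entirely of zero concentrations and was held
    up only by the pseudocount.
    """
    rows = []
    for donor in panel.donors:
        for condition in panel.conditions:
            for ratio in ratios:
                num = sum(
                    subset_aggregate(panel, donor, condition, t, subset_map, eps=eps, method=method)
                    for t in ratio.numerator
                )
                den = sum(
                    subset_aggregate(panel, donor, condition, t, subset_map, eps=eps, method=method)
                    for t in ratio.denominator
                )
                floored = math.isclose(den, eps * len(ratio.denominator))
                rows.append(
                    {
                        "donor_id": donor,
                        "condition": condition,
                        "ratio": ratio.name,
                        "value": num / den,
                        "denominator_floored": floored,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TestConfig:
    """Permutation-test configuration.

    ``n_permutations`` Monte Carlo label reshuffles (default 99,999);
    when the total number of label assignments C(n1+n2, n1) is at most
    ``exhaustive_cap`` the permutation distribution is enumerated
    exhaustively instead and the p-value is exact. Only the two-sided
    alternative is supported.
    """

    __test__ = False  # not a pytest class despite the name

    n_permutations: int = 99_999
    seed: int = 0
    alternative: str = "two-sided"
    exhaustive_cap: int = 200_000

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.alternative != "two-sided":
            raise ValueError("only the two-sided alternative is supported")


class MWUResult(NamedTuple):
    U: float
    p_value: float
    exact: bool
    n_permutations: int


@lru_cache(maxsize=16)
def _combination_indices(n: int, k: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def mwu_permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    config: TestConfig = TestConfig(),
    *,
    rng: Optional[np.random.Generator] = None,
) -> MWUResult:
    """Two-sided Mann-Whitney U test with a permutation p-value.

    U is the first group's statistic computed with midranks for ties;
    extremeness is measured by |U - n1*n2/2|. Exhaustive enumeration is
    used when tractable (exact p = extreme assignments / total);
    otherwise Monte Carlo sampling with
    ``p = (1 + #extreme) / (1 + n_permutations)``. Pass ``rng`` to
    override the seed-derived generator.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs >= 2 values, got sizes {a.size} and {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain only finite values")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = rankdata(np.concatenate([a, b]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    d_obs = abs(u_obs - mu)
    tol = 1e-9

    total = math.comb(n, n1)
    if total <= config.exhaustive_cap:
        idx = _combination_indices(n, n1)
        u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        count = int(np.count_nonzero(np.abs(u_all - mu) >= d_obs - tol))
        return MWUResult(U=float(u_obs), p_value=count / total, exact=True, n_permutations=total)

    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_perm = config.n_permutations
    count = 0
    chunk = max(1, min(n_perm, int(4e7 // max(n, 1))))
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        order = rng.random((size, n)).argsort(axis=1)[:, :n1]
        u_perm = ranks[order].sum(axis=1) - n1 * (n1 + 1) / 2.0
        count += int(np.count_nonzero(np.abs(u_perm - mu) >= d_obs - tol))
        done += size
    p = (1 + count) / (1 + n_perm)
    return MWUResult(U=float(u_obs), p_value=p, exact=False, n_permutations=n_perm)


def significance_stars(p_value: float) -> str:
    """Star label for a p-value: *** < 0.001 <= ** < 0.01 <= * < 0.05."""
    if not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p-value must be in [0, 1], got {p_value}")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def compare_conditions(
    panel: CytokinePanel,
    control: str = "activated",
    test_conditions: Optional[Sequence[str]] = None,
    *,
    cytokines: Optional[Sequence[str]] = None,
    ratios: Optional[Sequence[RatioDefinition]] = None,
    subset_map: Mapping[str, tuple] = DEFAULT_SUBSET_MAP,
    config: TestConfig = TestConfig(),
    eps: float = 0.01,
    adjust: bool = False,
) -> pd.DataFrame:
    """Permutation Mann-Whitney tests of each measure vs the control.

    For every measure (cytokine and/or ratio) and test condition, the
    per-donor control values and test-condition values are compared
    with :func:`mwu_permutation_test`; donors are treated as
    independent samples. ``cytokines=None`` means all panel cytokines
    (pass ``[]`` for none); ``ratios=None`` means no ratio measures.
    With ``adjust=True`` a Benjamini-Hochberg ``q_value`` column is
    added; the star labels always reflect the unadjusted p-values.
    """
    if control not in panel.conditions:
        raise ValueError(f"control condition {control!r} not present in panel")
    for donor in panel.donors:
        if panel.data[(panel.data["donor_id"] == donor) & (panel.data["condition"] == control)].empty:
            raise ValueError(f"control condition {control!r} missing for donor {donor!r}")
    if test_conditions is None:
        test_conditions = [c for c in panel.conditions if c != control]
    absent = [c for c in test_conditions if c not in panel.conditions]
    if absent:
        raise ValueError(f"test condition(s) not present in panel: {absent}")
    if cytokines is None:
        cyt_measures = list(panel.cytokines)
    else:
        cyt_measures = [canonical_cytokine(c) for c in cytokines]
    ratio_measures = list(ratios) if ratios is not None else []

    ratio_table = None
    if ratio_measures:
        ratio_table = compute_ratios(panel, ratio_measures, subset_map, eps=eps)

    def ratio_values(name: str, condition: str) -> np.ndarray:
        sel = ratio_table[(ratio_table["ratio"] == name) & (ratio_table["condition"] == condition)]
        return sel.sort_values("donor_id")["value"].to_numpy(dtype=float)

    measures = [("cytokine", c) for c in cyt_measures] + [
        ("ratio", r.name) for r in ratio_measures
    ]
    children = np.random.SeedSequence(config.seed).spawn(max(1, len(measures) * len(test_conditions)))
    rows = []
    k = 0
    for condition in test_conditions:
        for kind, name in measures:
            if kind == "cytokine":
                a = panel.values(control, name)
                b = panel.values(condition, name)
            else:
                a = ratio_values(name, control)
                b = ratio_values(name, condition)
            result = mwu_permutation_test(
                a, b, config, rng=np.random.default_rng(children[k])
            )
            k += 1
            rows.append(
                {
                    "measure": name,
                    "measure_type": kind,
                    "condition": condition,
                    "control": control,
                    "n_control": a.size,
                    "n_test": b.size,
                    "U": result.U,
                    "p_value": result.p_value,
                    "stars": significance_stars(result.p_value),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "measure", "measure_type", "condition", "control",
            "n_control", "n_test", "U", "p_value", "stars",
        ],
    )
    if adjust and not out.empty:
        out["q_value"] = false_discovery_control(out["p_value"].to_numpy(), method="bh")
    return out


def boxplot_summary(values_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Median/quartile/whisker summary table (Tukey 1.5 x IQR whiskers)."""
    rows = []
    for group, values in values_by_group.items():
        v = np.asarray(values, dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = v[v >= q1 - 1.5 * iqr].min()
        hi = v[v <= q3 + 1.5 * iqr].max()
        rows.append(
            {"group": group, "median": med, "q1": q1, "q3": q3, "whisker_low": lo, "whisker_high": hi}
        )
    return pd.DataFrame(rows)
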