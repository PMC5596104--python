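"""Fixtures and synthetic cytokine panels for end-to-end testing.

Ships the 15 synthesized bacterial peptides (with provenance and the
predicted bioactivity percent of each) as a machine-readable fixture,
and generates synthetic multiplex panels with the statistical structure
the analysis assumes: log-normal concentrations with additive donor
effects on the log10 scale and multiplicative condition fold changes,

    concentration(d, t, c) = 10 ** (mu_c + delta_d + log10 beta_{c,t} + eps),

with per-cytokine baseline ``mu_c`` (log10 pg/mL), donor effect
``delta_d ~ N(0, tau)``, and within-donor noise ``eps ~ N(0, sigma)``.
Multiplex cytokine data are right-skewed and analyzed by rank-based
nonparametrics, which makes the log-normal a natural free choice.

The default study layout mirrors the emulated experiment: 5 donors and
the conditions basal, activated (anti-CD3), lps, and two peptide
co-cultures. :func:`th17_scenario` programs a 3-fold elevation of the
Th17/Th22-axis cytokines (IL-6, IL-17A, IL-12p70, IL-22, IL-23, TNFα)
under the peptide conditions; :func:`null_scenario` programs no effect
anywhere. Scaled-up donor counts are used by the calibration and power
studies where the study-size 5 would be underpowered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alphabet import validate_sequence
from .immunoassay import (
    CYTOKINES,
    CytokinePanel,
    DEFAULT_RATIOS,
    DEFAULT_SUBSET_MAP,
    TestConfig,
    canonical_cytokine,
    compute_ratios,
    mwu_permutation_test,
    panel_from_dataframe,
)

__all__ = [
    "Table1Row",
    "table1_fixture",
    "SimulationScenario",
    "simulate_panel",
    "default_scenario",
    "null_scenario",
    "th17_scenario",
    "TH17_ELEVATED_CYTOKINES",
    "type1_error_study",
    "power_study",
]


class Table1Row(NamedTuple):
    peptide_name: str
    sequence: str
    uniprot_id: str
    protein_name: str
    organism: str
    gene: str
    bioactivity_prediction: float


_TABLE1 = (
    Table1Row("QE14", "QHVENNKSTPLPME", "P54355", "ENTM_BACFG Fragilysin",
              "Bacteroides fragilis", "btfP", 60),
    Table1Row("LR17", "LPLAFFVLTFLWALILR", "Q3V815",
              "MTGA_BACFR Monofunctional biosynthetic peptidoglycan transglycosylase",
              "Bacteroides fragilis YCH46", "mtgA", 80),
    Table1Row("DW15", "DEILENVDEVLGNDW", "Q45119",
              "TNPA_BACFG Transposase for insertion sequence element IS21-like",
              "Bacteroides fragilis", "tnpA", 75),
    Table1Row("KF14", "KETILEPVEGVGHF", "Q08425",
              "TETQ_BACFG Tetracycline resistance protein TetQ",
              "Bacteroides fragilis", "tetQ", 66),
    Table1Row("KE13", "KKMTPANEARPIE", "D4QFE7", "BGAL_BIFBI Beta-galactosidase BbgII",
              "Bifidobacterium bifidum", "bbgII", 75),
    Table1Row("SW14", "SASLVDGIARKDPW", "D4QFE7", "BGAL_BIFBI Beta-galactosidase BbgII",
              "Bifidobacterium bifidum", "bbgII", 66),
    Table1Row("EY12", "EMVEDILTGQCY", "C6H178", "BGAL2_LACAI Beta-galactosidase LacA",
              "Lactobacillus acidophilus", "lacA", 60),
    Table1Row("GR16", "GTSFEGNEYFEGPSIR", "P48790", "XYLA_CLOSR Xylosidase/arabinosidase",
              "Clostridium stercorarium", "xylA", 100),
    Table1Row("AR15", "AIQDEIDQLSTEIDR", "P80583", "FLA_CLOTY Flagellin (Fragment)",
              "Clostridium tyrobutyricum", "fla", 75),
    Table1Row("FR16", "FAIVDEVDSILIDEAR", "B3DR89", "SECA_BIFLD Protein translocase subunit SecA",
              "Bifidobacterium longum DJO10A", "secA", 100),
    Table1Row("WK19", "WIEAVGYSLTQHPDPELEK", "E8MGH8",
              "HYBA1_BIFL2 Non-reducing end beta-L-arabinofuranosidase",
              "Bifidobacterium longum subsp. longum ATCC 15707", "hypBA1", 100),
    Table1Row("VF10", "VPSEKKAELF", "P38059", "SLAP_LACHE S-layer protein",
              "Lactobacillus helveticus", "slpH", 80),
    Table1Row("HK11", "HIGVHSDPVDK", "P30269", "AMY_BUTFI Alpha-amylase",
              "Butyrivibrio fibrisolvens", "amyA", 75),
    Table1Row("AF16", "ASPEDEAASMEKAKAF", "A6L1Z2",
              "G1095_BACV8 Glycosyl hydrolase family 109 protein 5",
              "Bacteroides vulgatus ATCC 8482", "BVU_2041", 80),
    Table1Row("NR15", "NAALASYSLASDLDR", "Q9XD84",
              "TIBA_ECOH1 Adhesin/invasin TibA autotransporter",
              "Escherichia coli O78:H11 (H10407)", "tibA", 100),
)


def table1_fixture() -> list:
    """The 15 synthesized peptides with provenance and predicted percent.

    Stable across calls; every sequence is standard-alphabet and each
    name's trailing integer equals its sequence length.
    """
    return list(_TABLE1)


# Baseline log10 concentrations (log10 pg/mL) for 5-day anti-CD3
# stimulated PBMC supernatants: order-of-magnitude choices with IFNγ,
# IL-6 and TNFα high, innate IL-1β/IL-18 intermediate, and the Th2/Th9
# channels low, as typical of activated-PBMC multiplex panels.
DEFAULT_BASELINE_LOG10: Mapping[str, float] = {
    "GM-CSF": 2.0,
    "IFNγ": 3.0,
    "IL-1β": 2.3,
    "IL-2": 2.5,
    "IL-4": 1.0,
    "IL-5": 1.3,
    "IL-6": 3.0,
    "IL-9": 1.0,
    "IL-10": 2.0,
    "IL-12p70": 1.0,
    "IL-13": 1.7,
    "IL-17A": 2.0,
    "IL-18": 1.7,
    "IL-21": 1.3,
    "IL-22": 2.0,
    "IL-23": 1.7,
    "IL-27": 1.5,
    "TNFα": 2.7,
}

DEFAULT_CONDITIONS = ("basal", "activated", "lps", "peptide:FR16", "peptide:LR17")

# Cytokines of the Th17/Th22 axis elevated by the peptide conditions in
# the programmed-effect scenario.
TH17_ELEVATED_CYTOKINES = ("IL-6", "IL-17A", "IL-12p70", "IL-22", "IL-23", "TNFα")

# Innate-compartment channels elevated by LPS in the default scenario.
_LPS_ELEVATED = ("IL-1β", "IL-6", "TNFα", "IL-10", "IL-23", "GM-CSF")


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one synthetic panel experiment.

    ``fold_changes`` maps ``(condition, cytokine)`` to a multiplicative
    fold change beta > 0 (unlisted pairs default to 1). ``sigma`` is the
    within-donor noise and ``tau`` the donor-effect scale, both in
    log10 units.
    """

    donors: int = 5
    conditions: Tuple[str, ...] = DEFAULT_CONDITIONS
    baseline_log10: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_LOG10))
    sigma: float = 0.2
    tau: float = 0.1
    fold_changes: Mapping[tuple, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.donors < 1:
            raise ValueError("donors must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if self.sigma < 0 or self.tau < 0:
            raise ValueError("sigma and tau must be non-negative")
        baselines = {canonical_cytokine(c): float(mu) for c, mu in self.baseline_log10.items()}
        missing = [c for c in CYTOKINES if c not in baselines]
        if missing:
            raise ValueError(f"baseline_log10 missing cytokine(s): {', '.join(missing)}")
        folds = {}
        for (condition, cytokine), beta in dict(self.fold_changes).items():
            if beta <= 0:
                raise ValueError(f"fold change for {(condition, cytokine)} must be > 0, got {beta}")
            folds[(condition, canonical_cytokine(cytokine))] = float(beta)
        object.__setattr__(self, "baseline_log10", baselines)
        object.__setattr__(self, "fold_changes", folds)

    def beta(self, condition: str, cytokine: str) -> float:
        return self.fold_changes.get((condition, canonical_cytokine(cytokine)), 1.0)


def simulate_panel(scenario: SimulationScenario) -> CytokinePanel:
    """Draw one complete donors x conditions x 18-cytokine panel.

    Donor effects are drawn once per donor, then one noise term per
    grid cell, in a fixed order, so a fixed seed reproduces the panel
    byte-for-byte.
    """
    rng = np.random.default_rng(scenario.seed)
    donor_ids = [f"D{i + 1:02d}" for i in range(scenario.donors)]
    delta = rng.normal(0.0, scenario.tau, size=scenario.donors) if scenario.tau > 0 else np.zeros(scenario.donors)
    noise = (
        rng.normal(0.0, scenario.sigma, size=(scenario.donors, len(scenario.conditions), len(CYTOKINES)))
        if scenario.sigma > 0
        else np.zeros((scenario.donors, len(scenario.conditions), len(CYTOKINES)))
    )
    rows = []
    for d, donor in enumerate(donor_ids):
        for t, condition in enumerate(scenario.conditions):
            for c, cytokine in enumerate(CYTOKINES):
                log10_conc = (
                    scenario.baseline_log10[cytokine]
                    + delta[d]
                    + math.log10(scenario.beta(condition, cytokine))
                    + noise[d, t, c]
                )
                rows.append(
                    {
                        "donor_id": donor,
                        "condition": condition,
                        "cytokine": cytokine,
                        "concentration_pg_ml": 10.0 ** log10_conc,
                    }
                )
    return panel_from_dataframe(pd.DataFrame(rows))


def default_scenario(donors: int = 5, seed: int = 0) -> SimulationScenario:
    """Study-like layout: basal suppressed 5-fold relative to activation
    and LPS elevating the innate channels 2.5-fold; no peptide effect."""
    folds = {("basal", c): 0.2 for c in CYTOKINES}
    folds.update({("lps", c): 2.5 for c in _LPS_ELEVATED})
    return SimulationScenario(donors=donors, seed=seed, fold_changes=folds)


def null_scenario(donors: int = 5, seed: int = 0, conditions: Tuple[str, ...] = DEFAULT_CONDITIONS) -> SimulationScenario:
    """No programmed effect anywhere: every fold change is 1."""
    return SimulationScenario(donors=donors, seed=seed, conditions=conditions)


def th17_scenario(donors: int = 5, seed: int = 0, fold: float = 3.0) -> SimulationScenario:
    """Programmed Th17/Th22-axis elevation under the peptide conditions.

    IL-6, IL-17A, IL-12p70, IL-22, IL-23 and TNFα are raised ``fold``-
    fold (default 3) under both peptide conditions; every other channel
    stays at its condition baseline.
    """
    base = default_scenario(donors=donors, seed=seed)
    folds = dict(base.fold_changes)
    for condition in ("peptide:FR16", "peptide:LR17"):
        for cytokine in TH17_ELEVATED_CYTOKINES:
            folds[(condition, cytokine)] = fold
    return replace(base, fold_changes=folds)


def type1_error_study(
    n_comparisons: int = 1000,
    group_size: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    config: Optional[TestConfig] = None,
) -> dict:
    """Fraction of null comparisons rejected at *alpha*.

    Each comparison splits a freshly simulated null panel's activated
    condition into two independent donor groups of ``group_size`` and
    runs the permutation Mann-Whitney test, so the test is calibrated
    under its own independence assumptions (one comparison per
    cytokine per panel). With group size 10 the permutation
    distribution is enumerated exhaustively.
    """
    if config is None:
        config = TestConfig(seed=seed)
    master = np.random.default_rng(seed)
    p_values = []
    while len(p_values) < n_comparisons:
        scenario = null_scenario(
            donors=2 * group_size,
            seed=int(master.integers(2**31)),
            conditions=("activated",),
        )
        panel = simulate_panel(scenario)
        for cytokine in CYTOKINES:
            values = panel.values("activated", cytokine)
            result = mwu_permutation_test(values[:group_size], values[group_size:], config)
            p_values.append(result.p_value)
            if len(p_values) >= n_comparisons:
                break
    p = np.asarray(p_values)
    return {
        "fraction_rejected": float(np.mean(p < alpha)),
        "n_comparisons": int(p.size),
        "group_size": group_size,
        "alpha": alpha,
    }


def power_study(
    n_replicates: int = 200,
    donors: int = 20,
    n_perm: int = 9_999,
    seed: int = 0,
    fold: float = 3.0,
    condition: str = "peptide:LR17",
    alpha: float = 0.05,
) -> dict:
    """Detection power for the programmed Th17 elevation.

    For each replicate a :func:`th17_scenario` panel is simulated and
    (a) IL-17A under *condition* is tested against the activated
    control (Monte Carlo permutation MWU), (b) the per-donor Th17/Th1
    ratio medians are compared between *condition* and control.
    Returns the fraction of replicates with p < alpha and the fraction
    with an elevated ratio median.
    """
    master = np.random.default_rng(seed)
    ratio_def = [r for r in DEFAULT_RATIOS if r.name == "Th17/Th1"]
    rejected = 0
    ratio_up = 0
    for _ in range(n_replicates):
        scenario = th17_scenario(donors=donors, seed=int(master.integers(2**31)), fold=fold)
        scenario = replace(scenario, conditions=("activated", condition))
        panel = simulate_panel(scenario)
        a = panel.values("activated", "IL-17A")
        b = panel.values(condition, "IL-17A")
        config = TestConfig(n_permutations=n_perm, seed=int(master.integers(2**31)))
        result = mwu_permutation_test(a, b, config)
        if result.p_value < alpha:
            rejected += 1
        ratio_table = compute_ratios(panel, ratio_def, DEFAULT_SUBSET_MAP)
        med = ratio_table.groupby("condition")["value"].median()
        if med[condition] > med["activated"]:
            ratio_up += 1
    return {
        "il17a_power": rejected / n_replicates,
        "th17_th1_elevated_fraction": ratio_up / n_replicates,
        "n_replicates": n_replicates,
        "donors": donors,
        "fold": fold,
        "condition": condition,
    }
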