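"""Format readers/writers, configuration, and the mine-score pipeline.

All tabular I/O is plain TSV with documented headers. FASTA parsing
(via Biopython) accepts wrapped lines and ignores description text
after the first whitespace. The pipeline configuration is a single
YAML file whose values CLI flags override.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .bioactivity import AlignmentParams, ReferencePeptide, rank_candidates
from .immunoassay import RatioDefinition, canonical_cytokine
from .mining import MiningConfig, mine_peptides
from .proteolysis import ProteaseCocktail, intestinal_cocktail, parse_rules_text

logger = logging.getLogger("pepscreen")

__all__ = [
    "read_fasta",
    "read_tsv",
    "write_tsv",
    "read_rules_file",
    "read_reference_set",
    "demo_reference_set",
    "read_subset_map",
    "read_ratio_definitions",
    "PipelineConfig",
    "run_pipeline",
]


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence) pairs.

    The record id is the header token before the first whitespace;
    wrapped sequence lines are joined.
    """
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a table as TSV with header, stable column order, no index."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_rules_file(path) -> ProteaseCocktail:
    """Parse a cleavage-rules file (one rule per line, # comments)."""
    return parse_rules_text(Path(path).read_text())


def read_reference_set(path) -> List[ReferencePeptide]:
    """Read a reference-peptide TSV with columns ref_id, sequence, annotation."""
    df = read_tsv(path)
    required = {"ref_id", "sequence"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference set {path} must have columns ref_id, sequence[, annotation]")
    if df.empty:
        raise ValueError(f"reference set {path} is empty")
    ids = df["ref_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"reference set {path} has duplicate ref_id values")
    return [
        ReferencePeptide(
            ref_id=str(row["ref_id"]),
            sequence=str(row["sequence"]).upper(),
            annotation=str(row.get("annotation", "") or ""),
        )
        for _, row in df.iterrows()
    ]


def demo_reference_set() -> List[ReferencePeptide]:
    """The packaged synthetic demonstration reference set.

    These entries are synthetic stand-ins illustrating the schema, not
    curated published immunomodulatory sequences; supply your own TSV
    for real screening.
    """
    with resources.as_file(
        resources.files("pepscreen.data").joinpath("demo_references_synthetic.tsv")
    ) as p:
        return read_reference_set(p)


def read_subset_map(path) -> dict:
    """Read a subset map TSV with columns subset, cytokines (comma-separated)."""
    df = read_tsv(path)
    if not {"subset", "cytokines"}.issubset(df.columns):
        raise ValueError(f"subset map {path} must have columns subset, cytokines")
    out = {}
    for _, row in df.iterrows():
        members = tuple(
            canonical_cytokine(tok.strip()) for tok in str(row["cytokines"]).split(",") if tok.strip()
        )
        if not members:
            raise ValueError(f"subset {row['subset']!r} has no member cytokines")
        out[str(row["subset"])] = members
    return out


def read_ratio_definitions(path) -> List[RatioDefinition]:
    """Read ratio definitions TSV with columns name, numerator, denominator
    (terms '+'-separated within a field)."""
    df = read_tsv(path)
    if not {"name", "numerator", "denominator"}.issubset(df.columns):
        raise ValueError(f"ratio file {path} must have columns name, numerator, denominator")
    out = []
    for _, row in df.iterrows():
        out.append(
            RatioDefinition(
                name=str(row["name"]),
                numerator=tuple(t.strip() for t in str(row["numerator"]).split("+") if t.strip()),
                denominator=tuple(t.strip() for t in str(row["denominator"]).split("+") if t.strip()),
            )
        )
    return out


@dataclass
class PipelineConfig:
    """Resolved configuration for :func:`run_pipeline`."""

    rules_file: Optional[str] = None
    min_length: int = 10
    max_length: int = 19
    require_resistance: bool = True
    deduplicate: bool = False
    mode: str = "windows"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    threshold_percent: Optional[float] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def cocktail(self) -> ProteaseCocktail:
        if self.rules_file:
            return read_rules_file(self.rules_file)
        return intestinal_cocktail()

    def mining_config(self) -> MiningConfig:
        return MiningConfig(
            min_length=self.min_length,
            max_length=self.max_length,
            cocktail=self.cocktail(),
            require_resistance=self.require_resistance,
            deduplicate=self.deduplicate,
            mode=self.mode,
        )

    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(
            match=self.match, mismatch=self.mismatch,
            gap_open=self.gap_open, gap_extend=self.gap_extend,
        )


def run_pipeline(
    fasta_path,
    reference_path=None,
    config: Optional[PipelineConfig] = None,
    out_path=None,
    log_path=None,
) -> pd.DataFrame:
    """Mine candidates from a proteome and rank them against references.

    Executes mine -> score -> rank, writes the ranked TSV report to
    *out_path* if given, and a run log capturing every resolved
    parameter to *log_path*. Fully deterministic: identical inputs and
    configuration give a byte-identical report.
    """
    config = config or PipelineConfig()
    proteome = read_fasta(fasta_path)
    references = read_reference_set(reference_path) if reference_path else demo_reference_set()
    logger.info("mining %d protein(s) with lengths %d-%d", len(proteome), config.min_length, config.max_length)
    candidates = mine_peptides(proteome, config.mining_config())
    if candidates.empty:
        logger.warning("no candidates survived mining/filtering; report will have 0 rows")
    ranked = rank_candidates(
        candidates, references, config.alignment_params(), config.threshold_percent
    )
    if out_path is not None:
        write_tsv(ranked, out_path)
    if log_path is not None:
        log = {
            "pepscreen_version": __version__,
            "inputs": {"fasta": str(fasta_path), "references": str(reference_path or "packaged synthetic demo set")},
            "parameters": {
                k: getattr(config, k) for k in PipelineConfig.__dataclass_fields__
            },
            "cocktail": [r.protease_name for r in config.cocktail()],
            "n_candidates": int(len(ranked)),
        }
        Path(log_path).parent.mkdir(parents=True, exist_ok=True)
        Path(log_path).write_text(yaml.safe_dump(log, sort_keys=False))
    return ranked
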