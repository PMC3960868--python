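"""Pipeline configuration: one YAML file, flag overrides, inspectable defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from famscan.genome_scan import DEFAULT_UPSTREAM_BP, DEFAULT_DOWNSTREAM_BP
from famscan.gene_models import MIN_ORF_CODONS
from famscan.dupstats import DEFAULT_PROXIMAL_MAX_GAP


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of the annotation/classification/statistics pipeline.

    The two-threshold scheme mirrors the annotate-then-confirm logic of the
    workflow: ``scan_bits`` is the permissive detection threshold and
    ``confirm_bits`` the stricter cutoff a gene must pass to enter the final
    set.  The locus window (300 bp upstream, 19,700 bp downstream of the
    detected domain start) matches the published extraction window.
    """

    # paths
    assembly: str = ""
    cds: str = ""
    annotation: str = ""
    seed_alignment: str = ""
    references: str = ""
    ref_proteins: str = ""
    proteins: str = ""
    positions: str = ""
    tree: str = ""
    species_map: str = ""
    outdir: str = "famscan_out"
    # thresholds
    scan_bits: float = 10.0
    confirm_bits: float = 20.0
    min_reciprocal_overlap: float = 0.5
    min_peptide: int = 40
    min_orf_codons: int = MIN_ORF_CODONS
    proximal_max_gap: int = DEFAULT_PROXIMAL_MAX_GAP
    gap_threshold: float = 0.5
    pseudocount_weight: float = 1.0
    # locus window
    upstream_bp: int = DEFAULT_UPSTREAM_BP
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP
    # misc
    seed: int = 0
    gene_id_prefix: str = "FAM"
    external_predictor: str = ""  # command template with {fasta}; empty = naive caller
    outgroup: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        import math
        for name in ("scan_bits", "confirm_bits", "min_reciprocal_overlap"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ConfigError("window sizes must be >= 0")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def merged(self, **overrides) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig(**data)
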