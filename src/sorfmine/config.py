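"""Pipeline configuration: paths, thresholds and the seed, YAML-loadable."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # inputs
    transcripts_fasta: str = "transcripts.fasta"
    transcripts_tsv: str = "transcripts.tsv"
    refprot_fasta: str = "refprot.fasta"
    known_fasta: str = "known.fasta"
    peptides_tsv: str = "peptides.tsv"
    design_tsv: str = "design.tsv"
    spectra_mgf: str | None = "spectra.mgf"
    external_dbs: list[str] = field(default_factory=list)
    out_dir: str = "sorfmine_out"
    # sORF database
    start_codons: list[str] = field(default_factory=lambda: ["ATG", "CTG", "GTG"])
    min_aa: int = 7
    max_aa: int = 200
    emit_all_starts: bool = False
    # novelty
    similarity_cutoff: float = 80.0
    il_stage1: bool = True
    il_stage2: bool = False
    # spectra
    fragment_tolerance_da: float = 0.02
    spectral_thresholds: list[float] = field(default_factory=lambda: [0.5, 0.7, 0.75])
    # differential expression / DEP calling
    dep_fc_up: float = 2.0
    dep_fc_down: float = 0.5
    dep_alpha: float = 0.05
    equal_var: bool = True
    # nascent labeling
    nascent_min_ratio: float = 2.0
    # candidate selection
    candidate_sim_threshold: float = 0.75
    candidate_fc_threshold: float = 1.50
    candidate_min_donors: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.similarity_cutoff <= 100:
            raise ValueError("similarity_cutoff must lie in (0, 100]")
        if self.min_aa < 1 or self.max_aa < self.min_aa:
            raise ValueError("need 1 <= min_aa <= max_aa")
        if not 0 < self.dep_alpha < 1:
            raise ValueError("dep_alpha must lie in (0, 1)")
        if self.fragment_tolerance_da <= 0:
            raise ValueError("fragment_tolerance_da must be > 0")
        for t in self.spectral_thresholds:
            if not 0 <= t <= 1:
                raise ValueError("spectral thresholds must lie in [0, 1]")
        if not 0 <= self.candidate_sim_threshold <= 1:
            raise ValueError("candidate_sim_threshold must lie in [0, 1]")
        if self.candidate_min_donors < 1:
            raise ValueError("candidate_min_donors must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
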