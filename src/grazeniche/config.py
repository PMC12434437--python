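"""Validated pipeline configuration (YAML-serializable, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class SimulateSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    enabled: bool = True
    n_taxa: int = Field(25, gt=2)
    n_samples_per_species_year: int = Field(15, gt=0)
    n_subareas: int = Field(3, gt=0)
    n_replicates: int = Field(4, gt=0)
    reads_per_replicate: int = Field(5000, gt=0)
    diet_concentration: float = Field(40.0, gt=0)
    density_breadth_coefficient: float = 0.7
    contamination_rate: float = Field(0.02, ge=0, lt=1)
    tag_switch_rate: float = Field(0.002, ge=0, lt=1)


class FilterSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_len: int = 10
    max_len: int = 220
    min_reads_per_cell: int = 10
    cluster_identity: float = Field(0.97, gt=0, le=1)
    reference_identity: float = Field(0.97, gt=0, le=1)
    min_replicate_reads: int = 100


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    overlap_basis: str = "foo"
    energy_variants: tuple[str, ...] = ("total", "red_deer", "cattle", "horse", "geese")
    reference_variant: str = "total"
    neutral_band: float = Field(0.1, ge=0)
    energy_unit: str = "kJ/day"
    census_season: str = "October"


class PipelineConfig(BaseModel):
    """Full pipeline configuration; see docs/methods.md for parameter notes."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    output_dir: Path = Path("grazeniche_run")
    reads_tsv: Path | None = None
    sequences_fasta: Path | None = None
    reference_fasta: Path | None = None
    census_csv: Path | None = None
    survey_csv: Path | None = None
    simulate: SimulateSection = SimulateSection()
    filter: FilterSection = FilterSection()
    model: ModelSection = ModelSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
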