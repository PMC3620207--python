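"""Validated run configuration: one YAML, one root seed, every stage knob.

Unknown keys are rejected (``extra='forbid'``) and all defaults are
serialised into the run manifest, so a manifest alone reproduces a run.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .annotate import DEFAULT_PRIORITY
from .reference import ReferenceConfig
from .simulate import DEFAULT_ADAPTER, DEFAULT_LENGTH_PMF, DEFAULT_MIXTURE, SimConfig


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneratorSettings(_Model):
    contig_lengths: dict[str, int] = {"chr1": 200_000}
    gc: float = 0.42
    n_mirna: int = 50
    n_novel: int = 5
    n_genes: int = 200
    n_gene_sets: int = 20

    def to_reference_config(self) -> ReferenceConfig:
        return ReferenceConfig(
            contig_lengths=dict(self.contig_lengths), gc=self.gc,
            n_mirna=self.n_mirna, n_novel=self.n_novel,
            n_genes=self.n_genes, n_gene_sets=self.n_gene_sets)


class ReferenceSettings(_Model):
    mode: Literal["generate", "load"] = "generate"
    dir: Optional[str] = None  # required when mode == "load"
    generate: GeneratorSettings = GeneratorSettings()

    @model_validator(mode="after")
    def _check_dir(self) -> "ReferenceSettings":
        if self.mode == "load" and not self.dir:
            raise ValueError("reference.dir is required when reference.mode='load'")
        return self


class SimulateSettings(_Model):
    library_sizes: dict[str, int] = {"nm": 200_000, "bm": 200_000}
    adapter: str = DEFAULT_ADAPTER
    read_len: int = 36
    error_rate: float = 0.001
    low_quality_fraction: float = 0.02
    mixture: dict[str, float] = dict(DEFAULT_MIXTURE)
    fragment_length_pmf: dict[int, float] = dict(DEFAULT_LENGTH_PMF)
    n_effects: int = 10
    effect_magnitude: float = 3.0
    ncrna_species: int = 400
    unann_species: int = 250

    def to_sim_config(self) -> SimConfig:
        return SimConfig(
            library_sizes=dict(self.library_sizes), adapter=self.adapter,
            read_len=self.read_len, error_rate=self.error_rate,
            low_quality_fraction=self.low_quality_fraction,
            mixture=dict(self.mixture),
            fragment_length_pmf={int(k): v for k, v in self.fragment_length_pmf.items()},
            n_effects=self.n_effects, effect_magnitude=self.effect_magnitude,
            ncrna_species=self.ncrna_species, unann_species=self.unann_species)


class PreprocessSettings(_Model):
    min_overlap: int = 7
    min_quality: float = 20.0
    min_len: int = 12
    max_len: int = 30


class AnnotateSettings(_Model):
    max_hits: int = 1
    priority: list[str] = list(DEFAULT_PRIORITY)
    mirna_3p_tolerance: int = 2


class NovelSettings(_Model):
    flank: int = 100
    mfe_threshold: float = -18.0
    min_paired_mature: int = 16
    loop_min: int = 4
    loop_max: int = 30
    min_tag_count: int = 5


class DESettings(_Model):
    fc_threshold: float = 2.0
    alpha: float = 0.05
    filter_mode: Literal["both", "either"] = "both"


class TargetSettings(_Model):
    min_sites_per_edge: int = 1
    hub_min_degree: int = 5
    external_sites: Optional[str] = None  # TSV merged as a union


class EnrichSettings(_Model):
    method: Literal["BH", "bonferroni"] = "BH"
    alpha: float = 0.05


class RunConfig(_Model):
    seed: int = 0
    out_dir: str = "runs/run"
    log_level: str = "INFO"
    reference: ReferenceSettings = ReferenceSettings()
    simulate: SimulateSettings = SimulateSettings()
    preprocess: PreprocessSettings = PreprocessSettings()
    annotate: AnnotateSettings = AnnotateSettings()
    novel: NovelSettings = NovelSettings()
    de: DESettings = DESettings()
    targets: TargetSettings = TargetSettings()
    enrich: EnrichSettings = EnrichSettings()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})
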