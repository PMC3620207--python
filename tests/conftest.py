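import logging

import pytest

from mirmet.config import (GeneratorSettings, ReferenceSettings, RunConfig,
                           SimulateSettings)
from mirmet.pipeline import run_all
from mirmet.reference import ReferenceConfig, build_reference

logging.getLogger("mirmet").setLevel(logging.ERROR)

SMALL_REF = ReferenceConfig(
    contig_lengths={"chr1": 60_000}, n_mirna=20, n_novel=3,
    n_genes=40, n_gene_sets=8)


def small_run_config(out_dir: str, seed: int = 11) -> RunConfig:
    """A scaled-down experiment (30k reads/library) for fast integration tests."""
    return RunConfig(
        seed=seed, out_dir=out_dir, log_level="ERROR",
        reference=ReferenceSettings(generate=GeneratorSettings(
            contig_lengths={"chr1": 60_000}, n_mirna=20, n_novel=3,
            n_genes=40, n_gene_sets=8)),
        simulate=SimulateSettings(
            library_sizes={"nm": 30_000, "bm": 30_000}, n_effects=6,
            ncrna_species=100, unann_species=60))


@pytest.fixture(scope="session")
def small_bundle():
    return build_reference(SMALL_REF, seed=11)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One finished scaled-down pipeline run shared across tests."""
    out = tmp_path_factory.mktemp("smallrun")
    cfg = small_run_config(str(out / "run"))
    return run_all(cfg), cfg
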