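import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from paralethal import synthetic_data as sd
from paralethal.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def toy_genome():
    """Small genome with planted exact duplications (mutation rate 0)."""
    cfg = sd.GenomeConfig(
        n_chromosomes=2,
        chromosome_length=20_000,
        n_genes=12,
        gene_length=1_000,
        n_duplicate_pairs=2,
        duplication_mutation_rate=0.0,
    )
    genome, genes, dupmap = sd.generate_toy_genome(cfg, seed=11)
    return {"config": cfg, "genome": genome, "genes": genes, "dupmap": dupmap}


@pytest.fixture(scope="session")
def toy_guides(toy_genome):
    guides, warnings_ = sd.generate_guide_library(
        toy_genome["genome"], toy_genome["genes"], guides_per_gene=4, seed=11
    )
    return {"guides": guides, "warnings": warnings_}


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort at reduced size for fast unit tests."""
    cfg = sd.CohortConfig(
        n_genes=150, n_cell_lines=40, n_planted_sl_pairs=10, seed=7
    )
    return sd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default study conditions."""
    return run_pipeline(RunConfig(seed=1))
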