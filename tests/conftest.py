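"""Shared fixtures: small synthetic bundles generated once per session."""

import pytest

from symtox.simulate import SimConfig, generate_genome_set


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A scaled-down study: one focal genome, four reference genomes."""
    return SimConfig(
        n_focal_genomes=1, n_reference_genomes=4, n_core_genes=30,
        n_specific_genes=15,
        trg_plant_spec=[("YD", 6, 0.2), ("RTX", 3, 0.2), ("MARTX", 4, 0.2)],
        n_genomes_per_lifestyle=10, mean_protein_len=120, rng_seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_sim_config):
    return generate_genome_set(small_sim_config)
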