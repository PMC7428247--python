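"""Shared fixtures: a small world for fast integration checks and a
default-sized world (session-scoped) for the recovery tests."""

from __future__ import annotations

import numpy as np
import pytest

from beemir import WorldConfig, generate_world


def small_config(seed: int = 0, **overrides) -> WorldConfig:
    """A scaled-down world: 3 species, 60 kb genomes, 48 genes."""
    kwargs = dict(
        n_species=4,
        genome_length_per_species=60_000,
        n_genes=48,
        n_shared_mirna_families=12,
        n_lineage_specific_per_species=6,
        sites_per_ls_mirna=2,
        n_copy_accessions=12,
        rng_seed=seed,
    )
    kwargs.update(overrides)
    return WorldConfig(**kwargs)


@pytest.fixture(scope="session")
def small_world():
    return generate_world(small_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
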