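import pytest

from clustevo import WorldConfig, generate_world, run_pipeline, world_inputs

#: Planted cluster pairs covering the detection boundary on both sides.
PLANTED_PAIRS = (
    ("Afum", "Anid", 1, 1.0),
    ("Afum", "Aory", 1, 0.6),
    ("Anid", "Anig", 1, 0.5),
    ("Anig", "Aory", 1, 0.3),
)


@pytest.fixture(scope="session")
def small_world():
    """A compact seeded world with planted conserved cluster pairs."""
    cfg = WorldConfig(
        seed=42,
        genes_per_species=600,
        n_clusters_per_species=8,
        cluster_size_range=(2, 12),
        planted_conserved_pairs=PLANTED_PAIRS,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def small_world_result(small_world):
    return run_pipeline(world_inputs(small_world))
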