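import numpy as np
import pytest

from mitopop import forge


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down population: same structure as the study system
    (two types, shared repeats, insertion, marker) at desk-test size."""
    return forge.ForgeConfig(
        seed=11,
        molecule_specs=[(40_000, "circular"), (30_000, "circular"), (90_000, "linear")],
        repeat_specs=[
            forge.RepeatSpec(1_200, "direct", ((0, 2_000), (0, 20_000))),
            forge.RepeatSpec(800, "inverted", ((0, 30_000), (0, 35_000))),
            forge.RepeatSpec(2_000, "direct", ((2, 40_000), (0, 9_000))),
        ],
        plastome_length=30_000,
        cp_insert_length=3_000,
        cp_insert_molecule=1,
        cp_insert_pos=5_000,
        cp_insert_plastome_pos=8_000,
        n_insert_branch_variants=8,
        n_insert_internal_variants=12,
        marker_length=1_000,
        marker_molecule=1,
        marker_pos=20_000,
        n_differential_loci=30,
        n_samples_per_type=(4, 4),
        coverage=100.0,
        error_rate=0.001,
        heteroplasmy_fraction=0.04,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return forge.forge_population(small_config)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(20240917))
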