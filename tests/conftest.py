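import numpy as np
import pytest

from ageval import (
    CohortConfig,
    ReaderProfile,
    ScaleGeometryConfig,
    generate_cohort,
    simulate_reader_estimates,
    simulate_scale_radii,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-fish cohort with every freshwater age known (deterministic)."""
    return generate_cohort(CohortConfig(n_fish=60, fw_known_prob=1.0, seed=11))


@pytest.fixture(scope="session")
def exact_geometry():
    """Through-origin geometry with no per-fish spread: Lea-Dahl is exact."""
    return ScaleGeometryConfig(formation_length=0.0, per_fish_radius_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_readers():
    return [
        ReaderProfile(
            f"R{i}",
            sea_misclass_prob_by_class={"1SW": 0.0, "MSW": 0.0},
            fw_misclass_prob=0.0,
            fw_unreadable_prob=0.0,
            smolt_length_unreadable_prob=0.0,
            radius_noise_sd=0.0,
        )
        for i in (1, 2, 3)
    ]


@pytest.fixture(scope="session")
def full_synthetic(small_cohort):
    """Cohort + reads + radii under default geometry and reader profiles."""
    radii = simulate_scale_radii(small_cohort, seed=21)
    reads = simulate_reader_estimates(small_cohort, seed=22)
    return small_cohort, reads, radii
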