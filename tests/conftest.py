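import numpy as np
import pytest

from acceptorkit.sequence_io import ThreePrimeRegion
from acceptorkit.synthetic_data import (default_cohort_config,
                                        generate_cohort,
                                        structure_cohort_config)


def make_region(upstream: str, exon: str = "GGGAA",
                exon_id: str = "r1", group: str = "control",
                ) -> ThreePrimeRegion:
    """Region from explicit upstream (intron) and exon-side sequences."""
    return ThreePrimeRegion(exon_id=exon_id, sequence=upstream + exon,
                            up_len=len(upstream), down_len=len(exon),
                            group=group)


@pytest.fixture(scope="session")
def small_cohort():
    """Architecture-condition cohort, 40 exons per group."""
    return generate_cohort(default_cohort_config(seed=11, n_per_group=40))


@pytest.fixture(scope="session")
def full_cohort():
    """Architecture-condition cohort at the full study size (100/group)."""
    return generate_cohort(default_cohort_config(seed=23, n_per_group=100))


@pytest.fixture(scope="session")
def structure_cohort():
    """Hairpin-vs-unstructured cohort for PU contrasts (60/group)."""
    return generate_cohort(structure_cohort_config(seed=17, n_per_group=60))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
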