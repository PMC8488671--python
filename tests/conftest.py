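import pytest
from hypothesis import HealthCheck, settings

from introgmap import MosaicSpec, SimConfig, Zygosity, generate_parents

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=11, n_chrom=1, genes_per_chrom=60)


@pytest.fixture(scope="session")
def small_parents(small_cfg):
    return generate_parents(small_cfg)


@pytest.fixture(scope="session")
def thirds_mosaic() -> MosaicSpec:
    """60 genes split into hom-recurrent / het / hom-donor thirds."""
    return MosaicSpec("IL", [
        ("chr1", 0, 19, Zygosity.HOM_RECURRENT),
        ("chr1", 20, 39, Zygosity.HET),
        ("chr1", 40, 59, Zygosity.HOM_DONOR),
    ])
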