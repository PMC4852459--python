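import pytest
from hypothesis import HealthCheck, settings

from nlrevo.famsim import SimConfig, simulate_family

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: desk-scale chromosome table used where genome sequence is materialised
SMALL_CHROMS = {
    "chr4": 120_000,
    "chr1": 80_000,
    "chr17": 60_000,
    "chr15": 60_000,
    "chr22": 50_000,
}


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """Fast simulator configuration: 2 groups x 4 genes, short domains."""
    base = dict(
        n_groups=2,
        genes_per_group=4,
        codons_per_domain={"nacht": 40, "b30.2": 40},
        generations=120,
        embedded_motifs={"nacht": [(5, "GIAGIAGKT")], "b30.2": [(10, "WEVEVS")]},
        chrom_lengths=dict(SMALL_CHROMS),
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size simulated family shared by read-only tests."""
    return simulate_family(SimConfig(seed=11))


@pytest.fixture()
def small_dataset():
    return simulate_family(small_config())
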