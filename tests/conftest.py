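import pytest

from crossseq import GuideSpec, SimConfig, simulate_dataset

SPACER = "GACTGACTGACTGACTGACT"


@pytest.fixture(scope="session")
def guide():
    return GuideSpec(SPACER)


@pytest.fixture(scope="session")
def small_dataset(guide):
    """A modest nuclease simulation shared by read-level tests."""
    cfg = SimConfig(seed=11, genome_length=20_000, mean_depth=60,
                    n_offtargets=2, planted_bulges=1, cleavage_fraction=0.4)
    genome, sites, treated, control = simulate_dataset(cfg, guide)
    return cfg, genome, sites, treated, control
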