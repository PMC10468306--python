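import pytest

from felvar.annotate import annotate_variants
from felvar.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic scenario emulating the study (seed 1)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_annotation(default_bundle):
    b = default_bundle
    return annotate_variants(b.variants, b.genome, b.genes)


@pytest.fixture(scope="session")
def small_bundle():
    """A slimmed cohort (two engineered genes only) for oracle loops."""
    cfg = SimulationConfig(
        seed=7, n_candidate_genes=2, n_background_genes=0, n_background_variants=20
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def causal_variant(default_bundle):
    b = default_bundle
    return next(v for v in b.variants if v.pos == b.truth.causal["pos"])


@pytest.fixture()
def decoy_variant(default_bundle):
    b = default_bundle
    return next(v for v in b.variants if v.pos == b.truth.decoy["pos"])
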