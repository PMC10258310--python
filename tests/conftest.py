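import numpy as np
import pytest

from repsig import Clonotype, RepertoireSample, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small but structurally complete simulation world."""
    return SimulationConfig(
        n_patients=4,
        chains=("TRB", "IGH"),
        clones_per_sample=60,
        seed=7,
    )


def make_clonotype(**kwargs) -> Clonotype:
    """A valid productive TRB clonotype with overridable fields."""
    defaults = dict(
        clone_id="c1",
        count=1,
        cdr3_aa="CASSF",
        cdr3_nt="TGTGCCAGCAGCTTC",
        v_call="TRBV19",
        d_call="TRBD1",
        j_call="TRBJ2",
        chain="TRB",
    )
    defaults.update(kwargs)
    return Clonotype(**defaults)


def make_sample(clonotypes, patient="P1", tissue="tumor", chain="TRB") -> RepertoireSample:
    return RepertoireSample(
        patient_id=patient, tissue=tissue, chain=chain, clonotypes=list(clonotypes)
    )


@pytest.fixture
def random_profile_factory(rng):
    """Random abundance profiles for property tests."""
    from repsig import AbundanceProfile

    def factory(n_labels=None, shared_with=None, level="CDR3aa"):
        n = n_labels or int(rng.integers(1, 30))
        labels = [f"L{i}" for i in range(n)]
        if shared_with is not None:
            pool = list(shared_with.counts)
            k = int(rng.integers(0, min(len(pool), n) + 1))
            labels[:k] = list(rng.choice(pool, size=k, replace=False))
        counts = {lab: int(rng.integers(1, 100)) for lab in labels}
        return AbundanceProfile(level=level, counts=counts)

    return factory
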