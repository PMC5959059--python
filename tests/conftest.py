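import numpy as np
import pytest
from hypothesis import settings

from pigeonblup.pedigree import PedigreeRecord, validate_and_sort
from pigeonblup.simulate import SimulationConfig, simulate_pedigree

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def trio():
    """Unrelated sire and dam with one offspring."""
    return validate_and_sort(
        [
            PedigreeRecord("sire", sex="male"),
            PedigreeRecord("dam", sex="female"),
            PedigreeRecord("kid", "sire", "dam"),
        ]
    )


@pytest.fixture
def full_sib_mating():
    """Offspring of a full-sib mating (inbred, F = 0.25)."""
    return validate_and_sort(
        [
            PedigreeRecord("gs", sex="male"),
            PedigreeRecord("gd", sex="female"),
            PedigreeRecord("bro", "gs", "gd", "male"),
            PedigreeRecord("sis", "gs", "gd", "female"),
            PedigreeRecord("inbred", "bro", "sis"),
        ]
    )


@pytest.fixture
def random_pedigree():
    """~200-animal random multi-generation pedigree."""
    cfg = SimulationConfig(
        n_founders=40, n_generations=3, n_matings=14, offspring_per_mating=4, seed=42
    )
    return simulate_pedigree(cfg, np.random.default_rng(42))
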