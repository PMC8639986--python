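import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hdx_config():
    """Small HDX simulation: 56-residue construct, 6 overlapping peptides."""
    from rtkquant.synthetic import HdxSimConfig

    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
    rates = tuple(np.random.default_rng(11).uniform(0.1, 5.0, len(seq)))
    peptides = ((1, 12), (8, 20), (15, 30), (25, 40), (35, 50), (45, 56))
    return HdxSimConfig(sequence=seq, rates=rates, peptides=peptides, seed=7)


@pytest.fixture(scope="session")
def sphere_beads():
    from rtkquant.synthetic import gen_toy_structure

    return gen_toy_structure("solid_sphere_beads", radius=30.0, n_points=3000, seed=5)


@pytest.fixture(scope="session")
def dumbbell_beads():
    from rtkquant.synthetic import gen_toy_structure

    return gen_toy_structure(
        "dumbbell", radius=15.0, separation=80.0, n_points=3000, seed=6
    )
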