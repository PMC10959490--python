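import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import barfit as bf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_design():
    """All 7 treatments x 2 chemicals, 2 populations each: 56 lineages."""
    return bf.build_design(
        {
            "treatments": list(bf.design.STANDARD_SCHEDULES),
            "chemicals": ["salt", "copper"],
            "populations_per_treatment": 2,
        }
    )


@pytest.fixture(scope="session")
def sim(small_design):
    """One seeded synthetic experiment reused across read-level tests."""
    truth = bf.draw_true_effects(small_design, seed=11)
    exp = bf.simulate_experiment(
        small_design, truth, depth=30_000, seed=11, contamination=0.005
    )
    return exp


@pytest.fixture(scope="session")
def tiny_library():
    rng = np.random.default_rng(3)
    bases = np.array(list("ACGT"))
    seqs = {}
    for bc in ["d1H10", "A", "B", "C"]:
        seqs[bc] = "".join(rng.choice(bases, size=20))
    return bf.BarcodeLibrary(sequences=seqs, reference_id="d1H10")
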