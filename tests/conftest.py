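import numpy as np
import pytest

import statusgen as sg


@pytest.fixture(scope="session")
def small_pedigree():
    """Combined-calibration pedigree, 800 families, mediators attached."""
    cfg = sg.paper_scenario(n_families=800, seed=1)
    ped = sg.simulate_population(cfg)
    aug = sg.attach_mediators_health_panel(ped)
    return ped, aug


@pytest.fixture(scope="session")
def nurture_children():
    """Final generation of a noise-free nurture-only simulation
    (share 0.25, random mating): the workhorse for design-recovery checks."""
    cfg = sg.nurture_scenario(
        0.25, n_families=12_000, total_effect=1.0, n_generations=2, seed=2
    )
    last = sg.simulate_population(cfg).final_generation.copy()
    last["observed_pgs"] = last["additive_score"]
    return last


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
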