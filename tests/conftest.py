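import numpy as np
import pytest

from stratnet import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_study():
    """One cohort at the default desk-scale configuration."""
    return generate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def planted_small_study():
    """Planted cohort at reduced scale for fast module tests."""
    cfg = SimulationConfig(
        seed=11,
        n_subjects=400,
        n_nodes=30,
        n_networks=5,
        conditions=("cond_a", "cond_b"),
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noise_study():
    """Pure-noise cohort: effect sizes 0, nothing planted."""
    cfg = SimulationConfig(
        seed=21,
        n_subjects=200,
        n_nodes=20,
        n_networks=4,
        conditions=("c1",),
        effect_size_ext=0.0,
        effect_size_int=0.0,
        planted_ext_edges=0,
        planted_int_edges=0,
        planted_general_edges=0,
        waves=(("wave1", 14.0),),
    )
    return generate_cohort(cfg)


def wave1_views(study):
    """(connectomes, symptoms, covariates) at the first wave."""
    w1 = study.config.wave_labels[0]
    conn = {c: study.connectome_at(c, w1) for c in study.config.conditions}
    sym = study.symptoms_at(w1)
    cov = study.covariates_at(w1)[["site", "sex", "age"]]
    return conn, sym, cov


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
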