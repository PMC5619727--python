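import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import methylselect as ms

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def model_set6() -> ms.ModelSet:
    """The twelve-model candidate set of the six-population design."""
    return ms.hematopoietic_model_set()


@pytest.fixture(scope="session")
def strong_signal_run(model_set6):
    """Strong-signal simulation (effect 0.3, sigma 0.02, n=5, K=2000) with
    its fit and per-model marker panels; shared across tests."""
    cfg = ms.SimulationConfig(
        K=2000, n_per_sex={"F": 5}, sigma=0.02, effect_size=0.3,
        sex_shift=None, seed=11,
    )
    datasets, truth = ms.simulate_dataset(cfg)
    fit = ms.fit(datasets["F"], cfg.models)
    panels = {
        name: ms.select_markers(fit.probe_ids, fit.prob_for(name), 0.05, name)
        for name in fit.model_names
    }
    return cfg, datasets, truth, fit, panels


@pytest.fixture()
def tiny_dataset():
    """Small two-sex dataset for plumbing tests (K=40)."""
    cfg = ms.SimulationConfig(K=40, sigma=0.02, seed=5)
    datasets, truth = ms.simulate_dataset(cfg)
    return cfg, datasets, truth


def random_instance(rng: np.random.Generator, J: int, n_s: int):
    """A random (y, models) instance over J generic cell types."""
    from methylselect.lineage import LineageTree, enumerate_candidate_models

    labels = tuple(chr(ord("A") + j) for j in range(J))
    merges = []
    nodes = list(range(J))
    h = 1.0
    while len(nodes) > 1:
        merges.append((nodes[0], nodes[1], h))
        nodes = nodes[2:] + [J + len(merges) - 1]
        h += 1.0
    tree = LineageTree(leaves=labels, merges=tuple(merges), linkage="complete")
    models = enumerate_candidate_models(tree)
    y = np.clip(rng.normal(0.5, 0.15, size=(n_s, J)), 0.0, 1.0)
    return y, models
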