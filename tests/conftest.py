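import numpy as np
import pytest

import dotconn as dc
from dotconn.graph import BrainGraph
from dotconn.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_atlas():
    return dc.make_atlas(12, 3, nodes_per_parcel=4, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 3/3/3 cohort shared by pipeline-level tests (generated once)."""
    cfg = CohortConfig(n_hc=3, n_mci=3, n_ad=3, duration_s=120.0, seed=42)
    subjects, atlas, sens = generate_cohort(cfg)
    return cfg, subjects, atlas, sens


def graph_from_weights(w: np.ndarray) -> BrainGraph:
    """Wrap a raw symmetric weight matrix as a BrainGraph for metric tests."""
    w = np.asarray(w, dtype=float)
    v = w.shape[0]
    return BrainGraph(
        w=w,
        sign=(w > 0).astype(int),
        parcel_ids=np.arange(1, v + 1),
        network_labels=np.array(["Net01"] * v, dtype=object),
    )


@pytest.fixture
def make_graph():
    return graph_from_weights
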