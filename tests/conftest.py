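import numpy as np
import pytest

from winggrad import synthetic as syn


@pytest.fixture(scope="session")
def tree24():
    return syn.simulate_tree(24, seed=42)


@pytest.fixture(scope="session")
def tree128():
    return syn.simulate_tree(128, seed=8)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A 32-species synthetic study written to disk once per session."""
    out = tmp_path_factory.mktemp("study32")
    cfg = syn.SynthStudyConfig(n_species=32, seed=5)
    study = syn.generate_study(cfg, out_dir=out)
    study["dir"] = out
    return study


@pytest.fixture(scope="session")
def bench_wing():
    """A dense parametric wing scan with its generating geometry."""
    scan, geom = syn.simulate_wing_pointcloud(n_points=40000, seed=3)
    return scan, geom


def bm_samples(tree, sigma2, n_reps, seed):
    """Draw BM tip-value replicates on a tree (oracle-side simulator)."""
    C, order = tree.vcv()
    L = np.linalg.cholesky(C)
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        yield L @ rng.standard_normal(len(order)) * np.sqrt(sigma2)
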