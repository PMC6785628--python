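import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitosel.models import RateHeterogeneity, aa_model, gtr_model
from mitosel.trees import PhyloTree

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def quartet_tree():
    return PhyloTree.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.15):0.2);")


@pytest.fixture
def nt_gtr_ig(rng):
    return gtr_model(rng.uniform(0.5, 2.0, 6), np.array([0.1, 0.2, 0.3, 0.4]),
                     RateHeterogeneity(0.3317, 0.5895, 4))


@pytest.fixture
def mtmam_g4():
    return aa_model("mtmam", RateHeterogeneity(0.0, 0.8, 4))


def random_bifurcating_newick(rng, n_leaves, scale=0.2):
    parts = [f"L{i}" for i in range(n_leaves)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        a, b = parts[i], parts[j]
        la, lb = rng.exponential(scale, size=2)
        parts = [p for k, p in enumerate(parts) if k not in (i, j)]
        parts.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return parts[0] + ";"
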