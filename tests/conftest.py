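import numpy as np
import pytest

from pharmens.hashing import select_representatives
from pharmens.perception import perceive_pharmacophore
from pharmens.synth import SceneSpec, make_frames


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_scene():
    """A 20-frame synthetic trajectory with 3 planted geometry states."""
    spec = SceneSpec(n_frames=20, n_states=3, jitter_sd=0.05, seed=11)
    frames, truth = make_frames(spec)
    return spec, frames, truth


@pytest.fixture(scope="session")
def small_ensemble(small_scene):
    _, frames, truth = small_scene
    return [perceive_pharmacophore(f) for f in frames], truth


@pytest.fixture(scope="session")
def representatives(small_ensemble):
    models, _ = small_ensemble
    reps, groups = select_representatives(models)
    return reps, groups
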