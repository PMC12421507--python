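import numpy as np
import pytest

from evtrack import SceneParams, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One default-sized scene with a few of everything."""
    params = SceneParams(seed=11, n_cells=3, n_evs_internal=6, n_evs_external=4)
    frame, truth = generate_scene(params)
    return params, frame, truth


def onehot3(class_map: np.ndarray) -> np.ndarray:
    """(3, H, W) one-hot probabilities of an integer class map."""
    return np.eye(3)[class_map].transpose(2, 0, 1)
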