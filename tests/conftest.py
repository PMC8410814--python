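import numpy as np
import pytest

from nodeglia.synthetic_microscopy import generate_scene, high_snr_params, render


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0


@pytest.fixture(scope="session")
def high_snr_field():
    """One rendered high-SNR field with its scene and ground truth."""
    params = high_snr_params()
    scene, truth = generate_scene(
        seed=11, n_nodes=20, params=params, contacted_fraction=0.4
    )
    stacks = render(scene, truth, seed=11)
    return scene, truth, stacks


@pytest.fixture(scope="session")
def high_snr_movie():
    """Short high-SNR movie with Markov contact dynamics and tip tracks."""
    params = high_snr_params(n_frames=12)
    scene, truth = generate_scene(
        seed=23,
        n_nodes=10,
        params=params,
        contacted_fraction=0.5,
        n_frames=12,
        attach=1.0,
        detach=0.1,
    )
    stacks = render(scene, truth, seed=23)
    return scene, truth, stacks
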