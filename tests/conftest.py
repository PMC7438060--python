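import math

import numpy as np
import pytest

import fovalign as fa


@pytest.fixture(scope="session")
def small_scene():
    return fa.generate_scene(n_neurons=15, frame_shape=(192, 192), seed=7)


@pytest.fixture(scope="session")
def session_pair(small_scene):
    """A moderately tilted session pair with known ground truth."""
    spin = math.radians(8)
    phi = 0.6
    pose = fa.AffinePose(lambda_zoom=1.0, psi=(spin - phi) % (2 * math.pi),
                         tilt=1.0 / math.cos(math.radians(25)), phi=phi)
    idx = np.arange(15)
    template = fa.render_session(small_scene, pose=None, active_indices=idx[:12],
                                 noise_sigma=3, background_amplitude=0.1, seed=2)
    moving = fa.render_session(small_scene, pose=pose, translation=(8, -5),
                               active_indices=idx[3:], blur_sigma=1.0,
                               noise_sigma=3, background_amplitude=0.3, seed=3)
    true = template.true_transform @ moving.true_transform.inverse()
    return moving, template, true


@pytest.fixture(scope="session")
def blob_image():
    """10 bright Gaussian blobs on a dark textured background."""
    rng = np.random.default_rng(0)
    scene = fa.generate_scene(n_neurons=10, frame_shape=(200, 200), seed=3)
    r = fa.render_session(scene, noise_sigma=2, seed=1)
    return r.image, scene.neuron_centers
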