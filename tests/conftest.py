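import numpy as np
import pytest

from organgeo.centreline import Centreline, parameterize


def helix_points(a=1.0, c=1.0, turns=1.0, n=600):
    t = np.linspace(0.0, 2 * np.pi * turns, n)
    return np.c_[a * np.cos(t), a * np.sin(t), c * t]


@pytest.fixture
def helix_curve():
    return parameterize(Centreline(helix_points(), specimen_id="helix"))


@pytest.fixture
def circle_curve():
    th = np.linspace(0.0, 2 * np.pi, 800, endpoint=False)
    r = 7.0
    pts = np.c_[r * np.cos(th), r * np.sin(th), np.zeros_like(th)]
    return parameterize(Centreline(pts, specimen_id="circle"))


@pytest.fixture
def noiseless_female():
    from dataclasses import replace

    from organgeo.synthetic import default_female_params

    return replace(default_female_params(), noise_sd=0.0)


@pytest.fixture
def noiseless_male():
    from dataclasses import replace

    from organgeo.synthetic import default_male_params

    return replace(default_male_params(), noise_sd=0.0)


def random_rotation(seed):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=seed).as_matrix()
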