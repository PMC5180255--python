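import numpy as np
import pytest

from xorvision import (
    StimulusGeometry,
    linear_task,
    make_base_set,
    nonlinear_task,
    render,
    response_matrix,
)


@pytest.fixture(scope="session")
def geometry():
    return StimulusGeometry()


@pytest.fixture(scope="session")
def base_configs():
    return make_base_set()


@pytest.fixture(scope="session")
def base_images(base_configs, geometry):
    return [render(c, geometry) for c in base_configs]


@pytest.fixture(scope="session")
def pixel_features(base_images):
    return np.stack([img.pixels.ravel().astype(float) for img in base_images])


@pytest.fixture(scope="session")
def v1_features(base_images):
    """Default-parameter V1 responses of the four base stimuli (stride 4)."""
    R, D = response_matrix(base_images, stride=4)
    return R, D


def task_labels(task, configs):
    return np.array([1 if task.class_of(c) == "target" else -1 for c in configs])


@pytest.fixture(scope="session")
def linear_labels(base_configs):
    return task_labels(linear_task, base_configs)


@pytest.fixture(scope="session")
def nonlinear_labels(base_configs):
    return task_labels(nonlinear_task, base_configs)
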