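import numpy as np
import pytest

from lfaquant.design import assign_factors, get_array

# Published response-table level means (dB) of the ten-factor camera study
# plus its unassigned error column K, used as the reference fixture for the
# screening engine.
CAMERA_LEVEL1 = {
    "A": 41.7435, "B": 43.7364, "C": 43.9219, "D": 42.1578, "E": 43.8906,
    "F": 46.9984, "G": 43.7826, "H": 42.6729, "I": 41.3817, "J": 42.9600,
    "K": 43.5897,
}
CAMERA_LEVEL2 = {
    "A": 44.8924, "B": 42.8995, "C": 42.7140, "D": 44.4781, "E": 42.7453,
    "F": 39.6375, "G": 42.8533, "H": 43.9630, "I": 45.2542, "J": 43.6759,
    "K": 43.0462,
}

CAMERA_FACTORS = [
    {"id": "A", "name": "backlight compensation", "level1": True, "level2": False},
    {"id": "B", "name": "brightness", "level1": -8, "level2": -4},
    {"id": "C", "name": "contrast", "level1": 0.4, "level2": 0.5},
    {"id": "D", "name": "exposure", "level1": 0.4, "level2": 0.3},
    {"id": "E", "name": "gain", "level1": 2, "level2": 0},
    {"id": "F", "name": "gamma", "level1": 1, "level2": 3},
    {"id": "G", "name": "hue", "level1": 0, "level2": 0.4},
    {"id": "H", "name": "saturation", "level1": 50, "level2": 100},
    {"id": "I", "name": "sharpness", "level1": 0, "level2": 3},
    {"id": "J", "name": "white balance", "level1": "Auto", "level2": 2800},
]


@pytest.fixture(scope="session")
def l12():
    return get_array("L12")


@pytest.fixture(scope="session")
def camera_assignment(l12):
    return assign_factors(CAMERA_FACTORS, l12)


@pytest.fixture(scope="session")
def camera_run_sn(l12):
    """A run-S/N vector exactly consistent with the published level means.

    The additive reconstruction grand + sum(effect_j * contrast_j / 2)
    reproduces every column's level means on a balanced orthogonal design,
    so re-deriving the response table from it must give back the published
    effects, ranges and ranks.
    """
    labels = list(CAMERA_LEVEL1)
    grand = np.mean([(CAMERA_LEVEL1[c] + CAMERA_LEVEL2[c]) / 2 for c in labels])
    effects = np.array([CAMERA_LEVEL2[c] - CAMERA_LEVEL1[c] for c in labels])
    signs = np.where(l12.cells == 2, 1.0, -1.0)
    return grand + signs @ (effects / 2.0)
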