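import numpy as np
import pytest

from mangresil.accuracy import ConfusionMatrix
from mangresil.synthetic import SceneSpec, generate_scene

CLASS_LABELS = ("water", "mangrove", "bare_builtup", "other_vegetation")

# Frozen published error matrices (rows = classified, columns = reference).
TABLE3_COUNTS = np.array(
    [
        [81, 0, 0, 0],
        [0, 647, 0, 0],
        [0, 1, 26, 5],
        [0, 1, 0, 944],
    ]
)
TABLE4_COUNTS = np.array(
    [
        [81, 0, 0, 0],
        [0, 642, 1, 4],
        [0, 0, 32, 0],
        [0, 9, 0, 936],
    ]
)


@pytest.fixture(scope="session")
def scene():
    """Default synthetic scene, shared across tests (deterministic)."""
    return generate_scene(SceneSpec(seed=7))


@pytest.fixture()
def table3():
    return ConfusionMatrix(TABLE3_COUNTS, CLASS_LABELS)


@pytest.fixture()
def table4():
    return ConfusionMatrix(TABLE4_COUNTS, CLASS_LABELS)
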