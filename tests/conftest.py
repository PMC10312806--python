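import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lesionwise import LabelMap
from lesionwise.matching import EvalParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_params():
    return EvalParams()


def make_label_map(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0)):
    return LabelMap(voxels=np.zeros(shape, np.int16), spacing=spacing)


@pytest.fixture
def single_lesion_case():
    """32^3 ground truth with one 10-voxel enhancing lesion, empty prediction."""
    gt = np.zeros((32, 32, 32), np.int16)
    gt[10:12, 10:12, 10:12] = 3
    gt[12, 10, 10] = 3
    gt[12, 11, 10] = 3
    return LabelMap(gt), LabelMap(np.zeros_like(gt))
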