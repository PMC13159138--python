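import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def iou06_masks():
    """Pred/ref single-instance masks constructed to have IoU = 6/10."""
    pred = np.zeros((6, 8), dtype=np.int32)
    ref = np.zeros((6, 8), dtype=np.int32)
    pred[0:2, 0:4] = 1  # 8 px
    ref[0:2, 1:5] = 1   # 8 px, overlap 6 -> IoU 6/10
    return pred, ref
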