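import numpy as np
import pytest

from grainsight.data_io import Annotation, BoundingBox, ImageRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(w=100, h=80, boxes=((10, 20, 30, 40),), labels=None, difficult=None, seed=0):
    """Small annotated record with deterministic noise pixels."""
    r = np.random.default_rng(seed)
    pixels = r.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    labels = labels or ["Cfb"] * len(boxes)
    difficult = difficult or [False] * len(boxes)
    anns = [
        Annotation(lab, BoundingBox(*b), diff)
        for b, lab, diff in zip(boxes, labels, difficult)
    ]
    return ImageRecord("test_img", w, h, pixels, anns)


@pytest.fixture
def simple_record():
    return make_record()
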