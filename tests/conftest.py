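import numpy as np
import pytest

from endoart.geometry_metrics import Box
from endoart.io_formats import FrameAnnotations, SubmissionFrame
from endoart.synthetic_fixtures import (FixtureSpec, generate_ground_truth,
                                        perturb_to_predictions)


@pytest.fixture(scope="session")
def small_gt():
    """10 synthetic annotated frames with masks, fixed seed."""
    return generate_ground_truth(FixtureSpec(n_frames=10, seed=42,
                                             image_size=(128, 128)))


@pytest.fixture(scope="session")
def perfect_sub(small_gt):
    """Noise-free clone of the ground truth (boxes + masks)."""
    return perturb_to_predictions(small_gt, with_masks=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_box(x1, y1, x2, y2, cls="specularity", conf=None):
    return Box(class_label=cls, x1=x1, y1=y1, x2=x2, y2=y2, confidence=conf)


@pytest.fixture
def single_frame_pair():
    """One frame: 2 reference boxes, 3 predictions (1 tp geometry each class)."""
    gt = {"f0": FrameAnnotations(frame_id="f0", boxes=[
        make_box(0, 0, 10, 10, "specularity"),
        make_box(30, 30, 50, 50, "bubbles"),
    ], image_size=(64, 64))}
    sub = {"f0": SubmissionFrame(frame_id="f0", boxes=[
        make_box(1, 1, 11, 11, "specularity", conf=0.9),
        make_box(31, 31, 51, 51, "bubbles", conf=0.8),
        make_box(0, 40, 8, 60, "specularity", conf=0.3),
    ])}
    return gt, sub
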