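import numpy as np
import pytest

from bloomdet.boxes import BoundingBox, LabeledImage


@pytest.fixture
def two_box_image() -> LabeledImage:
    px = np.zeros((200, 100, 3), dtype=np.uint8)
    px[:] = (40, 80, 30)
    return LabeledImage(
        image_id="fixture_0",
        width=100,
        height=200,
        pixels=px,
        boxes=[
            BoundingBox(10, 10, 30, 40, "bud"),
            BoundingBox(50, 60, 90, 160, "flower"),
        ],
    )


@pytest.fixture
def uniform_image() -> LabeledImage:
    px = np.full((608, 608, 3), 255, dtype=np.uint8)
    return LabeledImage(image_id="u", width=608, height=608, pixels=px, boxes=[])
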