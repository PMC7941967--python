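import numpy as np
import pytest

from chemseg import PageImage, BinaryImage, BinaryMask, binarize, dilate
from chemseg.synthetic import PageSpec, generate_page


@pytest.fixture
def blank_page() -> PageImage:
    return PageImage(np.full((60, 80), 255, dtype=np.uint8), dpi=None, source_id="blank")


@pytest.fixture
def synthetic_page():
    """One deterministic 3-structure page with annotations."""
    return generate_page(PageSpec(n_structures=3, rng_seed=11))


@pytest.fixture
def dilated_synthetic(synthetic_page):
    """(page, annotation, dilated binary image) with the default 3-px kernel."""
    page, ann = synthetic_page
    return page, ann, dilate(binarize(page, 230), 3)


def random_binary_image(rng: np.random.Generator, h: int = 40, w: int = 40, p: float = 0.25) -> BinaryImage:
    return BinaryImage(rng.random((h, w)) < p)


def random_mask_over(rng: np.random.Generator, h: int, w: int) -> BinaryMask:
    """Random nonempty rectangle mask."""
    y0 = int(rng.integers(0, h - 1))
    x0 = int(rng.integers(0, w - 1))
    y1 = int(rng.integers(y0 + 1, h + 1))
    x1 = int(rng.integers(x0 + 1, w + 1))
    member = np.zeros((h, w), dtype=bool)
    member[y0:y1, x0:x1] = True
    return BinaryMask(member, "r")
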