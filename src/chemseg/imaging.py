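"""Pixel-level primitives shared by every stage of the workflow.

Conventions used throughout the package: 0-based coordinates, origin at the
top-left corner, ``y`` is the row index (increasing downward), ``x`` the
column index (increasing rightward).  Pages carry 8-bit intensities; masks
and binary images are boolean grids with the same height/width as their page.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import InvalidImageError, InvalidParameterError

#: Default binarization threshold.  A high cut filters near-white scan
#: relicts and non-white backgrounds out of the foreground.
DEFAULT_THRESHOLD = 230


@dataclass
class PageImage:
    """One rasterized document page.

    Parameters
    ----------
    pixels
        ``(H, W)`` grayscale or ``(H, W, 3)`` RGB array of uint8 intensities.
    dpi
        Rendering resolution in dots per inch, if known.
    source_id
        Provenance string, typically ``"<document>_p<page index>"``.
    """

    pixels: np.ndarray
    dpi: int | None = 300
    source_id: str = "page"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim == 2:
            pass
        elif arr.ndim == 3 and arr.shape[2] == 3:
            pass
        else:
            raise InvalidImageError(
                f"page must be (H, W) grayscale or (H, W, 3) RGB, got shape {arr.shape}"
            )
        if arr.size == 0:
            raise InvalidImageError("page must have positive dimensions")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise InvalidImageError("intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass
class BinaryImage:
    """Thresholded page: True marks ink (black) pixels."""

    foreground: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.foreground, dtype=bool)
        if arr.ndim != 2:
            raise InvalidImageError("binary image must be 2-D")
        self.foreground = arr

    @property
    def height(self) -> int:
        return self.foreground.shape[0]

    @property
    def width(self) -> int:
        return self.foreground.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.foreground.shape


@dataclass
class BinaryMask:
    """Per-pixel membership grid for one candidate structure depiction.

    Same height/width as the page it annotates; True marks pixels the
    detector attributes to the object.
    """

    member: np.ndarray
    mask_id: str = "mask"

    def __post_init__(self) -> None:
        arr = np.asarray(self.member, dtype=bool)
        if arr.ndim != 2:
            raise InvalidImageError("mask must be 2-D")
        self.member = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.member.shape

    def count(self) -> int:
        return int(self.member.sum())


def to_grayscale(page: PageImage) -> PageImage:
    """Convert a page to a single luminance channel.

    RGB input is collapsed with the ITU-R 601 luma weights
    ``round(0.299 R + 0.587 G + 0.114 B)``; grayscale input is returned
    unchanged.
    """
    if page.n_channels == 1:
        return page
    if page.n_channels != 3:
        raise InvalidImageError(f"expected 1 or 3 channels, got {page.n_channels}")
    rgb = page.pixels.astype(np.float64)
    luma = 0.299 * rgb[:, :, 0] + 0.587 * rgb[:, :, 1] + 0.114 * rgb[:, :, 2]
    gray = np.rint(luma).clip(0, 255).astype(np.uint8)
    return PageImage(gray, dpi=page.dpi, source_id=page.source_id)


def binarize(page: PageImage, threshold: int = DEFAULT_THRESHOLD) -> BinaryImage:
    """Threshold a grayscale page into ink vs background.

    A pixel is foreground iff its intensity is strictly below ``threshold``,
    so ties are background and ``threshold=255`` marks every non-pure-white
    pixel as ink.  The high default keeps light-gray scan noise out.
    """
    if page.n_channels != 1:
        raise InvalidImageError("binarize requires a single-channel page")
    if not (0 < threshold <= 255):
        raise InvalidParameterError(f"threshold must be in (0, 255], got {threshold}")
    return BinaryImage(page.pixels < threshold)


def _next_odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def auto_kernel_side(page: PageImage) -> int:
    """Resolution-dependent side length of the square dilation kernel.

    ``round(dpi / 100)`` when the page knows its dpi, else
    ``round(min(H, W) / 400)``; the result is clamped to at least 3 and
    bumped to the next odd integer so the kernel has a center pixel.
    """
    if page.dpi is not None:
        base = round(page.dpi / 100)
    else:
        base = round(min(page.height, page.width) / 400)
    return _next_odd(max(3, base))


def dilate(binary: BinaryImage, kernel_side: int) -> BinaryImage:
    """Morphological dilation with an all-True square structuring element.

    Fuses a structure's disconnected strokes — letter glyphs, broken bonds —
    into one connected object so that seeded growth can cover it whole.
    """
    if kernel_side < 1 or kernel_side % 2 == 0:
        raise InvalidParameterError(f"kernel side must be odd and >= 1, got {kernel_side}")
    if kernel_side == 1:
        return BinaryImage(binary.foreground.copy())
    footprint = np.ones((kernel_side, kernel_side), dtype=bool)
    return BinaryImage(ndimage.binary_dilation(binary.foreground, structure=footprint))


def read_page(path: str | Path, dpi: int | None = None, source_id: str | None = None) -> PageImage:
    """Load a PNG or JPEG file as a :class:`PageImage` (8-bit, 1 or 3 channels)."""
    path = Path(path)
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB" if im.mode in ("RGBA", "P", "CMYK") else "L")
        arr = np.asarray(im, dtype=np.uint8)
    return PageImage(arr, dpi=dpi, source_id=source_id or path.stem)


def write_page(page: PageImage, path: str | Path) -> None:
    """Write a page as PNG (8-bit grayscale or RGB, by channel count)."""
    Image.fromarray(page.pixels).save(Path(path), format="PNG")
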