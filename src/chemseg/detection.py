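"""Pluggable sources of candidate masks.

Two sources are provided: a self-contained rule-based baseline that finds
structure-like connected components by bounding-box size and ink density
(in the spirit of classical rule-based figure extractors), and a loader for
masks produced by any external detector and exported to the mask-exchange
JSON format.  Either source feeds the expansion stage identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, MaskPageMismatchError
from .imaging import PageImage, BinaryMask, to_grayscale, binarize, dilate, auto_kernel_side
from . import maskio

log = logging.getLogger(__name__)


@dataclass
class DetectorConfig:
    """Filter thresholds for the rule-based baseline detector.

    ``min_area`` is the minimum bounding-box area in px²; components larger
    than ``max_area_fraction`` of the page are rejected (full-page frames).
    Density bounds reject specks and solid photographs: line drawings put
    roughly 1–50% ink inside their bounding box.  ``detect_kernel_side``
    controls the pre-grouping dilation; None derives it from the page
    (coarser than the expansion kernel, so strokes group into figures).
    """

    min_area: int = 1600  # 40 x 40 px
    max_area_fraction: float = 0.9
    min_density: float = 0.01
    max_density: float = 0.5
    detect_kernel_side: int | None = None
    binarize_threshold: int = 230

    def __post_init__(self) -> None:
        if not (0 < self.min_density < self.max_density <= 1):
            raise InvalidParameterError("need 0 < min_density < max_density <= 1")
        if not (0 < self.max_area_fraction <= 1):
            raise InvalidParameterError("need 0 < max_area_fraction <= 1")


_EIGHT = np.ones((3, 3), dtype=bool)


def detect_baseline(page: PageImage, config: DetectorConfig | None = None) -> list[BinaryMask]:
    """Rule-based candidate detector.

    Binarize, dilate with a coarse kernel so each figure becomes one blob,
    label 8-connected components, then keep components whose bounding-box
    area and ink density fall inside the configured windows.  Each kept
    component contributes its own (dilated) pixel set as a complete mask.
    Deterministic; masks are sorted by bounding-box (ymin, xmin).
    """
    config = config or DetectorConfig()
    gray = to_grayscale(page)
    binary = binarize(gray, config.binarize_threshold)
    k = config.detect_kernel_side
    if k is None:
        k = auto_kernel_side(page) * 2 + 1
    dilated = dilate(binary, k)
    labels, n = ndimage.label(dilated.foreground, structure=_EIGHT)
    page_area = page.height * page.width
    ink = binary.foreground
    kept: list[tuple[tuple[int, int], BinaryMask]] = []
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        bbox_area = h * w
        if bbox_area < config.min_area or bbox_area > config.max_area_fraction * page_area:
            continue
        # density measured on the un-dilated ink inside the bounding box
        density = ink[sl].sum() / bbox_area
        if not (config.min_density <= density <= config.max_density):
            continue
        member = labels == i
        kept.append(((sl[0].start, sl[1].start), BinaryMask(member)))
    kept.sort(key=lambda t: t[0])
    out = []
    for j, (_, m) in enumerate(kept):
        m.mask_id = f"b{j}"
        out.append(m)
    return out


def load_masks(path: str | Path, page: PageImage) -> list[BinaryMask]:
    """Load externally produced masks, validating them against the page.

    Masks whose declared dimensions differ from the page raise
    :class:`MaskPageMismatchError`; all-False masks are skipped with a
    warning (upstream detectors should never emit them).
    """
    masks, _, _, (h, w) = maskio.read_masks(path)
    if (h, w) != page.shape:
        raise MaskPageMismatchError(
            f"mask file declares {(h, w)}, page {page.source_id!r} is {page.shape}"
        )
    valid = []
    for m in masks:
        if not m.member.any():
            log.warning("skipping empty mask %r from %s", m.mask_id, path)
            continue
        valid.append(m)
    return valid
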