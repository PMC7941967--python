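"""Turn final masks into standalone grayscale segment images.

Each mask is cropped to its tight bounding box, the mask-covered page
pixels are copied onto a white canvas (off-mask pixels inside the box stay
white), and the result is padded symmetrically to a square — optionally
rescaled to a fixed side length for downstream recognition models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import EmptyMaskError, InvalidInputError, InvalidParameterError
from .imaging import PageImage, BinaryMask, to_grayscale

log = logging.getLogger(__name__)


@dataclass
class Segment:
    """One cropped grayscale structure depiction with provenance.

    ``bbox`` is (ymin, xmin, ymax, xmax) in page coordinates, endpoints
    inclusive, recorded before any squaring/rescaling.
    """

    pixels: np.ndarray
    bbox: tuple[int, int, int, int]
    page_source_id: str
    mask_id: str


def crop_segment(page: PageImage, mask: BinaryMask) -> Segment:
    """Crop the mask's bounding box and copy only mask-covered pixels.

    The canvas is initialized to white (255), matching the page background,
    so content outside the mask — even inside the bounding box — cannot
    leak into the segment.
    """
    if page.shape != mask.shape:
        raise InvalidInputError(f"page {page.shape} vs mask {mask.shape}")
    if not mask.member.any():
        raise EmptyMaskError(f"mask {mask.mask_id!r} has no True pixel")
    gray = to_grayscale(page)
    ys, xs = np.nonzero(mask.member)
    ymin, ymax = int(ys.min()), int(ys.max())
    xmin, xmax = int(xs.min()), int(xs.max())
    canvas = np.full((ymax - ymin + 1, xmax - xmin + 1), 255, dtype=np.uint8)
    window = mask.member[ymin : ymax + 1, xmin : xmax + 1]
    canvas[window] = gray.pixels[ymin : ymax + 1, xmin : xmax + 1][window]
    return Segment(canvas, (ymin, xmin, ymax, xmax), page.source_id, mask.mask_id)


def pad_to_square(segment: Segment, target_side: int = 0) -> Segment:
    """Pad the shorter dimension with white to a square; optionally rescale.

    Padding is symmetric; an odd remainder puts the extra row/column at the
    bottom/right.  With ``target_side > 0`` the squared image is rescaled to
    that side by bilinear interpolation — the aspect ratio of the ink
    content is never distorted because squaring happens first.
    """
    if target_side < 0:
        raise InvalidParameterError(f"target_side must be >= 0, got {target_side}")
    h, w = segment.pixels.shape
    side = max(h, w)
    if (h, w) != (side, side):
        canvas = np.full((side, side), 255, dtype=np.uint8)
        top = (side - h) // 2
        left = (side - w) // 2
        canvas[top : top + h, left : left + w] = segment.pixels
    else:
        canvas = segment.pixels
    if target_side and target_side != side:
        im = Image.fromarray(canvas).resize((target_side, target_side), Image.BILINEAR)
        canvas = np.asarray(im, dtype=np.uint8)
    return Segment(canvas, segment.bbox, segment.page_source_id, segment.mask_id)


def segment_page(
    page: PageImage, masks: list[BinaryMask], target_side: int = 0
) -> list[Segment]:
    """Crop and square one segment per mask, preserving input order.

    A mask that fails (e.g. empty) is skipped with a logged warning rather
    than aborting the page.
    """
    gray = to_grayscale(page)
    out: list[Segment] = []
    for m in masks:
        try:
            out.append(pad_to_square(crop_segment(gray, m), target_side))
        except (EmptyMaskError, InvalidInputError) as exc:
            log.warning("skipping mask %r on page %r: %s", m.mask_id, page.source_id, exc)
    return out


def write_segments(segments: list[Segment], out_dir: str | Path) -> list[Path]:
    """Write segments as 8-bit grayscale PNGs plus one sidecar JSON.

    Files are named ``{page_source_id}_{mask_id}.png``; the sidecar
    ``segments.json`` lists every segment's bbox and provenance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    records = []
    for s in segments:
        p = out_dir / f"{s.page_source_id}_{s.mask_id}.png"
        Image.fromarray(s.pixels).save(p, format="PNG")
        paths.append(p)
        records.append(
            {
                "file": p.name,
                "page": s.page_source_id,
                "mask_id": s.mask_id,
                "bbox": list(s.bbox),
            }
        )
    sidecar = out_dir / "segments.json"
    existing = json.loads(sidecar.read_text()) if sidecar.exists() else []
    sidecar.write_text(json.dumps(existing + records, indent=1) + "\n")
    return paths
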