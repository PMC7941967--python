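"""Mask-exchange JSON: run-length encoded boolean masks.

The interchange format lets masks produced by any external detector (e.g. a
Mask R-CNN inference run) be fed into the expansion stage, and lets this
package's outputs be consumed elsewhere.  Layout::

    {
      "page": "<source_id>",
      "height": H,
      "width": W,
      "masks": [
        {"mask_id": "m0", "rle": [n0, n1, n2, ...], "class": "structure"},
        ...
      ]
    }

``rle`` is a row-major run-length encoding of the flattened boolean grid:
alternating run lengths starting with a False run (which may be 0).  The
optional ``class`` tag carries ground-truth object classes for synthetic
annotations.  Round trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import MaskFormatError
from .imaging import BinaryMask


def encode_rle(member: np.ndarray) -> list[int]:
    """Row-major RLE: alternating run lengths, first run counts False pixels."""
    flat = np.asarray(member, dtype=bool).ravel()
    if flat.size == 0:
        return []
    boundaries = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate(([0], boundaries, [flat.size])))
    if flat[0]:  # convention: leading False run, possibly empty
        runs = np.concatenate(([0], runs))
    return [int(r) for r in runs]


def decode_rle(rle: list[int], height: int, width: int) -> np.ndarray:
    """Inverse of :func:`encode_rle`; validates total length and run signs."""
    runs = np.asarray(rle, dtype=np.int64)
    if runs.size and (runs < 0).any():
        raise MaskFormatError("negative run length")
    if int(runs.sum()) != height * width:
        raise MaskFormatError(
            f"RLE totals {int(runs.sum())} pixels, expected {height * width}"
        )
    values = np.zeros(runs.size, dtype=bool)
    values[1::2] = True
    return np.repeat(values, runs).reshape(height, width)


def masks_to_dict(
    masks: list[BinaryMask],
    page_id: str,
    height: int,
    width: int,
    classes: list[str] | None = None,
) -> dict:
    entries = []
    for i, m in enumerate(masks):
        if m.shape != (height, width):
            raise MaskFormatError(
                f"mask {m.mask_id!r} shape {m.shape} != declared {(height, width)}"
            )
        entry: dict = {"mask_id": m.mask_id, "rle": encode_rle(m.member)}
        if classes is not None:
            entry["class"] = classes[i]
        entries.append(entry)
    return {"page": page_id, "height": height, "width": width, "masks": entries}


def dict_to_masks(doc: dict) -> tuple[list[BinaryMask], list[str], str, tuple[int, int]]:
    """Decode a mask-exchange dict → (masks, class tags, page id, (H, W))."""
    try:
        h, w = int(doc["height"]), int(doc["width"])
        page_id = str(doc.get("page", "page"))
        raw = doc["masks"]
    except (KeyError, TypeError) as exc:
        raise MaskFormatError(f"malformed mask-exchange document: {exc}") from exc
    masks, classes = [], []
    for entry in raw:
        try:
            member = decode_rle(entry["rle"], h, w)
            mask_id = str(entry.get("mask_id", f"m{len(masks)}"))
        except (KeyError, TypeError) as exc:
            raise MaskFormatError(f"malformed mask entry: {exc}") from exc
        masks.append(BinaryMask(member, mask_id))
        classes.append(str(entry.get("class", "structure")))
    return masks, classes, page_id, (h, w)


def write_masks(
    path: str | Path,
    masks: list[BinaryMask],
    page_id: str,
    height: int,
    width: int,
    classes: list[str] | None = None,
) -> None:
    doc = masks_to_dict(masks, page_id, height, width, classes)
    Path(path).write_text(json.dumps(doc, separators=(",", ":")) + "\n")


def read_masks(path: str | Path) -> tuple[list[BinaryMask], list[str], str, tuple[int, int]]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise MaskFormatError(f"not valid JSON: {exc}") from exc
    return dict_to_masks(doc)
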