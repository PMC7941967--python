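"""Seeded flood-growth mask expansion.

Detector masks frequently cover a chemical structure depiction only
partially.  Given the page's dilated binary image (in which every structure
is a single connected object) and such a candidate mask, this module grows
the mask along 8-connected ink pixels until no further connected ink can be
reached, so the final mask covers the depicted object completely.

The procedure has two regimes.  If ink pixels covered by the mask can be
found by marching from the mask's center in the four axis directions, those
become seeds and the mask is *replaced*: rebuilt from scratch as exactly the
connected ink reachable from the seeds.  Seeding from the interior rather
than the detector's contour discards near-boundary clutter the detector may
have wrongly included.  If no interior seed exists, ink crossing the mask's
contour seeds the growth instead and the original mask is *kept* and only
extended.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError, InvalidInputError
from .imaging import BinaryImage, BinaryMask

# 8-neighbourhood offsets (dy, dx)
_NEIGHBOURS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass
class SeedSet:
    """Seed pixels for flood growth plus the regime they imply.

    ``mode="replace"``: seeds were found inside the mask; growth starts from
    an all-False mask.  ``mode="keep"``: seeds (possibly none) come from the
    mask contour; growth starts from the original mask.
    """

    pixels: list[tuple[int, int]]
    mode: str  # "replace" | "keep"


@dataclass
class ExpansionResult:
    """Outcome of one mask expansion."""

    mask: BinaryMask
    mode: str
    seed_count: int
    changed: bool


def _bbox(member: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(member)
    return int(ys.min()), int(xs.min()), int(ys.max()), int(xs.max())


def mask_center(mask: BinaryMask, rng_seed: int = 0) -> tuple[int, int]:
    """Pick the growth center of a mask.

    Returns the midpoint between the extreme True coordinates,
    ``((ymin+ymax)//2, (xmin+xmax)//2)``, when that pixel itself is True.
    For asymmetric masks whose bounding-box midpoint falls outside the mask,
    falls back to a True pixel drawn uniformly at random (deterministic for
    a fixed ``rng_seed``).
    """
    member = mask.member
    if not member.any():
        raise EmptyMaskError(f"mask {mask.mask_id!r} has no True pixel")
    ymin, xmin, ymax, xmax = _bbox(member)
    cy, cx = (ymin + ymax) // 2, (xmin + xmax) // 2
    if member[cy, cx]:
        return cy, cx
    ys, xs = np.nonzero(member)
    rng = np.random.default_rng(rng_seed)
    i = int(rng.integers(len(ys)))
    return int(ys[i]), int(xs[i])


def directional_seeds(binary: BinaryImage, mask: BinaryMask, center: tuple[int, int]) -> SeedSet:
    """March from the center in the four axis directions looking for seeds.

    Each march steps one pixel at a time (starting at the center itself) and
    records the first pixel that is ink in ``binary`` and covered by the
    mask; a march stops once it leaves the mask's bounding box.  Any hit
    switches the expansion to replace mode; no hit at all defers to the
    contour fallback (keep mode).
    """
    member = mask.member
    fg = binary.foreground
    h, w = fg.shape
    cy, cx = center
    if not (0 <= cy < h and 0 <= cx < w):
        raise InvalidInputError(f"center {center} outside page bounds {(h, w)}")
    if member.any():
        ymin, xmin, ymax, xmax = _bbox(member)
    else:
        ymin, xmin, ymax, xmax = 0, 0, h - 1, w - 1
    seeds: list[tuple[int, int]] = []
    for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        y, x = cy, cx
        while ymin <= y <= ymax and xmin <= x <= xmax:
            if fg[y, x] and member[y, x]:
                if (y, x) not in seeds:
                    seeds.append((y, x))
                break
            y += dy
            x += dx
    return SeedSet(seeds, "replace" if seeds else "keep")


def contour_seeds(binary: BinaryImage, mask: BinaryMask) -> SeedSet:
    """Collect ink pixels on the mask's contour as fallback seeds.

    The contour is every True mask pixel with at least one False 4-neighbour
    or lying on the page border.  All contour pixels that are ink in
    ``binary`` are returned, in row-major order, with mode ``keep``.
    """
    member = mask.member
    if not member.any():
        raise EmptyMaskError(f"mask {mask.mask_id!r} has no True pixel")
    interior = np.zeros_like(member)
    interior[1:-1, 1:-1] = (
        member[1:-1, 1:-1]
        & member[:-2, 1:-1]
        & member[2:, 1:-1]
        & member[1:-1, :-2]
        & member[1:-1, 2:]
    )
    contour = member & ~interior
    hits = contour & binary.foreground
    ys, xs = np.nonzero(hits)
    return SeedSet([(int(y), int(x)) for y, x in zip(ys, xs)], "keep")


def _flood(fg: np.ndarray, covered: np.ndarray, seeds: list[tuple[int, int]]) -> None:
    """Grow ``covered`` in place along 8-connected ink from the seeds.

    Explicit BFS worklist; the contract is the fixed point (no reachable ink
    pixel left uncovered), and a queue avoids recursion limits on blobs that
    can span a whole page.
    """
    h, w = fg.shape
    queue: deque[tuple[int, int]] = deque()
    for y, x in seeds:
        if fg[y, x] and not covered[y, x]:
            covered[y, x] = True
        queue.append((y, x))
    while queue:
        y, x = queue.popleft()
        for dy, dx in _NEIGHBOURS:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and fg[ny, nx] and not covered[ny, nx]:
                covered[ny, nx] = True
                queue.append((ny, nx))


def expand_mask(binary: BinaryImage, mask: BinaryMask, rng_seed: int = 0) -> ExpansionResult:
    """Expand one candidate mask to full coverage of its connected object(s).

    Pipeline: pick the mask center, try :func:`directional_seeds`; on
    success rebuild the mask from scratch (replace mode) as the union of the
    8-connected ink components containing the seeds.  Otherwise fall back to
    :func:`contour_seeds` and extend the original mask (keep mode).  If both
    searches come back empty the input mask is returned unchanged.
    """
    if binary.shape != mask.shape:
        raise InvalidInputError(
            f"binary {binary.shape} and mask {mask.shape} shapes differ"
        )
    if not mask.member.any():
        raise EmptyMaskError(f"mask {mask.mask_id!r} has no True pixel")

    center = mask_center(mask, rng_seed)
    seedset = directional_seeds(binary, mask, center)
    if seedset.mode == "replace":
        covered = np.zeros(mask.shape, dtype=bool)
    else:
        seedset = contour_seeds(binary, mask)
        covered = mask.member.copy()
        if not seedset.pixels:
            return ExpansionResult(
                BinaryMask(covered, mask.mask_id), "keep", 0, changed=False
            )
    _flood(binary.foreground, covered, seedset.pixels)
    changed = not np.array_equal(covered, mask.member)
    return ExpansionResult(
        BinaryMask(covered, mask.mask_id), seedset.mode, len(seedset.pixels), changed
    )


def expand_all(
    binary: BinaryImage, masks: list[BinaryMask], rng_seed: int = 0
) -> list[ExpansionResult]:
    """Expand each mask independently and drop exact duplicates.

    Overlapping expanded masks are not merged (one segment per detected
    structure), but masks that become bit-identical after expansion are
    de-duplicated by content, keeping the first occurrence.
    """
    results: list[ExpansionResult] = []
    seen: set[bytes] = set()
    for m in masks:
        res = expand_mask(binary, m, rng_seed)
        key = np.packbits(res.mask.member).tobytes()
        if key in seen:
            continue
        seen.add(key)
        results.append(res)
    return results
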