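"""Deterministic generator of journal-like pages with ground truth.

Pages emulate the statistical structure the expansion algorithm assumes:
chemical-structure-like line drawings (hexagonal and fused rings drawn with
2-px strokes, with small gap-separated glyphs imitating atom labels inside
the ring), compound labels and reaction arrows placed at a controllable
distance from their structure, text blocks, and light near-white scan
noise that a high binarization threshold removes.  Every glyph is drawn
with geometric primitives — never fonts — so pages are byte-stable across
platforms.  Alongside each page the generator emits per-object ground-truth
masks and, on demand, *degraded* detector masks covering only a fraction of
each structure, which is the failure mode mask expansion exists to fix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line, polygon, disk

from .errors import EmptyMaskError, InvalidParameterError, PlacementError
from .imaging import PageImage, BinaryMask, DEFAULT_THRESHOLD

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class PageSpec:
    """Recipe for one synthetic page.

    ``label_offset`` is the Chebyshev gap in pixels between a structure's
    ink and its label/arrow ink; below the dilation kernel side the two
    merge into one connected object (the extra-object failure mode), above
    twice the kernel side they are guaranteed separate.  ``noise_level`` is
    the fraction of background pixels given a random intensity in
    ``[threshold, 254]`` — visible speckle that binarization removes.
    """

    height: int = 600
    width: int = 800
    n_structures: int = 3
    label_offset: int = 12
    arrow_probability: float = 0.5
    noise_level: float = 0.01
    rng_seed: int = 0
    threshold: int = DEFAULT_THRESHOLD
    kernel_side: int = 3
    text_block: bool = True


@dataclass
class PageAnnotation:
    """Ground-truth objects on a synthetic page.

    ``objects`` holds ``(class, mask)`` pairs with class one of
    ``structure | label | arrow | text``; masks are full-page booleans of
    the object's ink pixels.
    """

    objects: list[tuple[str, BinaryMask]] = field(default_factory=list)

    def by_class(self, cls: str) -> list[BinaryMask]:
        return [m for c, m in self.objects if c == cls]


def _thicken(mask: np.ndarray) -> np.ndarray:
    """2-px stroke width: dilate 1-px strokes with a 2x2 footprint."""
    return ndimage.binary_dilation(mask, structure=np.ones((2, 2), dtype=bool))


def _draw_structure(rng: np.random.Generator, size: int = 72) -> np.ndarray:
    """One structure glyph on a local canvas: ring(s) + interior atom glyph.

    A hexagonal ring, optionally fused with a second ring, drawn with 2-px
    bonds; one ring vertex region is broken and replaced by a 3x3 atom
    glyph separated by ~2-px gaps, so the glyph only joins the ring after
    dilation — exactly the disconnectedness the expansion kernel must heal.
    """
    canvas = np.zeros((size, size), dtype=bool)
    cy = cx = size // 2
    r = size // 2 - 8
    angles = np.deg2rad(30 + 60 * np.arange(6))
    verts = np.stack(
        [cy + r * np.sin(angles), cx + r * np.cos(angles)], axis=1
    ).round().astype(int)
    for i in range(6):
        y0, x0 = verts[i]
        y1, x1 = verts[(i + 1) % 6]
        rr, cc = line(y0, x0, y1, x1)
        canvas[rr, cc] = True
    if rng.random() < 0.5:  # fused second ring sharing the right edge
        shift = int(round(r * np.cos(np.deg2rad(30)) * 2))
        for i in range(6):
            y0, x0 = verts[i]
            y1, x1 = verts[(i + 1) % 6]
            rr, cc = line(y0, x0 + shift, y1, x1 + shift)
            ok = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            canvas[rr[ok], cc[ok]] = True
    canvas = _thicken(canvas)
    # break one vertex and insert an atom glyph; the ~2 px gaps disconnect
    # the glyph from the ring until dilation with a 3-px kernel heals them
    vy, vx = verts[0]
    rr, cc = disk((vy, vx), 4, shape=canvas.shape)
    canvas[rr, cc] = False
    canvas[vy - 1 : vy + 2, vx - 1 : vx + 2] = True
    return canvas


def _draw_label(rng: np.random.Generator) -> np.ndarray:
    """Compound-number-like glyph: two small stroke blocks side by side."""
    canvas = np.zeros((9, 14), dtype=bool)
    canvas[0:9, 0:2] = True          # vertical bar ("1")
    canvas[0:2, 5:12] = True         # letter-ish open box
    canvas[7:9, 5:12] = True
    canvas[0:9, 5:7] = True
    return canvas


def _draw_arrow(length: int = 36) -> np.ndarray:
    """Reaction arrow: horizontal 2-px shaft plus a filled triangle head."""
    canvas = np.zeros((11, length + 8), dtype=bool)
    canvas[5:7, 0:length] = True
    rr, cc = polygon([0, 10, 5], [length, length, length + 7], shape=canvas.shape)
    canvas[rr, cc] = True
    return canvas


def _draw_text_block(rng: np.random.Generator, rows: int = 4, width: int = 220) -> np.ndarray:
    """Body text imitation: rows of small filled rectangles (words)."""
    canvas = np.zeros((rows * 12, width), dtype=bool)
    for r in range(rows):
        x = 0
        while x < width - 10:
            w = int(rng.integers(12, 30))
            w = min(w, width - x)
            canvas[r * 12 : r * 12 + 7, x : x + w] = True
            x += w + int(rng.integers(4, 9))
    return canvas


def _stamp(page: np.ndarray, glyph: np.ndarray, y: int, x: int) -> np.ndarray:
    """Paint a glyph's ink (intensity 0) at (y, x); return its page mask."""
    h, w = glyph.shape
    mask = np.zeros(page.shape, dtype=bool)
    mask[y : y + h, x : x + w] = glyph
    page[mask] = 0
    return mask


def generate_page(spec: PageSpec) -> tuple[PageImage, PageAnnotation]:
    """Render one synthetic journal page with ground-truth annotations.

    Structures are laid out on a grid with gaps of at least twice the
    dilation kernel side between distinct structures (and their satellite
    labels/arrows), so dilation never merges two structures.  Each
    structure's ink is verified to be a single 8-connected component after
    dilation with ``spec.kernel_side``; the renderer raises if layout
    cannot honour these guarantees.
    """
    rng = np.random.default_rng(spec.rng_seed)
    page = np.full((spec.height, spec.width), 255, dtype=np.uint8)

    # near-white speckle first; object ink overwrites it
    if spec.noise_level > 0:
        n_noise = int(spec.noise_level * page.size)
        ys = rng.integers(0, spec.height, n_noise)
        xs = rng.integers(0, spec.width, n_noise)
        page[ys, xs] = rng.integers(spec.threshold, 255, n_noise).astype(np.uint8)

    ann = PageAnnotation()
    struct_size = 72
    sep = max(2 * spec.kernel_side + 2, 8)
    # cell must hold structure + offset label below + offset arrow right
    cell_h = struct_size + spec.label_offset + 9 + sep
    cell_w = struct_size + spec.label_offset + 44 + sep
    top_margin = 60 if spec.text_block else 8
    cols = max(1, (spec.width - 8) // cell_w)
    rows_avail = max(1, (spec.height - top_margin - 8) // cell_h)
    if spec.n_structures > cols * rows_avail:
        raise PlacementError(
            f"cannot place {spec.n_structures} structures on a "
            f"{spec.height}x{spec.width} page with label_offset={spec.label_offset}"
        )

    footprint = np.ones((spec.kernel_side, spec.kernel_side), dtype=bool)
    for i in range(spec.n_structures):
        r, c = divmod(i, cols)
        y0 = top_margin + r * cell_h
        x0 = 8 + c * cell_w
        glyph = _draw_structure(rng, struct_size)
        smask = _stamp(page, glyph, y0, x0)
        dil = ndimage.binary_dilation(smask, structure=footprint)
        _, n_comp = ndimage.label(dil, structure=_EIGHT)
        if n_comp != 1:
            raise PlacementError(
                f"structure {i} is {n_comp} components after dilation "
                f"with kernel {spec.kernel_side}"
            )
        ann.objects.append(("structure", BinaryMask(smask, f"s{i}")))

        ys, xs = np.nonzero(smask)
        s_ymax, s_xmax = int(ys.max()), int(xs.max())
        s_xmin = int(xs.min())
        # centered under the ring's bottom vertex so the vertical gap to the
        # structure's lowest ink is exactly label_offset empty rows
        label = _draw_label(rng)
        lx = (s_xmin + s_xmax) // 2 - label.shape[1] // 2
        lmask = _stamp(page, label, s_ymax + 1 + spec.label_offset, lx)
        ann.objects.append(("label", BinaryMask(lmask, f"l{i}")))

        if rng.random() < spec.arrow_probability:
            arrow = _draw_arrow()
            amask = _stamp(
                page, arrow, y0 + struct_size // 2 - 5, s_xmax + 1 + spec.label_offset
            )
            ann.objects.append(("arrow", BinaryMask(amask, f"a{i}")))

    if spec.text_block and spec.n_structures > 0:
        text = _draw_text_block(rng, rows=3, width=min(260, spec.width - 20))
        tmask = _stamp(page, text, 8, 10)
        if tmask.any():
            ann.objects.append(("text", BinaryMask(tmask, "t0")))

    return (
        PageImage(page, dpi=None, source_id=f"synthetic_{spec.rng_seed}"),
        ann,
    )


def degrade_mask(gt_mask: BinaryMask, coverage: float, rng_seed: int = 0) -> BinaryMask:
    """Simulate a detector that covers a structure only partially.

    Returns the intersection of the ground-truth mask with a random
    axis-aligned sub-rectangle of its bounding box, chosen (by randomly
    trimming rows/columns from the four sides) so that at least
    ``coverage`` of the original True pixels — and at least one pixel —
    survive.  Deterministic for a fixed ``rng_seed``.
    """
    if not (0 < coverage <= 1):
        raise InvalidParameterError(f"coverage must be in (0, 1], got {coverage}")
    member = gt_mask.member
    if not member.any():
        raise EmptyMaskError(f"mask {gt_mask.mask_id!r} has no True pixel")
    if coverage == 1.0:
        return BinaryMask(member.copy(), gt_mask.mask_id)
    rng = np.random.default_rng(rng_seed)
    ys, xs = np.nonzero(member)
    ymin, ymax = int(ys.min()), int(ys.max())
    xmin, xmax = int(xs.min()), int(xs.max())
    total = len(ys)
    floor = max(1, int(np.ceil(coverage * total)))

    # row/column marginal ink counts inside the bbox
    row_counts = member[ymin : ymax + 1, xmin : xmax + 1].sum(axis=1)
    col_counts = member[ymin : ymax + 1, xmin : xmax + 1].sum(axis=0)
    top, bottom = 0, len(row_counts) - 1
    left, right = 0, len(col_counts) - 1

    def _kept() -> int:
        return int(member[ymin + top : ymin + bottom + 1,
                          xmin + left : xmin + right + 1].sum())

    sides = [0, 1, 2, 3]
    stuck = set()
    while len(stuck) < 4:
        s = int(rng.choice([x for x in sides if x not in stuck]))
        t, b, l, r2 = top, bottom, left, right
        if s == 0:
            t += 1
        elif s == 1:
            b -= 1
        elif s == 2:
            l += 1
        else:
            r2 -= 1
        if t > b or l > r2:
            stuck.add(s)
            continue
        kept = int(member[ymin + t : ymin + b + 1, xmin + l : xmin + r2 + 1].sum())
        if kept < floor or kept < 1:
            stuck.add(s)
            continue
        top, bottom, left, right = t, b, l, r2
    sub = np.zeros_like(member)
    sub[ymin + top : ymin + bottom + 1, xmin + left : xmin + right + 1] = True
    return BinaryMask(member & sub, gt_mask.mask_id)
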