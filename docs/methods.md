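# Methods

## Problem and model

A scanned journal page contains chemical structure depictions — line
drawings of molecules — interleaved with captions, compound labels,
reaction arrows and body text.  An upstream instance detector proposes one
boolean mask per candidate depiction; these masks are often incomplete.
`chemseg` post-processes them under one structural assumption:

> after binarization and dilation, each structure depiction is a single
> 8-connected foreground object, and distinct page objects remain
> disconnected.

Under that assumption, any ink pixel inside a candidate mask identifies
the whole drawing: growing along 8-connected ink from it reaches exactly
the depicted object, no more and no less.  Everything else in the package
exists to establish the assumption (thresholding, kernel choice), to pick
good starting pixels (seed selection), or to measure what happens when the
assumption fails (evaluation, synthetic corpora).

## The expansion procedure

Given the dilated binary page `B` and a candidate mask `M`:

1. **Center.** The midpoint between the extreme True coordinates of `M`,
   `((ymin+ymax)//2, (xmin+xmax)//2)`.  If that pixel is not in `M` (an
   asymmetric mask), a True pixel drawn uniformly at random replaces it;
   the draw is seeded by the caller, so runs are reproducible.
2. **Directional seeds.** From the center, march one pixel at a time up,
   down, left and right, recording in each direction the first pixel that
   is ink in `B` *and* inside `M`; a march stops when it leaves `M`'s
   bounding box.  (The center itself qualifies, so a center on ink yields
   one seed.)  Any hit switches to **replace mode**: the output mask is
   rebuilt from all-False.  Seeding from the interior is what lets the
   procedure *drop* clutter that the detector wrongly included near the
   mask boundary.
3. **Contour fallback.** If no directional seed exists, every mask-contour
   pixel (True with a False 4-neighbour, or on the page border) that is
   ink becomes a seed, and the original mask is retained (**keep mode**) —
   the detector's area is trusted and only extended.
4. **Growth.** A breadth-first worklist adds every ink 8-neighbour of every
   frontier pixel until the frontier empties.  The contract is the fixed
   point — the union of 8-connected ink components containing the seeds
   (replace) or that union plus the original mask (keep).  An explicit
   queue is used rather than literal recursion: a full-page blob can exceed
   10⁶ pixels, far beyond any recursion limit.

With no seeds from either search the input mask is returned unchanged.
Masks are expanded independently; overlapping results are not merged (one
segment per detection), but bit-identical duplicates are dropped.

**Idempotence.** Re-expanding an expanded mask changes nothing *when the
mask is one connected object* — the regime the dilation is designed to
establish, and the one the tests assert.  It is not unconditional: a
replace-mode result spanning several disjoint components re-seeds from its
center on a second pass and keeps only the center's component.  This is a
property of the seeding rule, not an implementation artifact.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| binarization threshold | 230 | intensity (0–255) | high cut removes near-white scan relicts; ties are background, so 255 would make every non-pure-white pixel ink |
| dilation kernel side | auto | px | `round(dpi/100)` if dpi is known else `round(min(H,W)/400)`, clamped to ≥ 3 and made odd; a 300-dpi page gets 3, a 600-dpi page 7 |
| grayscale weights | ITU-R 601 | — | `round(0.299R + 0.587G + 0.114B)` |
| connectivity | 8 | — | diagonal strokes in drawings must connect |
| detection coverage | 0.5 | fraction of ink | a structure counts as detected when its best mask covers ≥ half its ink; the underlying manual criterion is visual, so an explicit numeric rule had to be fixed |
| baseline detector | 40×40 px min box, ≤ 0.9 page, ink density 0.01–0.5 | — | line drawings pass; specks, solid photos and full-page frames fail |

The kernel trade-off is the method's central dilemma: a larger kernel
guarantees connectivity of sparse drawings but welds nearby labels and
arrow tips onto the structure, which the expansion then faithfully
includes; a smaller kernel avoids the welding but risks leaving a drawing
split, and a split drawing expands incompletely in replace mode.  The
acceptance script quantifies both arms on the same corpus.

## Synthetic pages

The generator emulates exactly the statistics the algorithm cares about,
not photorealism: structures are hexagonal/fused rings drawn with 2-px
strokes, with one ring vertex replaced by a small glyph at a ~2-px gap —
so every structure is genuinely *disconnected* before dilation and one
component after it (asserted at generation time).  Compound labels sit at
a configurable Chebyshev gap below each structure, arrows to the right at
the same gap, text blocks at the page top, and a chosen fraction of pixels
gets a random intensity in `[threshold, 254]` — speckle that is visible
but vanishes at binarization.  Layout keeps distinct structures more than
twice the kernel side apart, so only the *intended* proximity failure
(label/arrow gap below the kernel side) can merge objects.  Degraded
detector masks are the ground-truth mask intersected with a random
bounding-box sub-rectangle retaining at least the requested ink fraction.
All drawing uses geometric primitives; pages are byte-identical for a
fixed seed across platforms.

What passing these corpora does *not* show: robustness to grayscale
halftones, curved or hand-drawn bonds, touching structures, skew, or
detectors whose masks miss the structure entirely — real-page phenomena
outside the generator's model.

## Numerical and format choices

- Coordinates are 0-based, row-major, origin top-left; bounding boxes use
  inclusive endpoints.
- Segment canvases are white (255); only mask-covered pixels are copied,
  so off-mask content inside the bounding box cannot leak into a segment.
- Squaring pads symmetrically, extra pixel at bottom/right; an optional
  target side rescales bilinearly *after* squaring, so ink aspect ratio is
  never distorted.
- The mask-exchange JSON stores row-major run-length encodings starting
  with a (possibly zero-length) False run; round trips are exact.
- The bundled PDF codec writes and reads single-image-per-page PDFs
  (Flate-compressed grayscale XObjects) — sufficient for document-level
  round-trip testing and for simple scanned documents; anything richer
  should be supplied as page images.
- Empty masks are an error for expansion and cropping (detectors should
  never emit them) but are skipped with a warning when loading external
  mask files, so one bad entry does not abort a run.
- Pipeline parallelism is page-level only and merged in page order; with
  the per-page seed derived from the run seed, output is byte-identical
  for any worker count.

## Scales used in the shipped checks

The acceptance script uses 50 pages × 5 structures (700×800 px) for the
completeness-recovery measurement, 10 pages × 3 structures for the
proximity failure mode, 120 random images for the oracle comparison, and a
3-page corpus for determinism — sizes at which every rate is stable across
seeds while the whole script completes in seconds.  The test suite uses
the same generators at smaller sizes.
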