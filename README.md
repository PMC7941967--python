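# chemseg

Segmentation of chemical structure depictions from scanned journal pages.

Mining chemistry from the printed literature starts with finding the 2-D
structure drawings on each page and cutting them out cleanly, so that an
optical chemical structure recognition (OCSR) system can translate each one
into a machine-readable form.  Instance detectors do the finding well, but
their pixel masks frequently cover a structure only *partially* — and a
clipped drawing is useless downstream.  `chemseg` implements the
post-detection half of that workflow as a reusable library with a thin CLI:

1. **Binarize** the page with a high threshold (default 230/255), removing
   near-white scan noise.
2. **Dilate** the ink with a square, resolution-dependent kernel so each
   drawing — bonds, heteroatom glyphs, broken strokes — becomes one
   8-connected object.
3. **Expand each candidate mask** by seeded flood growth: pick the mask
   center, march in the four axis directions to find ink pixels covered by
   the mask, then grow along 8-connected ink until a fixed point.  If
   interior seeds exist the mask is rebuilt from scratch around them
   (*replace* mode, which discards wrongly included near-boundary clutter);
   otherwise ink on the mask contour seeds growth and the mask is only
   extended (*keep* mode).
4. **Segment**: crop each final mask to its bounding box, copy mask-covered
   pixels onto a white canvas, pad to a square, and write grayscale PNGs.

Candidate masks come from a built-in rule-based baseline detector
(bounding-box size and ink-density filters) or from any external detector
via a run-length-encoded JSON mask-exchange format.  A deterministic
synthetic-page generator (ring drawings, compound labels, reaction arrows,
text blocks, scan noise — all geometric primitives, no fonts) provides
ground truth, and an evaluation module scores completeness, extra-object
inclusion and detection rate against it.

## Worked example

```sh
python examples/01_expand_partial_mask.py
```

```
ink coverage before expansion: 50.4%
ink coverage after expansion:  100.0%  (mode=replace)
```

A detector mask retaining only half of a drawing's ink is grown back to
100% coverage, because dilation made the drawing one connected object and
the flood reaches all of it from a single interior seed.  At corpus scale
(`examples/04_evaluate_expansion.py`, 10 pages × 3 structures, masks
degraded to half coverage):

```
before expansion: 0.0% complete, 0.0% with extra objects
after expansion:  100.0% complete, 0.0% with extra objects
detected: 100.0% of 30 structures
```

"Complete" means every ink pixel of the structure is covered; "extra" means
the mask also touches a nearby label, arrow or text block.  The remaining
examples show the generator (`02`) and the end-to-end pipeline (`03`).

## Command line

```sh
chemseg synth --out corpus/ --pages 5 --structures 3 --seed 1
chemseg run --input corpus_pages/ --output out/ --masks corpus_masks/ --seed 1
chemseg run --input doc.pdf --output out/ --detector baseline
chemseg eval --pred pred.json --truth truth.json --report report.json
```

`run` accepts a PDF (single-image-per-page PDFs, e.g. those written by the
bundled fixture writer), a page image, or a directory of page images; a
YAML config file (`--config`) can pre-set any flag.  Output is a folder of
square segment PNGs, a sidecar JSON with provenance, and a `manifest.json`
— byte-identical across runs and worker counts for a fixed seed.

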