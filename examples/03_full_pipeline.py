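"""Run the whole document pipeline: pages in, square segment PNGs out.

Writes a synthetic page plus degraded detector masks to a temp directory,
runs detect-file -> expand -> segment, and prints the run manifest summary.
"""

import tempfile
from pathlib import Path

from chemseg import RunConfig, process_document
from chemseg.imaging import write_page
from chemseg.maskio import write_masks
from chemseg.synthetic import PageSpec, generate_page, degrade_mask

with tempfile.TemporaryDirectory() as td:
    tmp = Path(td)
    (tmp / "pages").mkdir()
    (tmp / "masks").mkdir()
    spec = PageSpec(n_structures=4, height=700, width=800, rng_seed=2)
    page, ann = generate_page(spec)
    write_page(page, tmp / "pages" / "p0.png")
    degraded = [degrade_mask(m, 0.5, j) for j, m in enumerate(ann.by_class("structure"))]
    write_masks(tmp / "masks" / "p0.json", degraded, "p0", page.height, page.width)

    cfg = RunConfig(input_path=str(tmp / "pages"), output_dir=str(tmp / "out"),
                    detector="maskfile", mask_file=str(tmp / "masks"), rng_seed=0)
    manifest = process_document(cfg)
    for rec in manifest.pages:
        print(f"page {rec.page_id}: {rec.n_masks} masks in, "
              f"{rec.n_segments} segments out, modes {rec.expansion_modes}")
    segs = sorted(p.name for p in (tmp / "out" / "segments").glob("*.png"))
    print("segment files:", segs)
# Every input mask was expanded in 'replace' mode (interior seeds found) and
# yielded one cropped, white-padded square segment PNG.
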