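"""End-to-end orchestration: rasterize, detect, expand, segment, write.

Pages are independent units of work; the per-page stage chain is
binarize → dilate → expand each candidate mask → crop/square segments.
Output is bit-identical regardless of worker count because pages are
processed independently and merged in page order, and all randomness (the
mask-center fallback) is seeded per page from the run seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ChemsegError, InputError, InvalidParameterError
from .imaging import (
    PageImage,
    to_grayscale,
    binarize,
    dilate,
    auto_kernel_side,
    read_page,
    write_page,
    DEFAULT_THRESHOLD,
)
from .detection import DetectorConfig, detect_baseline, load_masks
from .expansion import expand_all
from .segmentation import segment_page, write_segments
from . import pdfio

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    Exactly one mask source is active: the rule-based ``baseline`` detector
    or a ``maskfile`` (mask-exchange JSON; for multi-page inputs, a
    directory of ``{source_id}.json`` files).
    """

    input_path: str
    output_dir: str
    dpi: int = 300
    binarize_threshold: int = DEFAULT_THRESHOLD
    kernel_side: int | str = "auto"
    detector: str = "baseline"  # "baseline" | "maskfile"
    detector_config: DetectorConfig | None = None
    mask_file: str | None = None
    target_side: int = 0
    rng_seed: int = 0
    jobs: int = 1

    def __post_init__(self) -> None:
        if self.detector not in ("baseline", "maskfile"):
            raise InvalidParameterError(f"unknown detector {self.detector!r}")
        if (self.detector == "maskfile") != (self.mask_file is not None):
            raise InvalidParameterError(
                "exactly one mask source: detector='maskfile' iff mask_file is set"
            )
        if self.kernel_side != "auto":
            k = int(self.kernel_side)
            if k < 1 or k % 2 == 0:
                raise InvalidParameterError("kernel_side must be 'auto' or an odd int")
            self.kernel_side = k


@dataclass
class PageRecord:
    page_id: str
    n_masks: int
    n_segments: int
    expansion_modes: list[str]
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunManifest:
    pages: list[PageRecord]
    version: str
    config: dict

    def as_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "pages": [dataclasses.asdict(p) for p in self.pages],
        }


def rasterize_pdf(pdf_path: str | Path, dpi: int = 300, out_dir: str | Path | None = None) -> list[PageImage]:
    """Convert every page of a PDF to a page image, in page order.

    When ``out_dir`` is given, pages are also persisted as PNGs in a folder
    named after the input file.
    """
    pages = pdfio.read_pdf(pdf_path, dpi=dpi)
    if out_dir is not None:
        folder = Path(out_dir) / Path(pdf_path).stem
        folder.mkdir(parents=True, exist_ok=True)
        for p in pages:
            write_page(p, folder / f"{p.source_id}.png")
    return pages


def load_pages(directory: str | Path, dpi: int | None = None) -> list[PageImage]:
    """Load a directory of PNG/JPEG page images, sorted by filename."""
    directory = Path(directory)
    files = sorted(
        f for f in directory.iterdir() if f.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not files:
        raise InputError(f"no page images found in {directory}")
    return [read_page(f, dpi=dpi) for f in files]


def _collect_pages(config: RunConfig) -> list[PageImage]:
    path = Path(config.input_path)
    if path.is_dir():
        return load_pages(path, dpi=config.dpi)
    if path.suffix.lower() == ".pdf":
        return rasterize_pdf(path, dpi=config.dpi, out_dir=config.output_dir)
    if path.suffix.lower() in (".png", ".jpg", ".jpeg"):
        return [read_page(path, dpi=config.dpi)]
    raise InputError(f"unsupported input: {path}")


def _masks_for_page(page: PageImage, config: RunConfig, warnings: list[str]):
    if config.detector == "baseline":
        return detect_baseline(page, config.detector_config)
    mf = Path(config.mask_file)
    path = mf / f"{page.source_id}.json" if mf.is_dir() else mf
    if not path.exists():
        warnings.append(f"no mask file for page {page.source_id}")
        return []
    return load_masks(path, page)


def _process_page(page: PageImage, config: RunConfig, page_index: int):
    """Full per-page chain; returns (record, segments)."""
    warnings: list[str] = []
    masks = _masks_for_page(page, config, warnings)
    gray = to_grayscale(page)
    binary = binarize(gray, config.binarize_threshold)
    k = auto_kernel_side(page) if config.kernel_side == "auto" else config.kernel_side
    dilated = dilate(binary, k)
    page_seed = (config.rng_seed + page_index) % (2**31)
    results = expand_all(dilated, masks, rng_seed=page_seed)
    for r in results:
        if r.mode == "keep":
            warnings.append(f"mask {r.mask.mask_id}: contour fallback (keep mode)")
    if len(results) < len(masks):
        warnings.append(f"{len(masks) - len(results)} duplicate mask(s) dropped")
    segments = segment_page(gray, [r.mask for r in results], config.target_side)
    record = PageRecord(
        page_id=page.source_id,
        n_masks=len(masks),
        n_segments=len(segments),
        expansion_modes=[r.mode for r in results],
        warnings=warnings,
    )
    return record, segments


def process_document(config: RunConfig) -> RunManifest:
    """Run the whole chain over a document and write all outputs.

    Writes segment PNGs plus a sidecar JSON under ``output_dir/segments``
    and a ``manifest.json`` with per-page records.  Page-level failures are
    recorded in the manifest and do not abort the run.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pages = _collect_pages(config)

    items: list[tuple[PageRecord, list]] = []
    if config.jobs > 1 and len(pages) > 1:
        with ProcessPoolExecutor(max_workers=config.jobs) as ex:
            futures = [
                ex.submit(_process_page, p, config, i) for i, p in enumerate(pages)
            ]
            for i, fut in enumerate(futures):
                try:
                    items.append(fut.result())
                except ChemsegError as exc:
                    log.error("page %s failed: %s", pages[i].source_id, exc)
                    items.append(
                        (PageRecord(pages[i].source_id, 0, 0, [], [str(exc)]), [])
                    )
    else:
        for i, p in enumerate(pages):
            try:
                items.append(_process_page(p, config, i))
            except ChemsegError as exc:
                log.error("page %s failed: %s", p.source_id, exc)
                items.append((PageRecord(p.source_id, 0, 0, [], [str(exc)]), []))

    seg_dir = out_dir / "segments"
    seg_dir.mkdir(parents=True, exist_ok=True)
    sidecar = seg_dir / "segments.json"
    if sidecar.exists():
        sidecar.unlink()  # fresh sidecar per run
    records = []
    for record, segments in items:  # merge strictly in page order
        write_segments(segments, seg_dir)
        records.append(record)

    cfg_dict = dataclasses.asdict(config)
    manifest = RunManifest(pages=records, version=_version(), config=cfg_dict)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest.as_dict(), indent=1, sort_keys=True) + "\n"
    )
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
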