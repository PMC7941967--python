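"""Minimal single-image-per-page PDF writer and reader.

The writer embeds each page as one Flate-compressed 8-bit grayscale image
XObject, which is enough to exercise document-level round trips (page
count, order, resolution scaling).  The reader handles exactly this layout:
PDFs where each page shows one embedded grayscale image.  Arbitrary PDFs
(vector content, other filters) are out of scope; page images can always be
supplied directly as a directory of PNGs instead.
"""

from __future__ import annotations

import re
import zlib
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InputError
from .imaging import PageImage


def write_pdf(pages: list[PageImage], path: str | Path, dpi: int = 300) -> None:
    """Write pages as a PDF, one embedded grayscale image per page."""
    path = Path(path)
    objects: list[bytes] = []  # 1-based object bodies, in numbering order

    page_obj_ids = []
    n_fixed = 2  # catalog, pages tree
    for i, p in enumerate(pages):
        page_obj_ids.append(n_fixed + 1 + 2 * i)  # page, then its image

    kids = b" ".join(b"%d 0 R" % oid for oid in page_obj_ids)
    objects.append(b"<< /Type /Catalog /Pages 2 0 R >>")
    objects.append(
        b"<< /Type /Pages /Kids [" + kids + b"] /Count %d >>" % len(pages)
    )
    for i, p in enumerate(pages):
        gray = p.pixels if p.pixels.ndim == 2 else np.asarray(
            Image.fromarray(p.pixels).convert("L")
        )
        h, w = gray.shape
        w_pt, h_pt = w * 72.0 / dpi, h * 72.0 / dpi
        img_id = page_obj_ids[i] + 1
        content_id = 2 * len(pages) + n_fixed + 1 + i
        objects.append(
            b"<< /Type /Page /Parent 2 0 R /MediaBox [0 0 %.4f %.4f] "
            b"/Resources << /XObject << /Im0 %d 0 R >> >> /Contents %d 0 R >>"
            % (w_pt, h_pt, img_id, content_id)
        )
        data = zlib.compress(gray.tobytes())
        objects.append(
            b"<< /Type /XObject /Subtype /Image /Width %d /Height %d "
            b"/ColorSpace /DeviceGray /BitsPerComponent 8 /Filter /FlateDecode "
            b"/Length %d >>\nstream\n" % (w, h, len(data))
            + data
            + b"\nendstream"
        )
    for i, p in enumerate(pages):
        gray = p.pixels if p.pixels.ndim == 2 else np.asarray(
            Image.fromarray(p.pixels).convert("L")
        )
        h, w = gray.shape
        content = b"q %.4f 0 0 %.4f 0 0 cm /Im0 Do Q" % (w * 72.0 / dpi, h * 72.0 / dpi)
        objects.append(
            b"<< /Length %d >>\nstream\n" % len(content) + content + b"\nendstream"
        )

    buf = bytearray(b"%PDF-1.4\n")
    offsets = [0]
    for i, body in enumerate(objects, start=1):
        offsets.append(len(buf))
        buf += b"%d 0 obj\n" % i + body + b"\nendobj\n"
    xref_at = len(buf)
    buf += b"xref\n0 %d\n" % (len(objects) + 1)
    buf += b"0000000000 65535 f \n"
    for off in offsets[1:]:
        buf += b"%010d 00000 n \n" % off
    buf += (
        b"trailer\n<< /Size %d /Root 1 0 R >>\nstartxref\n%d\n%%%%EOF\n"
        % (len(objects) + 1, xref_at)
    )
    path.write_bytes(bytes(buf))


_IMG_RE = re.compile(
    rb"/Subtype\s*/Image.*?/Width\s+(\d+).*?/Height\s+(\d+).*?"
    rb"stream\r?\n(.*?)\r?\nendstream",
    re.S,
)
_BOX_RE = re.compile(rb"/MediaBox\s*\[\s*0\s+0\s+([\d.]+)\s+([\d.]+)\s*\]")


def read_pdf(path: str | Path, dpi: int = 300) -> list[PageImage]:
    """Rasterize a single-image-per-page PDF at the requested dpi.

    Each embedded grayscale image is decompressed and rescaled so the page
    renders at ``dpi`` dots per inch of its MediaBox.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    data = path.read_bytes()
    if not data.startswith(b"%PDF"):
        raise InputError(f"not a PDF file: {path}")
    if b"/Encrypt" in data:
        raise InputError(f"encrypted PDF not supported: {path}")
    images = _IMG_RE.findall(data)
    boxes = _BOX_RE.findall(data)
    if not images:
        raise InputError(
            f"{path}: no embedded image pages found (only single-image-per-page "
            "PDFs are supported; supply page PNGs directly otherwise)"
        )
    pages = []
    for i, (w_b, h_b, stream) in enumerate(images):
        w, h = int(w_b), int(h_b)
        try:
            raw = zlib.decompress(stream)
            arr = np.frombuffer(raw, dtype=np.uint8).reshape(h, w)
        except (zlib.error, ValueError) as exc:
            raise InputError(f"{path}: bad image stream on page {i}: {exc}") from exc
        if i < len(boxes):
            w_pt, h_pt = float(boxes[i][0]), float(boxes[i][1])
            tw, th = round(w_pt * dpi / 72.0), round(h_pt * dpi / 72.0)
        else:
            tw, th = w, h
        if (th, tw) != (h, w):
            arr = np.asarray(
                Image.fromarray(arr).resize((tw, th), Image.BILINEAR), dtype=np.uint8
            )
        pages.append(PageImage(arr, dpi=dpi, source_id=f"{path.stem}_p{i}"))
    return pages
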