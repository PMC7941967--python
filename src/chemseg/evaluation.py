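"""Automated scoring of segmentation output against ground truth.

Mirrors, in automated form, the manual validation protocol for structure
segmentation: each output segment is classified as containing a *complete*
structure (every ink pixel of the matched ground-truth structure covered),
flagged when it also contains *extra objects* (any ink of a label, reaction
arrow or text block — glyphs drawn inside the structure belong to the
structure's own mask and never count), and unmatched structures are counted
as *missed*.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .imaging import BinaryMask
from .synthetic import PageAnnotation

#: A structure counts as detected when its best mask covers at least this
#: fraction of its ink pixels.
DETECTION_COVERAGE = 0.5


@dataclass
class EvaluationReport:
    """Counts and percentages over one page or a whole corpus."""

    n_structures_gt: int
    n_segments: int
    n_complete: int
    n_with_extra_objects: int
    n_missed: int
    pct_complete: float
    pct_extra: float
    pct_detected: float

    def as_dict(self) -> dict:
        return asdict(self)


def match_masks(
    pred: list[BinaryMask], annotations: PageAnnotation
) -> list[int | None]:
    """Assign each predicted mask to the structure it overlaps most.

    Returns, per predicted mask, the index of the ground-truth structure
    whose ink it covers most (ties broken toward the lowest structure
    index), or None for masks overlapping no structure ink.  A structure is
    *detected* when its best-overlapping mask covers at least half of its
    ink pixels; this threshold is applied by :func:`score_run`, not here.
    """
    structures = annotations.by_class("structure")
    assignment: list[int | None] = []
    for m in pred:
        overlaps = [int((m.member & s.member).sum()) for s in structures]
        best = int(np.argmax(overlaps)) if overlaps else None
        assignment.append(best if overlaps and overlaps[best] > 0 else None)
    return assignment


def score_run(pred: list[BinaryMask], annotations: PageAnnotation) -> EvaluationReport:
    """Score one page's predicted masks against its annotation.

    complete — the assigned mask covers 100% of the structure's ink;
    extra  — the mask covers at least one ink pixel of any label, arrow or
    text object; detected — some mask covers ≥ 50% of the structure's ink.
    Percentages are relative to the number of segments (complete, extra)
    and ground-truth structures (detected), reported to 0.1.
    """
    structures = annotations.by_class("structure")
    clutter = [
        m for c, m in annotations.objects if c in ("label", "arrow", "text")
    ]
    clutter_ink = (
        np.logical_or.reduce([m.member for m in clutter])
        if clutter
        else None
    )
    assignment = match_masks(pred, annotations)

    n_complete = 0
    n_extra = 0
    best_cover = [0.0] * len(structures)
    for m, gi in zip(pred, assignment):
        if gi is not None:
            s = structures[gi]
            frac = (m.member & s.member).sum() / s.member.sum()
            best_cover[gi] = max(best_cover[gi], float(frac))
            if frac == 1.0:
                n_complete += 1
        if clutter_ink is not None and (m.member & clutter_ink).any():
            n_extra += 1

    detected = sum(1 for f in best_cover if f >= DETECTION_COVERAGE)
    n_gt = len(structures)
    n_seg = len(pred)
    report = EvaluationReport(
        n_structures_gt=n_gt,
        n_segments=n_seg,
        n_complete=n_complete,
        n_with_extra_objects=n_extra,
        n_missed=n_gt - detected,
        pct_complete=round(100.0 * n_complete / n_seg, 1) if n_seg else 0.0,
        pct_extra=round(100.0 * n_extra / n_seg, 1) if n_seg else 0.0,
        pct_detected=round(100.0 * detected / n_gt, 1) if n_gt else 0.0,
    )
    return report


def combine_reports(reports: list[EvaluationReport]) -> EvaluationReport:
    """Pool per-page reports into corpus-level counts and percentages."""
    n_gt = sum(r.n_structures_gt for r in reports)
    n_seg = sum(r.n_segments for r in reports)
    n_complete = sum(r.n_complete for r in reports)
    n_extra = sum(r.n_with_extra_objects for r in reports)
    n_missed = sum(r.n_missed for r in reports)
    return EvaluationReport(
        n_structures_gt=n_gt,
        n_segments=n_seg,
        n_complete=n_complete,
        n_with_extra_objects=n_extra,
        n_missed=n_missed,
        pct_complete=round(100.0 * n_complete / n_seg, 1) if n_seg else 0.0,
        pct_extra=round(100.0 * n_extra / n_seg, 1) if n_seg else 0.0,
        pct_detected=round(100.0 * (n_gt - n_missed) / n_gt, 1) if n_gt else 0.0,
    )
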