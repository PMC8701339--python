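"""Inter-grader agreement and the reading-center adjudication rule.

Two trained graders outline the cup and the disc on every stereo-disc
photo.  Agreement is scored with the dice coefficient per structure,

    dice = 2 * overlap_area / (area_grader_1 + area_grader_2),

plus the absolute difference of the two graders' vertical CDRs.  An
image is sent to adjudication when either structure's dice falls below
0.7 or the VCDR difference exceeds 0.2; the inequalities are strict, so
dice exactly 0.7 or a difference of exactly 0.2 does not flag.  The
adjudicator may pick one grader's outlines, supply new outlines, or
declare the photo ungradable (removing it from all cohort outputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

from .geometry import close_gaps, overlap_area, polygon_area
from .profiles import CdrProfile, ProfileSource, average_graders, profile_from_outlines
from .roi_io import Eye, GradedImage, Resolution, Structure

__all__ = [
    "DICE_THRESHOLD",
    "VCDR_DIFF_THRESHOLD",
    "AdjudicationOutcome",
    "AdjudicationResult",
    "dice_coefficient",
    "evaluate_pair",
    "resolve",
    "resolved_profile",
    "worklist_to_csv",
]

DICE_THRESHOLD = 0.7
VCDR_DIFF_THRESHOLD = 0.2


class AdjudicationOutcome(str, Enum):
    NONE = "none"
    USE_GRADER_1 = "use_grader_1"
    USE_GRADER_2 = "use_grader_2"
    USE_ADJUDICATOR = "use_adjudicator"
    UNGRADABLE = "ungradable"


@dataclass
class AdjudicationResult:
    image_id: str
    eye: Eye
    dice_disc: float
    dice_cup: float
    vcdr_diff: float
    flagged: bool
    reason: set[str] = field(default_factory=set)
    resolution: AdjudicationOutcome = AdjudicationOutcome.NONE


def dice_coefficient(polygon_a, polygon_b) -> float:
    """Dice overlap of two simple closed polygons; symmetric, in [0, 1]."""
    pa = close_gaps(polygon_a)
    pb = close_gaps(polygon_b)
    # clipping is last-ulp sensitive to argument order; canonicalize so
    # dice(a, b) == dice(b, a) holds exactly
    if pa.tobytes() > pb.tobytes():
        pa, pb = pb, pa
    inter = overlap_area(pa, pb)
    return 2.0 * inter / (polygon_area(pa) + polygon_area(pb))


def evaluate_pair(
    image: GradedImage,
    grader_1: str | None = None,
    grader_2: str | None = None,
    *,
    dice_threshold: float = DICE_THRESHOLD,
    vcdr_diff_threshold: float = VCDR_DIFF_THRESHOLD,
) -> AdjudicationResult:
    """Score the two graders' outlines of one image against the flag rule.

    Each grader's VCDR is computed about that grader's own disc
    centroid.  Grader order defaults to first-seen order in the image.
    """
    graders = image.graders()
    if grader_1 is None or grader_2 is None:
        if len(graders) < 2:
            raise ValueError(f"{image.image_id}: need outlines from two graders")
        grader_1, grader_2 = graders[0], graders[1]
    for g in (grader_1, grader_2):
        for s in (Structure.CUP, Structure.DISC):
            if not image.has(g, s):
                raise ValueError(f"{image.image_id}: missing {s.value} outline from {g!r}")
    d_disc = dice_coefficient(
        image.get(grader_1, Structure.DISC).vertices,
        image.get(grader_2, Structure.DISC).vertices,
    )
    d_cup = dice_coefficient(
        image.get(grader_1, Structure.CUP).vertices,
        image.get(grader_2, Structure.CUP).vertices,
    )
    p1 = profile_from_outlines(
        image.get(grader_1, Structure.CUP), image.get(grader_1, Structure.DISC),
        source=ProfileSource.GRADER_1,
    )
    p2 = profile_from_outlines(
        image.get(grader_2, Structure.CUP), image.get(grader_2, Structure.DISC),
        source=ProfileSource.GRADER_2,
    )
    vdiff = abs(p1.vcdr - p2.vcdr)
    reason: set[str] = set()
    if d_disc < dice_threshold:
        reason.add("low_dice_disc")
    if d_cup < dice_threshold:
        reason.add("low_dice_cup")
    if vdiff > vcdr_diff_threshold:
        reason.add("high_vcdr_diff")
    return AdjudicationResult(
        image_id=image.image_id,
        eye=image.eye,
        dice_disc=d_disc,
        dice_cup=d_cup,
        vcdr_diff=vdiff,
        flagged=bool(reason),
        reason=reason,
    )


_RESOLUTION_MAP = {
    AdjudicationOutcome.NONE: Resolution.BOTH_GRADERS,
    AdjudicationOutcome.USE_GRADER_1: Resolution.GRADER_1,
    AdjudicationOutcome.USE_GRADER_2: Resolution.GRADER_2,
    AdjudicationOutcome.USE_ADJUDICATOR: Resolution.ADJUDICATOR,
}


def resolve(
    image: GradedImage,
    result: AdjudicationResult,
    resolution: AdjudicationOutcome | str,
    adjudicator_outlines: Sequence | None = None,
) -> GradedImage:
    """Apply the adjudicator's decision to a graded image.

    ``use_adjudicator`` requires a new cup + disc outline pair, which
    replaces both graders (no averaging downstream).  ``ungradable``
    marks the image for exclusion from every cohort output.
    """
    resolution = AdjudicationOutcome(resolution)
    if resolution is AdjudicationOutcome.UNGRADABLE:
        image.gradable = False
        result.resolution = resolution
        return image
    if resolution is AdjudicationOutcome.USE_ADJUDICATOR:
        if not adjudicator_outlines:
            raise ValueError("use_adjudicator requires adjudicator cup and disc outlines")
        structures = {o.structure for o in adjudicator_outlines}
        if structures != {Structure.CUP, Structure.DISC}:
            raise ValueError("adjudicator must supply exactly one cup and one disc outline")
        for o in adjudicator_outlines:
            if image.has(o.grader_id, o.structure):
                raise ValueError(f"grader id {o.grader_id!r} already present on image")
            image.add(o)
    elif resolution in (AdjudicationOutcome.USE_GRADER_1, AdjudicationOutcome.USE_GRADER_2):
        idx = 0 if resolution is AdjudicationOutcome.USE_GRADER_1 else 1
        graders = image.graders()
        if len(graders) <= idx:
            raise ValueError(f"{image.image_id}: grader {idx + 1} not present")
    image.resolution = _RESOLUTION_MAP[resolution]
    result.resolution = resolution
    return image


def resolved_profile(
    image: GradedImage,
    *,
    adjudicator_id: str = "adjudicator",
    averaging_mode: str = "average_cut_throughs",
) -> CdrProfile | None:
    """Downstream profile for an image after adjudication.

    Unflagged (or unresolved) images average the two graders; a
    resolution names the single source used instead.  Returns None for
    ungradable images.
    """
    if not image.gradable:
        return None
    graders = [g for g in image.graders() if g != adjudicator_id]

    def _one(grader: str, source: ProfileSource) -> CdrProfile:
        return profile_from_outlines(
            image.get(grader, Structure.CUP), image.get(grader, Structure.DISC),
            source=source,
        )

    if image.resolution is Resolution.GRADER_1:
        return _one(graders[0], ProfileSource.GRADER_1)
    if image.resolution is Resolution.GRADER_2:
        return _one(graders[1], ProfileSource.GRADER_2)
    if image.resolution is Resolution.ADJUDICATOR:
        return _one(adjudicator_id, ProfileSource.ADJUDICATOR)
    p1 = _one(graders[0], ProfileSource.GRADER_1)
    p2 = _one(graders[1], ProfileSource.GRADER_2)
    return average_graders(p1, p2, mode=averaging_mode)


def worklist_to_csv(results: Sequence[AdjudicationResult], path: str | Path) -> Path:
    rows = [
        {
            "image_id": r.image_id,
            "eye": r.eye.value,
            "dice_disc": r.dice_disc,
            "dice_cup": r.dice_cup,
            "vcdr_diff": r.vcdr_diff,
            "flagged": r.flagged,
            "reason": ";".join(sorted(r.reason)),
            "resolution": r.resolution.value,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
    return Path(path)
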