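"""Traditional segmentation metrics for the comparison panel.

Overlap (Dice, Jaccard) is computed on pixel masks; distance metrics
(Hausdorff family, surface Dice) on boundary-point sets in millimeters;
Added Path Length (APL) counts reference boundary pixels left unmatched by
the test boundary, in pixels. All implementations are deterministic with no
point subsampling. Conventions pinned here:

* HD95 combines the two directed 95th percentiles (linear interpolation) by
  their maximum; the average Hausdorff is the mean of the two directed means.
* Surface Dice pools both directions: the fraction of all boundary points
  (reference and test together) whose nearest-neighbor distance is within
  the tolerance (3 mm is the usual prostate setting).
* A pair of empty masks scores 1.0 on overlap and 0 on distances, flagged
  ``both-empty``; a single empty side scores 0 overlap, NaN distances, and
  full-rework APL, flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .contour_ops import Contour, Mask2D
from .errors import EmptyStructureError, IncompatibleVolumesError

__all__ = [
    "MetricPanel",
    "dice",
    "jaccard",
    "surface_distances",
    "hausdorff_family",
    "surface_dice",
    "added_path_length",
    "compute_panel",
]


@dataclass
class MetricPanel:
    """One row of traditional metrics for a (reference, test) pair."""

    dice: float
    jaccard: float
    avg_hausdorff_mm: float
    hd95_mm: float
    hausdorff_mm: float
    surface_dice: float
    surface_dice_tol_mm: float
    apl_px: int
    flags: tuple[str, ...] = ()


def _counts(a: Mask2D, b: Mask2D) -> tuple[int, int, int]:
    if a.pixels.shape != b.pixels.shape:
        raise IncompatibleVolumesError(
            f"mask shapes differ: {a.pixels.shape} vs {b.pixels.shape}"
        )
    inter = int((a.pixels & b.pixels).sum())
    return inter, a.area_px, b.area_px


def dice(a: Mask2D, b: Mask2D) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); defined as 1.0 when both empty."""
    inter, na, nb = _counts(a, b)
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def jaccard(a: Mask2D, b: Mask2D) -> float:
    """Jaccard overlap |A∩B| / |A∪B|; defined as 1.0 when both empty."""
    inter, na, nb = _counts(a, b)
    union = na + nb - inter
    if union == 0:
        return 1.0
    return inter / union


def surface_distances(
    a: Contour,
    b: Contour,
    spacing: tuple[float, float] = (1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Directed nearest-neighbor distance multisets ``(d(a->b), d(b->a))`` in mm."""
    if len(a) == 0 or len(b) == 0:
        raise EmptyStructureError("surface distances require non-empty contours")
    s = np.asarray(spacing, dtype=float)
    pa = a.points * s
    pb = b.points * s
    dmat = cdist(pa, pb)
    return dmat.min(axis=1), dmat.min(axis=0)


def hausdorff_family(dists: tuple[np.ndarray, np.ndarray]) -> tuple[float, float, float]:
    """``(avg_hausdorff, hd95, hausdorff)`` from the two directed multisets."""
    d_ab, d_ba = dists
    avg = float((d_ab.mean() + d_ba.mean()) / 2.0)
    hd95 = float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))
    hd = float(max(d_ab.max(), d_ba.max()))
    return avg, hd95, hd


def surface_dice(
    a: Contour,
    b: Contour,
    tol_mm: float,
    spacing: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Fraction of pooled boundary points within ``tol_mm`` of the other boundary."""
    if tol_mm < 0:
        raise ValueError("tolerance must be non-negative")
    d_ab, d_ba = surface_distances(a, b, spacing)
    hits = int((d_ab <= tol_mm).sum() + (d_ba <= tol_mm).sum())
    return hits / (len(d_ab) + len(d_ba))


def added_path_length(ref: Contour, test: Contour | None, tol_px: float = 0.0) -> int:
    """Reference boundary pixels farther than ``tol_px`` from the test boundary.

    A proxy for the contour length a clinician would have to redraw; with the
    default tolerance 0 only exact pixel agreement counts as matched. An
    absent/empty test contour means the whole reference needs drawing.
    """
    if len(ref) == 0:
        raise EmptyStructureError("APL requires a non-empty reference contour")
    if test is None or len(test) == 0:
        return len(ref)
    dmat = cdist(ref.points, test.points)
    return int((dmat.min(axis=1) > tol_px).sum())


def compute_panel(
    ref_mask: Mask2D,
    test_mask: Mask2D,
    spacing: tuple[float, float] = (1.0, 1.0),
    surface_dice_tol_mm: float = 3.0,
    apl_tol_px: float = 0.0,
    ref_contour: Contour | None = None,
    test_contour: Contour | None = None,
) -> MetricPanel:
    """Full traditional panel for one mask pair.

    Contours are extracted from the masks unless passed in (the pipeline
    reuses the ones it already traced for the MSI).
    """
    from .contour_ops import mask_to_contour

    flags: tuple[str, ...] = ()
    d = dice(ref_mask, test_mask)
    j = jaccard(ref_mask, test_mask)
    if ref_mask.area_px == 0 and test_mask.area_px == 0:
        return MetricPanel(1.0, 1.0, 0.0, 0.0, 0.0, 1.0, surface_dice_tol_mm, 0,
                           flags=("both-empty",))
    if ref_mask.area_px == 0 or test_mask.area_px == 0:
        flags += ("one-empty",)
        if ref_mask.area_px > 0:
            rc = ref_contour or mask_to_contour(ref_mask)
            apl = added_path_length(rc, None, apl_tol_px)
        else:
            apl = 0
        return MetricPanel(d, j, np.nan, np.nan, np.nan, 0.0, surface_dice_tol_mm,
                           apl, flags=flags)
    rc = ref_contour or mask_to_contour(ref_mask)
    tc = test_contour or mask_to_contour(test_mask)
    dists = surface_distances(rc, tc, spacing)
    avg, hd95, hd = hausdorff_family(dists)
    sd = surface_dice(rc, tc, surface_dice_tol_mm, spacing)
    apl = added_path_length(rc, tc, apl_tol_px)
    return MetricPanel(d, j, avg, hd95, hd, sd, surface_dice_tol_mm, apl, flags=flags)
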