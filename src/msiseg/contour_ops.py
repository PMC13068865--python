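"""Per-slice mask geometry: components, boundary contours, concavity, splitting.

Conventions (pinned for reproducibility):

* connected components use 8-connectivity;
* contours are the ordered *outer* boundary pixels of a component, traced
  with Moore neighbor following — clockwise in image coordinates (row grows
  downward), i.e. counter-clockwise in Cartesian axes — holes are ignored;
* centers of mass are unweighted means of foreground pixel coordinates;
* the hull ratio is ``hull_area / mask_area`` with the hull rasterized on the
  pixel grid, so a filled convex rectangle scores exactly 1.0 and the ratio
  is never below 1. A ratio above the threshold (default 1.2) marks a mask
  as concave enough to be a splitting candidate.

Touching structures appear as one concave component; ``split_concave_mask``
cuts them apart along the two deepest convexity-defect points, recursing on
the pieces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .errors import EmptyStructureError

__all__ = [
    "Mask2D",
    "Contour",
    "SplitParams",
    "connected_components",
    "mask_to_contour",
    "center_of_mass",
    "hull_ratio",
    "convexity_defects",
    "split_concave_mask",
    "point_in_mask",
    "points_in_mask",
]

logger = logging.getLogger(__name__)


@dataclass
class Mask2D:
    """A single-component binary mask kept in the full slice frame.

    ``pixels`` has the shape of the slice it came from, so component
    coordinates stay in slice coordinates across splitting and pairing.
    """

    pixels: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"Mask2D requires a 2D array, got shape {self.pixels.shape}")

    @cached_property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @cached_property
    def com(self) -> tuple[float, float]:
        return center_of_mass(self)

    def with_flag(self, flag: str) -> "Mask2D":
        return replace(self, flags=self.flags + (flag,))


@dataclass
class Contour:
    """Ordered boundary point sequence of one mask, in (row, col) pixels.

    ``com`` is the centroid used for center-of-mass alignment. For contours
    extracted from masks it is the *mask* centroid (area centroid); contours
    constructed directly from points default to the mean of the points.
    """

    points: np.ndarray
    closed: bool = True
    com: tuple[float, float] | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0:
            raise EmptyStructureError("a contour needs at least one point")
        if pts.shape[1] != 2:
            raise ValueError(f"contour points must be (N, 2), got {pts.shape}")
        self.points = pts
        if self.com is None:
            self.com = tuple(pts.mean(axis=0))

    def __len__(self) -> int:
        return len(self.points)

    def translated(self, offset: tuple[float, float]) -> "Contour":
        off = np.asarray(offset, dtype=float)
        return Contour(
            points=self.points + off,
            closed=self.closed,
            com=(self.com[0] + off[0], self.com[1] + off[1]),
            flags=self.flags,
        )


@dataclass(frozen=True)
class SplitParams:
    """Hyperparameters of the concave-mask splitting step.

    ``min_area_px`` filters splitting candidates; ``hull_ratio_threshold`` is
    the concavity trigger (hull area / mask area, default 1.2);
    ``max_iterations`` caps the recursion; ``cut_width_px`` is the rasterized
    thickness of the separating cut.
    """

    min_area_px: int = 50
    hull_ratio_threshold: float = 1.2
    max_iterations: int = 3
    cut_width_px: int = 1

    def __post_init__(self) -> None:
        if self.hull_ratio_threshold <= 1:
            raise ValueError("hull_ratio_threshold must exceed 1")
        if self.min_area_px < 1 or self.max_iterations < 1 or self.cut_width_px < 1:
            raise ValueError("min_area_px, max_iterations, cut_width_px must be >= 1")


def connected_components(slice_mask: np.ndarray) -> list[Mask2D]:
    """Split a binary slice into 8-connected components.

    Components are sorted by descending area, ties broken by the (row, col)
    of the topmost-leftmost pixel. An empty slice yields an empty list.
    """
    arr = np.asarray(slice_mask).astype(bool)
    if not arr.any():
        return []
    labels, n = skmeasure.label(arr, connectivity=2, return_num=True)
    comps = []
    for lab in range(1, n + 1):
        pix = labels == lab
        rows, cols = np.nonzero(pix)
        comps.append((-(len(rows)), int(rows[0]), int(cols[0]), Mask2D(pixels=pix)))
    comps.sort(key=lambda t: t[:3])
    return [c[-1] for c in comps]


def center_of_mass(mask: Mask2D) -> tuple[float, float]:
    """Unweighted mean (row, col) of the foreground pixels."""
    rows, cols = np.nonzero(mask.pixels)
    if len(rows) == 0:
        raise EmptyStructureError("center of mass of an empty mask is undefined")
    return (float(rows.mean()), float(cols.mean()))


# Moore neighborhood, clockwise in image coordinates, starting West.
_CLOCKWISE = (
    (0, -1), (-1, -1), (-1, 0), (-1, 1),
    (0, 1), (1, 1), (1, 0), (1, -1),
)
_OFFSET_INDEX = {off: k for k, off in enumerate(_CLOCKWISE)}


def _trace_boundary(pixels: np.ndarray) -> np.ndarray:
    """Moore-neighbor boundary following with Jacob's stopping criterion.

    Returns the ordered outer-boundary pixels of a single 8-connected
    component. Pixels on 1-px-wide spurs may appear more than once (the trace
    walks around them), but consecutive points are always distinct.
    """
    h, w = pixels.shape
    rows, cols = np.nonzero(pixels)
    if len(rows) == 0:
        raise EmptyStructureError("cannot trace the boundary of an empty mask")
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    if len(rows) == 1:
        return np.array([start])

    def fg(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < h and 0 <= p[1] < w and pixels[p]

    contour = [start]
    current = start
    backtrack = (start[0], start[1] - 1)  # background by choice of start
    first_transition = None
    max_steps = 4 * len(rows) + 8
    for _ in range(max_steps):
        b_off = (backtrack[0] - current[0], backtrack[1] - current[1])
        b_idx = _OFFSET_INDEX[b_off]
        nxt = None
        for k in range(1, 9):
            off = _CLOCKWISE[(b_idx + k) % 8]
            cand = (current[0] + off[0], current[1] + off[1])
            if fg(cand):
                prev_off = _CLOCKWISE[(b_idx + k - 1) % 8]
                nxt = cand
                new_backtrack = (current[0] + prev_off[0], current[1] + prev_off[1])
                break
        if nxt is None:  # isolated pixel, handled above; defensive
            break
        if first_transition is None:
            first_transition = (current, nxt)
        elif (current, nxt) == first_transition:
            break
        contour.append(nxt)
        current, backtrack = nxt, new_backtrack
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return np.array(contour)


def mask_to_contour(mask: Mask2D) -> Contour:
    """Ordered outer boundary of a component; holes are ignored.

    Degenerate masks (one or two boundary points) come back open and flagged
    rather than raising, so that tiny fragments survive the pipeline with an
    audit trail.
    """
    if mask.area_px == 0:
        raise EmptyStructureError("cannot extract a contour from an empty mask")
    pts = _trace_boundary(mask.pixels)
    degenerate = len(pts) < 3
    return Contour(
        points=pts.astype(float),
        closed=not degenerate,
        com=mask.com,
        flags=mask.flags + (("degenerate",) if degenerate else ()),
    )


def hull_ratio(mask: Mask2D) -> float:
    """Convex hull area divided by mask area, both as pixel counts.

    >= 1 by construction; 1.0 exactly for convex rasterized shapes. Degenerate
    (line-like) masks are defined to have ratio 1.
    """
    if mask.area_px == 0:
        raise EmptyStructureError("hull ratio of an empty mask is undefined")
    if mask.area_px < 3:
        return 1.0
    try:
        hull = skmorph.convex_hull_image(mask.pixels)
    except Exception:  # collinear / degenerate geometry
        return 1.0
    return float(hull.sum()) / float(mask.area_px)


def convexity_defects(contour: Contour) -> list[tuple[int, float]]:
    """Deepest inward deviation per convex-hull gap of a closed contour.

    For each pair of hull vertices consecutive along the contour, the defect
    is the intermediate contour point with the largest perpendicular distance
    to the hull edge. Returns ``(contour_index, depth_px)`` for every gap that
    contains at least one point with positive depth, sorted by descending
    depth.
    """
    pts = contour.points
    n = len(pts)
    if n < 4:
        return []
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return []
    hull_idx = sorted(int(i) for i in hull.vertices)
    defects: list[tuple[int, float]] = []
    for a, b in zip(hull_idx, hull_idx[1:] + [hull_idx[0] + n]):
        interior = np.arange(a + 1, b) % n
        if len(interior) == 0:
            continue
        p0, p1 = pts[a % n], pts[b % n]
        edge = p1 - p0
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        rel = pts[interior] - p0
        depths = np.abs(edge[0] * rel[:, 1] - edge[1] * rel[:, 0]) / norm
        dmax = depths.max()
        if dmax <= 0:
            continue
        # flat concavities (e.g. a straight neck edge) tie along a run of
        # points; anchor the defect at the middle of the maximal run so the
        # cut crosses the neck instead of running along it
        tied = np.nonzero(depths >= dmax - 1e-9)[0]
        k = int(tied[len(tied) // 2])
        defects.append((int(interior[k]), float(dmax)))
    defects.sort(key=lambda t: -t[1])
    return defects


def _cut_mask(shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray, width: int) -> np.ndarray:
    rr, cc = skdraw.line(int(round(p0[0])), int(round(p0[1])), int(round(p1[0])), int(round(p1[1])))
    cut = np.zeros(shape, dtype=bool)
    cut[rr, cc] = True
    if width > 1:
        cut = skmorph.dilation(cut, skmorph.disk(width // 2))
    return cut


def split_concave_mask(mask: Mask2D, params: SplitParams, _depth: int = 0) -> list[Mask2D]:
    """Recursively separate touching structures merged into one concave mask.

    A mask below ``min_area_px`` or with hull ratio <= threshold passes
    through unchanged. Otherwise the straight segment between the two deepest
    convexity-defect points is erased (``cut_width_px`` thick), components are
    re-extracted, and each piece is processed again up to ``max_iterations``
    levels. A candidate that cannot be separated (fewer than two defects, or a
    cut that fails to disconnect) is returned unchanged with a
    ``cannot-split`` flag; pieces still concave at the recursion cap carry a
    ``max-iterations`` flag.
    """
    if mask.area_px < params.min_area_px:
        return [mask]
    ratio = hull_ratio(mask)
    if ratio <= params.hull_ratio_threshold:
        return [mask]
    if _depth >= params.max_iterations:
        return [mask.with_flag("max-iterations")]
    contour = mask_to_contour(mask)
    defects = convexity_defects(contour)
    if len(defects) < 2:
        logger.debug("split: ratio %.3f but <2 convexity defects; cannot split", ratio)
        return [mask.with_flag("cannot-split")]
    # Two deepest defect points; on depth ties prefer the pair farther apart
    # along the contour.
    i0 = defects[0][0]
    rest = [d for d in defects if d[0] != i0]
    if not rest:
        return [mask.with_flag("cannot-split")]
    n = len(contour)

    def circ_sep(i: int, j: int) -> int:
        d = abs(i - j)
        return min(d, n - d)

    best_depth = rest[0][1]
    candidates = [d for d in rest if np.isclose(d[1], best_depth)]
    i1 = max(candidates, key=lambda d: circ_sep(i0, d[0]))[0]
    cut = _cut_mask(mask.pixels.shape, contour.points[i0], contour.points[i1], params.cut_width_px)
    remaining = mask.pixels & ~cut
    pieces = connected_components(remaining)
    if len(pieces) <= 1:
        logger.debug("split: cut between %s and %s did not disconnect", i0, i1)
        return [mask.with_flag("cannot-split")]
    logger.debug(
        "split: ratio %.3f > %.3f, cut %d px, %d pieces",
        ratio, params.hull_ratio_threshold, int(cut.sum()), len(pieces),
    )
    out: list[Mask2D] = []
    for piece in pieces:
        out.extend(split_concave_mask(piece, params, _depth + 1))
    return out


def _round_half_up(x: float) -> int:
    # deterministic nearest-pixel rule, .5 rounds toward +inf
    return int(np.floor(x + 0.5))


def point_in_mask(point: tuple[float, float], mask: Mask2D) -> str:
    """Classify a (possibly fractional) point as ``inside``/``outside``.

    The nearest-pixel rule applies (half-up rounding); out-of-bounds points
    are outside.
    """
    r = _round_half_up(float(point[0]))
    c = _round_half_up(float(point[1]))
    h, w = mask.pixels.shape
    if not (0 <= r < h and 0 <= c < w):
        return "outside"
    return "inside" if mask.pixels[r, c] else "outside"


def points_in_mask(points: np.ndarray, mask: Mask2D) -> np.ndarray:
    """Vectorized :func:`point_in_mask`: boolean array, True = inside."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rc = np.floor(pts + 0.5).astype(int)
    h, w = mask.pixels.shape
    valid = (rc[:, 0] >= 0) & (rc[:, 0] < h) & (rc[:, 1] >= 0) & (rc[:, 1] < w)
    inside = np.zeros(len(pts), dtype=bool)
    inside[valid] = mask.pixels[rc[valid, 0], rc[valid, 1]]
    return inside
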