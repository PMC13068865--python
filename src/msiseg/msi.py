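"""The Medical Similarity Index (MSI).

The MSI scores a test contour against a reference contour in [0, 1] with
clinically tunable asymmetry. The computation:

1. **COM correction** — translate the test contour so its center of mass
   coincides with the reference's, removing pure placement offsets.
2. **Bidirectional local distance (BLD)** — for every test point ``t``,
   ``forward(t)`` is the distance to the nearest reference point; every
   reference point *claims* its nearest test point, and ``backward_max(t)``
   is the largest distance over reference points claiming ``t``. The BLD is
   ``max(forward, backward_max)`` (forward alone where nothing claims ``t``).
   Unlike a plain nearest-neighbor distance, the backward term penalizes test
   contours that leave stretches of the reference unmatched.
3. **Direction classification** — a corrected test point lying within the
   filled reference mask deviates *inward*; otherwise *outward*. Boundary
   points count as inside (score-neutral at zero distance, pinned for
   determinism).
4. **Per-point similarity** — the default weighting is exponential decay
   ``exp(-l * d / tau)`` with ``l = il`` for inward points and ``l = ol`` for
   outward ones; ``tau`` (``distance_scale``) sets the distance at which an
   ``l = 1`` deviation decays to ``1/e``. A level of 0 disables that
   direction's penalty entirely. Alternative weightings plug in through a
   registry.
5. The contour MSI is the arithmetic mean of per-point similarities; a slice
   aggregates its contours by the **median**, a patient aggregates slices by
   the **mean**.

Raising ``il`` above ``ol`` makes under-segmentation (e.g. eroding into a
tumor volume) score worse than over-segmentation, and vice versa — the
asymmetry traditional overlap metrics cannot express.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .contour_ops import Contour, Mask2D, points_in_mask
from .errors import ConfigurationError, EmptyStructureError

__all__ = [
    "MSIParams",
    "BLDResult",
    "MSIScore",
    "register_weighting",
    "com_correct",
    "bld_distances",
    "classify_directions",
    "point_similarity",
    "msi_pair",
    "slice_msi",
    "patient_msi",
]

# --------------------------------------------------------------------------
# parameters and weighting registry

WeightingFn = Callable[[np.ndarray, float, float], np.ndarray]

_WEIGHTINGS: dict[str, WeightingFn] = {}


def register_weighting(name: str) -> Callable[[WeightingFn], WeightingFn]:
    """Register a per-point similarity function ``f(d, level, scale) -> [0,1]``."""

    def deco(fn: WeightingFn) -> WeightingFn:
        _WEIGHTINGS[name] = fn
        return fn

    return deco


@register_weighting("exponential")
def _exponential(d: np.ndarray, level: float, scale: float) -> np.ndarray:
    return np.exp(-level * np.asarray(d, dtype=float) / scale)


@register_weighting("reciprocal")
def _reciprocal(d: np.ndarray, level: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + level * np.asarray(d, dtype=float) / scale)


@dataclass(frozen=True)
class MSIParams:
    """MSI hyperparameters.

    ``il``/``ol`` are the inner/outer severity levels (non-negative
    multipliers; 1 is neutral, 0 disables the direction). ``distance_scale``
    is the decay scale tau, in ``units`` (px by default, mm via in-plane
    spacing). ``weighting`` selects the per-point similarity function.
    """

    il: float = 1.0
    ol: float = 1.0
    distance_scale: float = 5.0
    units: str = "px"
    weighting: str = "exponential"

    def __post_init__(self) -> None:
        if self.il < 0 or self.ol < 0:
            raise ConfigurationError("il and ol must be non-negative")
        if self.distance_scale <= 0:
            raise ConfigurationError("distance_scale must be positive")
        if self.units not in ("px", "mm"):
            raise ConfigurationError(f"units must be 'px' or 'mm', got {self.units!r}")
        if self.weighting not in _WEIGHTINGS:
            raise ConfigurationError(
                f"unknown weighting {self.weighting!r}; available: {sorted(_WEIGHTINGS)}"
            )

    @property
    def weighting_fn(self) -> WeightingFn:
        return _WEIGHTINGS[self.weighting]


# --------------------------------------------------------------------------
# results


@dataclass
class BLDResult:
    """Per-test-point bidirectional local distances.

    ``backward_max`` is NaN where no reference point claims the test point;
    there ``distances`` falls back to ``forward``.
    """

    test_points: np.ndarray
    forward: np.ndarray
    backward_max: np.ndarray
    distances: np.ndarray
    units: str = "px"


@dataclass
class MSIScore:
    """MSI of one contour pair, with the full per-point trace."""

    value: float
    n_points: int
    per_point_scores: np.ndarray
    distances: np.ndarray
    inside: np.ndarray
    params: MSIParams
    flags: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# operations


def com_correct(test: Contour, ref: Contour) -> Contour:
    """Translate ``test`` so its center of mass matches the reference's."""
    offset = (ref.com[0] - test.com[0], ref.com[1] - test.com[1])
    return test.translated(offset)


def _scaled(points: np.ndarray, units: str, spacing: tuple[float, float] | None) -> np.ndarray:
    if units == "px":
        return points
    if spacing is None:
        raise ConfigurationError("mm units require in-plane spacing")
    return points * np.asarray(spacing, dtype=float)


def bld_distances(
    test: Contour,
    ref: Contour,
    units: str = "px",
    spacing: tuple[float, float] | None = None,
) -> BLDResult:
    """Bidirectional local distance of every test point to the reference.

    ``forward(t) = min_r ||t - r||``; each reference point claims its nearest
    test point (distance ties resolved to the lower test index);
    ``backward_max(t)`` is the maximum distance over claiming reference
    points; ``BLD(t) = max(forward, backward_max)``. Distances are in
    ``units`` — mm scales coordinates by the in-plane spacing first.
    """
    if len(test) == 0 or len(ref) == 0:
        raise EmptyStructureError("BLD requires non-empty contours")
    t = _scaled(test.points, units, spacing)
    r = _scaled(ref.points, units, spacing)
    # all-pairs distances: contours are boundary point lists of single 2D
    # structures, small enough for a dense matrix
    diff = t[:, None, :] - r[None, :, :]
    dmat = np.sqrt((diff * diff).sum(axis=2))
    forward = dmat.min(axis=1)
    claims = dmat.argmin(axis=0)  # per ref point, first (lowest) test index on ties
    backward = np.full(len(t), -np.inf)
    np.maximum.at(backward, claims, dmat[claims, np.arange(len(r))])
    claimed = np.isfinite(backward)
    distances = np.where(claimed, np.maximum(forward, backward), forward)
    return BLDResult(
        test_points=test.points.copy(),
        forward=forward,
        backward_max=np.where(claimed, backward, np.nan),
        distances=distances,
        units=units,
    )


def classify_directions(test: Contour, ref_mask: Mask2D) -> np.ndarray:
    """Boolean array: True where the (corrected) test point lies inside the
    filled reference mask (nearest-pixel rule; boundary pixels are inside)."""
    return points_in_mask(test.points, ref_mask)


def point_similarity(d: float, direction: str, params: MSIParams) -> float:
    """Similarity in [0, 1] of a single deviation of size ``d``.

    The active level is ``il`` for ``direction == 'inside'``, ``ol`` for
    ``'outside'``; the registered weighting maps (d, level, tau) to a score
    that is 1 at d = 0 (or level 0) and strictly decreasing in both d and
    level otherwise.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    if direction not in ("inside", "outside"):
        raise ValueError(f"direction must be 'inside'/'outside', got {direction!r}")
    level = params.il if direction == "inside" else params.ol
    return float(params.weighting_fn(np.asarray([d]), level, params.distance_scale)[0])


def msi_pair(
    test: Contour,
    ref: Contour,
    ref_mask: Mask2D,
    params: MSIParams | None = None,
    spacing: tuple[float, float] | None = None,
) -> MSIScore:
    """MSI of one paired (test, reference) contour with full per-point trace.

    Composes COM correction, BLD, direction classification and the per-point
    weighting; the score is the mean of per-point similarities.
    """
    params = params or MSIParams()
    if ref_mask.area_px and not np.allclose(ref_mask.com, ref.com, atol=1e-6):
        raise ValueError(
            f"ref_mask COM {ref_mask.com} does not match ref contour COM {ref.com}"
        )
    corrected = com_correct(test, ref)
    bld = bld_distances(corrected, ref, units=params.units, spacing=spacing)
    inside = classify_directions(corrected, ref_mask)
    fn = params.weighting_fn
    scores = np.where(
        inside,
        fn(bld.distances, params.il, params.distance_scale),
        fn(bld.distances, params.ol, params.distance_scale),
    )
    return MSIScore(
        value=float(scores.mean()),
        n_points=len(corrected),
        per_point_scores=scores,
        distances=bld.distances,
        inside=inside,
        params=params,
        flags=test.flags + ref.flags,
    )


def slice_msi(scores: Sequence[MSIScore | float]) -> float | None:
    """Median MSI over the contours of one slice (None if no defined score)."""
    values = [s.value if isinstance(s, MSIScore) else float(s) for s in scores]
    if not values:
        return None
    return float(np.median(values))


def patient_msi(slice_values: Sequence[float | None]) -> float | None:
    """Mean MSI over slices with a defined value (None if there are none)."""
    defined = [v for v in slice_values if v is not None and not np.isnan(v)]
    if not defined:
        return None
    return float(np.mean(defined))
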