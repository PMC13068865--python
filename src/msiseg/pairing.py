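"""Nearest-center-of-mass pairing of reference and test contours on a slice.

Each reference is assigned its Euclidean-nearest test center of mass.
Assignments are made greedily in ascending distance order (ties by lower
reference index), which matches the nearest-COM strategy while keeping every
test claimed at most once. Configurations the strategy cannot resolve —
unequal counts, or one test being the nearest of two references — are
flagged ``ambiguous`` for manual review rather than raising; the greedy
assignment is still reported so a reviewer can inspect it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .contour_ops import Mask2D

__all__ = ["PairingResult", "pair_contours"]

logger = logging.getLogger(__name__)


@dataclass
class PairingResult:
    """Outcome of COM pairing on one slice.

    ``pairs`` holds ``(ref_index, test_index)``; indices absent from any pair
    appear in ``unmatched_refs`` / ``unmatched_tests``. ``ambiguous`` is True
    whenever the configuration needs manual review; ``reasons`` says why.
    """

    pairs: list[tuple[int, int]] = field(default_factory=list)
    unmatched_refs: list[int] = field(default_factory=list)
    unmatched_tests: list[int] = field(default_factory=list)
    ambiguous: bool = False
    reasons: list[str] = field(default_factory=list)


def pair_contours(refs: list[Mask2D], tests: list[Mask2D]) -> PairingResult:
    """Pair reference and test components of one slice by nearest COM.

    All failure modes are flags, never exceptions: a missed or spurious
    structure (empty vs non-empty side), a count mismatch, and contested
    nearest-neighbors all raise the ``ambiguous`` flag with a reason.
    Distances are computed in pixels on uncorrected COM positions — pairing
    must see absolute placement; COM correction happens only inside the MSI.
    """
    result = PairingResult()
    n_ref, n_test = len(refs), len(tests)
    if n_ref == 0 and n_test == 0:
        return result
    if n_test == 0:
        result.unmatched_refs = list(range(n_ref))
        result.ambiguous = True
        result.reasons.append(f"missed structure: {n_ref} reference contour(s), no test contour")
        return result
    if n_ref == 0:
        result.unmatched_tests = list(range(n_test))
        result.ambiguous = True
        result.reasons.append(f"spurious structure: {n_test} test contour(s), no reference contour")
        return result

    ref_coms = np.array([m.com for m in refs])
    test_coms = np.array([m.com for m in tests])
    dist = np.linalg.norm(ref_coms[:, None, :] - test_coms[None, :, :], axis=2)

    if n_ref != n_test:
        result.ambiguous = True
        result.reasons.append(f"count mismatch: {n_ref} reference vs {n_test} test contours")
    nearest_test = dist.argmin(axis=1)
    claimed, counts = np.unique(nearest_test, return_counts=True)
    for t in claimed[counts >= 2]:
        result.ambiguous = True
        refs_claiming = np.nonzero(nearest_test == t)[0].tolist()
        result.reasons.append(
            f"test contour {int(t)} is nearest to references {refs_claiming}"
        )

    order = sorted(
        ((dist[i, j], i, j) for i in range(n_ref) for j in range(n_test)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    ref_free = [True] * n_ref
    test_free = [True] * n_test
    for d, i, j in order:
        if ref_free[i] and test_free[j]:
            result.pairs.append((i, j))
            ref_free[i] = test_free[j] = False
            logger.debug("pairing: ref %d -> test %d at %.2f px", i, j, d)
    result.pairs.sort()
    result.unmatched_refs = [i for i, free in enumerate(ref_free) if free]
    result.unmatched_tests = [j for j, free in enumerate(test_free) if free]
    return result
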