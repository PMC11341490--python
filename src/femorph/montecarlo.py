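"""Monte Carlo area estimation on region masks, plus the exact-traversal oracle.

``n`` integer-coordinate points are drawn uniformly (with replacement) on the
full image rectangle. ``n1`` counts points landing in the overall femoral
region, ``n2`` counts points landing outside the cortical mask, so the
cortical hit count is ``n - n2`` and the medullary hit count is
``n1 - (n - n2)``. Proportions scale by the rectangle area ``a * b`` to give
area estimates in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np

from .imaging import RegionMasks

__all__ = [
    "MCAreaResult",
    "TraversalResult",
    "mc_area",
    "traversal_area",
    "mc_area_stack",
    "classify_points",
]


@dataclass
class MCAreaResult:
    """Counts and derived quantities of one per-slice sampling experiment."""

    n: int
    n1: int
    n2: int
    alpha_c: float
    alpha_m: float
    s_c: float
    s_m: float
    seed: Optional[int] = None
    slice_index: int = 0

    @classmethod
    def from_counts(
        cls,
        n: int,
        n1: int,
        n2: int,
        width: int,
        height: int,
        seed: Optional[int] = None,
        slice_index: int = 0,
    ) -> "MCAreaResult":
        """Derive proportions and areas exactly from raw counts."""
        if not (0 <= n - n2 <= n1 <= n):
            raise ValueError(f"inconsistent counts n={n}, n1={n1}, n2={n2}")
        alpha_c = (n - n2) / n
        alpha_m = (n1 - (n - n2)) / n
        return cls(
            n=n,
            n1=n1,
            n2=n2,
            alpha_c=alpha_c,
            alpha_m=alpha_m,
            s_c=alpha_c * width * height,
            s_m=alpha_m * width * height,
            seed=seed,
            slice_index=slice_index,
        )


@dataclass
class TraversalResult:
    """Exact pixel counts obtained by visiting every pixel exactly once."""

    cortical_count: int
    medullary_count: int
    alpha_ct: float
    alpha_mt: float


def _rng(seed: int, slice_index: Optional[int] = None) -> np.random.Generator:
    # Philox is counter-based: per-slice streams keyed on (seed, index) are
    # independent and platform-stable.
    if slice_index is None:
        ss = np.random.SeedSequence(seed)
    else:
        ss = np.random.SeedSequence(seed, spawn_key=(slice_index,))
    return np.random.Generator(np.random.Philox(ss))


def classify_points(
    xs: np.ndarray, ys: np.ndarray, masks: RegionMasks
) -> Tuple[int, int]:
    """Count ``(n1, n2)`` for given sample coordinates by mask lookup."""
    n = xs.size
    n1 = int(masks.overall[ys, xs].sum())
    n2 = n - int(masks.cortical[ys, xs].sum())
    return n1, n2


def mc_area(
    masks: RegionMasks, n: int, seed: int, slice_index: Optional[int] = None
) -> MCAreaResult:
    """Estimate cortical/medullary areas of one slice by random points.

    Draws ``n`` points with integer coordinates uniform on
    ``[0, a-1] x [0, b-1]`` with replacement; classification is a direct mask
    lookup. Reproducible for a given ``(seed, slice_index)`` pair.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    height, width = masks.shape
    if slice_index is None:
        slice_index = masks.slice_index
    rng = _rng(seed, slice_index)
    xs = rng.integers(0, width, size=n)
    ys = rng.integers(0, height, size=n)
    n1, n2 = classify_points(xs, ys, masks)
    return MCAreaResult.from_counts(
        n, n1, n2, width, height, seed=seed, slice_index=slice_index
    )


def census_result(masks: RegionMasks) -> MCAreaResult:
    """Counts as if every grid point were visited exactly once.

    Feeds exhaustive counts through the same proportion/area arithmetic as
    :func:`mc_area`, so ``alpha_c``/``alpha_m`` equal the traversal
    proportions exactly. Useful as a deterministic stand-in for the
    stochastic estimate.
    """
    height, width = masks.shape
    n = width * height
    n1 = int(np.count_nonzero(masks.overall))
    n2 = n - int(np.count_nonzero(masks.cortical))
    return MCAreaResult.from_counts(
        n, n1, n2, width, height, slice_index=masks.slice_index
    )


def traversal_area(masks: RegionMasks) -> TraversalResult:
    """Exact areas by exhaustive scan of the masks."""
    height, width = masks.shape
    total = width * height
    cc = int(np.count_nonzero(masks.cortical))
    mc = int(np.count_nonzero(masks.medullary))
    return TraversalResult(
        cortical_count=cc,
        medullary_count=mc,
        alpha_ct=cc / total,
        alpha_mt=mc / total,
    )


def mc_area_stack(
    masks: Iterable[Optional[RegionMasks]], n: int, seed: int
) -> Tuple[List[MCAreaResult], List[int]]:
    """Per-slice Monte Carlo estimates over a stack of masks.

    Flagged slices (``None`` entries) are skipped and their indices reported.
    Per-slice RNG streams are keyed on the master seed and the slice's own
    ``slice_index``, so reordering slices permutes results identically.
    """
    results: List[MCAreaResult] = []
    skipped: List[int] = []
    for pos, m in enumerate(masks):
        if m is None:
            skipped.append(pos)
            continue
        results.append(mc_area(m, n, seed, slice_index=m.slice_index))
    return results, skipped
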