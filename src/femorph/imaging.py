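"""Region-of-interest extraction from transverse slice images.

The per-slice pipeline is: Gaussian smoothing -> low-cut intensity threshold
-> Canny edge detection -> contour filling and subtraction, yielding three
nested binary masks per slice: the overall femoral region (everything inside
the outer cortical boundary), the medullary cavity, and the cortical annulus
(overall minus medullary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import canny as _skimage_canny
from skimage.morphology import disk

__all__ = [
    "SliceStack",
    "PreprocessParams",
    "RegionMasks",
    "ExtractionError",
    "gaussian_kernel",
    "gaussian_smooth",
    "threshold_low_cut",
    "detect_edges",
    "extract_masks",
    "extract_stack",
]


class ExtractionError(RuntimeError):
    """Raised when a slice yields no usable femoral region.

    ``flag`` is ``"no femur"`` (no closed outer contour) or ``"no cavity"``
    (no resolvable inner contour); distal slices may legitimately lack one.
    """

    def __init__(self, flag: str, message: str):
        super().__init__(message)
        self.flag = flag


@dataclass
class SliceStack:
    """Ordered transverse grayscale slices, proximal first, with spacing metadata.

    Parameters
    ----------
    images
        List of 2-D arrays (gray levels), all of identical shape.
    pixel_spacing
        In-plane pixel size in mm/pixel (isotropic).
    slice_interval
        Distance between consecutive slices in mm.
    provenance
        Free-text description of where the stack came from.
    """

    images: list
    pixel_spacing: float
    slice_interval: float
    provenance: str = ""

    def __post_init__(self):
        if len(self.images) > 0:
            shape = np.asarray(self.images[0]).shape
            for i, img in enumerate(self.images):
                if np.asarray(img).shape != shape:
                    raise ValueError(
                        f"slice {i} has shape {np.asarray(img).shape}, expected {shape}"
                    )
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.slice_interval <= 0:
            raise ValueError("slice_interval must be > 0")

    @property
    def n_slices(self) -> int:
        return len(self.images)

    @property
    def width(self) -> int:
        """Long side ``a`` in pixels (x axis)."""
        return int(np.asarray(self.images[0]).shape[1])

    @property
    def height(self) -> int:
        """Short side ``b`` in pixels (y axis)."""
        return int(np.asarray(self.images[0]).shape[0])


@dataclass
class PreprocessParams:
    """Parameters of the smoothing / thresholding / edge-detection stage.

    Defaults follow the reference configuration: 7x7 Gaussian window with
    sigma 3 and a low-cut threshold of 117 on the 8-bit gray scale. Canny
    gradient thresholds default to an automatic rule (high = 40% of the
    maximum gradient magnitude, low = high/2) and may be overridden.
    """

    sigma: float = 3.0
    window: int = 7
    t0: float = 117.0
    canny_sigma: float = 1.0
    canny_low: Optional[float] = None
    canny_high: Optional[float] = None

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.canny_low is not None and self.canny_high is not None:
            if not self.canny_low < self.canny_high:
                raise ValueError("canny_low must be < canny_high")


@dataclass
class RegionMasks:
    """Binary masks of one accepted slice: overall, cortical, medullary.

    Invariants: ``cortical & medullary`` is empty; both are subsets of
    ``overall``; the medullary mask lies inside the hole of the cortical
    annulus. Pixels on the inner contour belong to cortical, not medullary.
    """

    overall: np.ndarray
    cortical: np.ndarray
    medullary: np.ndarray
    slice_index: int = 0

    def __post_init__(self):
        self.overall = np.asarray(self.overall, dtype=bool)
        self.cortical = np.asarray(self.cortical, dtype=bool)
        self.medullary = np.asarray(self.medullary, dtype=bool)

    @property
    def shape(self):
        return self.overall.shape


def gaussian_kernel(sigma: float, window: int) -> np.ndarray:
    """Discrete isotropic 2-D Gaussian kernel on a ``window x window`` grid.

    The kernel is the product of two 1-D Gaussians with equal standard
    deviation, evaluated at integer offsets and renormalized to sum to 1
    (so constants are preserved exactly).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    half = window // 2
    offs = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(offs, offs)
    g = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return g / g.sum()


def gaussian_smooth(image: np.ndarray, sigma: float, window: int) -> np.ndarray:
    """Convolve ``image`` with a normalized Gaussian kernel; same shape out."""
    kernel = gaussian_kernel(sigma, window)
    return ndimage.convolve(np.asarray(image, dtype=float), kernel, mode="nearest")


def threshold_low_cut(image: np.ndarray, t0: float) -> np.ndarray:
    """Keep pixel values strictly greater than ``t0``; set the rest to 0."""
    image = np.asarray(image)
    return np.where(image > t0, image, 0)


def detect_edges(image: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Canny edge map (gradient, non-maximum suppression, hysteresis).

    When gradient thresholds are not supplied they are derived from the
    image: high = 0.4 * max gradient magnitude, low = high / 2. A constant
    image yields an empty edge map.
    """
    img = np.asarray(image, dtype=float)
    low, high = params.canny_low, params.canny_high
    if low is None or high is None:
        gmag = ndimage.gaussian_gradient_magnitude(img, params.canny_sigma)
        gmax = float(gmag.max())
        if gmax == 0.0:
            return np.zeros(img.shape, dtype=bool)
        if high is None:
            high = 0.4 * gmax
        if low is None:
            low = high / 2.0
    return _skimage_canny(
        img, sigma=params.canny_sigma, low_threshold=low, high_threshold=high
    )


_LABEL_8CONN = np.ones((3, 3), dtype=int)


def extract_masks(
    image: np.ndarray, params: Optional[PreprocessParams] = None, slice_index: int = 0
) -> RegionMasks:
    """Extract overall / cortical / medullary masks from one slice.

    Pipeline: smooth -> low-cut threshold -> Canny -> contour filling.
    The overall region is the filled largest closed edge contour; the
    medullary region is the interior of the largest closed contour nested
    inside it (contour pixels themselves assigned to cortical); cortical is
    the set difference overall minus medullary.

    Raises
    ------
    ExtractionError
        flag ``"no femur"`` when no closed outer contour exists, flag
        ``"no cavity"`` when no nested inner contour is found.
    """
    if params is None:
        params = PreprocessParams()
    smoothed = gaussian_smooth(image, params.sigma, params.window)
    cut = threshold_low_cut(smoothed, params.t0)
    edges = detect_edges(cut, params)
    # bridge 1-px gaps so slightly broken contours still close
    closed = ndimage.binary_closing(edges, structure=disk(1))
    labels, n_labels = ndimage.label(closed, structure=_LABEL_8CONN)
    if n_labels == 0:
        raise ExtractionError("no femur", f"slice {slice_index}: no edges detected")

    curves = [labels == k for k in range(1, n_labels + 1)]
    filled = [ndimage.binary_fill_holes(c) for c in curves]
    interior = [int(f.sum()) - int(c.sum()) for c, f in zip(curves, filled)]

    outer = int(np.argmax([f.sum() for f in filled]))
    if interior[outer] == 0:
        raise ExtractionError(
            "no femur", f"slice {slice_index}: outer contour is not closed"
        )
    overall = filled[outer]

    # largest closed contour strictly nested inside the overall region
    best, best_area = None, 0
    for k in range(n_labels):
        if k == outer:
            continue
        if interior[k] <= 0:
            continue
        if not np.all(overall[curves[k]]):
            continue
        if interior[k] > best_area:
            best, best_area = k, interior[k]
    if best is None:
        raise ExtractionError(
            "no cavity", f"slice {slice_index}: no nested inner contour"
        )

    medullary = filled[best] & ~curves[best]
    cortical = overall & ~medullary
    return RegionMasks(
        overall=overall, cortical=cortical, medullary=medullary, slice_index=slice_index
    )


def extract_stack(
    stack: SliceStack,
    params: Optional[PreprocessParams] = None,
    slice_range: Optional[tuple] = None,
):
    """Run :func:`extract_masks` over a stack.

    Returns ``(masks, flags)`` where ``masks`` is a list with one
    :class:`RegionMasks` per accepted slice and ``None`` for flagged slices,
    and ``flags`` is a list of ``(slice_index, flag)`` pairs. ``slice_range``
    restricts processing to ``[start, stop)`` indices.
    """
    start, stop = 0, stack.n_slices
    if slice_range is not None:
        start, stop = slice_range
    masks: list = []
    flags: list = []
    for i in range(start, stop):
        try:
            masks.append(extract_masks(stack.images[i], params, slice_index=i))
        except ExtractionError as err:
            masks.append(None)
            flags.append((i, err.flag))
    return masks, flags
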