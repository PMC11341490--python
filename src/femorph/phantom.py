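"""Synthetic femur phantom: slice stacks with analytically known geometry.

Each slice is an elliptical cortical annulus (bright) around an elliptical
medullary interior (dark) on a darker background. The inner semi-axis
profile narrows to a minimum at a designated isthmus slice and widens again
(trumpet shape); a localized widening of the outer x semi-axis near a
designated slice models the trochanteric prominence so prominence detection
has an exact ground truth.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .imaging import SliceStack

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PhantomError",
    "generate_phantom",
    "trumpet_spec",
    "constant_spec",
    "write_phantom",
]

# slice-index std-dev of the Gaussian profile of the trochanter bump
_BUMP_WIDTH_SLICES = 1.2


class PhantomError(ValueError):
    """Invalid phantom geometry (e.g. degenerate annulus)."""


@dataclass
class PhantomSpec:
    """Full parameterization of a synthetic stack.

    ``outer_radius_profile`` / ``inner_radius_profile`` are ``(n_slices, 2)``
    arrays of (x, y) semi-axes in mm of the outer cortical and inner
    medullary elliptical boundaries. ``trochanter_bump_amplitude`` (mm) is
    added to the outer x semi-axis with a Gaussian falloff (sd 1.2 slices)
    around ``trochanter_slice_index``.
    """

    n_slices: int
    outer_radius_profile: np.ndarray
    inner_radius_profile: np.ndarray
    isthmus_slice_index: int
    trochanter_slice_index: int
    image_width_px: int = 240
    image_height_px: int = 240
    pixel_spacing: float = 0.5  # mm / pixel
    slice_interval: float = 5.0  # mm
    trochanter_bump_amplitude: float = 0.0
    intensity_background: int = 10
    intensity_marrow: int = 34
    intensity_cortical: int = 200
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.outer_radius_profile = np.asarray(self.outer_radius_profile, dtype=float)
        self.inner_radius_profile = np.asarray(self.inner_radius_profile, dtype=float)
        for name in ("outer_radius_profile", "inner_radius_profile"):
            prof = getattr(self, name)
            if prof.shape != (self.n_slices, 2):
                raise PhantomError(
                    f"{name} must have shape ({self.n_slices}, 2), got {prof.shape}"
                )

    def effective_outer_profile(self) -> np.ndarray:
        """Outer semi-axes with the trochanter bump applied to the x axis."""
        prof = self.outer_radius_profile.copy()
        if self.trochanter_bump_amplitude != 0.0:
            i = np.arange(self.n_slices, dtype=float)
            bump = self.trochanter_bump_amplitude * np.exp(
                -0.5 * ((i - self.trochanter_slice_index) / _BUMP_WIDTH_SLICES) ** 2
            )
            prof[:, 0] += bump
        return prof

    def validate(self) -> None:
        outer = self.effective_outer_profile()
        inner = self.inner_radius_profile
        bad = np.nonzero(~np.all(inner < outer, axis=1))[0]
        if bad.size:
            raise PhantomError(
                f"degenerate annulus (inner >= outer) at slices {bad.tolist()}"
            )
        if np.any(inner <= 0):
            raise PhantomError("inner semi-axes must be positive")
        if not 0 <= self.isthmus_slice_index < self.n_slices:
            raise PhantomError("isthmus_slice_index out of range")
        if not 0 <= self.trochanter_slice_index < self.n_slices:
            raise PhantomError("trochanter_slice_index out of range")
        inner_area = inner[:, 0] * inner[:, 1]
        if inner_area[self.isthmus_slice_index] > inner_area.min() + 1e-12:
            raise PhantomError(
                "inner radius profile does not attain its minimum at "
                f"isthmus_slice_index={self.isthmus_slice_index}"
            )
        hi = max(self.intensity_cortical, self.intensity_marrow, self.intensity_background)
        if not (
            self.intensity_cortical > self.intensity_marrow >= self.intensity_background
        ):
            raise PhantomError("need intensity_cortical > intensity_marrow >= background")
        if hi > 255 or self.intensity_background < 0:
            raise PhantomError("intensities must lie in [0, 255]")
        if self.pixel_spacing <= 0 or self.slice_interval <= 0:
            raise PhantomError("spacings must be positive")


@dataclass
class GroundTruth:
    """Noise-free rasterizations and analytic areas of a phantom stack."""

    cortical_masks: list
    medullary_masks: list
    cortical_px: np.ndarray
    medullary_px: np.ndarray
    cortical_mm2: np.ndarray  # analytic annulus area pi*(Ao*Bo - Ai*Bi)
    medullary_mm2: np.ndarray  # analytic inner-ellipse area pi*Ai*Bi
    isthmus_slice_index: int
    trochanter_slice_index: int
    inner_profile_mm: np.ndarray
    outer_profile_mm: np.ndarray  # effective (bump included)

    @property
    def overall_masks(self) -> list:
        return [c | m for c, m in zip(self.cortical_masks, self.medullary_masks)]


def _ellipse_mask(
    width: int, height: int, cx: float, cy: float, a_px: float, b_px: float
) -> np.ndarray:
    # pixel belongs to the ellipse iff its integer center satisfies <= 1
    x = np.arange(width, dtype=float)
    y = np.arange(height, dtype=float)
    xx, yy = np.meshgrid(x, y)
    return ((xx - cx) / a_px) ** 2 + ((yy - cy) / b_px) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> Tuple[SliceStack, GroundTruth]:
    """Rasterize a phantom stack and its ground truth.

    Returns the noisy (or exact, when ``noise_sd == 0``) 8-bit image stack
    and a :class:`GroundTruth` holding the noise-free masks, exact pixel
    counts, analytic ellipse areas and the designed key-section indices.
    Two calls with the same spec (including seed) are bit-identical.
    """
    spec.validate()
    w, h = spec.image_width_px, spec.image_height_px
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    sp = spec.pixel_spacing
    outer = spec.effective_outer_profile()
    inner = spec.inner_radius_profile
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(spec.seed)))

    images = []
    cort_masks, med_masks = [], []
    for i in range(spec.n_slices):
        m_out = _ellipse_mask(w, h, cx, cy, outer[i, 0] / sp, outer[i, 1] / sp)
        m_in = _ellipse_mask(w, h, cx, cy, inner[i, 0] / sp, inner[i, 1] / sp)
        cort = m_out & ~m_in
        img = np.full((h, w), float(spec.intensity_background))
        img[cort] = spec.intensity_cortical
        img[m_in] = spec.intensity_marrow
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        images.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
        cort_masks.append(cort)
        med_masks.append(m_in)

    med_mm2 = np.pi * inner[:, 0] * inner[:, 1]
    cort_mm2 = np.pi * (outer[:, 0] * outer[:, 1] - inner[:, 0] * inner[:, 1])
    gt = GroundTruth(
        cortical_masks=cort_masks,
        medullary_masks=med_masks,
        cortical_px=np.array([int(m.sum()) for m in cort_masks]),
        medullary_px=np.array([int(m.sum()) for m in med_masks]),
        cortical_mm2=cort_mm2,
        medullary_mm2=med_mm2,
        isthmus_slice_index=spec.isthmus_slice_index,
        trochanter_slice_index=spec.trochanter_slice_index,
        inner_profile_mm=inner.copy(),
        outer_profile_mm=outer,
    )
    stack = SliceStack(
        images=images,
        pixel_spacing=sp,
        slice_interval=spec.slice_interval,
        provenance=f"phantom(seed={spec.seed}, n_slices={spec.n_slices})",
    )
    return stack, gt


def trumpet_spec(
    n_slices: int = 50,
    isthmus_index: Optional[int] = None,
    trochanter_index: Optional[int] = None,
    proximal_inner_mm: float = 25.0,
    isthmus_inner_mm: float = 6.0,
    distal_inner_mm: float = 9.0,
    wall_proximal_mm: float = 4.0,
    wall_distal_mm: float = 9.0,
    ellipticity: float = 0.9,
    bump_mm: float = 6.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    **overrides,
) -> PhantomSpec:
    """Trumpet-shaped canal: wide proximally, narrowest at the isthmus,
    slightly widening distally; cortical wall thickens toward the shaft.

    Section indices default to fixed fractions of the stack (isthmus at 70%,
    trochanter at 16% of the proximal-to-distal extent).

    Inner x semi-axes follow two concave arcs meeting at the isthmus with
    nonzero slope on both sides (so the minimum is sharply resolvable after
    rasterization); y semi-axes are ``ellipticity`` times the x ones.
    """
    if isthmus_index is None:
        isthmus_index = min(n_slices - 1, max(1, round(0.7 * (n_slices - 1))))
    if trochanter_index is None:
        trochanter_index = min(isthmus_index - 1, max(0, round(0.16 * (n_slices - 1))))
        trochanter_index = max(0, trochanter_index)
    i = np.arange(n_slices, dtype=float)
    inner_x = np.empty(n_slices)
    up = i <= isthmus_index
    # proximal arc: wide and flat at the top, steepening into the isthmus
    t_up = i[up] / max(isthmus_index, 1)
    inner_x[up] = isthmus_inner_mm + (proximal_inner_mm - isthmus_inner_mm) * (
        1.0 - t_up**2
    )
    # distal arc: linear taper, nonzero slope everywhere
    down_span = max(n_slices - 1 - isthmus_index, 1)
    t_dn = (i[~up] - isthmus_index) / down_span
    inner_x[~up] = isthmus_inner_mm + (distal_inner_mm - isthmus_inner_mm) * t_dn
    wall = wall_proximal_mm + (wall_distal_mm - wall_proximal_mm) * i / max(n_slices - 1, 1)
    outer_x = inner_x + wall
    inner = np.column_stack([inner_x, ellipticity * inner_x])
    outer = np.column_stack([outer_x, ellipticity * outer_x])
    return PhantomSpec(
        n_slices=n_slices,
        outer_radius_profile=outer,
        inner_radius_profile=inner,
        isthmus_slice_index=isthmus_index,
        trochanter_slice_index=trochanter_index,
        trochanter_bump_amplitude=bump_mm,
        noise_sd=noise_sd,
        seed=seed,
        **overrides,
    )


def constant_spec(
    inner_mm: float = 25.0,
    outer_mm: float = 33.0,
    n_slices: int = 3,
    ellipticity: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    **overrides,
) -> PhantomSpec:
    """Constant circular (or elliptical) geometry on every slice."""
    inner = np.tile([inner_mm, ellipticity * inner_mm], (n_slices, 1))
    outer = np.tile([outer_mm, ellipticity * outer_mm], (n_slices, 1))
    return PhantomSpec(
        n_slices=n_slices,
        outer_radius_profile=outer,
        inner_radius_profile=inner,
        isthmus_slice_index=0,
        trochanter_slice_index=0,
        noise_sd=noise_sd,
        seed=seed,
        **overrides,
    )


def write_phantom(stack: SliceStack, gt: GroundTruth, outdir: str, seed: Optional[int] = None) -> None:
    """Write slices as zero-padded 8-bit PNGs plus a JSON manifest."""
    import imageio.v3 as iio

    os.makedirs(outdir, exist_ok=True)
    for i, img in enumerate(stack.images):
        iio.imwrite(os.path.join(outdir, f"slice_{i:04d}.png"), img)
    manifest = {
        "pixel_spacing": stack.pixel_spacing,
        "slice_interval": stack.slice_interval,
        "n_slices": stack.n_slices,
        "provenance": stack.provenance,
        "seed": seed,
        "ground_truth": {
            "isthmus_slice_index": int(gt.isthmus_slice_index),
            "trochanter_slice_index": int(gt.trochanter_slice_index),
            "medullary_px": gt.medullary_px.tolist(),
            "cortical_px": gt.cortical_px.tolist(),
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
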