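"""Key cross-section location and morphometric parameters of the canal.

Locates the trochanteric reference section (most prominent medial-lateral
extent within a proximal window), the sections 20 mm above/below it, and the
isthmus (global minimum of the medullary area profile), then computes the
classical diameter/length/ratio parameters (CFI, MCFI, DCFI, CI, IH/LH) and
the area-based per-slice parameters (s_c, s_m, q1, q2) with the two growth
rates r1, r2, plus the canal-shape classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .imaging import RegionMasks
from .montecarlo import MCAreaResult

__all__ = [
    "KeySections",
    "MorphometryReport",
    "find_isthmus",
    "find_trochanter_section",
    "offset_section",
    "section_diameters",
    "compute_lengths",
    "flare_indices",
    "growth_rates",
    "classify_canal",
    "per_slice_table",
    "analyze_stack",
]

#: CFI bands of the canal-shape classification
CHIMNEY_MAX = 3.0
NORMAL_MAX = 4.7
CHAMPAGNE_MAX = 6.5


@dataclass
class KeySections:
    """Slice indices of the four marked cross sections (proximal-first order)."""

    c_m0: int
    c_m0_plus20: int  # 20 mm above (proximal of) c_m0
    c_m0_minus20: int  # 20 mm below (distal of) c_m0
    c_m1: int  # isthmus

    def validate(self) -> None:
        if not self.c_m0_plus20 < self.c_m0 < self.c_m0_minus20 < self.c_m1:
            raise ValueError(
                "expected c_m0_plus20 < c_m0 < c_m0_minus20 < c_m1, got "
                f"{self.c_m0_plus20}, {self.c_m0}, {self.c_m0_minus20}, {self.c_m1}"
            )


@dataclass
class MorphometryReport:
    """All computed morphometric parameters of one stack."""

    key_sections: KeySections
    t_plus20: float  # medullary inner diameter 20 mm above c_m0 (mm)
    t_minus20: float
    t_0: float
    t_mi: float  # inner diameter at isthmus (mm)
    t_mo: float  # outer diameter at isthmus (mm)
    ih: float  # isthmus height (mm)
    lh: float  # femur length (mm)
    ih_over_lh: float
    cfi: float
    mcfi: float
    dcfi: float
    ci: float
    r_1: Optional[float]
    r_2: Optional[float]
    canal_class: str
    per_slice: pd.DataFrame  # slice_index, s_c, s_m, s, q_1, q_2, t_c
    s_m_plus20: float
    s_m_minus20: float
    s_m1: float
    rounded: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "key_sections": {
                "c_m0": self.key_sections.c_m0,
                "c_m0_plus20": self.key_sections.c_m0_plus20,
                "c_m0_minus20": self.key_sections.c_m0_minus20,
                "c_m1": self.key_sections.c_m1,
            },
            "diameters_mm": {
                "t_plus20": self.t_plus20,
                "t_minus20": self.t_minus20,
                "t_0": self.t_0,
                "t_mi": self.t_mi,
                "t_mo": self.t_mo,
            },
            "lengths_mm": {"ih": self.ih, "lh": self.lh},
            "ratios": {
                "ih_over_lh": self.ih_over_lh,
                "cfi": self.cfi,
                "mcfi": self.mcfi,
                "dcfi": self.dcfi,
                "ci": self.ci,
                "r_1": self.r_1,
                "r_2": self.r_2,
            },
            "areas_px": {
                "s_m_plus20": self.s_m_plus20,
                "s_m_minus20": self.s_m_minus20,
                "s_m1": self.s_m1,
            },
            "canal_class": self.canal_class,
            "rounded": self.rounded,
        }


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def round_reported(value: float, decimals: int) -> float:
    """Round half away from zero, matching hand-reported precision."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def find_isthmus(s_m: Sequence[float], indices: Optional[Sequence[int]] = None) -> int:
    """Slice index of the global minimum of the medullary area profile.

    ``indices`` maps positions to slice indices (accepted slices only);
    ties resolve to the most proximal index.
    """
    s_m = np.asarray(s_m, dtype=float)
    if s_m.size == 0:
        raise ValueError("no accepted slices: isthmus undefined")
    pos = int(np.argmin(s_m))  # argmin takes the first minimum: most proximal
    return int(indices[pos]) if indices is not None else pos


def _x_extent_px(mask: np.ndarray) -> int:
    """Medial-lateral extent (pixels spanned) of a mask through its centroid row."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask")
    row = _round_half_up(float(ys.mean()))
    cols = np.nonzero(mask[row])[0]
    if cols.size == 0:
        raise ValueError("mask empty on centroid row")
    return int(cols.max() - cols.min() + 1)


def find_trochanter_section(
    masks: Sequence[Optional[RegionMasks]],
    window: Tuple[int, int],
    override: Optional[int] = None,
) -> int:
    """Slice of maximal medial-lateral extent of the overall region.

    ``window`` is a ``[start, stop)`` range of slice indices to search
    (the prominence is a proximal feature; searching the whole stack would
    pick up the flaring proximal metaphysis instead). A manual ``override``
    index takes precedence verbatim. Ties resolve to the most proximal slice.
    """
    if override is not None:
        return int(override)
    start, stop = window
    best_idx, best_ext = None, -1
    for m in masks:
        if m is None or not (start <= m.slice_index < stop):
            continue
        ext = _x_extent_px(m.overall)
        if ext > best_ext:
            best_idx, best_ext = m.slice_index, ext
    if best_idx is None:
        raise ValueError(f"no accepted slices in search window [{start}, {stop})")
    return best_idx


def offset_section(
    c_m0: int,
    offset_mm: float,
    slice_interval: float,
    direction: str,
    n_slices: Optional[int] = None,
) -> int:
    """Index of the section ``offset_mm`` proximal or distal of ``c_m0``.

    Proximal means a smaller index. The offset in slices is
    ``round(offset_mm / slice_interval)`` (half rounds up).
    """
    k = _round_half_up(offset_mm / slice_interval)
    if direction == "proximal":
        idx = c_m0 - k
    elif direction == "distal":
        idx = c_m0 + k
    else:
        raise ValueError("direction must be 'proximal' or 'distal'")
    if idx < 0 or (n_slices is not None and idx >= n_slices):
        raise ValueError(
            f"offset section {idx} out of range [0, {n_slices}) "
            f"(c_m0={c_m0}, offset={offset_mm} mm, interval={slice_interval} mm)"
        )
    return idx


def section_diameters(
    masks: RegionMasks, pixel_spacing: float
) -> Tuple[float, float, float]:
    """(inner, outer, cortical thickness) in mm for one slice.

    Diameters are medial-lateral (x-axis) extents through the respective
    mask's centroid row; thickness is ``(outer - inner) / 2``.
    """
    if not masks.medullary.any():
        raise ValueError(f"slice {masks.slice_index}: empty medullary mask")
    inner = _x_extent_px(masks.medullary) * pixel_spacing
    outer = _x_extent_px(masks.overall) * pixel_spacing
    return inner, outer, (outer - inner) / 2.0


def compute_lengths(
    key: KeySections,
    n_slices: int,
    slice_interval: float,
    lh_mm: Optional[float] = None,
) -> Tuple[float, float]:
    """(IH, LH) in mm.

    IH is the vertical distance between the trochanteric section and the
    isthmus. LH defaults to the full stack extent; for a cropped stack the
    true femur length must be supplied via ``lh_mm``.
    """
    ih = abs(key.c_m1 - key.c_m0) * slice_interval
    lh = lh_mm if lh_mm is not None else (n_slices - 1) * slice_interval
    return ih, lh


def flare_indices(
    t_plus20: float, t_minus20: float, t_mi: float, t_mo: float
) -> Dict[str, float]:
    """Canal flare indices and cortical index from the four diameters."""
    return {
        "cfi": t_plus20 / t_mi,
        "mcfi": t_plus20 / t_minus20,
        "dcfi": t_minus20 / t_mi,
        "ci": (t_mo - t_mi) / t_mo,
    }


def growth_rates(
    s_m_plus20: float, s_m_minus20: float, s_m1: float
) -> Tuple[Optional[float], Optional[float]]:
    """Medullary growth rates r1 (trochanteric) and r2 (upper femur).

    r1 = (s_m0+20 - s_m0-20) / s_m0-20;  r2 = (s_m0+20 - s_m1) / s_m1.
    A zero denominator makes the corresponding rate undefined (None).
    """
    r1 = (s_m_plus20 - s_m_minus20) / s_m_minus20 if s_m_minus20 != 0 else None
    r2 = (s_m_plus20 - s_m1) / s_m1 if s_m1 != 0 else None
    return r1, r2


def classify_canal(cfi: float) -> str:
    """Canal shape from CFI: chimney < 3.0 <= normal < 4.7 <= champagne < 6.5."""
    if not cfi > 0:
        raise ValueError("cfi must be positive")
    if cfi < CHIMNEY_MAX:
        return "chimney"
    if cfi < NORMAL_MAX:
        return "normal"
    if cfi < CHAMPAGNE_MAX:
        return "champagne"
    return "unclassified"


def per_slice_table(
    results: Sequence[MCAreaResult],
    masks: Optional[Sequence[Optional[RegionMasks]]] = None,
    pixel_spacing: Optional[float] = None,
) -> pd.DataFrame:
    """Per-slice table of s_c, s_m, s, q_1, q_2 (and T_c when masks given)."""
    rows = []
    mask_by_index = {}
    if masks is not None:
        mask_by_index = {m.slice_index: m for m in masks if m is not None}
    for r in results:
        s = r.s_c + r.s_m
        q1 = r.s_m / s if s > 0 else np.nan
        q2 = r.s_m / r.s_c if r.s_c > 0 else np.nan
        t_c = np.nan
        m = mask_by_index.get(r.slice_index)
        if m is not None and pixel_spacing is not None and m.medullary.any():
            t_c = section_diameters(m, pixel_spacing)[2]
        rows.append(
            {
                "slice_index": r.slice_index,
                "s_c": r.s_c,
                "s_m": r.s_m,
                "s": s,
                "q_1": q1,
                "q_2": q2,
                "t_c": t_c,
            }
        )
    return pd.DataFrame(rows)


def analyze_stack(
    masks: Sequence[Optional[RegionMasks]],
    results: Sequence[MCAreaResult],
    slice_interval: float,
    pixel_spacing: float,
    n_slices: Optional[int] = None,
    trochanter_override: Optional[int] = None,
    trochanter_window: Optional[Tuple[int, int]] = None,
    lh_mm: Optional[float] = None,
    offset_mm: float = 20.0,
) -> MorphometryReport:
    """Full morphometric analysis of one stack of masks + area estimates."""
    if n_slices is None:
        n_slices = max(r.slice_index for r in results) + 1
    if trochanter_window is None:
        # proximal band: skip the femoral-head slices, stop above mid-shaft
        trochanter_window = (max(1, n_slices // 10), max(2, n_slices // 3))

    accepted = [r.slice_index for r in results]
    s_m = [r.s_m for r in results]
    by_index = {r.slice_index: r for r in results}
    mask_by_index = {m.slice_index: m for m in masks if m is not None}

    c_m1 = find_isthmus(s_m, accepted)
    c_m0 = find_trochanter_section(masks, trochanter_window, trochanter_override)
    c_plus = offset_section(c_m0, offset_mm, slice_interval, "proximal", n_slices)
    c_minus = offset_section(c_m0, offset_mm, slice_interval, "distal", n_slices)
    key = KeySections(c_m0=c_m0, c_m0_plus20=c_plus, c_m0_minus20=c_minus, c_m1=c_m1)
    key.validate()

    def _inner(idx: int) -> float:
        return section_diameters(mask_by_index[idx], pixel_spacing)[0]

    t_plus20 = _inner(c_plus)
    t_minus20 = _inner(c_minus)
    t_0 = _inner(c_m0)
    t_mi, t_mo, _ = section_diameters(mask_by_index[c_m1], pixel_spacing)

    ih, lh = compute_lengths(key, n_slices, slice_interval, lh_mm)
    flare = flare_indices(t_plus20, t_minus20, t_mi, t_mo)
    s_m_plus20 = by_index[c_plus].s_m
    s_m_minus20 = by_index[c_minus].s_m
    s_m1 = by_index[c_m1].s_m
    r_1, r_2 = growth_rates(s_m_plus20, s_m_minus20, s_m1)

    table = per_slice_table(results, masks, pixel_spacing)
    rounded = {
        "t_plus20": round_reported(t_plus20, 2),
        "t_minus20": round_reported(t_minus20, 2),
        "t_0": round_reported(t_0, 2),
        "t_mi": round_reported(t_mi, 2),
        "t_mo": round_reported(t_mo, 2),
        "ih": round_reported(ih, 2),
        "lh": round_reported(lh, 2),
        "ih_over_lh": round_reported(ih / lh, 3),
        "cfi": round_reported(flare["cfi"], 2),
        "mcfi": round_reported(flare["mcfi"], 2),
        "dcfi": round_reported(flare["dcfi"], 2),
        "ci": round_reported(flare["ci"], 2),
    }
    if r_1 is not None:
        rounded["r_1"] = round_reported(r_1, 3)
    if r_2 is not None:
        rounded["r_2"] = round_reported(r_2, 2)

    return MorphometryReport(
        key_sections=key,
        t_plus20=t_plus20,
        t_minus20=t_minus20,
        t_0=t_0,
        t_mi=t_mi,
        t_mo=t_mo,
        ih=ih,
        lh=lh,
        ih_over_lh=ih / lh,
        cfi=flare["cfi"],
        mcfi=flare["mcfi"],
        dcfi=flare["dcfi"],
        ci=flare["ci"],
        r_1=r_1,
        r_2=r_2,
        canal_class=classify_canal(flare["cfi"]),
        per_slice=table,
        s_m_plus20=s_m_plus20,
        s_m_minus20=s_m_minus20,
        s_m1=s_m1,
        rounded=rounded,
    )
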