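"""Readers and writers: PNG/TIFF slice directories, optional DICOM series,
mask directories, and the per-slice results CSV."""

from __future__ import annotations

import csv
import json
import os
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .imaging import RegionMasks, SliceStack
from .montecarlo import MCAreaResult, TraversalResult

__all__ = [
    "read_image_dir",
    "read_dicom_series",
    "write_masks",
    "read_masks",
    "write_mc_csv",
    "read_mc_csv",
]

_IMAGE_EXTS = (".png", ".tif", ".tiff")

MC_CSV_COLUMNS = [
    "slice_index",
    "n",
    "n1",
    "n2",
    "alpha_c",
    "alpha_m",
    "s_c",
    "s_m",
    "alpha_ct",
    "alpha_mt",
]


def _read_sidecar(path: str) -> dict:
    for name in ("manifest.json", "meta.json"):
        p = os.path.join(path, name)
        if os.path.exists(p):
            with open(p) as fh:
                return json.load(fh)
    raise FileNotFoundError(
        f"no manifest.json/meta.json sidecar with pixel_spacing/slice_interval in {path}"
    )


def read_image_dir(path: str) -> SliceStack:
    """Read an ordered PNG/TIFF directory with a JSON spacing sidecar.

    Files are ordered lexicographically (zero-padded names expected); the
    sidecar must provide ``pixel_spacing`` and ``slice_interval`` in mm.
    """
    import imageio.v3 as iio

    meta = _read_sidecar(path)
    files = sorted(
        f for f in os.listdir(path) if f.lower().endswith(_IMAGE_EXTS)
    )
    if not files:
        raise FileNotFoundError(f"no slice images found in {path}")
    images = [np.asarray(iio.imread(os.path.join(path, f))) for f in files]
    images = [img[..., 0] if img.ndim == 3 else img for img in images]
    return SliceStack(
        images=images,
        pixel_spacing=float(meta["pixel_spacing"]),
        slice_interval=float(meta["slice_interval"]),
        provenance=f"image dir {path}",
    )


def _window_level_8bit(img: np.ndarray) -> np.ndarray:
    """Window-level >8-bit data to the 8-bit scale the threshold expects."""
    img = img.astype(float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.clip(np.rint((img - lo) / (hi - lo) * 255.0), 0, 255).astype(np.uint8)


def read_dicom_series(path: str) -> SliceStack:
    """Read a DICOM series (requires the optional ``pydicom`` dependency).

    Slices are ordered by InstanceNumber; PixelSpacing and
    SpacingBetweenSlices (falling back to SliceThickness) populate the
    spatial metadata. Pixel data beyond 8 bits is window-levelled to 8-bit.
    """
    try:
        import pydicom
    except ImportError as err:  # pragma: no cover - environment dependent
        raise ImportError(
            "DICOM input requires pydicom; install femorph[dicom]"
        ) from err
    files = sorted(
        os.path.join(path, f) for f in os.listdir(path) if f.lower().endswith(".dcm")
    )
    if not files:
        raise FileNotFoundError(f"no .dcm files in {path}")
    datasets = sorted(
        (pydicom.dcmread(f) for f in files),
        key=lambda ds: int(getattr(ds, "InstanceNumber", 0)),
    )
    first = datasets[0]
    spacing = float(first.PixelSpacing[0])
    interval = float(
        getattr(first, "SpacingBetweenSlices", getattr(first, "SliceThickness", 1.0))
    )
    images = []
    for ds in datasets:
        arr = ds.pixel_array
        images.append(arr if arr.dtype == np.uint8 else _window_level_8bit(arr))
    return SliceStack(
        images=images,
        pixel_spacing=spacing,
        slice_interval=interval,
        provenance=f"dicom series {path}",
    )


def write_masks(
    masks: Sequence[Optional[RegionMasks]],
    flags: Sequence[Tuple[int, str]],
    outdir: str,
    pixel_spacing: float,
    slice_interval: float,
) -> None:
    """Write per-slice mask PNGs (0/255), a flags CSV and a meta sidecar."""
    import imageio.v3 as iio

    os.makedirs(outdir, exist_ok=True)
    for m in masks:
        if m is None:
            continue
        for name, arr in (
            ("overall", m.overall),
            ("cortical", m.cortical),
            ("medullary", m.medullary),
        ):
            iio.imwrite(
                os.path.join(outdir, f"mask_{m.slice_index:04d}_{name}.png"),
                (arr.astype(np.uint8) * 255),
            )
    with open(os.path.join(outdir, "flags.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice_index", "flag"])
        for idx, flag in flags:
            writer.writerow([idx, flag])
    with open(os.path.join(outdir, "meta.json"), "w") as fh:
        json.dump(
            {"pixel_spacing": pixel_spacing, "slice_interval": slice_interval}, fh
        )


def read_masks(path: str):
    """Read a mask directory written by :func:`write_masks`.

    Returns ``(masks, flags, meta)`` with masks sorted by slice index.
    """
    import imageio.v3 as iio

    meta = _read_sidecar(path)
    indices = sorted(
        {
            int(f.split("_")[1])
            for f in os.listdir(path)
            if f.startswith("mask_") and f.endswith("_overall.png")
        }
    )
    masks = []
    for i in indices:
        parts = {}
        for name in ("overall", "cortical", "medullary"):
            arr = np.asarray(iio.imread(os.path.join(path, f"mask_{i:04d}_{name}.png")))
            parts[name] = arr > 127
        masks.append(RegionMasks(slice_index=i, **parts))
    flags = []
    flags_path = os.path.join(path, "flags.csv")
    if os.path.exists(flags_path):
        with open(flags_path, newline="") as fh:
            for row in csv.DictReader(fh):
                flags.append((int(row["slice_index"]), row["flag"]))
    return masks, flags, meta


def write_mc_csv(
    results: Sequence[MCAreaResult],
    traversals: Sequence[TraversalResult],
    path: str,
) -> None:
    """Write the per-slice results CSV (fixed column set)."""
    if len(results) != len(traversals):
        raise ValueError("results and traversals must align")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MC_CSV_COLUMNS)
        for r, t in zip(results, traversals):
            writer.writerow(
                [
                    r.slice_index,
                    r.n,
                    r.n1,
                    r.n2,
                    repr(r.alpha_c),
                    repr(r.alpha_m),
                    repr(r.s_c),
                    repr(r.s_m),
                    repr(t.alpha_ct),
                    repr(t.alpha_mt),
                ]
            )


def read_mc_csv(path: str):
    """Read a results CSV back into plain dict rows (floats/ints parsed)."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(
                {
                    "slice_index": int(row["slice_index"]),
                    "n": int(row["n"]),
                    "n1": int(row["n1"]),
                    "n2": int(row["n2"]),
                    "alpha_c": float(row["alpha_c"]),
                    "alpha_m": float(row["alpha_m"]),
                    "s_c": float(row["s_c"]),
                    "s_m": float(row["s_m"]),
                    "alpha_ct": float(row["alpha_ct"]),
                    "alpha_mt": float(row["alpha_mt"]),
                }
            )
    return rows
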