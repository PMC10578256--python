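"""Seed-grown 3-D segmentation and per-muscle volume / map statistics.

The extra-ocular muscles stand out on the water image against the bright
intra-orbital fat, so a seeded region grow with an intensity band
suffices: voxels 26-connected to a seed whose water intensity lies in
the band join that seed's label.  Volumes are voxel counts times the
voxel volume; map statistics are arithmetic means over (optionally
eroded) label masks.
"""

from __future__ import annotations

import warnings
from collections import deque
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "region_grow",
    "erode_inplane",
    "muscle_volume",
    "roi_mean_map",
    "dice",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _band_from_seed(
    image: np.ndarray, seed: tuple[int, int, int], k_sigma: float
) -> tuple[float, float]:
    """Intensity band [mu - k sigma, inf) from a 3^3 seed neighbourhood."""
    sl = tuple(
        slice(max(0, c - 1), min(n, c + 2))
        for c, n in zip(seed, image.shape)
    )
    patch = image[sl]
    return float(patch.mean() - k_sigma * patch.std()), np.inf


def region_grow(
    water_image: np.ndarray,
    seeds: Mapping[int, Sequence[tuple[int, int, int]]],
    intensity_band: tuple[float, float] | None = None,
    max_voxels: int = 200_000,
    band_k_sigma: float = 2.0,
    largest_component_only: bool = False,
) -> np.ndarray:
    """26-connected flood fill from seeds over an intensity band.

    ``seeds`` maps each requested label to one or more voxel-index
    triples.  When ``intensity_band`` is None, a per-label band
    ``[mu_seed - k sigma_seed, inf)`` is estimated from the seed's 3x3x3
    neighbourhood.  Growth stops (with a warning) once a label reaches
    ``max_voxels``.  Labels are grown independently; a voxel claimed by
    an earlier label is not revisited, so seed groups must be disjoint
    in practice.
    """
    img = np.asarray(water_image, dtype=float)
    labels = np.zeros(img.shape, dtype=np.int16)
    if not seeds:
        raise ValueError("at least one seed per requested label is required")

    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for label, points in seeds.items():
        if label <= 0:
            raise ValueError("labels must be positive")
        pts = [tuple(int(c) for c in p) for p in points]
        for p in pts:
            if any(not 0 <= c < n for c, n in zip(p, img.shape)):
                raise ValueError(f"seed {p} outside the image grid")
        lo, hi = (
            intensity_band
            if intensity_band is not None
            else _band_from_seed(img, pts[0], band_k_sigma)
        )
        for p in pts:
            if not lo <= img[p] <= hi:
                raise ValueError(
                    f"seed {p} intensity {img[p]:.4g} outside band "
                    f"[{lo:.4g}, {hi:.4g}]"
                )
        queue = deque(pts)
        count = 0
        for p in pts:
            if labels[p] == 0:
                labels[p] = label
                count += 1
        truncated = False
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                q = (x + dx, y + dy, z + dz)
                if any(not 0 <= c < n for c, n in zip(q, img.shape)):
                    continue
                if labels[q] != 0 or not lo <= img[q] <= hi:
                    continue
                if count >= max_voxels:
                    truncated = True
                    queue.clear()
                    break
                labels[q] = label
                count += 1
                queue.append(q)
        if truncated:
            warnings.warn(
                f"label {label} reached max_voxels={max_voxels}; "
                "region truncated",
                stacklevel=2,
            )
        if largest_component_only:
            mask = labels == label
            comps, n_comp = ndimage.label(mask, structure=_STRUCT26)
            if n_comp > 1:
                sizes = ndimage.sum_labels(mask, comps, range(1, n_comp + 1))
                keep = 1 + int(np.argmax(sizes))
                labels[mask & (comps != keep)] = 0
    return labels


def erode_inplane(labels: np.ndarray, n: int = 1, axis: int = 2) -> np.ndarray:
    """Per-slice morphological erosion of every label by ``n`` voxels.

    Erosion uses the full 3x3 in-plane structuring element, applied
    independently on each slice along ``axis``; thin labels may vanish
    entirely (legal, left empty).  ``n = 0`` is the identity.
    """
    if n < 0:
        raise ValueError("erosion size must be >= 0")
    labels = np.asarray(labels)
    if n == 0:
        return labels.copy()
    out = np.zeros_like(labels)
    struct = np.ones((3, 3), dtype=bool)
    for lab in (int(v) for v in np.unique(labels) if v != 0):
        mask = labels == lab
        eroded = np.zeros_like(mask)
        for k in range(labels.shape[axis]):
            sl = [slice(None)] * 3
            sl[axis] = k
            sl = tuple(sl)
            plane = mask[sl]
            if plane.any():
                eroded[sl] = ndimage.binary_erosion(
                    plane, structure=struct, iterations=n
                )
        out[eroded] = lab
    return out


def muscle_volume(
    labels: np.ndarray,
    voxel_size_mm: float | Sequence[float] = 0.8,
) -> dict[int, float]:
    """Label volumes in mm^3: voxel count times voxel volume."""
    vs = np.atleast_1d(np.asarray(voxel_size_mm, dtype=float))
    voxel_mm3 = float(np.prod(vs)) if vs.size > 1 else float(vs[0] ** 3)
    labels = np.asarray(labels)
    out: dict[int, float] = {}
    for lab in (int(v) for v in np.unique(labels) if v != 0):
        out[lab] = float((labels == lab).sum() * voxel_mm3)
    return out


def roi_mean_map(
    value_map: np.ndarray,
    labels: np.ndarray,
) -> dict[int, dict[str, float]]:
    """Arithmetic mean of a map over each label.

    NaN voxels (undefined fits) are excluded and counted; a label whose
    voxels are all undefined gets a NaN mean and is flagged.
    """
    value_map = np.asarray(value_map, dtype=float)
    labels = np.asarray(labels)
    if value_map.shape != labels.shape:
        raise ValueError("map not congruent with labels")
    out: dict[int, dict[str, float]] = {}
    for lab in (int(v) for v in np.unique(labels) if v != 0):
        vals = value_map[labels == lab]
        n_undef = int(np.isnan(vals).sum())
        valid = vals[~np.isnan(vals)]
        out[lab] = {
            "mean": float(valid.mean()) if valid.size else np.nan,
            "n_voxels": int(vals.size),
            "n_undefined": n_undef,
        }
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (reproducibility tooling)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / float(denom)
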