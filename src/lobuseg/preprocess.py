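"""Contrast-enhancement filtering, binarization and core/periphery separation.

The central operator is a Kuwahara-type filter adapted to emphasize the thin,
dark mesenchymal septa that separate adipose subunits: every voxel is
replaced by the average, over the eight octant boxes touching it, of the
per-box mean-to-variance ratio.  Homogeneous regions (low variance) come out
bright; septa and their borders (high local variance) come out dark, which
makes a single global threshold sufficient to isolate subunit interiors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters as _skfilters
from skimage import morphology as _skmorph

from .types import (
    BinaryMask,
    ConsistencyError,
    DegenerateHistogramError,
    DimensionalityError,
    EmptySLAError,
    ImageVolume,
    ParameterError,
)

__all__ = [
    "PreprocessParams",
    "kuwahara_ratio_filter",
    "binarize",
    "otsu_threshold",
    "cleanup",
    "tissue_foreground",
    "separate_sla",
]


@dataclass
class PreprocessParams:
    """Parameters for filtering, binarization and the core/periphery split.

    box_radius
        Half-extent (voxels, per axis) of the octant boxes of the Kuwahara
        filter; each box spans ``radius + 1`` voxels per axis including the
        center voxel.
    variance_epsilon
        Additive regularizer (intensity squared) for the mean/variance ratio;
        bounds the filter response on perfectly homogeneous boxes.
    binarize_threshold
        Threshold applied to the *filtered* image, or ``"otsu"``.
    foreground_threshold
        Threshold applied to the *raw* image to delineate tissue from the
        clearing-solution background: a number, ``"otsu"``, or
        ``"multiotsu"`` (default) — the lowest cut of a three-class Otsu,
        which keeps the dim mesenchymal stroma with the tissue instead of
        grouping it with the dark background.
    foreground_closing_radius
        Ball radius (voxels) of the closing that absorbs thin dark septa into
        the tissue foreground before hole filling; should exceed half the
        septum width in voxels.
    kuwahara_mode
        ``"ratio"`` (average of per-box mean/variance ratios) or ``"classic"``
        (mean of the minimum-variance box).
    closing_radius / min_island_voxels
        Morphological cleanup of the binarized filtered image.
    sla_contrast_threshold / sla_margin_voxels / sla_pocket_ratio
        Controls of the core/periphery separation heuristic (see
        :func:`separate_sla`).
    """

    box_radius: tuple[int, int, int] = (1, 1, 1)
    variance_epsilon: float = 1.0
    binarize_threshold: float | str = "otsu"
    foreground_threshold: float | str = "otsu"
    foreground_closing_radius: int = 2
    kuwahara_mode: str = "ratio"
    closing_radius: int = 0
    min_island_voxels: int = 30
    sla_contrast_threshold: float | str = "otsu"
    sla_margin_voxels: int = 3
    sla_pocket_ratio: float = 0.5

    def __post_init__(self):
        self.box_radius = tuple(int(r) for r in np.atleast_1d(self.box_radius).ravel())
        if len(self.box_radius) == 1:
            self.box_radius = self.box_radius * 3
        if len(self.box_radius) != 3 or any(r < 1 for r in self.box_radius):
            raise ParameterError(f"box_radius must be >= 1 per axis, got {self.box_radius}")
        if self.variance_epsilon <= 0:
            raise ParameterError("variance_epsilon must be > 0")
        if self.min_island_voxels < 0:
            raise ParameterError("min_island_voxels must be >= 0")
        if self.kuwahara_mode not in ("ratio", "classic"):
            raise ParameterError(f"unknown kuwahara_mode {self.kuwahara_mode!r}")


def _integral(arr: np.ndarray) -> np.ndarray:
    """Zero-padded 3D integral image: I[a,b,c] = sum(arr[:a,:b,:c])."""
    out = np.zeros(tuple(s + 1 for s in arr.shape), dtype=np.float64)
    out[1:, 1:, 1:] = arr.cumsum(0).cumsum(1).cumsum(2)
    return out


def _box_sum(integral: np.ndarray, lo_idx, hi_idx) -> np.ndarray:
    """Sum over the inclusive box [lo, hi] per voxel from an integral image.

    ``lo_idx``/``hi_idx`` are per-axis 1D index arrays (already clipped);
    the box for voxel (i, j, k) is the outer product of the axis ranges.
    """
    (x0, y0, z0), (x1, y1, z1) = lo_idx, hi_idx
    a, b, c = x1 + 1, y1 + 1, z1 + 1
    s = integral[np.ix_(a, b, c)]
    s -= integral[np.ix_(x0, b, c)]
    s -= integral[np.ix_(a, y0, c)]
    s -= integral[np.ix_(a, b, z0)]
    s += integral[np.ix_(x0, y0, c)]
    s += integral[np.ix_(x0, b, z0)]
    s += integral[np.ix_(a, y0, z0)]
    s -= integral[np.ix_(x0, y0, z0)]
    return s


def kuwahara_ratio_filter(vol: ImageVolume, params: PreprocessParams) -> ImageVolume:
    """Edge-preserving contrast filter based on per-box mean/variance statistics.

    For every voxel the eight corner-anchored octant boxes of per-axis extent
    ``box_radius`` (the 3D analogue of the four 2D Kuwahara quadrants) are
    evaluated; each box yields a mean ``m`` and population variance ``v``.
    In ``"ratio"`` mode the output is ``mean_b(m_b / (v_b + eps))``; in
    ``"classic"`` mode it is the mean of the minimum-variance box.  Boxes
    clipped at the volume border use only in-bounds voxels.
    """
    r = params.box_radius
    if all(s < rr + 1 for s, rr in zip(vol.shape, r)):
        raise DimensionalityError(
            f"volume shape {vol.shape} smaller than one Kuwahara box in every "
            f"axis (radius {r})"
        )
    data = vol.data.astype(np.float64)
    i1 = _integral(data)
    i2 = _integral(data * data)
    axes_idx = [np.arange(n) for n in vol.shape]

    acc = np.zeros(vol.shape, dtype=np.float64)
    best_var = np.full(vol.shape, np.inf) if params.kuwahara_mode == "classic" else None
    best_mean = np.zeros(vol.shape) if params.kuwahara_mode == "classic" else None

    for sx in (-1, +1):
        for sy in (-1, +1):
            for sz in (-1, +1):
                lo, hi, counts = [], [], []
                for ax, sign, rr in zip(range(3), (sx, sy, sz), r):
                    n = vol.shape[ax]
                    idx = axes_idx[ax]
                    if sign < 0:
                        l = np.clip(idx - rr, 0, n - 1)
                        h = idx
                    else:
                        l = idx
                        h = np.clip(idx + rr, 0, n - 1)
                    lo.append(l)
                    hi.append(h)
                    counts.append((h - l + 1).astype(np.float64))
                n_box = counts[0][:, None, None] * counts[1][None, :, None] * counts[2][None, None, :]
                s1 = _box_sum(i1, lo, hi)
                s2 = _box_sum(i2, lo, hi)
                m = s1 / n_box
                v = np.maximum(s2 / n_box - m * m, 0.0)
                if params.kuwahara_mode == "classic":
                    take = v < best_var
                    best_var[take] = v[take]
                    best_mean[take] = m[take]
                else:
                    acc += m / (v + params.variance_epsilon)

    if params.kuwahara_mode == "classic":
        out = best_mean
    else:
        out = acc / 8.0
    return ImageVolume(data=out, spacing=vol.spacing, origin=vol.origin)


def otsu_threshold(data: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold from a fixed-width histogram over the data range."""
    data = np.asarray(data, dtype=np.float64).ravel()
    if data.size == 0 or np.ptp(data) == 0:
        raise DegenerateHistogramError(
            "cannot compute an Otsu threshold on a constant (or empty) volume"
        )
    counts, edges = np.histogram(data, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(_skfilters.threshold_otsu(hist=(counts, centers)))


def _resolve_threshold(data: np.ndarray, threshold) -> float:
    if isinstance(threshold, str):
        if threshold == "otsu":
            return otsu_threshold(data)
        if threshold == "multiotsu":
            flat = np.asarray(data, dtype=np.float64).ravel()
            if flat.size == 0 or np.ptp(flat) == 0:
                raise DegenerateHistogramError(
                    "cannot compute a multi-Otsu threshold on a constant volume"
                )
            try:
                cuts = _skfilters.threshold_multiotsu(flat, classes=3, nbins=256)
            except ValueError as exc:
                raise DegenerateHistogramError(str(exc)) from exc
            return float(cuts[0])
        raise ParameterError(f"unknown threshold method {threshold!r}")
    return float(threshold)


def binarize(vol: ImageVolume, threshold) -> BinaryMask:
    """Threshold a volume: foreground where ``value > threshold``.

    ``threshold="otsu"`` derives the threshold from a 256-bin histogram over
    the intensity range; ``"multiotsu"`` takes the lowest cut of a
    three-class Otsu.  A constant volume has no histogram to split and raises
    :class:`DegenerateHistogramError`.
    """
    thr = _resolve_threshold(vol.data, threshold)
    return BinaryMask(
        data=vol.data > thr, spacing=vol.spacing, origin=vol.origin
    )


def cleanup(mask: BinaryMask, closing_radius: int, min_island_voxels: int) -> BinaryMask:
    """Morphological closing (ball, voxel units) then small-island removal.

    Islands are foreground 26-connected components with fewer than
    ``min_island_voxels`` voxels.  Anisotropy is deliberately ignored: the
    cleanup operates at the scale of one or two voxels.
    """
    data = mask.data
    if closing_radius >= 1:
        data = _skmorph.closing(data, _skmorph.ball(int(closing_radius))).astype(bool)
    if min_island_voxels > 1 and data.any():
        structure = ndimage.generate_binary_structure(3, 3)
        lab, n = ndimage.label(data, structure=structure)
        sizes = np.bincount(lab.ravel(), minlength=n + 1)
        small = sizes < int(min_island_voxels)
        small[0] = False
        data = data & ~small[lab]
    return BinaryMask(data=data, spacing=mask.spacing, origin=mask.origin)


def tissue_foreground(vol: ImageVolume, params: PreprocessParams) -> BinaryMask:
    """Tissue support: bright voxels, closed to absorb thin dark septa, holes
    filled.  Separates the specimen from the clearing-solution background."""
    bright = binarize(vol, params.foreground_threshold).data
    r = int(params.foreground_closing_radius)
    if r >= 1:
        bright = _skmorph.closing(bright, _skmorph.ball(r)).astype(bool)
    tissue = ndimage.binary_fill_holes(bright)
    return BinaryMask(data=tissue, spacing=vol.spacing, origin=vol.origin)


def _local_std(data: np.ndarray, box_radius) -> np.ndarray:
    """Per-voxel standard deviation over the centered box neighbourhood."""
    size = tuple(2 * r + 1 for r in box_radius)
    m = ndimage.uniform_filter(data, size=size, mode="nearest")
    m2 = ndimage.uniform_filter(data * data, size=size, mode="nearest")
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def _largest_component(mask: np.ndarray) -> np.ndarray:
    structure = ndimage.generate_binary_structure(3, 3)
    lab, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def separate_sla(
    vol: ImageVolume,
    params: PreprocessParams,
    exclusion: BinaryMask | None = None,
) -> tuple[BinaryMask, BinaryMask]:
    """Split tissue into the segmentable core (SLA) and the periphery.

    The core of a fat pad is septated — its local intensity contrast is
    structured — whereas the periphery is bright but unstructured.  The
    heuristic:

    1. tissue = hole-filled threshold of the raw volume (tissue vs background);
    2. a local-contrast map (box standard deviation) is thresholded inside the
       eroded tissue, yielding the septum-edge network;
    3. low-contrast pockets are labelled: large pockets (periphery bulk) are
       discarded, small pockets (lobule interiors) are kept with the network;
    4. the largest component is closed, hole-filled, dilated back by the
       erosion margin, clipped to tissue, and the exclusion mask removed.

    Returns disjoint ``(sla, periphery)`` masks.
    """
    if exclusion is not None and exclusion.shape != vol.shape:
        raise ConsistencyError(
            f"exclusion mask shape {exclusion.shape} != volume shape {vol.shape}"
        )
    data = vol.data.astype(np.float64)
    try:
        tissue = tissue_foreground(vol, params).data
    except DegenerateHistogramError as exc:
        raise EmptySLAError(f"uniform volume: {exc}") from exc

    margin = max(int(params.sla_margin_voxels), 1)
    interior = ndimage.binary_erosion(
        tissue, ndimage.generate_binary_structure(3, 1), iterations=margin
    )
    std_map = _local_std(data, params.box_radius)

    thr = params.sla_contrast_threshold
    if isinstance(thr, str):
        if thr != "otsu":
            raise ParameterError(f"unknown threshold method {thr!r}")
        inside = std_map[interior]
        if inside.size == 0 or np.ptp(inside) == 0:
            raise EmptySLAError("no contrast inside the tissue: cannot delineate a core")
        counts, edges = np.histogram(inside, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2.0
        thr = float(_skfilters.threshold_otsu(hist=(counts, centers)))
    high = (std_map > float(thr)) & interior
    if not high.any():
        raise EmptySLAError("no voxel passes the contrast threshold")

    # Pockets: low-contrast regions inside the tissue.  The periphery bulk is
    # by far the largest; lobule interiors are small and stay with the core.
    low = interior & ~high
    structure = ndimage.generate_binary_structure(3, 3)
    lab, n = ndimage.label(low, structure=structure)
    core_cand = high.copy()
    if n:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        big = sizes >= max(1, int(params.sla_pocket_ratio * sizes.max()))
        keep = ~big[lab] & low
        core_cand |= keep

    core_cand = _largest_component(core_cand)
    if not core_cand.any():
        raise EmptySLAError("contrast network vanished during cleanup")
    core_cand = ndimage.binary_closing(
        core_cand, ndimage.generate_binary_structure(3, 1), iterations=2
    )
    core_cand = ndimage.binary_fill_holes(core_cand)
    # one-voxel dilation recovers the immediate rind of the contrast network
    # without leaking far into the unstructured periphery
    core_cand = ndimage.binary_dilation(
        core_cand, ndimage.generate_binary_structure(3, 1)
    )
    sla = core_cand & tissue
    if exclusion is not None:
        sla &= ~exclusion.data
    if not sla.any():
        raise EmptySLAError("segmentable core is empty after applying the exclusion mask")
    periphery = tissue & ~sla
    if exclusion is not None:
        periphery &= ~exclusion.data
    return (
        BinaryMask(data=sla, spacing=vol.spacing, origin=vol.origin),
        BinaryMask(data=periphery, spacing=vol.spacing, origin=vol.origin),
    )
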