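"""Morphometrics of segmented label volumes and intensity-based density proxies.

Units: voxel spacing is in micrometres, subunit volumes are reported in mm³
(1 mm³ = 1e9 µm³), contact areas in mm² (1 mm² = 1e6 µm²).  Summary
statistics follow the conventional "mean ± SEM" reporting, with the SEM
computed from the sample (n - 1) standard deviation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import adjusted_rand_score

from .segmentation import SegmentationParams, pair_face_counts, segment_lobules
from .preprocess import PreprocessParams
from .types import (
    BinaryMask,
    ConsistencyError,
    ImageVolume,
    LabelVolume,
    ParameterError,
)

__all__ = [
    "SubunitRecord",
    "ContactEdge",
    "SummaryStats",
    "subunit_volumes",
    "contact_surfaces",
    "sla_ratio",
    "normalized_volumes",
    "summarize",
    "density_proxy_mean",
    "labelled_fraction",
    "parameter_sweep",
]

_UM3_PER_MM3 = 1e9
_UM2_PER_MM2 = 1e6


@dataclass(frozen=True)
class SubunitRecord:
    """Per-label morphometrics of one segmented subunit."""

    label: int
    voxel_count: int
    volume_mm3: float
    barycenter: tuple[float, float, float]  # physical µm coordinates


@dataclass(frozen=True)
class ContactEdge:
    """Shared interface between two labels (i < j).

    ``weight`` is the contact ratio: shared face count divided by the mean of
    the two labels' total surface face counts.
    """

    label_i: int
    label_j: int
    face_count: int
    area_mm2: float
    weight: float


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sem: float | None  # None for n = 1, where the SEM is undefined


def subunit_volumes(labels: LabelVolume) -> list[SubunitRecord]:
    """One record per positive label: voxel count, physical volume, barycenter.

    The barycenter is the unweighted mean of member-voxel physical centers.
    """
    present = labels.labels()
    if present.size == 0:
        raise ParameterError("label volume contains no positive label")
    data = labels.data
    voxvol = labels.voxel_volume_um3
    counts = ndimage.sum_labels(np.ones_like(data), data, index=present)
    coms = ndimage.center_of_mass(np.ones_like(data), data, index=present)
    records = []
    for lab, count, com in zip(present, counts, coms):
        bary = tuple(
            o + c * s for o, c, s in zip(labels.origin, com, labels.spacing)
        )
        records.append(
            SubunitRecord(
                label=int(lab),
                voxel_count=int(count),
                volume_mm3=float(count) * voxvol / _UM3_PER_MM3,
                barycenter=bary,
            )
        )
    return records


def _per_axis_face_counts(labels: np.ndarray):
    """Face counts between positive label pairs, split by face orientation."""
    padded = np.pad(np.asarray(labels, dtype=np.int64), 1, constant_values=0)
    per_axis: list[dict[tuple[int, int], int]] = []
    for axis in range(3):
        a = np.moveaxis(padded, axis, 0)[:-1].ravel()
        b = np.moveaxis(padded, axis, 0)[1:].ravel()
        diff = (a != b) & (a > 0) & (b > 0)
        lo = np.minimum(a[diff], b[diff])
        hi = np.maximum(a[diff], b[diff])
        pairs = np.stack([lo, hi], axis=1)
        uniq, c = np.unique(pairs, axis=0, return_counts=True)
        per_axis.append({(int(p), int(q)): int(n) for (p, q), n in zip(uniq, c)})
    return per_axis


def contact_surfaces(labels: LabelVolume) -> list[ContactEdge]:
    """Every unordered pair of positive labels sharing at least one face.

    The physical area sums per-orientation face areas (a face normal to axis
    a has the area of the product of the two other spacings); the weight
    divides the shared face count by the mean total surface face count of the
    pair.
    """
    dx, dy, dz = labels.spacing
    face_area = (dy * dz, dx * dz, dx * dy)  # normal to x, y, z

    all_counts = pair_face_counts(labels.data)
    totals: dict[int, int] = {}
    for (p, q), n in all_counts.items():
        if p > 0:
            totals[p] = totals.get(p, 0) + n
        if q > 0:
            totals[q] = totals.get(q, 0) + n

    per_axis = _per_axis_face_counts(labels.data)
    pairs = sorted(set().union(*[d.keys() for d in per_axis])) if per_axis else []
    edges = []
    for i, j in pairs:
        counts = [d.get((i, j), 0) for d in per_axis]
        face_count = sum(counts)
        area_um2 = sum(c * a for c, a in zip(counts, face_area))
        weight = face_count / ((totals[i] + totals[j]) / 2.0)
        edges.append(
            ContactEdge(
                label_i=i,
                label_j=j,
                face_count=face_count,
                area_mm2=area_um2 / _UM2_PER_MM2,
                weight=weight,
            )
        )
    return edges


def sla_ratio(sla_volume: float, total_volume: float) -> float:
    """Segmentable-core volume as a percentage of the whole fat-pad volume."""
    if total_volume <= 0:
        raise ParameterError("total volume must be > 0")
    if sla_volume > total_volume:
        raise ConsistencyError(
            f"core volume {sla_volume} exceeds total volume {total_volume}"
        )
    return 100.0 * sla_volume / total_volume


def normalized_volumes(records: list[SubunitRecord], fat_pad_volume: float) -> list[float]:
    """Each subunit volume divided by the whole fat-pad volume."""
    if fat_pad_volume <= 0:
        raise ParameterError("fat pad volume must be > 0")
    return [r.volume_mm3 / fat_pad_volume for r in records]


def summarize(values) -> SummaryStats:
    """Mean and standard error of the mean (sample sd / sqrt(n))."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ParameterError("cannot summarize an empty list")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else None
    return SummaryStats(n=int(arr.size), mean=mean, sem=sem)


def density_proxy_mean(vol: ImageVolume, roi: BinaryMask) -> float:
    """Mean intensity over an ROI — a proxy for e.g. vessel density when the
    signal labels vessel walls."""
    if vol.shape != roi.shape:
        raise ConsistencyError(f"volume shape {vol.shape} != ROI shape {roi.shape}")
    if not roi.data.any():
        raise ParameterError("ROI is empty")
    return float(vol.data[roi.data].mean())


def labelled_fraction(binary: BinaryMask, roi: BinaryMask) -> float:
    """Fraction of ROI voxels that are foreground in ``binary`` (in [0, 1])."""
    if binary.shape != roi.shape:
        raise ConsistencyError(f"mask shape {binary.shape} != ROI shape {roi.shape}")
    n_roi = int(roi.data.sum())
    if n_roi == 0:
        raise ParameterError("ROI is empty")
    return int((binary.data & roi.data).sum()) / n_roi


def records_to_frame(records: list[SubunitRecord]) -> pd.DataFrame:
    rows = [
        {
            "label": r.label,
            "voxel_count": r.voxel_count,
            "volume_mm3": r.volume_mm3,
            "bx": r.barycenter[0],
            "by": r.barycenter[1],
            "bz": r.barycenter[2],
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["label", "voxel_count", "volume_mm3", "bx", "by", "bz"])


def edges_to_frame(edges: list[ContactEdge]) -> pd.DataFrame:
    rows = [
        {
            "label_i": e.label_i,
            "label_j": e.label_j,
            "face_count": e.face_count,
            "area_mm2": e.area_mm2,
            "weight": e.weight,
        }
        for e in edges
    ]
    return pd.DataFrame(
        rows, columns=["label_i", "label_j", "face_count", "area_mm2", "weight"]
    )


def parameter_sweep(
    vol: ImageVolume,
    grid: dict[str, list],
    pre: PreprocessParams | None = None,
    seg: SegmentationParams | None = None,
    region: BinaryMask | None = None,
) -> pd.DataFrame:
    """Robustness sweep: rerun the segmentation over a parameter grid.

    ``grid`` maps parameter names (fields of :class:`SegmentationParams` or
    :class:`PreprocessParams`) to value lists; the full Cartesian product is
    evaluated.  Each row reports the subunit count, the volume distribution
    and the adjusted Rand index against the first grid point (empty for the
    first row itself).
    """
    pre = pre or PreprocessParams()
    seg = seg or SegmentationParams()
    if not grid:
        raise ParameterError("parameter grid is empty")
    names = sorted(grid)
    seg_fields = set(SegmentationParams.__dataclass_fields__)
    pre_fields = set(PreprocessParams.__dataclass_fields__)
    for name in names:
        if name not in seg_fields | pre_fields:
            raise ParameterError(f"unknown sweep parameter {name!r}")

    rows = []
    first_labels = None
    for values in itertools.product(*(grid[n] for n in names)):
        point = dict(zip(names, values))
        seg_i = replace(seg, **{k: v for k, v in point.items() if k in seg_fields})
        pre_i = replace(pre, **{k: v for k, v in point.items() if k in pre_fields})
        labels = segment_lobules(vol, pre_i, seg_i, region=region)
        records = subunit_volumes(labels)
        vols = [r.volume_mm3 for r in records]
        if first_labels is None:
            first_labels = labels.data.ravel()
            ari = np.nan
        else:
            ari = adjusted_rand_score(first_labels, labels.data.ravel())
        rows.append(
            {
                **point,
                "n_subunits": len(records),
                "total_volume_mm3": float(np.sum(vols)),
                "mean_volume_mm3": float(np.mean(vols)),
                "min_volume_mm3": float(np.min(vols)),
                "max_volume_mm3": float(np.max(vols)),
                "ari_vs_first": ari,
            }
        )
    return pd.DataFrame(rows)
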