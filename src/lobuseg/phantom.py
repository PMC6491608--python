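"""Synthetic cleared-fat-pad phantom with voxel-level ground truth.

The phantom forward-models the anatomy the segmentation pipeline is built
for: a septated core slab (the segmentable lobule area) packed with
inter-digitated poly-lobular subunits — each the union of a few overlapping
random ellipsoids, elongated in the x-y plane — separated by darker
mesenchymal septa; an unstructured bright periphery; an ovoid occluder
standing in for the inguinal lymph node; and additive Gaussian noise.
Ground truth (label volume, core mask, morphometric records, contact edges)
is returned alongside the intensity volume, so every downstream operation can
be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .quantify import ContactEdge, SubunitRecord, contact_surfaces, subunit_volumes
from .types import (
    BinaryMask,
    ImageVolume,
    LabelVolume,
    ParameterError,
    PlacementError,
)

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom"]


@dataclass
class PhantomSpec:
    """Full parameterization of the synthetic fat-pad generator.

    Geometry is physical (µm); the defaults model a desk-scale fat pad:
    18 subunits (the mid-range of the 15-21 counts typical of murine inguinal
    pads) packed into a core slab spanning 20% of the x extent (the core of a
    real pad occupies about a fifth of its volume), subunit ellipsoids with
    in-plane radii roughly twice the axial radius, 30 µm septa, and a bright
    but unstructured periphery elsewhere.  Intensities are 8-bit-like:
    (lobule, septum, periphery, background).
    """

    shape: tuple[int, int, int] = (128, 128, 32)
    spacing: tuple[float, float, float] = (10.0, 10.0, 12.0)
    n_subunits: int = 18
    lobes_per_subunit: tuple[int, int] = (2, 4)
    ellipsoid_radii: tuple = ((160.0, 260.0), (160.0, 260.0), (90.0, 140.0))
    septum_width: float = 30.0
    core_fraction: float = 0.2
    intensities: tuple[float, float, float, float] = (200.0, 60.0, 130.0, 10.0)
    noise_sd: float = 8.0
    include_node_occluder: bool = True
    rng_seed: int = 42
    margin_voxels: tuple[int, int, int] = (4, 4, 2)
    periphery_shell_voxels: tuple[int, int, int] = (4, 4, 3)

    def __post_init__(self):
        lobule, septum, periphery, background = self.intensities
        if not (lobule > septum >= background):
            raise ParameterError(
                "intensities must satisfy lobule_mean > septum_mean >= background_mean"
            )
        if self.n_subunits < 1:
            raise ParameterError("n_subunits must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not (0 < self.core_fraction <= 1):
            raise ParameterError("core_fraction must be in (0, 1]")
        lo, hi = self.lobes_per_subunit
        if lo < 1 or hi < lo:
            raise ParameterError("lobes_per_subunit must be a range with 1 <= lo <= hi")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom volume."""

    labels: LabelVolume  # subunits after septum carving; septa are 0
    core_mask: BinaryMask  # the SLA-like core (occluder excluded)
    periphery_mask: BinaryMask
    node_mask: BinaryMask  # the ovoid occluder (empty if disabled)
    records: list[SubunitRecord]
    edges: list[ContactEdge]  # adjacency of the pre-septum tessellation


def _sample_centers(rng, n, bounds_lo, bounds_hi, min_sep, max_tries):
    centers = []
    for _ in range(max_tries):
        c = bounds_lo + rng.random(3) * (bounds_hi - bounds_lo)
        if all(np.linalg.norm(c - p) >= min_sep for p in centers):
            centers.append(c)
            if len(centers) == n:
                return np.asarray(centers)
    raise PlacementError(
        f"could not place {n} subunit centers with separation {min_sep:.0f} µm "
        f"after {max_tries} attempts"
    )


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Generate one phantom volume and its ground truth, deterministically.

    Each subunit is the union of 1..k overlapping random ellipsoids (rotated
    about z; in-plane radii exceed the axial radius, giving the planar
    elongation seen in real subunits).  Voxels claimed by several subunits go
    to the one whose ellipsoid field is smallest, which inter-digitates
    neighbouring subunits.  Septa are carved by eroding every subunit by half
    the septum width (via the Euclidean distance transform, so the width is
    physical).  All randomness comes from a single generator seeded with
    ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    nx_, ny_, nz_ = spec.shape
    dx, dy, dz = spec.spacing
    mx, my, mz = spec.margin_voxels

    extents = (nx_ * dx, ny_ * dy, nz_ * dz)
    for ax, (extent, radii) in enumerate(zip(extents, spec.ellipsoid_radii)):
        if extent < max(radii):
            raise PlacementError(
                f"axis {ax} extent {extent} µm too small for ellipsoid radii "
                f"up to {max(radii)} µm"
            )

    ii, jj, kk = np.meshgrid(
        np.arange(nx_), np.arange(ny_), np.arange(nz_), indexing="ij"
    )
    xs = ii * dx
    ys = jj * dy
    zs = kk * dz

    tissue = (
        (ii >= mx) & (ii < nx_ - mx)
        & (jj >= my) & (jj < ny_ - my)
        & (kk >= mz) & (kk < nz_ - mz)
    )
    core_extent = max(int(round(spec.core_fraction * nx_)), 1)
    # the segmentable core sits behind a shell of unstructured periphery on
    # every side, as in a real pad where the lobular core is interior
    sx, sy_, sz_ = spec.periphery_shell_voxels
    core = (
        (ii >= mx + sx) & (ii < mx + sx + core_extent)
        & (jj >= my + sy_) & (jj < ny_ - my - sy_)
        & (kk >= mz + sz_) & (kk < nz_ - mz - sz_)
    ) & tissue
    if not core.any():
        raise PlacementError("core slab is empty; enlarge shape or core_fraction")

    # subunit centers, spread through the physical core slab
    core_lo = np.array([(mx + sx) * dx, (my + sy_) * dy, (mz + sz_) * dz])
    core_hi = np.array(
        [
            (mx + sx + core_extent) * dx,
            (ny_ - my - sy_) * dy,
            (nz_ - mz - sz_) * dz,
        ]
    )
    core_vol_um3 = float(core.sum()) * dx * dy * dz
    cell_side = (core_vol_um3 / spec.n_subunits) ** (1.0 / 3.0)
    min_sep = 0.65 * cell_side

    # ovoid occluder (lymph-node stand-in) at the core's inner edge
    node = np.zeros(spec.shape, dtype=bool)
    if spec.include_node_occluder:
        node_center = np.array(
            [(mx + sx + core_extent) * dx, (ny_ // 2) * dy, (nz_ // 2) * dz]
        )
        node_radii = np.array([100.0, 130.0, 80.0])
        fnode = np.sqrt(
            ((xs - node_center[0]) / node_radii[0]) ** 2
            + ((ys - node_center[1]) / node_radii[1]) ** 2
            + ((zs - node_center[2]) / node_radii[2]) ** 2
        )
        node = (fnode <= 1.0) & tissue

    # a draw of centers/lobes occasionally leaves one subunit without voxels
    # (crowded out, or emptied by septum carving); retry a bounded number of
    # times, advancing the same RNG stream
    lo_lobes, hi_lobes = spec.lobes_per_subunit
    half_w = spec.septum_width / 2.0
    tessellation = labels = None
    for _attempt in range(5):
        centers = _sample_centers(
            rng, spec.n_subunits, core_lo, core_hi, min_sep,
            max_tries=400 * spec.n_subunits,
        )
        # ellipsoid field per subunit: min over lobes of the normalized distance
        field = np.full((spec.n_subunits,) + spec.shape, np.inf, dtype=np.float32)
        for s in range(spec.n_subunits):
            n_lobes = int(rng.integers(lo_lobes, hi_lobes + 1))
            lobe_centers = [centers[s]]
            radii0 = np.array([rng.uniform(*r) for r in spec.ellipsoid_radii])
            lobe_radii = [radii0]
            for _ in range(n_lobes - 1):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                step = rng.uniform(0.3, 0.7) * radii0
                lobe_centers.append(lobe_centers[0] + direction * step)
                lobe_radii.append(
                    np.array([rng.uniform(*r) for r in spec.ellipsoid_radii])
                )
            for c, radii in zip(lobe_centers, lobe_radii):
                theta = rng.uniform(0, 2 * np.pi)
                ct, st = np.cos(theta), np.sin(theta)
                u = ct * (xs - c[0]) + st * (ys - c[1])
                v = -st * (xs - c[0]) + ct * (ys - c[1])
                w = zs - c[2]
                f = np.sqrt(
                    (u / radii[0]) ** 2 + (v / radii[1]) ** 2 + (w / radii[2]) ** 2
                ).astype(np.float32)
                np.minimum(field[s], f, out=field[s])

        fmin = field.min(axis=0)
        owner = field.argmin(axis=0)
        tess = np.where(core & (fmin <= 1.0), owner + 1, 0).astype(np.int32)
        tess[node] = 0
        placed = np.unique(tess)
        placed = placed[placed > 0]
        if placed.size < spec.n_subunits:
            continue

        # carve septa: erode each subunit by half the septum width (physical)
        lab_arr = np.zeros(spec.shape, dtype=np.int32)
        for lab in placed:
            m = tess == lab
            interior = (
                ndimage.distance_transform_edt(m, sampling=spec.spacing) > half_w
            )
            lab_arr[interior] = lab
        present = np.unique(lab_arr)
        if (present[present > 0]).size == spec.n_subunits:
            tessellation, labels = tess, lab_arr
            break
    if tessellation is None:
        raise PlacementError(
            f"could not realize {spec.n_subunits} subunits after 5 attempts; "
            "decrease septum_width or n_subunits, or enlarge the core"
        )

    core_mask = core & ~node
    periphery = tissue & ~core & ~node

    lobule_mean, septum_mean, periphery_mean, background_mean = spec.intensities
    vol = np.full(spec.shape, background_mean, dtype=np.float64)
    vol[periphery] = periphery_mean
    vol[core_mask] = septum_mean  # septa / interstitial mesenchyme
    vol[labels > 0] = lobule_mean
    vol[node] = lobule_mean  # dense bright ovoid
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=spec.shape)

    label_vol = LabelVolume(data=labels, spacing=spec.spacing)
    truth = PhantomTruth(
        labels=label_vol,
        core_mask=BinaryMask(data=core_mask, spacing=spec.spacing),
        periphery_mask=BinaryMask(data=periphery, spacing=spec.spacing),
        node_mask=BinaryMask(data=node, spacing=spec.spacing),
        records=subunit_volumes(label_vol),
        edges=[
            e
            for e in contact_surfaces(
                LabelVolume(data=tessellation, spacing=spec.spacing)
            )
        ],
    )
    return ImageVolume(data=vol, spacing=spec.spacing), truth
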