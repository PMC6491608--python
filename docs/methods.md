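# Methods

This note documents the models, numerical choices and limitations behind
`lobuseg`. Volumes are arrays indexed `(x, y, z)` with anisotropic voxel
spacing `(dx, dy, dz)` in µm; the physical center of voxel `(i, j, k)` is
`origin + (i·dx, j·dy, k·dz)`. Volumes are reported in mm³, areas in mm².

## Contrast enhancement: the Kuwahara-ratio filter

For every voxel, the eight corner-anchored octant boxes of per-axis extent
`box_radius` (the 3D analogue of the four quadrants of the classic 2D
Kuwahara filter) are evaluated. Each box *b* yields a mean `m_b` and a
population variance `v_b` (divide by n, over in-bounds voxels only — boxes
are clipped at the borders). The output is

```
f(x) = (1/8) Σ_b  m_b / (v_b + ε)
```

with `ε = variance_epsilon` (default 1.0, intensity²) regularizing
zero-variance boxes. Homogeneous bright regions (lobule interiors,
periphery) map to large values; septa are darker, and voxels whose boxes
straddle an edge acquire a large `v_b` and map to small values. The result
is that subunit interiors become bright islands separated by wide dark
moats, and one global Otsu threshold (256 fixed-width bins over the data
range) isolates them. The classic Kuwahara output (mean of the
minimum-variance box) is available via `kuwahara_mode: classic`.
`box_radius` defaults to `(1, 1, 1)`: larger boxes widen the moats and
erode thin processes of the subunits.

Implementation: box sums come from a zero-padded 3D integral image, so the
filter is exact (no border padding approximations) and runs in eight
constant-time passes regardless of the radius.

## Tissue foreground

The specimen support (`tissue_foreground`) is obtained by thresholding the
raw volume (`foreground_threshold`, default Otsu; `multiotsu` — lowest cut
of a three-class Otsu — suits volumes where dim stroma would otherwise fall
below a two-class cut), closing with a voxel ball (`foreground_closing_radius`,
default 2) so that thin dark septa do not puncture the support, then filling
holes. Everything downstream is restricted to this mask.

## Core/periphery separation

The segmentable core is septated, hence locally contrasted; the periphery is
bright but flat. `separate_sla`:

1. erodes the tissue by `sla_margin_voxels` (default 3) to discard the
   high-contrast shell at the tissue/background interface;
2. computes a per-voxel standard deviation over the `box_radius`
   neighbourhood and thresholds it (Otsu over in-tissue voxels by default);
3. labels the *low*-contrast pockets: pockets comparable in size to the
   largest one (ratio `sla_pocket_ratio`, default 0.5) are periphery bulk
   and are discarded; small pockets are lobule interiors and stay;
4. keeps the largest 26-connected candidate component, closes and
   hole-fills it, dilates by one voxel to recover the rind, clips to the
   tissue, and subtracts the user-supplied exclusion mask (e.g. the lymph
   node; there is no automatic node detection).

A uniform volume, or an exclusion mask covering everything, raises an
empty-core error. The heuristic assumes the core is *surrounded* by
periphery or background on most sides; a core whose septa open directly
into the image border will lose the affected pockets.

## Segmentation pipeline

`segment_lobules` composes, deterministically:

1. Kuwahara-ratio filter → global threshold → cleanup (optional ball
   closing, default off; removal of 26-connected islands smaller than
   `min_island_voxels`, default 30) = the **subunit blobs**;
2. Euclidean distance transform of the blobs (physical µm, anisotropic);
3. seeds = connected components (default 26-connectivity) of
   `distance > distance_threshold` (default 15 µm), dropping components
   smaller than `min_seed_voxels` (default 10). Expressing the threshold in
   µm makes it robust to downscaling. With the default the seeds nearly
   coincide with the blobs, so the subunit count is primarily set by the
   blob topology, not by seed fragmentation;
4. priority-flood watershed over the working region (the SLA if provided,
   else the tissue), flooding in ascending relief order with ties broken by
   ascending linear voxel index, then by ascending label;
5. pointwise masking by the working region/tissue foreground;
6. greedy merging: while some label pair has contact ratio
   `S_ij / ((S_i+S_j)/2) ≥ merge_threshold` (default 0.4), merge the
   highest-ratio pair (ties: lexicographically smallest pair), the larger
   label collapsing into the smaller. Interface/surface bookkeeping is
   updated incrementally, which is algebraically identical to recomputing
   from the relabelled volume (the merged interface becomes interior and
   leaves both surfaces: `S = S_i + S_j − 2·S_ij`).

### The watershed relief

Two reliefs are available (`relief_source`):

- `binary_gradient`: the Euclidean norm of the three axis-wise 3D Sobel
  responses of the binary blob mask (borders by edge replication). This is
  the textbook "borders from the gradient" formulation, but on clean data it
  is degenerate: the relief is exactly zero both inside blobs and in the
  space between them, and the boundary ridge delays every region's entry
  into that flat plateau — whichever region breaches first floods the entire
  connected inter-blob space, however ties are broken. On noisy acquired
  images the plateau is broken up by texture and the formulation behaves; on
  a noise-free phantom it does not.
- `distance` (default): the distance from the nearest blob,
  `EDT(¬blobs)`, plus a small multiple (0.01) of the Sobel term to order
  equidistant voxels. Its watershed lines are the midlines of the inter-blob
  gaps — the same borders the Sobel ridge marks — but the flooding order is
  well-posed: fronts from both sides climb the ramp symmetrically and meet
  at the septum medial axis.

The merging step repairs over-segmentation caused by leaks through holes in
the inter-blob borders. It cannot repair a subunit whose blob was *split*
by filtering (a pinched neck): the two fragments then meet only across a
background gap with a small interface, indistinguishable from a genuine
septum contact. Such splits show up as a +1 in the subunit count.

## Morphometrics

- Volume: voxel count × dx·dy·dz, converted to mm³; barycenter: unweighted
  mean of member-voxel physical centers.
- Contact surfaces: 6-neighbour voxel faces between distinct labels; the
  array border counts as background, so an isolated voxel has surface 6.
  Physical area sums per-orientation face areas (a face normal to x has
  area dy·dz, etc.); the dimensionless edge weight used in the graph is
  face-count based: `S_ij / ((S_i+S_j)/2) ∈ [0, 1]`.
- Summary statistics are mean ± SEM with the sample (n−1) standard
  deviation; the SEM of a single value is reported as missing.
- Density proxies: mean grayscale intensity over an ROI (vessel-density
  proxy for lectin-labelled volumes), and labelled-voxel fraction of an ROI
  for binarized immunolabel images.

## The subunit graph

Nodes are subunits (position = barycenter, size attribute = volume); edges
carry the contact ratio as weight. `partition_clusters` keeps edges with
weight ≥ threshold and returns connected components (singletons included);
raising the threshold never decreases the number of clusters. The default
threshold (0.1) is this package's choice — cluster structure in real pads
was identified visually in the source imagery, and no numeric criterion is
established — so greedy-modularity communities are provided as an
alternative (`greedy_modularity_clusters`), with neither method privileged.

## The synthetic phantom

The generator emulates the anatomy the pipeline targets, at desk scale:

- **Grid**: 128×128×32 voxels at (10, 10, 12) µm — ~1.3 × 1.3 × 0.38 mm,
  with coarser axial sampling as in confocal stacks. A background margin of
  (4, 4, 2) voxels surrounds the tissue.
- **Core**: a slab spanning 20% of the x extent (`core_fraction`), inset
  behind a periphery shell of (4, 4, 3) voxels on every side — the
  segmentable core of a real pad is interior. With the defaults the core is
  ~15.5% of the pad volume, matching the ~20% core/pad volume ratio scale
  of real pads (15–25% band).
- **Subunits**: 18 by default (the mid-range of the 15–21 counts reported
  for murine inguinal pads). Each is the union of 1–4 overlapping random
  ellipsoids rotated about z, with in-plane radii (160–260 µm) roughly twice
  the axial radii (90–140 µm), reproducing the preferential x–y elongation
  of real subunits. A voxel inside several subunits' lobes goes to the one
  whose normalized ellipsoid field is smallest, which inter-digitates
  neighbours; voxels inside no lobe are interstitial stroma.
- **Septa**: every subunit is eroded by half the septum width (30 µm
  default) via the distance transform, so septa have physical width
  regardless of anisotropy. The ground-truth contact edges are computed on
  the *pre-erosion* tessellation (adjacency across septa), matching what
  the segmentation measures.
- **Occluder**: an ovoid (100, 130, 80 µm radii) at the core's inner edge
  stands in for the inguinal lymph node; its mask is part of the ground
  truth and is meant to be passed as the exclusion mask.
- **Intensities**: lobule 200, septum 60, periphery 130, background 10
  (8-bit-like arbitrary units), plus additive Gaussian noise of sd 8.
  Septa must sit between background and lobule; the periphery is bright but
  unstructured.
- **Determinism**: a single `numpy` generator seeded by `rng_seed` drives
  everything; a draw that leaves a subunit without voxels (crowded out or
  emptied by septum carving) is retried a bounded number of times on the
  same stream, then fails.

What the phantom does *not* model: optics (PSF, depth attenuation,
vignetting), mosaic stitching seams, intensity inhomogeneity across the
field, vessel networks, and partial-volume voxels at septum borders (septa
are crisp here). Passing the phantom recovery tests therefore demonstrates
the correctness and calibration of the geometric pipeline, not robustness
to acquisition artefacts; on acquired data the thresholds ("parameters must
be chosen accordingly") are expected to need per-dataset adjustment, for
which `lobuseg sweep` provides a one-command robustness study.

## Numerical choices and degenerate inputs

- Flooding order ties: (relief, linear index, label), making the watershed
  bit-reproducible; the scan-order seed numbering and the lexicographic
  merge tie-break do the same for the other stages.
- Otsu thresholds always use 256 fixed-width bins over the data range;
  constant images raise an explicit degenerate-histogram error rather than
  returning an arbitrary cut.
- Population (divide-by-n) variance in the Kuwahara boxes; clipped boxes
  use only in-bounds voxels.
- Downscaling is block-mean (not subsampling), preserving septum contrast
  statistics; output spacing is multiplied by the factors and trailing
  partial blocks are dropped.
- Distances to "background" are to the nearest background voxel *center*.
- Labels after merging are not renumbered consecutively; gaps are
  meaningful (they record which label absorbed which).

## Validation strategy and problem sizes

Every geometric kernel is checked against an independent brute-force
reference on small instances: exhaustive nearest-background search for the
distance transform (grids ≤ 8³), an exhaustive-scan priority flood for the
watershed (200 random reliefs/masks ≤ 6³ with ≤ 3 seeds), direct kernel
application for the Sobel responses, a full face-enumeration scan for
contact surfaces (5³ label fields), and a recompute-everything greedy
merger (100 random 3–6-label toys). End-to-end recovery runs on the
default 128×128×32 phantom: core/periphery separation must recover ≥ 90% of
true core voxels with ≤ 10% periphery contamination, and segmentation must
recover 18 ± 3 subunits at an adjusted Rand index ≥ 0.8 over the true
subunit voxels. These sizes keep the full suite under a minute while the
oracles remain exhaustive.
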