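"""Brute-force reference implementations used only by the test suite.

Every function here recomputes a quantity by direct enumeration (loops over
voxels, exhaustive searches), deliberately sharing no code with the package
implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_block_mean(data: np.ndarray, factor):
    fx, fy, fz = factor
    nx, ny, nz = (s // f for s, f in zip(data.shape, factor))
    out = np.zeros((nx, ny, nz))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                block = data[
                    i * fx : (i + 1) * fx, j * fy : (j + 1) * fy, k * fz : (k + 1) * fz
                ]
                out[i, j, k] = block.mean()
    return out


def brute_kuwahara_ratio(data: np.ndarray, radius, eps):
    """Per-voxel average of per-octant-box mean/(variance + eps)."""
    data = np.asarray(data, dtype=float)
    nx, ny, nz = data.shape
    rx, ry, rz = radius
    out = np.zeros_like(data)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                acc = 0.0
                for sx, sy, sz in itertools.product((-1, 1), repeat=3):
                    x0, x1 = (i - rx, i) if sx < 0 else (i, i + rx)
                    y0, y1 = (j - ry, j) if sy < 0 else (j, j + ry)
                    z0, z1 = (k - rz, k) if sz < 0 else (k, k + rz)
                    box = data[
                        max(x0, 0) : min(x1, nx - 1) + 1,
                        max(y0, 0) : min(y1, ny - 1) + 1,
                        max(z0, 0) : min(z1, nz - 1) + 1,
                    ]
                    m = box.mean()
                    v = box.var()  # population variance
                    acc += m / (v + eps)
                out[i, j, k] = acc / 8.0
    return out


def brute_otsu_256(data: np.ndarray):
    """Threshold (bin center) maximizing between-class variance, 256 bins."""
    flat = np.asarray(data, dtype=float).ravel()
    counts, edges = np.histogram(flat, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    best_var, best_thr = -1.0, centers[0]
    for t in range(1, 256):
        w0 = counts[:t].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:t] * centers[:t]).sum() / w0
        m1 = (counts[t:] * centers[t:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[t - 1]
    return best_thr


def brute_distance_map(mask: np.ndarray, spacing):
    """Exhaustive nearest-background search with anisotropic spacing."""
    mask = np.asarray(mask, dtype=bool)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=float)
    if bg.size == 0:
        out[mask] = np.inf
        return out
    sp = np.asarray(spacing, dtype=float)
    for idx in np.argwhere(mask):
        d = ((bg - idx) * sp) ** 2
        out[tuple(idx)] = np.sqrt(d.sum(axis=1).min())
    return out


_SOBEL_1D = {
    "deriv": np.array([-1.0, 0.0, 1.0]),
    "smooth": np.array([1.0, 2.0, 1.0]),
}


def sobel_response_at(data: np.ndarray, voxel, axis):
    """Direct 3x3x3 Sobel kernel application at one voxel, edge replication.

    Matches the scipy convention: the derivative kernel along ``axis`` is
    correlation with [-1, 0, 1] (i.e. value[x+1] - value[x-1]) and smoothing
    [1, 2, 1] along the two other axes.
    """
    data = np.asarray(data, dtype=float)
    shape = data.shape
    acc = 0.0
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                w = 1.0
                for ax, off in enumerate((dx, dy, dz)):
                    kern = _SOBEL_1D["deriv"] if ax == axis else _SOBEL_1D["smooth"]
                    w *= kern[off + 1]
                pos = tuple(
                    min(max(v + o, 0), s - 1)
                    for v, o, s in zip(voxel, (dx, dy, dz), shape)
                )
                acc += w * data[pos]
    return acc


def brute_gradient_magnitude_at(data, voxel):
    return np.sqrt(
        sum(sobel_response_at(data, voxel, ax) ** 2 for ax in range(3))
    )


def _neighbors6(idx, shape):
    i, j, k = idx
    for d, n in ((-1, 0), (1, 0), (-1, 1), (1, 1), (-1, 2), (1, 2)):
        pos = [i, j, k]
        pos[n] += d
        if 0 <= pos[n] < shape[n]:
            yield tuple(pos)


def scan_watershed(relief: np.ndarray, seeds: np.ndarray, mask: np.ndarray):
    """Exhaustive priority flood: a plain list stands in for the heap.

    Pending entries (relief, linear index, label) start from the seed voxels;
    each step removes the minimal entry by linear scan, labels the voxel if
    still unlabelled, and enqueues its unlabelled masked 6-neighbours with
    the voxel's label.
    """
    relief = np.asarray(relief, dtype=float)
    labels = np.asarray(seeds).astype(np.int64).copy()
    mask = np.asarray(mask, dtype=bool)
    shape = labels.shape
    pending = []
    for idx in np.argwhere(labels > 0):
        idx = tuple(idx)
        lin = int(np.ravel_multi_index(idx, shape))
        pending.append((float(relief[idx]), lin, int(labels[idx])))
    expanded = set()
    while pending:
        entry = min(pending)
        pending.remove(entry)
        _, lin, lab = entry
        idx = tuple(int(v) for v in np.unravel_index(lin, shape))
        if labels[idx] == 0:
            labels[idx] = lab
        if lin in expanded:
            continue
        expanded.add(lin)
        for nb in _neighbors6(idx, shape):
            if mask[nb] and labels[nb] == 0:
                nb_lin = int(np.ravel_multi_index(nb, shape))
                pending.append((float(relief[nb]), nb_lin, int(labels[idx])))
    return labels


def brute_face_scan(labels: np.ndarray):
    """All 6-neighbour face pairs with distinct labels, border = background.

    Returns ``(pair_counts, per_axis_counts)`` where ``pair_counts`` maps
    unordered pairs (including background) to face counts and
    ``per_axis_counts`` maps positive pairs to per-orientation counts.
    """
    labels = np.asarray(labels, dtype=int)
    nx, ny, nz = labels.shape
    pair_counts: dict[tuple[int, int], int] = {}
    per_axis: dict[tuple[int, int], list[int]] = {}

    def _add(a, b, axis):
        if a == b:
            return
        key = (min(a, b), max(a, b))
        pair_counts[key] = pair_counts.get(key, 0) + 1
        if a > 0 and b > 0:
            per_axis.setdefault(key, [0, 0, 0])[axis] += 1

    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                here = labels[i, j, k]
                # faces in +direction per axis; border faces against 0
                for axis, nxt in enumerate(
                    [(i + 1, j, k), (i, j + 1, k), (i, j, k + 1)]
                ):
                    if nxt[axis] < labels.shape[axis]:
                        _add(here, labels[nxt], axis)
                    else:
                        _add(here, 0, axis)
                for axis, prv in enumerate(
                    [(i - 1, j, k), (i, j - 1, k), (i, j, k - 1)]
                ):
                    if prv[axis] < 0:
                        _add(here, 0, axis)
    return pair_counts, per_axis


def brute_contact_ratio(labels: np.ndarray, i: int, j: int):
    pair_counts, _ = brute_face_scan(labels)
    s_ij = pair_counts.get((min(i, j), max(i, j)), 0)
    totals = {}
    for (p, q), n in pair_counts.items():
        for lab in (p, q):
            if lab > 0:
                totals[lab] = totals.get(lab, 0) + n
    return s_ij / ((totals[i] + totals[j]) / 2.0)


def oracle_merge(labels: np.ndarray, threshold: float):
    """Greedy merging, recomputing every ratio from the relabelled volume
    after each merge (the slow but obviously correct formulation)."""
    labels = np.asarray(labels, dtype=int).copy()
    while True:
        pair_counts, _ = brute_face_scan(labels)
        totals: dict[int, int] = {}
        for (p, q), n in pair_counts.items():
            for lab in (p, q):
                if lab > 0:
                    totals[lab] = totals.get(lab, 0) + n
        best = None
        for (p, q), n in sorted(pair_counts.items()):
            if p <= 0:
                continue
            ratio = n / ((totals[p] + totals[q]) / 2.0)
            if ratio >= threshold and (
                best is None
                or ratio > best[0]
                or (ratio == best[0] and (p, q) < best[1:])
            ):
                best = (ratio, p, q)
        if best is None:
            return labels
        _, p, q = best
        labels[labels == q] = p
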