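"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package: connected
components by explicit flood fill, region properties by direct moment
summation and exact convex-hull geometry, metrics by per-item counting.
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.spatial import ConvexHull, QhullError


def flood_fill_components(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    """8-connected components by stack-based flood fill; cells sorted."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                cells = []
                while stack:
                    a, b = stack.pop()
                    cells.append((a, b))
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            na, nb = a + da, b + db
                            if (0 <= na < h and 0 <= nb < w
                                    and mask[na, nb] and not seen[na, nb]):
                                seen[na, nb] = True
                                stack.append((na, nb))
                comps.append(sorted(cells))
    return comps


def convex_hull_pixel_area(cells: list[tuple[int, int]]) -> float:
    """Pixelated convex-hull area: hull of the four edge-midpoints of every
    cell, rasterised by counting cell centres inside or on the hull."""
    rows = np.array([c[0] for c in cells], dtype=float)
    cols = np.array([c[1] for c in cells], dtype=float)
    pts = set()
    for r, c in cells:
        for dr, dc in ((-0.5, 0), (0.5, 0), (0, -0.5), (0, 0.5)):
            pts.add((r + dr, c + dc))
    pts = np.array(sorted(pts))
    if len(cells) <= 2 or np.linalg.matrix_rank(pts - pts[0]) < 2:
        return float(len(cells))
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return float(len(cells))
    verts = pts[hull.vertices]
    rmin, rmax = int(rows.min()), int(rows.max())
    cmin, cmax = int(cols.min()), int(cols.max())
    gr, gc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    centres = np.column_stack([gr.ravel(), gc.ravel()]).astype(float)
    path = MplPath(verts)
    inside = path.contains_points(centres, radius=1e-9) | path.contains_points(
        centres, radius=-1e-9
    )
    return float(inside.sum())


def brute_region_props(cells: list[tuple[int, int]], channel: np.ndarray) -> dict:
    """Region properties by direct summation over the cell list.

    Raw central moments define the covariance matrix whose eigenvalues give
    the equivalent-ellipse axis lengths (4*sqrt(lambda)) and eccentricity.
    """
    rows = np.array([c[0] for c in cells], dtype=float)
    cols = np.array([c[1] for c in cells], dtype=float)
    n = len(cells)
    r0, c0 = rows.mean(), cols.mean()
    mu20 = ((rows - r0) ** 2).mean()
    mu02 = ((cols - c0) ** 2).mean()
    mu11 = ((rows - r0) * (cols - c0)).mean()
    common = np.sqrt(((mu20 - mu02) / 2) ** 2 + mu11**2)
    l1 = (mu20 + mu02) / 2 + common
    l2 = (mu20 + mu02) / 2 - common
    bbox_h = rows.max() - rows.min() + 1
    bbox_w = cols.max() - cols.min() + 1
    values = np.asarray(channel)[rows.astype(int), cols.astype(int)]
    return {
        "area": float(n),
        "bbox_area": float(bbox_h * bbox_w),
        "extent": n / float(bbox_h * bbox_w),
        "solidity": n / convex_hull_pixel_area(cells),
        "eccentricity": float(np.sqrt(1 - l2 / l1)) if l1 > 0 else 0.0,
        "major_axis_length": float(4 * np.sqrt(max(l1, 0))),
        "minor_axis_length": float(4 * np.sqrt(max(l2, 0))),
        "aspect_ratio": float(bbox_w / bbox_h),
        "max_prob": float(values.max()),
        "min_prob": float(values.min()),
        "mean_prob": float(values.mean()),
    }


def brute_confusion(preds, truth, classes) -> np.ndarray:
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, t in zip(preds, truth):
        counts[classes.index(t), classes.index(p)] += 1
    return counts


def brute_kappa(a, b) -> float:
    """Cohen's kappa from first principles."""
    labels = sorted(set(a) | set(b))
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    pe = sum((a.count(l) / n) * (b.count(l) / n) for l in labels)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)
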