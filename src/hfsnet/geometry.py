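"""Shared geometric primitives: maximum pairwise extent of point sets.

The size of a lesion is defined throughout the package as the maximum
pairwise Euclidean distance between member voxel centers (its longest axis).
For large components the distance is computed on the convex hull vertices,
which leaves the result unchanged (the diameter of a finite point set is
attained at hull vertices) while keeping the pairwise pass cheap.
"""

from __future__ import annotations

import numpy as np

_HULL_CUTOVER = 400  # above this many points, reduce to hull vertices first


def max_pairwise_distance(coords: np.ndarray) -> float:
    """Maximum Euclidean distance between rows of an (n, d) coordinate array.

    Returns 0.0 for a single point; raises on an empty set.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2:
        raise ValueError("coords must be an (n, d) array")
    n = coords.shape[0]
    if n == 0:
        raise ValueError("empty coordinate set has no extent")
    if n == 1:
        return 0.0
    if n > _HULL_CUTOVER:
        coords = _hull_vertices(coords)
        n = coords.shape[0]
    # blockwise pairwise distances to bound memory
    best = 0.0
    block = 2048
    for i in range(0, n, block):
        diff = coords[i:i + block, None, :] - coords[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        best = max(best, float(d2.max()))
    return float(np.sqrt(best))


def _hull_vertices(coords: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull, QhullError

    # degenerate (collinear/coplanar) sets make Qhull fail; fall back
    try:
        hull = ConvexHull(coords)
        return coords[hull.vertices]
    except (QhullError, ValueError):
        return coords
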