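"""Half-space (Tukey) depth of points in a finite cloud, open-half-space variant.

The depth of a query point x is the minimum, over all hyperplanes through x, of
the number of cloud points strictly on one side.  With this open-half-space
counting convention points on the convex hull boundary have depth exactly 0,
and a central point of a symmetric cloud attains the maximum floor(n/2).

Two evaluators are provided: an exact one that enumerates candidate hyperplane
normals (the minimum of the piecewise-constant direction count is always
attained at a direction orthogonal to d-1 cloud-point offsets, so enumerating
pair cross-products in 3-D / point normals in 2-D is exhaustive), and a fast
approximate one that samples random directions and therefore never
under-reports the true depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Tuple

import numpy as np

__all__ = [
    "PointCloud", "DepthQuery", "ResidueDepthMap",
    "exact_depth", "approx_depth", "residue_depths",
]

_EXACT_N_GUARD = 500
_EPS = 1e-9


@dataclass
class PointCloud:
    """A finite set of points carrying unit mass each (the empirical measure)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[0] < 1:
            raise ValueError("cloud must be a nonempty n x d array")
        if pts.shape[1] not in (1, 2, 3):
            raise ValueError(f"unsupported dimension d={pts.shape[1]}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("cloud coordinates must be finite")
        self.points = pts

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]


@dataclass
class DepthQuery:
    x: np.ndarray
    depth: int


@dataclass
class ResidueDepthMap:
    """Integer half-space depth per residue, keyed by (chain_id, seq_index)."""

    depths: Dict[Tuple[str, int], int] = field(default_factory=dict)

    def __getitem__(self, key: Tuple[str, int]) -> int:
        return self.depths[key]

    def __len__(self) -> int:
        return len(self.depths)

    def items(self):
        return self.depths.items()


def _side_counts(offsets: np.ndarray, normals: np.ndarray) -> int:
    """Minimum over candidate normals of points strictly on the positive side.

    Each normal is tried in both orientations; points exactly on the
    hyperplane (|dot| <= eps * scale) count for neither side.
    """
    scale = max(1.0, float(np.abs(offsets).max()))
    proj = offsets @ normals.T  # n x m
    pos = (proj > _EPS * scale).sum(axis=0)
    neg = (proj < -_EPS * scale).sum(axis=0)
    return int(min(pos.min(), neg.min()))


def _candidate_normals(offsets: np.ndarray, d: int) -> np.ndarray:
    """Directions at which the strict-side count can attain its minimum."""
    eye = np.eye(d)
    nonzero = offsets[np.linalg.norm(offsets, axis=1) > _EPS]
    if d == 1:
        return np.array([[1.0]])
    if d == 2:
        if nonzero.size == 0:
            return eye
        perp = np.column_stack([-nonzero[:, 1], nonzero[:, 0]])
        return np.vstack([perp, eye])
    # d == 3: vertices of the direction arrangement are orthogonal to two offsets
    cands = [eye]
    if len(nonzero) >= 2:
        i, j = np.triu_indices(len(nonzero), k=1)
        cross = np.cross(nonzero[i], nonzero[j])
        cross = cross[np.linalg.norm(cross, axis=1) > _EPS]
        if cross.size:
            cands.append(cross)
    # collinear/coplanar degeneracy: directions orthogonal to a single offset
    # paired with coordinate axes still sweep the arrangement
    for axis in eye:
        c = np.cross(nonzero, axis) if nonzero.size else np.empty((0, 3))
        c = c[np.linalg.norm(c, axis=1) > _EPS] if c.size else c
        if c.size:
            cands.append(c)
    return np.vstack(cands)


def exact_depth(cloud: PointCloud, x: np.ndarray) -> int:
    """Exact open-half-space depth of ``x`` by hyperplane-normal enumeration.

    Guarded to clouds with n <= 500 (the enumeration is cubic in n); use
    :func:`approx_depth` beyond that.
    """
    if cloud.d > 3:
        raise ValueError("exact_depth supports d <= 3 only")
    if cloud.n > _EXACT_N_GUARD:
        raise ValueError(f"exact_depth guarded to n <= {_EXACT_N_GUARD}; got {cloud.n}")
    x = np.asarray(x, dtype=float).reshape(cloud.d)
    offsets = cloud.points - x
    normals = _candidate_normals(offsets, cloud.d)
    return _side_counts(offsets, normals)


def approx_depth(cloud: PointCloud, x: np.ndarray, n_dirs: int = 1000,
                 seed: int = 0) -> int:
    """Approximate depth: minimum strict-side count over random directions.

    Sampling a subset of directions can only miss the minimizing one, so the
    result is always >= the exact depth; it is deterministic given ``seed``.
    """
    if n_dirs < 1:
        raise ValueError("n_dirs must be >= 1")
    x = np.asarray(x, dtype=float).reshape(cloud.d)
    rng = np.random.default_rng(seed)
    offsets = cloud.points - x
    scale = max(1.0, float(np.abs(offsets).max()))
    best = cloud.n
    remaining = n_dirs
    while remaining > 0:  # chunked so very large n_dirs stays memory-bounded
        m = min(remaining, 100_000)
        dirs = rng.standard_normal((m, cloud.d))
        dirs /= np.maximum(np.linalg.norm(dirs, axis=1, keepdims=True), 1e-12)
        counts = (offsets @ dirs.T > _EPS * scale).sum(axis=0)
        best = min(best, int(counts.min()))
        remaining -= m
    return best


def residue_depths(structure, method: Literal["exact", "approx"] = "approx",
                   n_dirs: int = 1000, seed: int = 0) -> ResidueDepthMap:
    """Half-space depth of every residue within the pooled heavy-atom cloud.

    The cloud is all protein heavy atoms of all chains; each residue is
    represented by its C-alpha (heavy-atom centroid when absent).  At protein
    scale the sampled evaluator is the default; exact enumeration is practical
    only for the small fixtures used in testing.
    """
    coords = structure.protein_heavy_coords()
    cloud = PointCloud(coords)
    result = ResidueDepthMap()

    if method == "exact":
        for res in structure.residues():
            result.depths[res.key] = exact_depth(cloud, res.representative_point())
        return result

    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n_dirs, 3))
    dirs /= np.maximum(np.linalg.norm(dirs, axis=1, keepdims=True), 1e-12)
    proj = coords @ dirs.T  # n_atoms x n_dirs, shared across residues
    scale = max(1.0, float(np.abs(coords).max()))
    for res in structure.residues():
        x = res.representative_point()
        counts = (proj - x @ dirs.T > _EPS * scale).sum(axis=0)
        result.depths[res.key] = int(counts.min())
    return result
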