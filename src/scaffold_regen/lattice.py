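"""Strut-lattice generation, trimming, porosity and mesh export.

A :class:`Lattice` is a straight-strut frame: node coordinates in mm, strut
connectivity, and one radius per strut.  Three generators cover the scaffold
architectures used in the study:

* :func:`generate_octetruss` -- the fully triangulated FCC/octet tiling
  (every strut has length ``unit_cell / sqrt(2)``),
* :func:`generate_cubic` -- an axis-aligned orthogonal grid,
* :func:`generate_stochastic` -- Poisson-disk seeded points wired to a target
  mean connectivity.

Implant geometry is obtained by trimming a block lattice to the implant
cylinder (:func:`trim_to_cylinder`), strut radii are solved against the
design's nominal porosity (:func:`solve_radius_for_porosity`), and the strut
network can be voxelized (:func:`voxelize`) or exported as an STL surface
(:func:`export_mesh`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial import cKDTree
from scipy.stats import qmc

from .designs import Material, ScaffoldDesign

__all__ = [
    "Lattice",
    "Cylinder",
    "Box",
    "DegenerateDomainError",
    "PackingError",
    "CalibrationError",
    "generate_octetruss",
    "generate_cubic",
    "generate_stochastic",
    "trim_to_cylinder",
    "porosity",
    "solve_radius_for_porosity",
    "grade_thickness",
    "voxelize",
    "export_mesh",
    "build_design",
]


class DegenerateDomainError(ValueError):
    """Requested domain cannot hold the requested structure."""


class PackingError(RuntimeError):
    """Poisson-disk sampling or connectivity targeting is infeasible."""


class CalibrationError(RuntimeError):
    """A solve-for-target (porosity or stiffness) cannot be bracketed."""


_MERGE_DECIMALS = 6  # node dedup resolution, 1e-6 mm


# ---------------------------------------------------------------------------
# domains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned (z) cylinder domain."""

    diameter: float
    height: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        return np.pi * self.radius**2 * self.height

    @property
    def zlim(self) -> tuple[float, float]:
        return (self.center[2] - self.height / 2.0,
                self.center[2] + self.height / 2.0)

    def bounds(self) -> np.ndarray:
        c = np.asarray(self.center)
        r = self.radius
        lo = c - (r, r, self.height / 2.0)
        hi = c + (r, r, self.height / 2.0)
        return np.array([lo, hi])

    def contains(self, pts: np.ndarray, eps: float = 1e-9) -> np.ndarray:
        pts = np.atleast_2d(pts)
        cx, cy, cz = self.center
        rad2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
        z0, z1 = self.zlim
        return ((rad2 <= self.radius**2 * (1 + 1e-12) + eps)
                & (pts[:, 2] >= z0 - eps) & (pts[:, 2] <= z1 + eps))


@dataclass(frozen=True)
class Box:
    """Axis-aligned box domain given by (2, 3) bounds."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    @property
    def volume(self) -> float:
        ext = np.subtract(self.hi, self.lo)
        return float(np.prod(ext))

    def bounds(self) -> np.ndarray:
        return np.array([self.lo, self.hi], dtype=float)

    def contains(self, pts: np.ndarray, eps: float = 1e-9) -> np.ndarray:
        pts = np.atleast_2d(pts)
        lo = np.asarray(self.lo) - eps
        hi = np.asarray(self.hi) + eps
        return np.all((pts >= lo) & (pts <= hi), axis=1)


# ---------------------------------------------------------------------------
# Lattice container
# ---------------------------------------------------------------------------

@dataclass
class Lattice:
    """Straight-strut frame: nodes (mm), strut index pairs, per-strut radii.

    Invariants enforced on construction: no self-loop struts, unordered strut
    pairs unique, all radii positive, all indices valid.
    """

    nodes: np.ndarray          # (N, 3) float
    struts: np.ndarray         # (M, 2) int
    radii: np.ndarray          # (M,) float
    material: Material

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.struts = np.asarray(self.struts, dtype=np.int64).reshape(-1, 2)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if self.radii.size == 1 and len(self.struts) > 1:
            self.radii = np.full(len(self.struts), float(self.radii[0]))
        self.validate()

    def validate(self) -> None:
        n, m = len(self.nodes), len(self.struts)
        if len(self.radii) != m:
            raise ValueError("radii length must match strut count")
        if m:
            if self.struts.min() < 0 or self.struts.max() >= n:
                raise ValueError("strut index out of range")
            if np.any(self.struts[:, 0] == self.struts[:, 1]):
                raise ValueError("self-loop strut")
            key = np.sort(self.struts, axis=1)
            if len(np.unique(key, axis=0)) != m:
                raise ValueError("duplicate strut")
            if np.any(self.radii <= 0):
                raise ValueError("non-positive strut radius")

    # -- geometry -----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_struts(self) -> int:
        return len(self.struts)

    def strut_vectors(self) -> np.ndarray:
        return self.nodes[self.struts[:, 1]] - self.nodes[self.struts[:, 0]]

    def strut_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.strut_vectors(), axis=1)

    def total_strut_length(self) -> float:
        return float(self.strut_lengths().sum())

    def bbox(self) -> np.ndarray:
        return np.array([self.nodes.min(axis=0), self.nodes.max(axis=0)])

    def degrees(self) -> np.ndarray:
        return np.bincount(self.struts.ravel(), minlength=self.n_nodes)

    def mean_degree(self) -> float:
        return 2.0 * self.n_struts / self.n_nodes

    def adjacency(self):
        m = self.n_struts
        data = np.ones(2 * m)
        rows = np.concatenate([self.struts[:, 0], self.struts[:, 1]])
        cols = np.concatenate([self.struts[:, 1], self.struts[:, 0]])
        return coo_matrix((data, (rows, cols)),
                          shape=(self.n_nodes, self.n_nodes)).tocsr()

    def n_components(self) -> int:
        if self.n_nodes == 0:
            return 0
        return connected_components(self.adjacency(), directed=False)[0]

    # -- transforms ---------------------------------------------------------
    def with_radii(self, radii) -> "Lattice":
        radii = np.broadcast_to(np.asarray(radii, float),
                                (self.n_struts,)).copy()
        return Lattice(self.nodes.copy(), self.struts.copy(), radii,
                       self.material)

    def rotated(self, rot: np.ndarray) -> "Lattice":
        """Rigidly rotate about the bbox center by 3x3 matrix ``rot``."""
        c = self.bbox().mean(axis=0)
        nodes = (self.nodes - c) @ np.asarray(rot).T + c
        return Lattice(nodes, self.struts.copy(), self.radii.copy(),
                       self.material)

    def translated(self, offset) -> "Lattice":
        return Lattice(self.nodes + np.asarray(offset, float),
                       self.struts.copy(), self.radii.copy(), self.material)


def _dedupe_nodes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge coincident points; returns (unique_points, index_map)."""
    key = np.round(points, _MERGE_DECIMALS)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    # representative coordinates: first occurrence
    first = np.full(len(uniq), -1, dtype=np.int64)
    for i, j in enumerate(inv):
        if first[j] < 0:
            first[j] = i
    return points[first], inv


def _finalize(points, pairs, radii, material) -> Lattice:
    """Dedupe nodes/struts, drop degenerate struts and orphan nodes."""
    points = np.asarray(points, float).reshape(-1, 3)
    pairs = np.asarray(pairs, np.int64).reshape(-1, 2)
    radii = np.asarray(radii, float).reshape(-1)
    uniq, inv = _dedupe_nodes(points)
    pairs = inv[pairs]
    keep = pairs[:, 0] != pairs[:, 1]
    pairs, radii = pairs[keep], radii[keep]
    key = np.sort(pairs, axis=1)
    _, idx = np.unique(key, axis=0, return_index=True)
    idx.sort()
    pairs, radii = key[idx], radii[idx]
    # drop orphan nodes
    used = np.zeros(len(uniq), dtype=bool)
    used[pairs.ravel()] = True
    remap = np.cumsum(used) - 1
    return Lattice(uniq[used], remap[pairs], radii, material)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _check_bbox(bbox, unit_cell: float) -> tuple[np.ndarray, np.ndarray]:
    bbox = np.asarray(bbox, float)
    if bbox.shape == (3,):
        lo, hi = np.zeros(3), bbox
    else:
        lo, hi = bbox[0], bbox[1]
    ext = hi - lo
    if unit_cell <= 0:
        raise ValueError("unit_cell must be positive")
    if np.any(ext < unit_cell * (1 - 1e-9)):
        raise DegenerateDomainError(
            f"bbox extents {ext} smaller than one {unit_cell} mm cell")
    return lo, ext


def generate_octetruss(bbox, unit_cell: float, radius: float,
                       material: Material) -> Lattice:
    """Octet-truss (FCC) tiling of ``bbox``.

    Nodes are the FCC sites (cell corners plus face centers); struts connect
    nearest FCC neighbours, all of length ``unit_cell / sqrt(2)``.  The
    tiling is fully triangulated, so axial strut action dominates in every
    loading direction.
    """
    if radius >= unit_cell / 2:
        raise ValueError("radius must be below unit_cell / 2")
    lo, ext = _check_bbox(bbox, unit_cell)
    n = np.floor(ext / unit_cell + 1e-9).astype(int)
    h = unit_cell / 2.0
    # FCC sites in half-cell units: integer triples with even coordinate sum
    ii, jj, kk = np.meshgrid(np.arange(2 * n[0] + 1),
                             np.arange(2 * n[1] + 1),
                             np.arange(2 * n[2] + 1), indexing="ij")
    pts = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    pts = pts[pts.sum(axis=1) % 2 == 0]
    world = lo + pts * h
    tree = cKDTree(world)
    pairs = np.array(sorted(tree.query_pairs(
        unit_cell / np.sqrt(2) * (1 + 1e-9), output_type="set")))
    if len(pairs) == 0:
        raise DegenerateDomainError("no struts generated")
    return _finalize(world, pairs, np.full(len(pairs), radius), material)


def generate_cubic(bbox, unit_cell: float, radius: float,
                   material: Material) -> Lattice:
    """Orthogonal 3D grid: nodes on a regular lattice, struts axis-aligned."""
    if radius >= unit_cell / 2:
        raise ValueError("radius must be below unit_cell / 2")
    lo, ext = _check_bbox(bbox, unit_cell)
    n = np.floor(ext / unit_cell + 1e-9).astype(int)
    axes = [np.arange(n[d] + 1) * unit_cell + lo[d] for d in range(3)]
    ii, jj, kk = np.meshgrid(*[np.arange(n[d] + 1) for d in range(3)],
                             indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = lo + idx * unit_cell

    def flat(i, j, k):
        return (i * (n[1] + 1) + j) * (n[2] + 1) + k

    pairs = []
    for d, off in enumerate(np.eye(3, dtype=int)):
        src = idx[idx[:, d] < n[d]]
        dst = src + off
        pairs.append(np.stack([flat(*src.T), flat(*dst.T)], axis=1))
    pairs = np.concatenate(pairs)
    return _finalize(world, pairs, np.full(len(pairs), radius), material)


def _poisson_disk_points(lo, ext, n_points: int, seed) -> tuple[np.ndarray, float]:
    """Poisson-disk sample ``n_points`` in the box; returns (points, r_min)."""
    volume = float(np.prod(ext))
    # sphere-packing feasibility: RSA saturates near 0.38 volume fraction for
    # spheres of diameter r_min; use 0.2 for reliable attainment
    r_min = (0.2 * 6.0 * volume / (np.pi * n_points)) ** (1.0 / 3.0)
    side = float(ext.max())
    rng = np.random.default_rng(seed)
    engine = qmc.PoissonDisk(d=3, radius=r_min / side, seed=rng,
                             ncandidates=45)
    # sample the enclosing cube, keep points landing in the box
    want_cube = int(np.ceil(n_points * side**3 / volume * 1.5)) + 8
    unit = engine.random(want_cube)
    pts = lo + unit * side
    inside = np.all((pts >= lo) & (pts <= lo + ext), axis=1)
    pts = pts[inside]
    if len(pts) < n_points:
        raise PackingError(
            f"Poisson-disk sampling placed {len(pts)} < {n_points} points "
            f"(r_min={r_min:.3f} mm)")
    return pts[:n_points], r_min


def generate_stochastic(bbox, n_points: int, target_connectivity: float = 4.5,
                        seed: int | None = 0, material: Material | None = None,
                        radius: float = 0.25) -> Lattice:
    """Stochastic trabecular-like network.

    Points are placed by Poisson-disk sampling (guaranteed minimum pairwise
    distance) and wired to a target mean degree: the minimum spanning tree of
    the k-nearest-neighbour candidate graph guarantees a single connected
    component, then the shortest remaining neighbour edges are added until
    the mean node degree reaches ``target_connectivity`` (within 2/n).
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    if target_connectivity < 3:
        raise ValueError("target_connectivity must be >= 3")
    if material is None:
        from .designs import TITANIUM
        material = TITANIUM
    bbox = np.asarray(bbox, float)
    lo, hi = (np.zeros(3), bbox) if bbox.shape == (3,) else (bbox[0], bbox[1])
    ext = hi - lo
    if target_connectivity > min(n_points - 1, 12):
        # beyond ~12 the wiring is no longer a nearest-neighbour network
        # (trabecular-like coordination is 3-8)
        raise PackingError(
            f"target connectivity {target_connectivity} is outside the "
            "nearest-neighbour wiring regime")

    pts, _ = _poisson_disk_points(lo, ext, n_points, seed)
    n = len(pts)
    m_target = int(np.ceil(target_connectivity * n / 2.0))

    k = min(n - 1, max(8, int(np.ceil(target_connectivity)) + 4))
    tree = cKDTree(pts)
    dist, nbr = tree.query(pts, k=k + 1)
    src = np.repeat(np.arange(n), k)
    dst = nbr[:, 1:].ravel()
    w = dist[:, 1:].ravel()
    a, b = np.minimum(src, dst), np.maximum(src, dst)
    key = a * n + b
    _, first = np.unique(key, return_index=True)
    a, b, w = a[first], b[first], w[first]
    if len(a) < m_target:
        raise PackingError(
            f"candidate graph has {len(a)} edges < {m_target} required for "
            f"mean degree {target_connectivity}")

    graph = coo_matrix((w, (a, b)), shape=(n, n))
    ncomp, _ = connected_components(graph, directed=False)
    if ncomp != 1:
        raise PackingError("k-NN candidate graph is disconnected")
    mst = minimum_spanning_tree(graph).tocoo()
    mst_pairs = {(min(i, j), max(i, j)) for i, j in zip(mst.row, mst.col)}
    order = np.argsort(w, kind="stable")
    pairs = list(mst_pairs)
    for idx in order:
        if len(pairs) >= m_target:
            break
        e = (int(a[idx]), int(b[idx]))
        if e not in mst_pairs:
            pairs.append(e)
    pairs = np.array(sorted(pairs))
    lat = _finalize(pts, pairs, np.full(len(pairs), radius), material)
    if abs(lat.mean_degree() - target_connectivity) > 0.1:
        raise PackingError(
            f"achieved mean degree {lat.mean_degree():.2f} outside "
            f"{target_connectivity} +/- 0.1")
    return lat


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def _clip_segment_cylinder(a, b, cyl: Cylinder) -> tuple[float, float] | None:
    """Parameter interval [t0, t1] of segment a->b inside the cylinder."""
    eps = 1e-9
    d = b - a
    z0, z1 = cyl.zlim
    t_lo, t_hi = 0.0, 1.0
    # z slab
    if abs(d[2]) < 1e-15:
        if not (z0 - eps <= a[2] <= z1 + eps):
            return None
    else:
        ta = (z0 - a[2]) / d[2]
        tb = (z1 - a[2]) / d[2]
        t_lo = max(t_lo, min(ta, tb))
        t_hi = min(t_hi, max(ta, tb))
    # infinite cylinder x^2 + y^2 <= R^2
    cx, cy, _ = cyl.center
    ax, ay = a[0] - cx, a[1] - cy
    dx, dy = d[0], d[1]
    qa = dx * dx + dy * dy
    qb = 2.0 * (ax * dx + ay * dy)
    qc = ax * ax + ay * ay - cyl.radius**2 * (1 + 1e-12)
    if qa < 1e-15:
        if qc > eps:
            return None
    else:
        disc = qb * qb - 4 * qa * qc
        if disc < 0:
            return None
        sq = np.sqrt(disc)
        t_lo = max(t_lo, (-qb - sq) / (2 * qa))
        t_hi = min(t_hi, (-qb + sq) / (2 * qa))
    if t_hi - t_lo < 1e-9:
        return None
    return (t_lo, t_hi)


def trim_to_cylinder(lat: Lattice, diameter: float, height: float,
                     center=(0.0, 0.0, 0.0)) -> Lattice:
    """Clip the lattice to an axis-aligned cylinder.

    Struts wholly outside are removed; boundary-crossing struts are clipped
    at the surface (partial struts are kept, matching the press-fit implant
    surface); orphan nodes are dropped.
    """
    if diameter <= 0 or height <= 0:
        raise DegenerateDomainError("cylinder must have positive size")
    cyl = Cylinder(diameter, height, tuple(center))
    bb = lat.bbox()
    cb = cyl.bounds()
    if np.any(cb[1] < bb[0]) or np.any(cb[0] > bb[1]):
        raise DegenerateDomainError("cylinder does not intersect lattice bbox")
    pts, pairs, radii = [], [], []
    for (i, j), r in zip(lat.struts, lat.radii):
        a, b = lat.nodes[i], lat.nodes[j]
        clip = _clip_segment_cylinder(a, b, cyl)
        if clip is None:
            continue
        t0, t1 = clip
        pa = a if t0 <= 1e-12 else a + t0 * (b - a)
        pb = b if t1 >= 1 - 1e-12 else a + t1 * (b - a)
        pts.extend([pa, pb])
        pairs.append((len(pts) - 2, len(pts) - 1))
        radii.append(r)
    if not pairs:
        raise DegenerateDomainError("cylinder intersects no struts")
    return _finalize(np.array(pts), np.array(pairs), np.array(radii),
                     lat.material)


# ---------------------------------------------------------------------------
# porosity
# ---------------------------------------------------------------------------

def voxelize(lat: Lattice, voxel_size: float,
             domain: Cylinder | Box | None = None,
             pad: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the strut network onto a regular voxel grid.

    Struts are treated as capsules (cylinders with spherical end caps, so
    junctions are filled).  Returns ``(solid, origin)`` where ``solid`` is a
    boolean array and ``origin`` the world position of the (0,0,0) voxel
    corner.  Voxel membership tests the voxel center.
    """
    if domain is None:
        bb = lat.bbox()
        rmax = lat.radii.max() if lat.n_struts else 0.0
        domain = Box(tuple(bb[0] - rmax - pad), tuple(bb[1] + rmax + pad))
    lo, hi = domain.bounds()
    h = float(voxel_size)
    shape = np.maximum(np.ceil((hi - lo) / h - 1e-9).astype(int), 1)
    solid = np.zeros(shape, dtype=bool)
    nodes, struts, radii = lat.nodes, lat.struts, lat.radii
    for (i, j), r in zip(struts, radii):
        a, b = nodes[i], nodes[j]
        smin = np.minimum(a, b) - r - h
        smax = np.maximum(a, b) + r + h
        i0 = np.maximum(np.floor((smin - lo) / h).astype(int), 0)
        i1 = np.minimum(np.ceil((smax - lo) / h).astype(int), shape)
        if np.any(i0 >= i1):
            continue
        xs = lo[0] + (np.arange(i0[0], i1[0]) + 0.5) * h
        ys = lo[1] + (np.arange(i0[1], i1[1]) + 0.5) * h
        zs = lo[2] + (np.arange(i0[2], i1[2]) + 0.5) * h
        wx = (xs - a[0])[:, None, None]
        wy = (ys - a[1])[None, :, None]
        wz = (zs - a[2])[None, None, :]
        d = b - a
        dd = float(d @ d)
        wd = wx * d[0] + wy * d[1] + wz * d[2]
        t = np.clip(wd / dd, 0.0, 1.0) if dd > 1e-18 else 0.0
        dist2 = (wx * wx + wy * wy + wz * wz) - 2.0 * t * wd + t * t * dd
        solid[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= dist2 <= r * r
    return solid, lo


def _domain_mask(domain: Cylinder | Box, origin: np.ndarray, h: float,
                 shape) -> np.ndarray:
    xs = origin[0] + (np.arange(shape[0]) + 0.5) * h
    ys = origin[1] + (np.arange(shape[1]) + 0.5) * h
    zs = origin[2] + (np.arange(shape[2]) + 0.5) * h
    if isinstance(domain, Cylinder):
        cx, cy, _ = domain.center
        r2 = (xs - cx)[:, None] ** 2 + (ys - cy)[None, :] ** 2
        inplane = r2 <= domain.radius**2
        z0, z1 = domain.zlim
        inz = (zs >= z0) & (zs <= z1)
        return inplane[:, :, None] & inz[None, None, :]
    lo, hi = domain.bounds()
    mx = (xs >= lo[0]) & (xs <= hi[0])
    my = (ys >= lo[1]) & (ys <= hi[1])
    mz = (zs >= lo[2]) & (zs <= hi[2])
    return mx[:, None, None] & my[None, :, None] & mz[None, None, :]


def porosity(lat: Lattice, domain: Cylinder | Box, mode: str = "voxel",
             voxel_size: float = 0.05) -> float:
    """Pore fraction of ``domain`` not occupied by struts, in [0, 1].

    ``voxel`` mode counts non-solid voxel centers inside the domain and is
    the authoritative mode.  ``analytic`` sums clipped strut cylinder
    volumes with a coarse junction double-count correction; it is accurate
    for slender struts and is used for bracketing only.
    """
    if domain.volume <= 0:
        raise DegenerateDomainError("domain volume must be positive")
    if lat.n_struts == 0:
        return 1.0
    if mode == "voxel":
        solid, origin = voxelize(lat, voxel_size, domain=domain)
        dmask = _domain_mask(domain, origin, voxel_size, solid.shape)
        n_dom = int(dmask.sum())
        if n_dom == 0:
            raise DegenerateDomainError("domain contains no voxels")
        n_solid = int((solid & dmask).sum())
        return 1.0 - n_solid / n_dom
    if mode == "analytic":
        vol = 0.0
        if isinstance(domain, Cylinder):
            for (i, j), r in zip(lat.struts, lat.radii):
                clip = _clip_segment_cylinder(lat.nodes[i], lat.nodes[j],
                                              domain)
                if clip is None:
                    continue
                t0, t1 = clip
                L = (t1 - t0) * np.linalg.norm(lat.nodes[j] - lat.nodes[i])
                vol += np.pi * r * r * L
        else:
            inside = domain.contains(lat.nodes)
            for (i, j), r in zip(lat.struts, lat.radii):
                # box-clip by slab intersection per axis
                a, b = lat.nodes[i], lat.nodes[j]
                t_lo, t_hi = 0.0, 1.0
                lo, hi = domain.bounds()
                ok = True
                for d in range(3):
                    dd = b[d] - a[d]
                    if abs(dd) < 1e-15:
                        if not (lo[d] - 1e-9 <= a[d] <= hi[d] + 1e-9):
                            ok = False
                            break
                    else:
                        ta = (lo[d] - a[d]) / dd
                        tb = (hi[d] - a[d]) / dd
                        t_lo = max(t_lo, min(ta, tb))
                        t_hi = min(t_hi, max(ta, tb))
                if not ok or t_hi <= t_lo:
                    continue
                L = (t_hi - t_lo) * np.linalg.norm(b - a)
                vol += np.pi * r * r * L
        # junction double-count correction: each strut beyond the first at a
        # node overlaps its siblings near the node by roughly a spherical cap
        deg = lat.degrees()
        rbar = float(lat.radii.mean())
        vol -= (2.0 / 3.0) * np.pi * rbar**3 * np.maximum(deg - 1, 0).sum()
        return float(np.clip(1.0 - vol / domain.volume, 0.0, 1.0))
    raise ValueError(f"unknown porosity mode {mode!r}")


def solve_radius_for_porosity(design: ScaffoldDesign, seed: int | None = 0,
                              voxel_size: float = 0.05, tol: float = 0.002,
                              max_iter: int = 40) -> float:
    """Bisect the uniform strut radius so the trimmed implant cylinder meets
    the design's nominal porosity (|measured - nominal| < ``tol``).

    When the unit cell is commensurate with the voxel grid the measured
    porosity is quantized (whole symmetry orbits of voxels flip together),
    and the staircase can step over the ``tol`` band.  In that case the
    radius whose measured porosity is nearest the target is returned with a
    warning, provided the residual stays within 0.005; otherwise a
    :class:`CalibrationError` is raised.
    """
    target = design.nominal_porosity
    lat0 = _block_lattice(design, radius=0.1, seed=seed)
    lat0 = trim_to_cylinder(lat0, design.cylinder_diameter,
                            design.cylinder_height)
    cyl = Cylinder(design.cylinder_diameter, design.cylinder_height)

    lengths = lat0.strut_lengths()
    r_hi = 0.49 * float(np.median(lengths))
    r_lo = 1e-3

    def measured(r: float) -> float:
        return porosity(lat0.with_radii(r), cyl, mode="voxel",
                        voxel_size=voxel_size)

    p_lo, p_hi = measured(r_lo), measured(r_hi)
    if not (p_hi < target < p_lo):
        raise CalibrationError(
            f"porosity {target} not bracketed by radii "
            f"[{r_lo:.3f}, {r_hi:.3f}] -> [{p_lo:.3f}, {p_hi:.3f}]")
    best_r, best_err = None, np.inf
    for _ in range(max_iter):
        r_mid = 0.5 * (r_lo + r_hi)
        p_mid = measured(r_mid)
        err = abs(p_mid - target)
        if err < best_err:
            best_r, best_err = r_mid, err
        if err < tol:
            return r_mid
        if p_mid > target:   # too porous -> thicken
            r_lo = r_mid
        else:
            r_hi = r_mid
        if r_hi - r_lo < 1e-7:
            break
    if best_r is not None and best_err <= 0.005:
        warnings.warn(
            f"{design.acronym}: voxel-quantized porosity; nearest attainable "
            f"value is {best_err:.4f} from the nominal {target}",
            stacklevel=2)
        return best_r
    raise CalibrationError(
        f"porosity bisection did not converge (best residual {best_err:.4f})")


def grade_thickness(lat: Lattice, target_axial_modulus: float,
                    span: float | None = None, rtol: float = 0.01,
                    max_iter: int = 60) -> Lattice:
    """Scale all strut radii uniformly so the axial apparent modulus matches
    ``target_axial_modulus`` within ``rtol`` relative tolerance.

    A single global radius scale is the default stiffness-grading policy;
    spatially varying grading can be applied afterwards by editing
    ``lattice.radii`` directly.
    """
    from .mechanics import apparent_modulus  # local import: avoid cycle

    def modulus(scale: float) -> float:
        return apparent_modulus(lat.with_radii(lat.radii * scale),
                                np.array([0.0, 0.0, 1.0]), span=span)

    e0 = modulus(1.0)
    if abs(e0 - target_axial_modulus) <= rtol * target_axial_modulus:
        return lat.with_radii(lat.radii)
    s_lo, s_hi = 1.0, 1.0
    e_lo = e_hi = e0
    for _ in range(30):
        if e_lo > target_axial_modulus:
            s_lo *= 0.7
            e_lo = modulus(s_lo)
        elif e_hi < target_axial_modulus:
            s_hi *= 1.4
            e_hi = modulus(s_hi)
        else:
            break
        if s_lo < 0.01 or s_hi > 50:
            raise CalibrationError("target modulus not bracketable")
    for _ in range(max_iter):
        s_mid = np.sqrt(s_lo * s_hi)
        e_mid = modulus(s_mid)
        if abs(e_mid - target_axial_modulus) <= rtol * target_axial_modulus:
            return lat.with_radii(lat.radii * s_mid)
        if e_mid < target_axial_modulus:
            s_lo = s_mid
        else:
            s_hi = s_mid
    raise CalibrationError("thickness grading did not converge")


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def _block_lattice(design: ScaffoldDesign, radius: float,
                   seed: int | None = 0, margin: float = 0.0) -> Lattice:
    """Untrimmed block lattice covering the implant cylinder (+ margin)."""
    d = design.cylinder_diameter + 2 * margin
    h = design.cylinder_height + 2 * margin
    if design.generator == "stochastic":
        vol = d * d * h
        n = max(10, int(round(design.point_density * vol)))
        lat = generate_stochastic(np.array([d, d, h]), n,
                                  design.target_connectivity, seed=seed,
                                  material=design.material, radius=radius)
    else:
        a = design.unit_cell
        n = np.ceil(np.array([d, d, h]) / a).astype(int)
        bbox = n * a
        gen = generate_octetruss if design.generator == "octetruss" \
            else generate_cubic
        lat = gen(bbox, a, radius, design.material)
    # center on the origin
    return lat.translated(-lat.bbox().mean(axis=0))


def build_design(design: ScaffoldDesign, seed: int | None = 0,
                 radius: float | None = None,
                 solve_voxel_size: float = 0.05) -> Lattice:
    """Build a design's implant-cylinder lattice with porosity-solved radii."""
    if radius is None:
        radius = solve_radius_for_porosity(design, seed=seed,
                                           voxel_size=solve_voxel_size)
    lat = _block_lattice(design, radius=radius, seed=seed)
    return trim_to_cylinder(lat, design.cylinder_diameter,
                            design.cylinder_height)


# ---------------------------------------------------------------------------
# mesh export
# ---------------------------------------------------------------------------

def export_mesh(lat: Lattice, path, sections: int = 16) -> Path:
    """Write the strut network as a binary STL (one capped cylinder per
    strut) plus a JSON sidecar recording design metadata.

    Each strut tessellates to ``2 * sections + 2`` vertices.
    """
    import trimesh

    if lat.n_struts == 0:
        raise ValueError("cannot export an empty lattice")
    path = Path(path)
    meshes = []
    for (i, j), r in zip(lat.struts, lat.radii):
        seg = np.array([lat.nodes[i], lat.nodes[j]])
        meshes.append(trimesh.creation.cylinder(radius=r, segment=seg,
                                                sections=sections))
    mesh = trimesh.util.concatenate(meshes)
    mesh.export(path, file_type="stl")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "n_nodes": int(lat.n_nodes),
        "n_struts": int(lat.n_struts),
        "sections": sections,
        "material": lat.material.name,
        "radius_mean_mm": float(lat.radii.mean()),
    }, indent=2))
    return path
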