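"""Vectorizable random lattice (VRL) construction and finite-volume geometry.

The VRL places exactly one node, uniformly at random, in every cell of a
regular ``nx x ny`` reference lattice with spacing ``h``.  Nodes of
face-adjacent cells closer than a per-axis minimum distance are redrawn,
which tunes the lattice between fully random (``d = 0``) and rectangular
(``d = h``).  Linking all natural neighbors (Voronoi cells sharing a face)
gives a Delaunay triangulation whose Voronoi dual, clipped to the domain
rectangle, supplies the finite-volume weights

    w_ij = f_ij / (l_ij * A_i)

with ``f_ij`` the shared-face length, ``l_ij`` the node distance and
``A_i`` the clipped Voronoi-cell area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError, Voronoi

__all__ = [
    "MeshSpec",
    "VRLMesh",
    "NeighborStatistics",
    "draw_nodes",
    "build_vrl",
    "compute_geometry",
    "neighbor_statistics",
    "build_mesh",
    "mesh_from_nodes",
    "adjacency_violations",
]

_MAX_SWEEPS = 100_000


@dataclass(frozen=True)
class MeshSpec:
    """Parameters of the reference lattice and the node-drawing rule.

    The domain is the rectangle ``[0, nx*h] x [0, ny*h]``.
    """

    nx: int = 100
    ny: int = 100
    h: float = 1.0
    d_x: float | None = None  # default 0.5*h, see __post_init__
    d_y: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_x is None:
            object.__setattr__(self, "d_x", 0.5 * self.h)
        if self.d_y is None:
            object.__setattr__(self, "d_y", 0.5 * self.h)
        if self.nx < 3 or self.ny < 3 or self.nx * self.ny < 9:
            raise ValueError("reference lattice must have nx, ny >= 3")
        if self.h <= 0:
            raise ValueError("h must be positive")
        for name, d in (("d_x", self.d_x), ("d_y", self.d_y)):
            if not 0 <= d <= self.h:
                raise ValueError(f"{name} must lie in [0, h]")

    @property
    def domain(self) -> tuple[float, float]:
        """Width and height of the rectangular domain."""
        return self.nx * self.h, self.ny * self.h

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny


@dataclass
class VRLMesh:
    """A VRL with (optionally) its finite-volume geometry attached.

    Nodes are stored in reference-lattice row-major order: the node of cell
    ``(i, j)`` (column ``i``, row ``j``) has index ``j*nx + i``.

    Attributes
    ----------
    nodes : (N, 2) float array of node coordinates.
    cell_index : (N, 2) int array, the (i, j) reference cell of each node.
    edges : (E, 2) int array of natural-neighbor pairs, ``i < j`` per row.
    f : (E,) shared Voronoi-face lengths (geometry stage).
    l : (E,) Euclidean node distances.
    A : (N,) clipped Voronoi-cell areas.
    boundary : (N,) bool, True where the Voronoi cell touches the domain
        boundary.
    """

    spec: MeshSpec
    nodes: np.ndarray
    cell_index: np.ndarray
    edges: np.ndarray
    f: np.ndarray | None = None
    l: np.ndarray | None = None
    A: np.ndarray | None = None
    boundary: np.ndarray | None = None
    _neighbors: list[np.ndarray] | None = field(default=None, repr=False)
    _edge_cache: tuple | None = field(default=None, repr=False)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cached (i, j, f/l) contiguous per-edge arrays for the hot paths."""
        if self._edge_cache is None:
            self._require_geometry()
            i = np.ascontiguousarray(self.edges[:, 0])
            j = np.ascontiguousarray(self.edges[:, 1])
            self._edge_cache = (i, j, self.f / self.l)
        return self._edge_cache

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def has_geometry(self) -> bool:
        return self.A is not None

    def weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Directed finite-volume weights ``(w_ij, w_ji)`` per edge row.

        ``w_ij = f/(l*A_i)`` multiplies fluxes into the first endpoint,
        ``w_ji = f/(l*A_j)`` into the second.
        """
        self._require_geometry()
        fl = self.f / self.l
        i, j = self.edges[:, 0], self.edges[:, 1]
        return fl / self.A[i], fl / self.A[j]

    def neighbor_lists(self) -> list[np.ndarray]:
        """Per-node arrays of natural-neighbor indices (cached)."""
        if self._neighbors is None:
            nbr: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for a, b in self.edges:
                nbr[a].append(b)
                nbr[b].append(a)
            self._neighbors = [np.asarray(v, dtype=np.int64) for v in nbr]
        return self._neighbors

    def _require_geometry(self) -> None:
        if not self.has_geometry:
            raise ValueError("mesh geometry not computed; call compute_geometry")


@dataclass(frozen=True)
class NeighborStatistics:
    """Interior-node adjacency statistics of a VRL."""

    n_interior: int
    mean_neighbors: float
    long_bond_fraction: float
    long_bond_cutoff: float
    shell_bond_probability: dict[int, float]
    other_shell_fraction: float

    def to_dict(self) -> dict:
        return {
            "n_interior": self.n_interior,
            "mean_neighbors": self.mean_neighbors,
            "long_bond_cutoff_h": self.long_bond_cutoff,
            "long_bond_fraction": self.long_bond_fraction,
            "shell_bond_probability": {
                str(k): v for k, v in self.shell_bond_probability.items()
            },
            "other_shell_fraction": self.other_shell_fraction,
        }


def _cell_offsets(spec: MeshSpec, rng: np.random.Generator, count: int) -> np.ndarray:
    return rng.uniform(0.0, spec.h, size=(count, 2))


def adjacency_violations(nodes: np.ndarray, spec: MeshSpec) -> np.ndarray:
    """Mask of nodes violating the minimum-distance rule with a face neighbor.

    A pair of cells adjacent along axis x (resp. y) violates the rule when
    the Euclidean distance between their nodes is below ``d_x`` (``d_y``).
    Both members of a violating pair are flagged.
    """
    nx, ny = spec.nx, spec.ny
    pos = nodes.reshape(ny, nx, 2)
    bad = np.zeros((ny, nx), dtype=bool)
    # x-adjacent pairs
    dx = np.linalg.norm(pos[:, 1:, :] - pos[:, :-1, :], axis=-1)
    vx = dx < spec.d_x
    bad[:, 1:] |= vx
    bad[:, :-1] |= vx
    # y-adjacent pairs
    dy = np.linalg.norm(pos[1:, :, :] - pos[:-1, :, :], axis=-1)
    vy = dy < spec.d_y
    bad[1:, :] |= vy
    bad[:-1, :] |= vy
    return bad.reshape(-1)


def draw_nodes(
    spec: MeshSpec,
    rng: np.random.Generator | None = None,
    max_sweeps: int = _MAX_SWEEPS,
) -> np.ndarray:
    """Draw one node uniformly in each reference cell, enforcing minimum
    distances between nodes of face-adjacent cells by redrawing both members
    of every violating pair until a sweep is clean.

    Deterministic for a given ``spec.seed`` when ``rng`` is not supplied.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    nx, ny = spec.nx, spec.ny
    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    corners = np.stack([ii.ravel() * spec.h, jj.ravel() * spec.h], axis=1).astype(float)
    nodes = corners + _cell_offsets(spec, rng, nx * ny)
    if spec.d_x == 0 and spec.d_y == 0:
        return nodes
    for _ in range(max_sweeps):
        bad = adjacency_violations(nodes, spec)
        if not bad.any():
            return nodes
        nodes[bad] = corners[bad] + _cell_offsets(spec, rng, int(bad.sum()))
    raise RuntimeError(
        f"minimum-distance redraw did not terminate within {max_sweeps} sweeps "
        f"(d_x={spec.d_x}, d_y={spec.d_y}, h={spec.h})"
    )


def cell_index_grid(spec: MeshSpec) -> np.ndarray:
    jj, ii = np.meshgrid(np.arange(spec.ny), np.arange(spec.nx), indexing="ij")
    return np.stack([ii.ravel(), jj.ravel()], axis=1)


def build_vrl(
    nodes: np.ndarray, spec: MeshSpec, rng: np.random.Generator | None = None
) -> VRLMesh:
    """Link all natural-neighbor pairs: the edge set is the Delaunay edge set.

    Exactly degenerate (cocircular) configurations are resolved by a seeded
    relative jitter of 1e-9*h and a rebuild.
    """
    nodes = np.asarray(nodes, dtype=float)
    if rng is None:
        rng = np.random.default_rng(spec.seed + 0x9E3779B9)
    for attempt in range(5):
        try:
            tri = Delaunay(nodes)
            break
        except QhullError:
            nodes = nodes + rng.normal(scale=1e-9 * spec.h, size=nodes.shape)
    else:  # pragma: no cover - Qhull handles near-degeneracy robustly
        raise RuntimeError("Delaunay triangulation failed after jitter retries")
    edges = _edges_from_simplices(tri.simplices)
    return VRLMesh(spec=spec, nodes=nodes, cell_index=cell_index_grid(spec), edges=edges)


def _edges_from_simplices(simplices: np.ndarray) -> np.ndarray:
    e = np.vstack(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [2, 0]]]
    )
    e.sort(axis=1)
    return np.unique(e, axis=0)


def _mirror_points(nodes: np.ndarray, Lx: float, Ly: float) -> np.ndarray:
    """Reflect all nodes across the four domain walls.

    The Voronoi diagram of the augmented set restricted to the original
    nodes is exactly the clipped-to-rectangle Voronoi partition: each wall
    is the perpendicular bisector between a node and its mirror image.
    """
    left = nodes * [-1, 1]
    right = nodes * [-1, 1] + [2 * Lx, 0]
    bottom = nodes * [1, -1]
    top = nodes * [1, -1] + [0, 2 * Ly]
    return np.vstack([nodes, left, right, bottom, top])


def compute_geometry(mesh: VRLMesh) -> VRLMesh:
    """Populate clipped Voronoi areas, face lengths, distances and flags.

    Edges whose shared face is entirely clipped away by the domain boundary
    are removed.  Mutates and returns ``mesh``.
    """
    spec = mesh.spec
    Lx, Ly = spec.domain
    N = mesh.n_nodes
    pts = _mirror_points(mesh.nodes, Lx, Ly)
    vor = Voronoi(pts)

    A = np.zeros(N)
    for idx in range(N):
        region = vor.regions[vor.point_region[idx]]
        if -1 in region or len(region) < 3:  # pragma: no cover - impossible w/ mirrors
            raise RuntimeError(f"unbounded Voronoi cell for node {idx}")
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        A[idx] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    if np.any(A <= 0):  # pragma: no cover
        raise RuntimeError("zero-area Voronoi cell encountered")

    boundary = np.zeros(N, dtype=bool)
    edge_map: dict[tuple[int, int], float] = {}
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        p_real, q_real = p < N, q < N
        if not (p_real or q_real):
            continue
        if -1 in rv:  # pragma: no cover - mirrored set has finite ridges
            continue
        seg = vor.vertices[rv]
        flen = float(np.linalg.norm(seg[1] - seg[0]))
        if p_real and q_real:
            if flen > 1e-12 * spec.h:
                key = (min(p, q), max(p, q))
                edge_map[key] = edge_map.get(key, 0.0) + flen
        elif flen > 1e-12 * spec.h:
            boundary[p if p_real else q] = True

    edges = np.array(sorted(edge_map), dtype=np.int64).reshape(-1, 2)
    f = np.array([edge_map[tuple(e)] for e in edges])
    l = np.linalg.norm(mesh.nodes[edges[:, 0]] - mesh.nodes[edges[:, 1]], axis=1)

    mesh.edges = edges
    mesh.f = f
    mesh.l = l
    mesh.A = A
    mesh.boundary = boundary
    mesh._neighbors = None
    return mesh


def build_mesh(spec: MeshSpec) -> VRLMesh:
    """Draw nodes, triangulate and compute the full finite-volume geometry."""
    nodes = draw_nodes(spec)
    mesh = build_vrl(nodes, spec)
    return compute_geometry(mesh)


def mesh_from_nodes(nodes: np.ndarray, spec: MeshSpec) -> VRLMesh:
    """Build a complete mesh from explicitly supplied node positions.

    Used for the rectangular limit (cell-center nodes), which rejection
    sampling at ``d = h`` cannot produce in finite time.
    """
    mesh = build_vrl(np.asarray(nodes, dtype=float), spec)
    return compute_geometry(mesh)


def rectangular_mesh(spec: MeshSpec) -> VRLMesh:
    """The ``d = h`` limit: nodes at the reference-cell centers."""
    cells = cell_index_grid(spec)
    nodes = (cells + 0.5) * spec.h
    return mesh_from_nodes(nodes, spec)


def neighbor_statistics(mesh: VRLMesh, long_bond_cutoff: float = 4.0) -> NeighborStatistics:
    """Adjacency statistics over interior nodes (boundary cells excluded to
    avoid clipping bias).

    Returns the mean neighbor count, the fraction of interior nodes with at
    least one natural neighbor farther than ``long_bond_cutoff * h``, and
    per-shell bond probabilities keyed by reference-cell offset shell:
    shell 1 = (±1,0)/(0,±1); shell 2 = (±1,±1); shell 3 = (±2,0)/(0,±2);
    shell 4 = (±1,±2); shell 5 = (±2,±2).
    """
    mesh._require_geometry()
    spec = mesh.spec
    interior = ~mesh.boundary
    n_int = int(interior.sum())
    if n_int < 100:
        warnings.warn(
            f"only {n_int} interior nodes; neighbor statistics are unreliable",
            stacklevel=2,
        )
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]

    deg = np.bincount(i, minlength=mesh.n_nodes) + np.bincount(j, minlength=mesh.n_nodes)
    mean_neighbors = float(deg[interior].mean()) if n_int else float("nan")

    is_long = mesh.l > long_bond_cutoff * spec.h
    has_long = np.zeros(mesh.n_nodes, dtype=bool)
    has_long[i[is_long]] = True
    has_long[j[is_long]] = True
    long_fraction = float(has_long[interior].mean()) if n_int else float("nan")

    # bond probability per cell-offset shell, over pairs with both nodes interior
    both_int = interior[i] & interior[j]
    off = np.abs(mesh.cell_index[i] - mesh.cell_index[j])
    off = np.sort(off, axis=1)  # (min, max) of |di|, |dj|
    shells = {1: (0, 1), 2: (1, 1), 3: (0, 2), 4: (1, 2), 5: (2, 2)}
    shell_prob: dict[int, float] = {}
    n_bonded_classified = 0
    for s, (a, b) in shells.items():
        bonded = int(np.sum(both_int & (off[:, 0] == a) & (off[:, 1] == b)))
        n_bonded_classified += bonded
        total = _n_interior_pairs_at_offset(mesh, (a, b))
        shell_prob[s] = bonded / total if total else float("nan")
    other = int(both_int.sum()) - n_bonded_classified
    other_fraction = other / int(both_int.sum()) if both_int.any() else 0.0

    return NeighborStatistics(
        n_interior=n_int,
        mean_neighbors=mean_neighbors,
        long_bond_fraction=long_fraction,
        long_bond_cutoff=long_bond_cutoff,
        shell_bond_probability=shell_prob,
        other_shell_fraction=other_fraction,
    )


def _n_interior_pairs_at_offset(mesh: VRLMesh, off: tuple[int, int]) -> int:
    """Count unordered interior-node cell pairs at |offset| = (a, b), a<=b,
    including both orientations when a != b and signed diagonal variants."""
    spec = mesh.spec
    interior = (~mesh.boundary).reshape(spec.ny, spec.nx)
    a, b = off
    offsets: set[tuple[int, int]] = set()
    for di, dj in ((a, b), (b, a)):
        offsets.update({(di, dj), (di, -dj)})
    # deduplicate antiparallel directions: each unordered pair counted once
    uniq: list[tuple[int, int]] = []
    for d in offsets:
        if (-d[0], -d[1]) not in uniq:
            uniq.append(d)
    count = 0
    for di, dj in uniq:
        if di == 0 and dj == 0:
            continue
        s0 = interior[max(0, -dj):spec.ny - max(0, dj), max(0, -di):spec.nx - max(0, di)]
        s1 = interior[max(0, dj):spec.ny - max(0, -dj), max(0, di):spec.nx - max(0, -di)]
        count += int(np.sum(s0 & s1))
    return count
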