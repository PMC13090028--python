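"""Graph-embedded cortical surfaces.

A :class:`SurfaceGraph` is the package's stand-in for a cortical surface
mesh: vertices with spatial coordinates plus an undirected edge set that
defines adjacency for cluster statistics. Searchlight neighborhoods are
built from the coordinates; TFCE connected components from the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull

from .errors import ConfigurationError

__all__ = ["SurfaceGraph", "generate_surface_graph"]


@dataclass(frozen=True)
class SurfaceGraph:
    """Vertices embedded in 2- or 3-space with an undirected edge set.

    Parameters
    ----------
    coords : (n_vertices, ndim) float array
        Vertex coordinates in arbitrary distance units.
    edges : (n_edges, 2) int array
        Undirected edges as vertex-index pairs; no self-loops or duplicates.
    vertex_ids : (n_vertices,) int array, optional
        External identifiers; defaults to ``0..n-1``.
    """

    coords: np.ndarray
    edges: np.ndarray
    vertex_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise ConfigurationError("coords must be (n_vertices, 2|3)")
        if not np.all(np.isfinite(coords)):
            raise ConfigurationError("coords must be finite")
        n = coords.shape[0]
        if np.any(edges < 0) or np.any(edges >= n):
            raise ConfigurationError("edge endpoint out of range")
        if np.any(edges[:, 0] == edges[:, 1]):
            raise ConfigurationError("self-loops are not allowed")
        canon = np.sort(edges, axis=1)
        if len({(int(a), int(b)) for a, b in canon}) != len(canon):
            raise ConfigurationError("duplicate edges are not allowed")
        vids = self.vertex_ids
        vids = np.arange(n) if vids is None else np.asarray(vids, dtype=np.intp)
        if vids.shape != (n,) or len(np.unique(vids)) != n:
            raise ConfigurationError("vertex_ids must be unique, one per vertex")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "edges", canon)
        object.__setattr__(self, "vertex_ids", vids)
        if not self.is_connected():
            raise ConfigurationError("surface graph must be connected")

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric boolean adjacency matrix (CSR)."""
        n = self.n_vertices
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(len(i), dtype=np.int8)
        a = sparse.coo_matrix((data, (i, j)), shape=(n, n))
        return (a + a.T).tocsr()

    def is_connected(self) -> bool:
        if self.n_vertices == 1:
            return True
        n_comp, _ = connected_components(self.adjacency(), directed=False)
        return n_comp == 1


def _grid_shape(n: int) -> tuple[int, int]:
    rows = int(np.floor(np.sqrt(n)))
    while rows > 1 and n % rows:
        rows -= 1
    if rows <= 1:
        raise ConfigurationError(
            f"cannot factor n_vertices={n} into a 2-D lattice; use a composite count"
        )
    return rows, n // rows


def generate_surface_graph(
    n_vertices: int, topology: str = "grid", seed: int | None = None
) -> SurfaceGraph:
    """Build a connected synthetic surface.

    ``grid`` lays vertices on an r x c integer lattice (r*c = n_vertices)
    with 4-neighborhood edges. ``icosphere`` scatters points on the unit
    sphere (seeded) and takes convex-hull triangulation edges, giving an
    irregular closed mesh closer in spirit to a cortical surface.
    """
    if n_vertices < 9:
        raise ConfigurationError("n_vertices must be >= 9")
    if topology == "grid":
        rows, cols = _grid_shape(n_vertices)
        ys, xs = np.divmod(np.arange(n_vertices), cols)
        coords = np.column_stack([xs, ys]).astype(float)
        edges = []
        for v in range(n_vertices):
            if xs[v] + 1 < cols:
                edges.append((v, v + 1))
            if ys[v] + 1 < rows:
                edges.append((v, v + cols))
        return SurfaceGraph(coords, np.array(edges))
    if topology == "icosphere":
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((n_vertices, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        hull = ConvexHull(pts)
        edge_set = set()
        for simplex in hull.simplices:
            for a, b in ((0, 1), (1, 2), (0, 2)):
                i, j = sorted((int(simplex[a]), int(simplex[b])))
                edge_set.add((i, j))
        return SurfaceGraph(pts, np.array(sorted(edge_set)))
    raise ConfigurationError(f"unknown topology {topology!r}")
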