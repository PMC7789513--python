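"""Areal contiguity and intrinsic CAR (ICAR) machinery.

The adjacency matrix W is binary and symmetric with a zero diagonal:
``w_ij = 1`` when areas i and j are neighbours.  The ICAR prior puts, for
each area, a conditional Gaussian centred at the mean of its neighbours'
values with variance ``sigma2 / m_i`` where ``m_i`` is the neighbour count.
The joint prior is improper (the graph Laplacian ``Q = diag(m) - W`` is
rank N-1 on a connected graph); every ICAR-distributed vector is identified
by a sum-to-zero constraint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AdjacencyStructure",
    "IslandError",
    "adjacency_from_edges",
    "adjacency_from_polygons",
    "icar_full_conditional",
    "sample_icar",
    "icar_pairwise_quadform",
]


class IslandError(ValueError):
    """An area has no neighbours (or the graph is disconnected)."""


def _connected_components(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    labels = np.full(n, -1, dtype=np.int64)
    comp = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = comp
        while stack:
            i = stack.pop()
            for j in np.nonzero(W[i])[0]:
                if labels[j] < 0:
                    labels[j] = comp
                    stack.append(j)
        comp += 1
    return labels


@dataclass(frozen=True)
class AdjacencyStructure:
    """Symmetric binary contiguity structure over N ordered areas."""

    area_ids: tuple
    W: np.ndarray = field(repr=False)

    def __post_init__(self):
        W = np.asarray(self.W, dtype=np.float64)
        object.__setattr__(self, "area_ids", tuple(self.area_ids))
        n = len(self.area_ids)
        if W.shape != (n, n):
            raise ValueError(f"W must be ({n}, {n}), got {W.shape}")
        if not np.array_equal(W, W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("W diagonal must be zero")
        if not np.isin(W, (0.0, 1.0)).all():
            raise ValueError("W entries must be binary")
        object.__setattr__(self, "W", W)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def neighbor_counts(self) -> np.ndarray:
        """m_i = row sums of W."""
        return self.W.sum(axis=1)

    @property
    def component_labels(self) -> np.ndarray:
        return _connected_components(self.W)

    @property
    def laplacian(self) -> np.ndarray:
        """Q = diag(m) - W; the ICAR precision structure."""
        return np.diag(self.neighbor_counts) - self.W

    def is_connected(self) -> bool:
        return self.component_labels.max() == 0

    def neighbors_of(self, i: int) -> np.ndarray:
        return np.nonzero(self.W[i])[0]

    # -- WinBUGS-style adjacency lists ------------------------------------

    def to_winbugs(self) -> dict:
        """Export as the ``num`` / ``adj`` / ``sumNumNeigh`` arrays (1-based)."""
        num = self.neighbor_counts.astype(int)
        adj = [int(j) + 1 for i in range(self.n_areas) for j in self.neighbors_of(i)]
        return {"num": num.tolist(), "adj": adj, "sumNumNeigh": int(num.sum())}

    @classmethod
    def from_winbugs(cls, num, adj, area_ids=None) -> "AdjacencyStructure":
        num = list(num)
        n = len(num)
        if sum(num) != len(adj):
            raise ValueError("sum(num) must equal len(adj)")
        if area_ids is None:
            area_ids = [f"a{i + 1:03d}" for i in range(n)]
        W = np.zeros((n, n))
        pos = 0
        for i, m in enumerate(num):
            for j in adj[pos : pos + m]:
                W[i, int(j) - 1] = 1.0
            pos += m
        return cls(area_ids=tuple(area_ids), W=W)

    def save_winbugs(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_winbugs(), fh)


def adjacency_from_edges(area_ids, edges, allow_islands: bool = False) -> AdjacencyStructure:
    """Build W from an undirected edge list of area-id pairs.

    Edges are symmetrized and duplicates collapsed; self-loops and unknown
    ids are errors.  Areas without any neighbour raise :class:`IslandError`
    unless ``allow_islands`` is set.
    """
    ids = tuple(str(a) for a in area_ids)
    index = {a: k for k, a in enumerate(ids)}
    if len(index) != len(ids):
        raise ValueError("duplicate area ids")
    n = len(ids)
    W = np.zeros((n, n))
    for a, b in edges:
        a, b = str(a), str(b)
        if a == b:
            raise ValueError(f"self-loop edge ({a}, {b})")
        if a not in index or b not in index:
            raise ValueError(f"edge references unknown area id: ({a}, {b})")
        W[index[a], index[b]] = 1.0
        W[index[b], index[a]] = 1.0
    adj = AdjacencyStructure(area_ids=ids, W=W)
    _check_islands(adj, allow_islands)
    return adj


def adjacency_from_polygons(
    geometries: dict, contiguity: str = "queen", allow_islands: bool = False
) -> AdjacencyStructure:
    """Contiguity matrix from a mapping of area id -> shapely (multi)polygon.

    Queen contiguity (default) marks any pair of polygons sharing at least a
    boundary point as neighbours; rook requires a shared boundary segment of
    positive length.
    """
    from shapely.geometry.base import BaseGeometry
    from shapely.strtree import STRtree

    if contiguity not in ("queen", "rook"):
        raise ValueError("contiguity must be 'queen' or 'rook'")
    ids = tuple(sorted(str(a) for a in geometries))
    geoms = []
    for a in ids:
        g = geometries[str(a)] if str(a) in geometries else geometries[a]
        if not isinstance(g, BaseGeometry) or g.is_empty or not g.is_valid:
            raise ValueError(f"invalid geometry for area {a}")
        geoms.append(g)
    n = len(ids)
    W = np.zeros((n, n))
    tree = STRtree(geoms)
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(geoms[j])
            if inter.is_empty:
                continue
            if contiguity == "queen" or inter.length > 0:
                W[i, j] = W[j, i] = 1.0
    adj = AdjacencyStructure(area_ids=ids, W=W)
    _check_islands(adj, allow_islands)
    return adj


def read_geojson(path, id_property: str = "area_id") -> dict:
    """Load a GeoJSON FeatureCollection into {area_id: shapely geometry}."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    out = {}
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if id_property not in props:
            raise ValueError(f"feature missing {id_property!r} property")
        out[str(props[id_property])] = shape(feat["geometry"])
    if len(out) != len(gj["features"]):
        raise ValueError(f"duplicate {id_property!r} values in FeatureCollection")
    return out


def read_edge_csv(path) -> list:
    """Edge-list CSV with columns ``from_id,to_id``."""
    import pandas as pd

    df = pd.read_csv(path)
    return [(str(a), str(b)) for a, b in zip(df["from_id"], df["to_id"])]


def _check_islands(adj: AdjacencyStructure, allow_islands: bool) -> None:
    if allow_islands:
        return
    m = adj.neighbor_counts
    if np.any(m == 0):
        i = int(np.argmax(m == 0))
        raise IslandError(
            f"area {adj.area_ids[i]} has no neighbours; pass allow_islands=True to keep it"
        )


def icar_full_conditional(x, i: int, adj: AdjacencyStructure, sigma2: float):
    """Conditional mean and variance of x_i under the ICAR prior.

    mean = average of the neighbours' values; variance = sigma2 / m_i.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    x = np.asarray(x, dtype=np.float64)
    nbrs = adj.neighbors_of(i)
    if nbrs.size == 0:
        raise IslandError(f"area {adj.area_ids[i]} has no neighbours")
    return float(x[nbrs].mean()), float(sigma2 / nbrs.size)


def _icar_eigenbasis(adj: AdjacencyStructure):
    """Eigendecomposition of the Laplacian restricted to the non-null space."""
    lam, V = np.linalg.eigh(adj.laplacian)
    # connected graph: exactly one (near-)zero eigenvalue
    return lam[1:], V[:, 1:]


def sample_icar(
    adj: AdjacencyStructure, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw from the sum-to-zero-constrained ICAR distribution.

    Places independent Gaussian mass ``sigma2 / lambda_k`` on each non-null
    eigenvector of the Laplacian; the draw sums to zero by construction
    (re-centred against floating-point drift).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not adj.is_connected():
        raise IslandError(
            "graph is disconnected: the ICAR prior needs a per-component "
            "sum-to-zero constraint; split the map or connect the components"
        )
    lam, V = _icar_eigenbasis(adj)
    z = rng.standard_normal(lam.size)
    x = V @ (z * np.sqrt(sigma2 / lam))
    return x - x.mean()


def icar_pairwise_quadform(x, adj: AdjacencyStructure) -> float:
    """x' Q x, equal to (1/2) * sum_ij w_ij (x_i - x_j)^2."""
    x = np.asarray(x, dtype=np.float64)
    return float(x @ (adj.laplacian @ x))
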