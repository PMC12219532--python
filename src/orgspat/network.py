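"""Centroid interaction networks and nearest-neighbour randomness testing.

Organelle centroids become nodes of an undirected radius graph: two nodes
are connected when their Euclidean distance is at most ``radius_nm``
(default 500 nm, ties at exactly the radius are edges).  Connected
components of this graph are "communities", size-classed as isolated (1),
1to3 (2-3 nodes), 4to10 (4-10) and 10+ (11 or more).

`nn_csr_test` compares the observed mean nearest-neighbour distance of a
point pattern against complete spatial randomness (CSR).  The expected CSR
mean is the Clark-Evans value 0.5/sqrt(lambda) with intensity lambda =
n/area, area being the axis-aligned bounding box
(max_x - min_x) * (max_y - min_y) of the observed points; no edge
correction is applied.  The ratio R = observed/expected flags clustering
(R < 1) or dispersion (R > 1), and a z-score is obtained by Monte Carlo:
``n_sims`` patterns of n uniform points in the same bounding box give the
null mean and standard deviation of the pattern-level mean NN distance.
|z| <= 2 is conventionally read as compatible with randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from orgspat.defaults import DEFAULT_CSR_N_SIMS, DEFAULT_NETWORK_RADIUS_NM


@dataclass
class NodeNetwork:
    """Radius graph over organelle centroids.

    ``graph`` is a networkx Graph whose nodes are object ids with
    ``cls`` (class or contact-class label) and ``pos`` (x_nm, y_nm)
    attributes.
    """

    graph: nx.Graph
    radius_nm: float = DEFAULT_NETWORK_RADIUS_NM

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(nodes: pd.DataFrame, radius_nm: float = DEFAULT_NETWORK_RADIUS_NM) -> NodeNetwork:
    """Connect all node pairs within ``radius_nm`` of each other.

    ``nodes`` needs columns id, class, x_nm, y_nm.  A KD-tree accelerates
    the search; the edge set equals all-pairs thresholding with ties at the
    radius included.
    """
    required = {"id", "class", "x_nm", "y_nm"}
    if not required.issubset(nodes.columns):
        raise ValueError(f"nodes table needs columns {sorted(required)}")
    if len(nodes) == 0:
        raise ValueError("need at least one node")
    g = nx.Graph()
    ids = nodes["id"].to_numpy()
    xy = nodes[["x_nm", "y_nm"]].to_numpy(dtype=float)
    for i, row in nodes.iterrows():
        g.add_node(row["id"], cls=row["class"], pos=(float(row["x_nm"]), float(row["y_nm"])))
    if len(nodes) > 1:
        tree = cKDTree(xy)
        pairs = tree.query_pairs(r=radius_nm, output_type="ndarray")
        for i, j in pairs:
            g.add_edge(ids[i], ids[j])
    return NodeNetwork(graph=g, radius_nm=radius_nm)


def _size_class(size: int) -> str:
    if size == 1:
        return "isolated"
    if size <= 3:
        return "1to3"
    if size <= 10:
        return "4to10"
    return "10+"


def communities(network: NodeNetwork) -> pd.DataFrame:
    """Connected components with community size classes.

    Returns one row per node: (id, community, community_size, size_class).
    Size classes: isolated (1), 1to3 (2-3), 4to10 (4-10), 10+ (>= 11).
    """
    rows = []
    comps = sorted(nx.connected_components(network.graph), key=lambda c: sorted(map(str, c)))
    for cid, comp in enumerate(comps, start=1):
        size = len(comp)
        for node in sorted(comp, key=str):
            rows.append(
                {
                    "id": node,
                    "community": cid,
                    "community_size": size,
                    "size_class": _size_class(size),
                }
            )
    return pd.DataFrame(rows, columns=["id", "community", "community_size", "size_class"])


def connectivity_fraction(network: NodeNetwork) -> float:
    """Fraction of nodes with at least one neighbour."""
    n = network.n_nodes
    if n == 0:
        raise ValueError("empty network")
    connected = sum(1 for _, d in network.graph.degree if d >= 1)
    return connected / n


def first_neighbor_proportions(network: NodeNetwork) -> pd.DataFrame:
    """Per source class, the proportion of nodes with >= 1 neighbour of each class.

    Rows are source classes, columns target classes.  A node with neighbours
    of several classes counts toward each, so rows need not sum to 1.
    """
    classes = sorted({d["cls"] for _, d in network.graph.nodes(data=True)})
    counts = {src: {tgt: 0 for tgt in classes} for src in classes}
    totals = {src: 0 for src in classes}
    for node, data in network.graph.nodes(data=True):
        src = data["cls"]
        totals[src] += 1
        neighbor_classes = {network.graph.nodes[nb]["cls"] for nb in network.graph[node]}
        for tgt in neighbor_classes:
            counts[src][tgt] += 1
    table = pd.DataFrame(
        {tgt: [counts[src][tgt] / totals[src] for src in classes] for tgt in classes},
        index=pd.Index(classes, name="source_class"),
    )
    return table


@dataclass
class CSRResult:
    """Nearest-neighbour randomness statistics for one point pattern."""

    n: int
    area_nm2: float
    observed_mean_nn: float
    expected_mean_nn: float
    R: float
    z: float
    sim_mean: float
    sim_sd: float
    n_sims: int
    seed: int | None


def _mean_nn(points: np.ndarray) -> float:
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(d[:, 1].mean())


def nn_csr_test(
    points,
    n_sims: int = DEFAULT_CSR_N_SIMS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CSRResult:
    """Monte-Carlo nearest-neighbour test of complete spatial randomness.

    ``points`` is an (n, 2) array of coordinates in nm, n >= 3.  The
    bounding box of the observed pattern defines both the Clark-Evans
    expectation and the simulation window (the observed box is reused for
    every replicate).  Deterministic under a fixed ``seed``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points")
    mins = pts.min(axis=0)
    maxs = pts.max(axis=0)
    extent = maxs - mins
    area = float(extent[0] * extent[1])
    if area <= 0:
        raise ValueError("degenerate (zero-area) bounding box")
    observed = _mean_nn(pts)
    expected = 0.5 / np.sqrt(n / area)
    if rng is None:
        rng = np.random.default_rng(seed)
    sims = np.empty(n_sims)
    for i in range(n_sims):
        sim_pts = mins + rng.random((n, 2)) * extent
        sims[i] = _mean_nn(sim_pts)
    sim_mean = float(sims.mean())
    sim_sd = float(sims.std(ddof=1))
    z = (observed - sim_mean) / sim_sd if sim_sd > 0 else float("inf")
    return CSRResult(
        n=n,
        area_nm2=area,
        observed_mean_nn=observed,
        expected_mean_nn=float(expected),
        R=float(observed / expected),
        z=float(z),
        sim_mean=sim_mean,
        sim_sd=sim_sd,
        n_sims=n_sims,
        seed=seed,
    )
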