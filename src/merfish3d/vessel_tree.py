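"""Vascular tree reconstruction from marker-selected cells.

Coronary vessel cells are selected as the top fraction (3% by default)
of cells by smooth-muscle marker expression (MYH11), density-filtered,
then clustered per tissue section with DBSCAN (eps 50 μm, min_samples 5,
noise excluded).  Each cluster is one vessel cross-section node.  The
tree is built top-down: each node connects to the visited node with the
lowest connection loss

    L_total = w * L_angle + (1 - w) * L_euc,        w = 0.5

where ``L_angle = 1 - arccos(cos θ)/π`` measures how far the candidate
parent's own parent, the candidate, and the current node deviate from a
straight line (0 for collinear continuation, 0.5 for a right angle, 1
for a reversal), and ``L_euc`` is the squared centroid distance.  As
printed the two terms live on different scales (μm² vs [0, 1]), so
``L_euc`` is normalized over each node's candidate set before mixing.
The default normalization is *relative*: ``d²/d²_min - 1``, zero for
the nearest candidate and growing in units of the nearest squared
distance, which keeps the distance term decisive against section-
skipping jumps while letting the angle term arbitrate between near-
equidistant candidates (as at a bifurcation); min-max rescaling to
[0, 1] and raw squared-μm units are available as alternatives.  Same-
section connections are disallowed and parents must lie in strictly
higher (earlier) sections; manual edges override the loss where vessels
locally violate the top-down assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

__all__ = [
    "VesselNode",
    "VesselTree",
    "select_marker_cells",
    "cluster_sections",
    "angle_loss",
    "connection_loss",
    "build_tree",
    "extract_paths",
]

DBSCAN_EPS_UM = 50.0
DBSCAN_MIN_SAMPLES = 5
TOP_FRACTION = 0.03
LOSS_WEIGHT = 0.5


@dataclass
class VesselNode:
    """One vessel cross-section: a per-section cluster of marker cells."""

    node_id: int
    section: int
    centroid: np.ndarray  # (x, y, z) μm, unweighted mean of member positions
    member_cells: list[int]
    parent: int | None = None


@dataclass
class VesselTree:
    nodes: dict[int, VesselNode]
    w: float = LOSS_WEIGHT
    manual_edges: list[tuple[int, int]] = field(default_factory=list)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes.values():
            g.add_node(n.node_id, section=n.section, centroid=n.centroid,
                       n_cells=len(n.member_cells))
        for n in self.nodes.values():
            if n.parent is not None:
                g.add_edge(n.parent, n.node_id)
        return g

    def validate(self) -> None:
        """Assert the forest invariants; raises AssertionError on violation."""
        g = self.to_graph()
        assert nx.is_forest(g.to_undirected()) or g.number_of_edges() == 0, (
            "vessel tree contains a cycle"
        )
        for child, deg in g.in_degree():
            assert deg <= 1, f"node {child} has multiple parents"
        for parent, child in g.edges():
            ps, cs = self.nodes[parent].section, self.nodes[child].section
            assert ps < cs, (
                f"edge {parent}->{child} is not top-down ({ps} !< {cs})"
            )

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        for n in sorted(self.nodes.values(), key=lambda v: v.node_id):
            rows.append(
                {
                    "child": n.node_id,
                    "parent": -1 if n.parent is None else n.parent,
                    "section": n.section,
                    "x": n.centroid[0],
                    "y": n.centroid[1],
                    "z": n.centroid[2],
                    "n_cells": len(n.member_cells),
                }
            )
        return pd.DataFrame(rows)


def select_marker_cells(
    cells: pd.DataFrame, gene: str = "MYH11", top_fraction: float = TOP_FRACTION
) -> pd.DataFrame:
    """Cells at or above the (1 - top_fraction) expression quantile.

    Ties straddling the cutoff are all included, so the returned count
    can exceed ``top_fraction * n``.  ``top_fraction=1`` returns all
    cells.
    """
    if gene not in cells.columns:
        raise KeyError(f"gene {gene!r} not present in the cell table")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    expr = cells[gene].to_numpy(dtype=float)
    cutoff = np.quantile(expr, 1.0 - top_fraction)
    return cells[expr >= cutoff]


def cluster_sections(
    cells: pd.DataFrame,
    eps: float = DBSCAN_EPS_UM,
    min_samples: int = DBSCAN_MIN_SAMPLES,
) -> dict[int, VesselNode]:
    """DBSCAN per section on in-plane (x, y) μm coordinates.

    Noise points (DBSCAN label -1) are excluded; each remaining cluster
    becomes a :class:`VesselNode` whose centroid is the unweighted mean
    of its member cell positions.
    """
    nodes: dict[int, VesselNode] = {}
    next_id = 0
    for section in sorted(cells["section"].unique()):
        sec = cells[cells["section"] == section]
        if len(sec) == 0:
            continue
        xy = sec[["x", "y"]].to_numpy(dtype=float)
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(xy)
        for lab in sorted(set(labels) - {-1}):
            members = sec[labels == lab]
            centroid = members[["x", "y", "z"]].to_numpy(dtype=float).mean(axis=0)
            nodes[next_id] = VesselNode(
                node_id=next_id,
                section=int(section),
                centroid=centroid,
                member_cells=members["cell_id"].tolist(),
            )
            next_id += 1
    return nodes


def angle_loss(current: np.ndarray, candidate: np.ndarray,
               candidate_parent: np.ndarray | None) -> float:
    """Straightness penalty in [0, 1] across three consecutive nodes.

    Uses the angle at the candidate between the directions to the current
    node and to the candidate's own parent: collinear continuation
    (parent and current on opposite sides) gives cos θ = -1 -> loss 0; a
    right angle gives 0.5; a reversal gives 1.  A parentless candidate
    has no angle term (returns None upstream); coincident centroids are
    treated as orthogonal (0.5).
    """
    u = np.asarray(current, float) - np.asarray(candidate, float)
    if candidate_parent is None:
        raise ValueError("candidate has no parent; omit the angle term")
    v = np.asarray(candidate_parent, float) - np.asarray(candidate, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        return 0.5
    cos = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return 1.0 - np.arccos(cos) / np.pi


def _euc_normalizer(d2_candidates: list[float], mode: str):
    """Normalization of the squared-distance term over one candidate set."""
    lo, hi = min(d2_candidates), max(d2_candidates)
    if mode == "relative":
        return lambda d2: d2 / lo - 1.0 if lo > 0 else d2
    if mode == "minmax":
        return lambda d2: (d2 - lo) / (hi - lo) if hi > lo else 0.0
    if mode == "raw":
        return lambda d2: d2
    raise ValueError("euc_norm must be 'relative', 'minmax' or 'raw'")


def connection_loss(
    current: VesselNode,
    candidate: VesselNode,
    nodes: dict[int, VesselNode],
    w: float = LOSS_WEIGHT,
    *,
    euc_transform=None,
) -> float:
    """Total connection loss of attaching ``current`` under ``candidate``.

    ``euc_transform`` maps the squared centroid distance (μm²) onto the
    scale mixed with the angle term (see :func:`_euc_normalizer`); None
    uses raw squared-μm units as printed.
    """
    if candidate.section >= current.section:
        raise ValueError("candidate must lie in a strictly higher layer")
    d2 = float(np.sum((candidate.centroid - current.centroid) ** 2))
    l_euc = euc_transform(d2) if euc_transform is not None else d2
    if candidate.parent is None:
        return (1 - w) * l_euc
    parent_centroid = nodes[candidate.parent].centroid
    l_angle = angle_loss(current.centroid, candidate.centroid, parent_centroid)
    return w * l_angle + (1 - w) * l_euc


def build_tree(
    nodes: dict[int, VesselNode],
    w: float = LOSS_WEIGHT,
    manual_edges: list[tuple[int, int]] | None = None,
    *,
    euc_norm: str = "relative",
    max_parent_distance: float | None = None,
) -> VesselTree:
    """Top-down minimum-loss tree construction.

    All nodes of the topmost (lowest-index) nonempty section are roots.
    Subsequent sections are processed in order; within a section nodes
    are visited by descending member count then node id, and each is
    attached to the visited node with the lowest connection loss (same-
    section connections disallowed).  Manual ``(child, parent)`` edges
    override the loss; ``max_parent_distance`` (μm) optionally prunes
    implausibly long candidate links.
    """
    nodes = {k: VesselNode(v.node_id, v.section, np.asarray(v.centroid, float),
                           list(v.member_cells)) for k, v in nodes.items()}
    manual = dict()
    for child, parent in manual_edges or []:
        if child not in nodes or parent not in nodes:
            raise KeyError(f"manual edge ({child}, {parent}) references unknown node")
        manual[child] = parent
    sections = sorted({n.section for n in nodes.values()})
    if not sections:
        return VesselTree(nodes={}, w=w, manual_edges=list(manual.items()))
    visited: list[int] = []
    for si, section in enumerate(sections):
        layer = [n for n in nodes.values() if n.section == section]
        layer.sort(key=lambda n: (-len(n.member_cells), n.node_id))
        for node in layer:
            if node.node_id in manual:
                parent = manual[node.node_id]
                if nodes[parent].section >= node.section:
                    raise ValueError(
                        f"manual edge ({node.node_id}, {parent}) is not top-down"
                    )
                node.parent = parent
            elif si > 0 and visited:
                candidates = [nodes[i] for i in visited
                              if nodes[i].section < node.section]
                if max_parent_distance is not None:
                    candidates = [
                        c for c in candidates
                        if np.linalg.norm(c.centroid - node.centroid)
                        <= max_parent_distance
                    ] or candidates
                d2 = [float(np.sum((c.centroid - node.centroid) ** 2))
                      for c in candidates]
                transform = _euc_normalizer(d2, euc_norm)
                losses = [
                    connection_loss(node, c, nodes, w, euc_transform=transform)
                    for c in candidates
                ]
                node.parent = candidates[int(np.argmin(losses))].node_id
            visited.append(node.node_id)
    tree = VesselTree(nodes=nodes, w=w, manual_edges=list(manual.items()))
    tree.validate()
    return tree


def extract_paths(tree: VesselTree, longest: int | None = None) -> list[pd.DataFrame]:
    """Root-to-leaf polylines with monotone arc-length positions.

    Each leaf yields one path; rows carry node id, section, centroid and
    cumulative arc length.  ``longest`` keeps only the k longest paths by
    arc length.
    """
    g = tree.to_graph()
    roots = [n for n, d in g.in_degree() if d == 0]
    leaves = [n for n, d in g.out_degree() if d == 0]
    paths = []
    for leaf in leaves:
        chain = [leaf]
        while tree.nodes[chain[-1]].parent is not None:
            chain.append(tree.nodes[chain[-1]].parent)
        chain.reverse()
        if chain[0] not in roots:
            continue
        centroids = np.array([tree.nodes[i].centroid for i in chain])
        seg = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        paths.append(
            pd.DataFrame(
                {
                    "node_id": chain,
                    "section": [tree.nodes[i].section for i in chain],
                    "x": centroids[:, 0],
                    "y": centroids[:, 1],
                    "z": centroids[:, 2],
                    "arc_length": arc,
                }
            )
        )
    paths.sort(key=lambda p: -p["arc_length"].iloc[-1])
    if longest is not None:
        paths = paths[:longest]
    return paths
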