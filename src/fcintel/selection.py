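"""Connection-selection schemes as explicit edge masks with provenance.

Five families of selections over the edge set of an atlas:

(i)   whole brain — every edge;
(ii)  within-network — both endpoints in one network (7 masks);
(iii) between-network — one endpoint in each of two networks (21 masks);
(iv)  all-but-one-network — every edge not touching one network (7 masks);
(v)   network-all — every edge touching one network (7 masks);

plus theory-driven node selections (nearest node to each proposed cluster
coordinate), random-edge and random-node null selections, and data-driven
top-k selections from a relevance ranking. For 7 networks, families
(i)-(v) give exactly 1 + 7 + 21 + 7 + 7 = 43 selections.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .connectome import NodeAtlas, EdgeIndex

logger = logging.getLogger(__name__)

__all__ = ["ConnectionSelection", "n_connections", "whole_brain",
           "within_network_edges", "between_network_edges",
           "exclude_network_edges", "network_all_edges",
           "enumerate_network_selections", "theory_selection",
           "random_edge_selection", "random_node_selection",
           "top_k_selection"]


@dataclass(frozen=True)
class ConnectionSelection:
    """Boolean edge mask plus the provenance string that determines it."""

    mask: np.ndarray
    provenance: str

    def __post_init__(self):
        object.__setattr__(self, "mask",
                           np.asarray(self.mask, dtype=bool))

    @property
    def k(self) -> int:
        """Number of selected edges."""
        return int(self.mask.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def to_json(self) -> str:
        return json.dumps({"provenance": self.provenance,
                           "n_edges": len(self.mask),
                           "indices": self.indices.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "ConnectionSelection":
        d = json.loads(text)
        mask = np.zeros(d["n_edges"], dtype=bool)
        mask[d["indices"]] = True
        return cls(mask=mask, provenance=d["provenance"])


def n_connections(n_nodes: int) -> int:
    """Number of undirected edges among ``n_nodes``: n(n-1)/2."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return n_nodes * (n_nodes - 1) // 2


def _node_mask_to_edges(ei: EdgeIndex, nodes_a: np.ndarray,
                        nodes_b: np.ndarray | None = None) -> np.ndarray:
    rows, cols = ei.pairs()
    in_a = np.zeros(ei.n_nodes, bool)
    in_a[nodes_a] = True
    if nodes_b is None:
        return in_a[rows] & in_a[cols]
    in_b = np.zeros(ei.n_nodes, bool)
    in_b[nodes_b] = True
    return (in_a[rows] & in_b[cols]) | (in_b[rows] & in_a[cols])


def whole_brain(atlas: NodeAtlas) -> ConnectionSelection:
    ei = EdgeIndex(atlas.n_nodes)
    return ConnectionSelection(np.ones(ei.n_edges, bool), "whole_brain")


def within_network_edges(net: str, atlas: NodeAtlas) -> ConnectionSelection:
    """Edges with both endpoints in ``net`` (m member nodes -> m(m-1)/2)."""
    ei = EdgeIndex(atlas.n_nodes)
    mask = _node_mask_to_edges(ei, atlas.nodes_in(net))
    return ConnectionSelection(mask, f"within:{net}")


def between_network_edges(a: str, b: str,
                          atlas: NodeAtlas) -> ConnectionSelection:
    """Edges with one endpoint in each network (sizes p, q -> p*q edges)."""
    if a == b:
        raise ValueError("between-network selection needs two distinct labels")
    ei = EdgeIndex(atlas.n_nodes)
    mask = _node_mask_to_edges(ei, atlas.nodes_in(a), atlas.nodes_in(b))
    first, second = sorted([a, b])
    return ConnectionSelection(mask, f"between:{first}-{second}")


def exclude_network_edges(net: str, atlas: NodeAtlas) -> ConnectionSelection:
    """All edges not touching ``net`` (whole brain minus network-all)."""
    ei = EdgeIndex(atlas.n_nodes)
    rows, cols = ei.pairs()
    in_net = np.zeros(atlas.n_nodes, bool)
    in_net[atlas.nodes_in(net)] = True
    mask = ~(in_net[rows] | in_net[cols])
    return ConnectionSelection(mask, f"exclude:{net}")


def network_all_edges(net: str, atlas: NodeAtlas) -> ConnectionSelection:
    """Edges within ``net`` plus edges between it and every other network."""
    ei = EdgeIndex(atlas.n_nodes)
    rows, cols = ei.pairs()
    in_net = np.zeros(atlas.n_nodes, bool)
    in_net[atlas.nodes_in(net)] = True
    mask = in_net[rows] | in_net[cols]
    return ConnectionSelection(mask, f"network_all:{net}")


def enumerate_network_selections(atlas: NodeAtlas) -> list[ConnectionSelection]:
    """All network-based selections: whole brain, within, between,
    all-but-one, and network-all. For m networks this yields
    1 + m + C(m,2) + m + m masks (43 for the canonical seven)."""
    if any(lab is None or lab == "" for lab in atlas.networks):
        raise ValueError("every node must carry a network label")
    nets = atlas.network_names
    out = [whole_brain(atlas)]
    out += [within_network_edges(n, atlas) for n in nets]
    out += [between_network_edges(a, b, atlas)
            for a, b in combinations(nets, 2)]
    out += [exclude_network_edges(n, atlas) for n in nets]
    out += [network_all_edges(n, atlas) for n in nets]
    return out


def theory_selection(coordinates: np.ndarray, atlas: NodeAtlas,
                     name: str = "theory") -> ConnectionSelection:
    """Edges among the atlas nodes nearest to theory-proposed clusters.

    For each coordinate the node with the smallest Euclidean centroid
    distance is selected (deduplicated; distance ties resolved by lowest
    node id, logged). The mask contains all edges among selected nodes.
    """
    coords = np.atleast_2d(np.asarray(coordinates, float))
    if coords.size == 0 or coords.shape[1] != 3:
        raise ValueError("need a non-empty list of 3-vectors (mm)")
    if atlas.centroids is None:
        raise ValueError("atlas has no centroids")
    nodes = []
    for c in coords:
        d = np.linalg.norm(atlas.centroids - c, axis=1)
        best = d.min()
        ties = np.flatnonzero(d <= best + 1e-12)
        if len(ties) > 1:
            logger.info("theory_selection: distance tie at %s resolved to "
                        "node %d", c, ties[0])
        nodes.append(ties[0])
    nodes = np.unique(nodes)
    ei = EdgeIndex(atlas.n_nodes)
    mask = _node_mask_to_edges(ei, nodes)
    return ConnectionSelection(mask, f"theory:{name}")


def random_edge_selection(k: int, n_edges: int,
                          seed: int) -> ConnectionSelection:
    """``k`` edges sampled uniformly without replacement."""
    if not 0 < k <= n_edges:
        raise ValueError(f"k={k} out of range (1..{n_edges})")
    rng = np.random.default_rng(seed)
    mask = np.zeros(n_edges, bool)
    mask[rng.choice(n_edges, size=k, replace=False)] = True
    return ConnectionSelection(mask, f"random_edges:{k}:{seed}")


def random_node_selection(m: int, atlas: NodeAtlas,
                          seed: int) -> ConnectionSelection:
    """All C(m,2) edges among ``m`` uniformly sampled nodes."""
    if not 2 <= m <= atlas.n_nodes:
        raise ValueError(f"m={m} out of range (2..{atlas.n_nodes})")
    rng = np.random.default_rng(seed)
    nodes = rng.choice(atlas.n_nodes, size=m, replace=False)
    ei = EdgeIndex(atlas.n_nodes)
    mask = _node_mask_to_edges(ei, nodes)
    return ConnectionSelection(mask, f"random_nodes:{m}:{seed}")


def top_k_selection(relevance: np.ndarray, k: int, source: str = "lrp",
                    signed: bool = False) -> ConnectionSelection:
    """The ``k`` most relevant edges.

    Ranking is by absolute relevance by default (``signed=True`` ranks by
    the raw value); ties are broken by edge index (stable sort, logged).
    """
    rel = np.asarray(relevance, float)
    finite = np.isfinite(rel)
    if k > finite.sum():
        raise ValueError("k exceeds edges with finite relevance")
    key = rel if signed else np.abs(rel)
    key = np.where(finite, key, -np.inf)
    order = np.argsort(-key, kind="stable")
    top = order[:k]
    if k < len(rel) and key[order[k - 1]] == key[order[k]]:
        logger.info("top_k_selection: tie at rank %d broken by edge index", k)
    mask = np.zeros(len(rel), bool)
    mask[top] = True
    return ConnectionSelection(mask, f"top_relevant:{k}:{source}")
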