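"""Rooted neurite trees with branch-order labels.

A :class:`NeuriteTree` is a rooted geometric tree stored as a directed
``networkx`` graph whose edges point away from the soma.  Nodes carry a
micrometre position and a role (``root``/``branch``/``tip``/``path``);
edges carry an arclength, a branch order (1 = primary, 2 = secondary,
3 = tertiary, higher orders are overflow) and optionally the full polyline
they trace.

Branch-order semantics: a primary neurite is a maximal path leaving the
soma; each side path leaving a primary is one secondary neurite; side paths
off secondaries are tertiary.  At a branch point exactly one child edge
*continues* the parent neurite (keeps its order); the remaining children
start neurites of order + 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["NeuriteTree", "neurite_paths"]


@dataclass
class NeuriteTree:
    """Rooted neurite arbor.

    ``graph`` is a ``networkx.DiGraph`` with edges oriented away from
    ``root``.  Node attributes: ``pos`` (x, y[, z]) in µm, ``role``.
    Edge attributes: ``length_um``, ``order`` (int), optional ``points``
    (polyline in µm).
    """

    graph: nx.DiGraph
    root: int

    def validate(self) -> None:
        g = self.graph
        if self.root not in g:
            raise ValueError("root is not a node of the graph")
        und = g.to_undirected(as_view=True)
        if g.number_of_nodes() > 1 and not nx.is_connected(und):
            raise ValueError("tree graph is disconnected")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("tree graph has a cycle")
        for n in g:
            if n != self.root and g.in_degree(n) != 1:
                raise ValueError(f"node {n} has in-degree {g.in_degree(n)}")

    # -- structure queries -------------------------------------------------
    def tips(self) -> list[int]:
        """Degree-1 non-root nodes (terminal endings)."""
        return [
            n
            for n in self.graph
            if n != self.root and self.graph.out_degree(n) == 0
        ]

    def node_pos(self, n: int) -> np.ndarray:
        return np.asarray(self.graph.nodes[n]["pos"], dtype=float)

    def total_length(self) -> float:
        return float(
            sum(d["length_um"] for _, _, d in self.graph.edges(data=True))
        )

    def polylines(self) -> list[np.ndarray]:
        """Per-edge polylines (µm); straight chords where none is stored."""
        out = []
        for u, v, d in self.graph.edges(data=True):
            pts = d.get("points")
            if pts is None:
                pts = np.vstack([self.node_pos(u), self.node_pos(v)])
            out.append(np.asarray(pts, dtype=float))
        return out

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        nodes = [
            {
                "id": int(n),
                "pos": [float(c) for c in self.graph.nodes[n]["pos"]],
                "role": self.graph.nodes[n].get("role", "path"),
            }
            for n in self.graph
        ]
        edges = [
            {
                "source": int(u),
                "target": int(v),
                "length_um": float(d["length_um"]),
                "order": int(d["order"]),
                "points": np.asarray(d["points"]).tolist()
                if d.get("points") is not None
                else None,
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return json.dumps({"root": int(self.root), "nodes": nodes, "edges": edges})

    @classmethod
    def from_json(cls, text: str) -> "NeuriteTree":
        rec = json.loads(text)
        g = nx.DiGraph()
        for n in rec["nodes"]:
            g.add_node(n["id"], pos=tuple(n["pos"]), role=n.get("role", "path"))
        for e in rec["edges"]:
            pts = np.asarray(e["points"], dtype=float) if e.get("points") else None
            g.add_edge(
                e["source"],
                e["target"],
                length_um=e["length_um"],
                order=e["order"],
                points=pts,
            )
        return cls(graph=g, root=rec["root"])

    def to_swc(self) -> str:
        """SWC text (id, type, x, y, z, radius, parent); radius fixed at 1."""
        order = list(nx.dfs_preorder_nodes(self.graph, self.root))
        swc_id = {n: i + 1 for i, n in enumerate(order)}
        lines = []
        for n in order:
            pos = self.node_pos(n)
            x, y = float(pos[0]), float(pos[1])
            z = float(pos[2]) if len(pos) > 2 else 0.0
            preds = list(self.graph.predecessors(n))
            parent = swc_id[preds[0]] if preds else -1
            stype = 1 if n == self.root else 3
            lines.append(f"{swc_id[n]} {stype} {x:.3f} {y:.3f} {z:.3f} 1.0 {parent}")
        return "\n".join(lines) + "\n"


def neurite_paths(tree: NeuriteTree) -> list[dict]:
    """Decompose a labeled tree into individual neurites.

    Follows the continuation rule: starting from each root-incident edge, a
    neurite extends through successive edges of the same order; a child edge
    whose order differs from its parent's starts a new neurite.  Returns one
    record per neurite: ``{"order", "length_um", "edges"}``.
    """
    g = tree.graph
    paths: list[dict] = []

    def follow(u: int, v: int) -> None:
        k = g.edges[u, v]["order"]
        length = g.edges[u, v]["length_um"]
        edges = [(u, v)]
        node = v
        while True:
            children = list(g.successors(node))
            same = [w for w in children if g.edges[node, w]["order"] == k]
            new = [w for w in children if g.edges[node, w]["order"] != k]
            for w in new:
                follow(node, w)
            if not same:
                break
            cont, extra = same[0], same[1:]
            for w in extra:  # defensive: only one continuation is expected
                follow(node, w)
            length += g.edges[node, cont]["length_um"]
            edges.append((node, cont))
            node = cont
        paths.append({"order": k, "length_um": float(length), "edges": edges})

    for v in g.successors(tree.root):
        follow(tree.root, v)
    return paths
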