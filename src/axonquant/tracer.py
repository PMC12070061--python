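"""Automated neurite tracing and branch-order morphometry.

Replaces manual tracing of single labeled neurons: the channel is
thresholded, the seeded connected component is skeletonized, the skeleton
becomes a geometric graph (spurs pruned, loops broken at the dimmest
pixel), the graph is rooted at the soma seed, and each edge is assigned a
branch order.  At a branch point the parent neurite *continues* into the
child that minimizes the turning angle — the way a human tracer follows
"the" neurite through a branch — and the remaining children start neurites
of the next order.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

from .core import ImageScene, max_projection
from .geometry import polyline_length
from .trees import NeuriteTree, neurite_paths

__all__ = ["NeuriteTree", "trace_neuron", "branch_order_metrics"]

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _pixel_graph(skel: np.ndarray) -> nx.Graph:
    coords = np.argwhere(skel)
    g = nx.Graph()
    index = {tuple(rc): True for rc in coords}
    for r, c in coords:
        g.add_node((r, c))
        for dr, dc in _N8:
            nb = (r + dr, c + dc)
            if nb in index:
                g.add_edge((r, c), nb)
    # 8-connected skeletons contain spurious triangles at diagonal steps;
    # drop the diagonal edge of any triangle so chains stay 1-px wide
    for u, v in list(g.edges()):
        if abs(u[0] - v[0]) + abs(u[1] - v[1]) == 2:  # diagonal
            common = set(g[u]) & set(g[v])
            if common:
                g.remove_edge(u, v)
    return g


def _break_loops(g: nx.Graph, intensity: np.ndarray) -> None:
    """Remove one edge per cycle, adjacent to the cycle's dimmest pixel."""
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        nodes = [e[0] for e in cycle]
        dimmest = min(nodes, key=lambda rc: intensity[rc])
        for u, v in cycle:
            if dimmest in (u, v):
                g.remove_edge(u, v)
                break


def _contract(g: nx.Graph) -> nx.Graph:
    """Collapse degree-2 chains of a pixel tree into path-carrying edges."""
    h = nx.Graph()
    junctions = [n for n in g if g.degree(n) != 2]
    if not junctions:  # a bare chain or single pixel
        nodes = list(g.nodes)
        if len(nodes) <= 1:
            h.add_nodes_from(nodes)
            return h
        junctions = [nodes[0]]
    seen = set()
    for j in junctions:
        for nb in list(g[j]):
            if frozenset((j, nb)) in seen:
                continue
            path = [j, nb]
            seen.add(frozenset((j, nb)))
            prev, cur = j, nb
            while g.degree(cur) == 2:
                nxt = next(n for n in g[cur] if n != prev)
                if frozenset((cur, nxt)) in seen:
                    break
                seen.add(frozenset((cur, nxt)))
                path.append(nxt)
                prev, cur = cur, nxt
            if path[0] != path[-1]:
                h.add_edge(path[0], path[-1], path=path)
    h.add_nodes_from(j for j in junctions if j not in h)
    return h


def _prune_spurs(h: nx.Graph, spur_len_px: float) -> nx.Graph:
    """Iteratively drop short leaf chains that hang off junctions."""
    changed = True
    while changed:
        changed = False
        for n in [n for n in h if h.degree(n) == 1]:
            (nb,) = h[n]
            if h.degree(nb) < 3:
                continue
            if len(h.edges[n, nb]["path"]) - 1 < spur_len_px:
                h.remove_node(n)
                changed = True
        # re-merge pass-through nodes created by pruning
        for n in [n for n in h if h.degree(n) == 2]:
            a, b = h[n]
            if a == b or h.has_edge(a, b):
                continue
            pa = h.edges[n, a]["path"]
            pb = h.edges[n, b]["path"]
            if pa[0] != n:
                pa = pa[::-1]
            if pb[0] != n:
                pb = pb[::-1]
            h.add_edge(a, b, path=pa[::-1] + pb[1:])
            h.remove_node(n)
            changed = True
    return h


def _decimate_um(path, pixel_size_um: float, every: int = 4) -> np.ndarray:
    """Pixel chain -> µm polyline, decimated to tame staircase length bias."""
    idx = list(range(0, len(path) - 1, every)) + [len(path) - 1]
    pts = np.array([(path[i][1], path[i][0]) for i in idx], dtype=float)
    return pts * pixel_size_um


def _edge_dir(
    points: np.ndarray, at_end: bool, skip_um: float = 2.5, span_um: float = 9.0
) -> np.ndarray:
    """Unit travel direction of a polyline near one end.

    ``at_end=True``: direction of arrival at the last point;
    ``at_end=False``: direction of departure from the first point.  The
    chord is taken over arclengths ``[skip_um, span_um]`` from that end:
    skeleton geometry within a stroke width of a junction is distorted by
    the filled wedge there, so the first couple of µm are excluded.
    """
    pts = points[::-1] if at_end else points
    s = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])
    total = s[-1]
    if total <= 0:
        return np.array([1.0, 0.0])
    skip = min(skip_um, 0.25 * total)
    span = min(span_um, total)
    i0 = int(np.searchsorted(s, skip))
    i1 = int(np.searchsorted(s, span))
    i1 = max(i1, i0 + 1)
    i1 = min(i1, len(pts) - 1)
    i0 = min(i0, i1 - 1)
    v = pts[i1] - pts[i0]
    if at_end:
        v = -v
    n = np.hypot(*v)
    return v / n if n > 0 else np.array([1.0, 0.0])


def _chord_dir(points: np.ndarray, at_end: bool, span_um: float = 14.0) -> np.ndarray:
    """Unit chord direction over up to ``span_um`` of arclength from one end.

    Junction wedges distort skeleton geometry over most of a stroke-merge
    zone; a long chord anchored at the junction dilutes that distortion, so
    this is the estimator used when comparing turning angles at a branch.
    """
    pts = points[::-1] if at_end else points
    s = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])
    i1 = min(int(np.searchsorted(s, span_um)), len(pts) - 1)
    i1 = max(i1, 1)
    v = pts[i1] - pts[0]
    if at_end:
        v = -v
    n = np.hypot(*v)
    return v / n if n > 0 else np.array([1.0, 0.0])


def trace_neuron(
    scene: ImageScene,
    channel: str,
    soma_seed: tuple[float, float],
    threshold: float | None = None,
    spur_len_px: float = 5.0,
    soma_radius_um: float = 0.0,
    root_snap_um: float = 5.0,
) -> NeuriteTree:
    """Trace one neuron into a rooted, order-labeled tree.

    ``soma_seed`` is in µm and must lie in a suprathreshold region.  Stacks
    are max-projected before tracing.  Only the seeded connected component
    is traced; other suprathreshold components trigger a warning.  Edges
    fully inside ``soma_radius_um`` of the root are left unordered
    (order 0): neurites begin at the soma boundary.
    """
    from skimage.filters import threshold_otsu
    from skimage.morphology import skeletonize

    img = max_projection(scene, channel).astype(float)
    px = scene.pixel_size_um
    if threshold is None:
        if img.max() == img.min():
            raise ValueError(f"blank channel: no signal at seed {soma_seed}")
        threshold = float(threshold_otsu(img))
    mask = img > threshold
    seed_rc = (int(round(soma_seed[1] / px)), int(round(soma_seed[0] / px)))
    if not (
        0 <= seed_rc[0] < img.shape[0] and 0 <= seed_rc[1] < img.shape[1]
    ) or not mask[seed_rc]:
        raise ValueError(f"soma seed {soma_seed} lies in background")
    lab, n = ndi.label(mask, structure=np.ones((3, 3)))
    if n > 1:
        warnings.warn(
            f"{n} suprathreshold components; tracing only the seeded one",
            stacklevel=2,
        )
    mask = lab == lab[seed_rc]
    skel = skeletonize(mask)
    if not skel.any():
        raise ValueError("skeletonization produced no pixels")
    g = _pixel_graph(skel)
    _break_loops(g, img)
    h = _contract(g)
    h = _prune_spurs(h, spur_len_px)
    if h.number_of_edges() == 0:
        raise ValueError("no skeleton structure left after pruning")

    # root at the skeleton point nearest the seed; a graph node (junction or
    # endpoint) within the snap radius wins over a mid-chain pixel, since the
    # soma junction is displaced by up to a stroke width in the rendering
    nodes = np.array(list(h.nodes))
    dn = cdist([seed_rc], nodes)[0]
    if dn.min() * px <= root_snap_um:
        root_rc = tuple(nodes[int(np.argmin(dn))])
    else:
        skel_pts = np.array([rc for e in h.edges for rc in h.edges[e]["path"]])
        d = cdist([seed_rc], skel_pts)[0]
        root_rc = tuple(skel_pts[int(np.argmin(d))])
    if root_rc not in h:
        for u, v in list(h.edges):
            path = h.edges[u, v]["path"]
            if root_rc in path[1:-1]:
                i = path.index(root_rc)
                h.remove_edge(u, v)
                h.add_edge(u, root_rc, path=path[: i + 1])
                h.add_edge(root_rc, v, path=path[i:])
                break

    t = nx.DiGraph()
    order_nodes = {root_rc: 0}
    t.add_node(0, pos=tuple(np.array([root_rc[1], root_rc[0]]) * px), role="root")
    next_id = 1
    for u, v in nx.bfs_edges(h, root_rc):
        path = h.edges[u, v]["path"]
        if path[0] != u:
            path = path[::-1]
        pts = _decimate_um(path, px)
        if v not in order_nodes:
            order_nodes[v] = next_id
            next_id += 1
        t.add_node(order_nodes[v], pos=tuple(pts[-1]), role="path")
        t.add_edge(
            order_nodes[u],
            order_nodes[v],
            length_um=polyline_length(pts),
            points=pts,
            order=0,
        )
    for nid in t.nodes:
        if nid == 0:
            continue
        t.nodes[nid]["role"] = "tip" if t.out_degree(nid) == 0 else "branch"

    _extend_tips(t, mask, px)
    _assign_orders(t, 0, soma_radius_um)
    _reanchor_branch_starts(t, 0)
    tree = NeuriteTree(graph=t, root=0)
    tree.validate()
    return tree


def _extend_tips(t: nx.DiGraph, mask: np.ndarray, px: float) -> None:
    """March each terminal end outward to the mask boundary.

    Skeletonization retracts about half a stroke width from free line ends.
    The march along the end tangent recovers that length; it is then pulled
    back by 0.4× the local mask half-width, since the thresholded mask of a
    line end overshoots the true endpoint by roughly that much.
    """
    h, w = mask.shape
    edt = ndi.distance_transform_edt(mask)
    for v in [n for n in t.nodes if t.out_degree(n) == 0 and t.in_degree(n) == 1]:
        (u,) = t.predecessors(v)
        pts = t.edges[u, v]["points"]
        d = _edge_dir(pts, at_end=True)
        pos = np.array(pts[-1], dtype=float)
        r0, c0 = int(round(pos[1] / px)), int(round(pos[0] / px))
        halfwidth_um = float(edt[r0, c0]) * px if (0 <= r0 < h and 0 <= c0 < w) else 0.0
        step = 0.5 * px
        ext = 0.0
        while ext < 20.0 * px:
            nxt = pos + step * d
            r, c = int(round(nxt[1] / px)), int(round(nxt[0] / px))
            if not (0 <= r < h and 0 <= c < w) or not mask[r, c]:
                break
            pos = nxt
            ext += step
        ext = max(ext - 0.4 * halfwidth_um, 0.0)
        if ext > 0:
            pos = np.asarray(pts[-1], dtype=float) + ext * d
            new_pts = np.vstack([pts, pos])
            t.edges[u, v]["points"] = new_pts
            t.edges[u, v]["length_um"] = polyline_length(new_pts)
            t.nodes[v]["pos"] = tuple(pos)


def _reanchor_branch_starts(t: nx.DiGraph, root: int) -> None:
    """Back-extend side-branch starts to the parent centerline.

    The rendered wedge at a junction displaces the skeleton branch point a
    few µm down the child; the child's clean direction (estimated away from
    the junction) is extrapolated backward onto the parent's polyline and
    the distorted lead-in replaced by the straight chord from that apex.
    """
    for u in list(t.nodes):
        preds = list(t.predecessors(u))
        if not preds:
            continue
        (p,) = preds
        parent_pts = t.edges[p, u]["points"]
        parent_order = t.edges[p, u]["order"]
        for v in t.successors(u):
            e = t.edges[u, v]
            if e["order"] == parent_order:
                continue  # the continuation keeps the parent's line
            pts = e["points"]
            s = np.concatenate(
                [[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))]
            )
            if s[-1] < 8.0:
                continue
            i0 = int(np.searchsorted(s, 5.0))
            i0 = min(max(i0, 1), len(pts) - 2)
            p0 = pts[i0]
            d = _edge_dir(pts, at_end=False, skip_um=5.0, span_um=15.0)
            # parent point nearest the backward ray, within a short reach
            rel = parent_pts - p0
            along = rel @ d
            perp = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])
            cand = np.where((along < 0) & (along > -18.0))[0]
            if len(cand) == 0:
                continue
            best = cand[np.argmin(perp[cand])]
            if perp[best] > 2.5:
                continue
            apex = parent_pts[best]
            new_pts = np.vstack([apex, pts[i0:]])
            e["points"] = new_pts
            e["length_um"] = polyline_length(new_pts)


def _assign_orders(t: nx.DiGraph, root: int, soma_radius_um: float) -> None:
    root_pos = np.asarray(t.nodes[root]["pos"], dtype=float)

    def inside_soma(u, v) -> bool:
        pts = t.edges[u, v]["points"]
        return bool(
            np.all(np.hypot(*(pts - root_pos).T) <= soma_radius_um)
        )

    stack = []
    for v in t.successors(root):
        if inside_soma(root, v):
            t.edges[root, v]["order"] = 0
            # children of a soma-interior edge start primaries
            stack.extend((v, w, 1) for w in t.successors(v))
        else:
            stack.append((root, v, 1))
    while stack:
        u, v, order = stack.pop()
        t.edges[u, v]["order"] = order
        pts = t.edges[u, v]["points"]
        out_dir = _chord_dir(pts, at_end=True)
        children = list(t.successors(v))
        if not children:
            continue
        cos = {
            w: float(
                np.dot(out_dir, _chord_dir(t.edges[v, w]["points"], at_end=False))
            )
            for w in children
        }
        cont = max(children, key=lambda w: cos[w])
        for w in children:
            stack.append((v, w, order if w == cont else order + 1))


def branch_order_metrics(tree: NeuriteTree) -> dict:
    """Counts and mean arclengths of primary/secondary/tertiary neurites.

    Neurites are the maximal same-order chains of :func:`neurite_paths`;
    orders above 3 are reported as an overflow count rather than folded into
    the tertiary bin.  Mean length is ``None`` for absent orders.
    """
    paths = [p for p in neurite_paths(tree) if p["order"] > 0]
    counts = {1: 0, 2: 0, 3: 0}
    sums = {1: 0.0, 2: 0.0, 3: 0.0}
    overflow = 0
    for p in paths:
        k = p["order"]
        if k in counts:
            counts[k] += 1
            sums[k] += p["length_um"]
        else:
            overflow += 1
    mean = {
        k: (sums[k] / counts[k] if counts[k] else None) for k in counts
    }
    return {"counts": counts, "mean_length_um": mean, "overflow": overflow}
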