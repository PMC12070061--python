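"""Seeded synthetic fluorescence scenes with exact ground truth.

Generators for the scene families the quantification pipeline is built for:

* single branching neuron arbors (up to tertiary order),
* ganglion explants (bright core plus radial axon outgrowth),
* fasciculated nerves ramifying into terminal endings,
* two-channel fields where a labeled soma subpopulation carries a
  membrane-enriched second-channel signal,
* 1-D gel lane profiles of Gaussian bands on a baseline.

Every generator consumes one explicitly seeded RNG and returns the rendered
:class:`~axonquant.core.ImageScene` together with a :class:`GroundTruth`
bundle holding the exact geometry and signal content, so each downstream
measurement has an oracle.

Growth model: a neurite is a persistent random walk (fixed 2 µm steps,
Gaussian heading diffusion) whose total arclength is drawn from a truncated
normal; side branches occur as a Poisson process along the arclength and
carry order ``parent + 1`` up to ``max_order``.  Strokes are rendered by
arclength sampling at quarter-pixel steps with a Gaussian cross-section and
a single PSF convolution, so rendered intensity is proportional to
arclength and lines look diffraction-limited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

from .core import ImageScene
from .geometry import circle_polyline_crossings, polyline_length, resample_polyline
from .trees import NeuriteTree

__all__ = [
    "GrowthParams",
    "GroundTruth",
    "sample_neuron_tree",
    "generate_neuron_scene",
    "generate_explant_scene",
    "generate_nerve_scene",
    "generate_coloc_scene",
    "generate_gel_profile",
]

_STEP_UM = 2.0  # growth step of the persistent random walk
_MAX_TRIES = 60


def explant_params(seed: int) -> "GrowthParams":
    """Canonical growth parameters for explant outgrowth scenes.

    Long, gently curving, sparsely branching radial axons (2 µm stroke
    sigma, ~700 µm extent) — the regime ridge detection and ring
    intersection profiling are designed for.
    """
    return GrowthParams(
        seed=seed,
        branch_prob_per_um=0.0008,
        segment_len_um=(700.0, 150.0),
        turn_sd_deg=1.5,
        line_width_um=2.0,
        psf_sigma_um=1.0,
    )


@dataclass
class GrowthParams:
    """Arbor-growth and rendering parameters.

    Lengths are µm.  ``segment_len_um`` is the (mean, sd) of a neurite's
    total arclength; ``branch_prob_per_um`` the Poisson rate of side
    branches per µm of arclength; ``turn_sd_deg`` the heading diffusion per
    2 µm growth step.  ``line_width_um`` is the Gaussian cross-section sigma
    of rendered strokes and ``psf_sigma_um`` the extra blur applied once to
    the whole frame.  ``noise`` is ``(poisson_gain, gaussian_sd)``; a gain
    of 0 disables shot noise.
    """

    seed: int = 0
    n_primary: int = 3
    branch_prob_per_um: float = 0.02
    max_order: int = 3
    segment_len_um: tuple[float, float] = (45.0, 10.0)
    turn_sd_deg: float = 3.0
    line_width_um: float = 1.0
    psf_sigma_um: float = 0.4
    amplitude: float = 120.0
    background: float = 10.0
    noise: tuple[float, float] = (0.0, 5.0)
    branch_angle_deg: tuple[float, float] = (25.0, 55.0)
    min_separation_um: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.branch_prob_per_um:
            raise ValueError("branch_prob_per_um must be >= 0")
        if self.max_order not in (1, 2, 3):
            raise ValueError("max_order must be 1, 2 or 3")
        for name in ("line_width_um", "psf_sigma_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.segment_len_um[0] <= 0:
            raise ValueError("segment mean length must be > 0")


@dataclass
class GroundTruth:
    """Exact truth bundle paired with a generated scene."""

    trees: list[NeuriteTree] = field(default_factory=list)
    core_mask: np.ndarray | None = None
    tip_points: list[dict] = field(default_factory=list)
    region_signal: dict | None = None
    band_areas: list[float] | None = None
    cells: list[dict] = field(default_factory=list)
    ring_radii_um: np.ndarray | None = None
    ring_crossings: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        for t in self.trees:
            t.validate()
        if self.region_signal is not None:
            for ch in self.region_signal.values():
                if any(v < -1e-9 for v in ch.values()):
                    raise ValueError("region_signal entries must be non-negative")

    def polylines(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for t in self.trees:
            out.extend(t.polylines())
        return out


# ---------------------------------------------------------------------------
# arbor growth
# ---------------------------------------------------------------------------

def _grow_neurite(rng, start, heading_deg, order, p: GrowthParams):
    """Walk one neurite; return (points, branch_events).

    ``branch_events`` is a list of ``(point_index, child_heading_deg)``
    tuples.  RNG draw order: total length, then per-step headings, with a
    branch-gap and branch-angle draw interleaved exactly where each branch
    event falls.
    """
    mean, sd = p.segment_len_um
    length = max(float(rng.normal(mean, sd)), 0.25 * mean)
    pts = [np.asarray(start, dtype=float)]
    events: list[tuple[int, float]] = []
    can_branch = order < p.max_order and p.branch_prob_per_um > 0
    next_branch = (
        rng.exponential(1.0 / p.branch_prob_per_um) if can_branch else np.inf
    )
    heading = float(heading_deg)
    s = 0.0
    while s < length:
        step = min(_STEP_UM, length - s)
        heading += float(rng.normal(0.0, p.turn_sd_deg))
        rad = np.deg2rad(heading)
        pts.append(pts[-1] + step * np.array([np.cos(rad), np.sin(rad)]))
        s += step
        # a branch landing on the final point would be a pure tip kink, not
        # a branch; events trigger only at interior points
        if can_branch and s >= next_branch and s < length - 1e-9:
            lo, hi = p.branch_angle_deg
            delta = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
            events.append((len(pts) - 1, heading + delta))
            next_branch += rng.exponential(1.0 / p.branch_prob_per_um)
    return np.asarray(pts), events


def sample_neuron_tree(
    params: GrowthParams,
    rng: np.random.Generator | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
    primary_headings_deg: list[float] | None = None,
) -> NeuriteTree:
    """Sample one rooted arbor (geometry only, no rendering).

    Primary neurites leave the origin at evenly spaced headings with ±10°
    jitter unless explicit headings are given.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if primary_headings_deg is None:
        base = np.linspace(0.0, 360.0, params.n_primary, endpoint=False)
        primary_headings_deg = [
            float(b + rng.normal(0.0, 10.0)) for b in base
        ]
    g = nx.DiGraph()
    g.add_node(0, pos=tuple(np.asarray(origin, float)), role="root")
    next_id = 1
    # FIFO queue keeps the RNG draw order deterministic and documented
    queue: list[tuple[int, tuple[float, float], float, int]] = [
        (0, tuple(np.asarray(origin, float)), h, 1) for h in primary_headings_deg
    ]
    while queue:
        parent_node, start, heading, order = queue.pop(0)
        pts, events = _grow_neurite(rng, start, heading, order, params)
        cut_idx = [0] + [i for i, _ in events] + [len(pts) - 1]
        cut_idx = sorted(set(cut_idx))
        ev_by_idx = {i: h for i, h in events}
        prev_node = parent_node
        for a, b in zip(cut_idx[:-1], cut_idx[1:]):
            seg = pts[a : b + 1]
            node = next_id
            next_id += 1
            role = "branch" if b in ev_by_idx else "tip"
            g.add_node(node, pos=tuple(seg[-1]), role=role)
            g.add_edge(
                prev_node,
                node,
                length_um=polyline_length(seg),
                order=order,
                points=seg,
            )
            if b in ev_by_idx:
                queue.append((node, tuple(seg[-1]), ev_by_idx[b], order + 1))
            prev_node = node
    tree = NeuriteTree(graph=g, root=0)
    return tree


def _edges_well_separated(tree: NeuriteTree, min_sep: float) -> bool:
    """True if the arbor is resolvable at a ``min_sep`` µm length scale.

    Requires every edge to be at least ``2 min_sep`` long (no micro-stubs
    at branch points) and no two non-adjacent edges to pass within
    ``min_sep`` of each other.
    Edges meeting at a node must also diverge: their matched-arclength
    separation over the first ~16 µm has to grow at least as fast as a 20°
    opening angle, otherwise the rendered strokes merge into one wedge.
    """
    edges = list(tree.graph.edges(data=True))
    if any(d["length_um"] < 2.0 * min_sep for _, _, d in edges):
        return False
    g = tree.graph.to_undirected(as_view=True)
    for n in g.nodes:
        inc = list(g.edges(n, data=True))
        if len(inc) < 2:
            continue
        polys = []
        npos = np.asarray(g.nodes[n]["pos"], dtype=float)
        for u, v, d in inc:
            pts = np.asarray(d["points"], dtype=float)
            if np.hypot(*(pts[0] - npos)) > np.hypot(*(pts[-1] - npos)):
                pts = pts[::-1]
            polys.append(resample_polyline(pts, 2.0))
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                m = min(len(polys[i]), len(polys[j]), 9)  # ~16 µm at 2 µm steps
                for k in range(2, m):
                    s = 2.0 * k
                    sep = float(np.hypot(*(polys[i][k] - polys[j][k])))
                    if sep < 2.0 * s * np.sin(np.deg2rad(10.0)):
                        return False
    samples = [
        resample_polyline(d["points"], _STEP_UM) for _, _, d in edges
    ]
    for i in range(len(edges)):
        ui, vi, _ = edges[i]
        for j in range(i + 1, len(edges)):
            uj, vj, _ = edges[j]
            if {ui, vi} & {uj, vj}:
                continue
            if cdist(samples[i], samples[j]).min() < min_sep:
                return False
    return True


def _tree_in_bounds(tree: NeuriteTree, extent_um, margin_um: float) -> bool:
    w, h = extent_um
    for pts in tree.polylines():
        if (
            pts[:, 0].min() < margin_um
            or pts[:, 1].min() < margin_um
            or pts[:, 0].max() > w - margin_um
            or pts[:, 1].max() > h - margin_um
        ):
            return False
    return True


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_strokes(
    polylines_um, shape, pixel_size_um, sigma_tot_px, amplitude
) -> np.ndarray:
    """Splat polylines onto a canvas and blur.

    Deposits arclength density at quarter-pixel steps with bilinear weights,
    then convolves once with the total Gaussian (cross-section ⊕ PSF).  The
    density is scaled so an isolated straight line peaks at ``amplitude``.
    """
    canvas = np.zeros(shape, dtype=float)
    rho = amplitude * np.sqrt(2.0 * np.pi) * sigma_tot_px  # per px of arclength
    step_px = 0.25
    for pts in polylines_um:
        pts_px = np.asarray(pts, dtype=float) / pixel_size_um
        res = resample_polyline(pts_px, step_px)
        if len(res) < 2:
            continue
        ds = polyline_length(res) / (len(res) - 1)
        w = rho * ds
        x, y = res[:, 0], res[:, 1]
        x0 = np.floor(x).astype(int)
        y0 = np.floor(y).astype(int)
        fx, fy = x - x0, y - y0
        for dy in (0, 1):
            for dx in (0, 1):
                wt = w * (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
                yy = np.clip(y0 + dy, 0, shape[0] - 1)
                xx = np.clip(x0 + dx, 0, shape[1] - 1)
                np.add.at(canvas, (yy, xx), wt)
    return ndi.gaussian_filter(canvas, sigma_tot_px)


def _apply_noise(img: np.ndarray, p: GrowthParams, rng) -> np.ndarray:
    gain, gsd = p.noise
    out = img.copy()
    if gain > 0:
        out = rng.poisson(np.clip(out, 0, None) * gain).astype(float) / gain
    if gsd > 0:
        out = out + rng.normal(0.0, gsd, size=out.shape)
    return np.clip(np.round(out), 0, 65535).astype(np.uint16)


def _sigma_tot_px(p: GrowthParams, pixel_size_um: float) -> float:
    return float(
        np.hypot(p.line_width_um, p.psf_sigma_um) / pixel_size_um
    )


# ---------------------------------------------------------------------------
# scene generators
# ---------------------------------------------------------------------------

def generate_neuron_scene(
    params: GrowthParams,
    canvas_px: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.5,
    channel: str = "GFP",
) -> tuple[ImageScene, GroundTruth]:
    """Render one branching neuron rooted at the canvas center.

    The arbor is resampled until it stays inside the canvas (and, when
    ``params.min_separation_um`` is set, until no two non-adjacent branches
    pass closer than that); exhausting the retries raises with a suggestion
    to enlarge the canvas.
    """
    rng = np.random.default_rng(params.seed)
    extent = (canvas_px[1] * pixel_size_um, canvas_px[0] * pixel_size_um)
    origin = (extent[0] / 2.0, extent[1] / 2.0)
    margin = 6.0 * _sigma_tot_px(params, pixel_size_um) * pixel_size_um
    tree = None
    for _ in range(_MAX_TRIES):
        cand = sample_neuron_tree(params, rng, origin=origin)
        if not _tree_in_bounds(cand, extent, margin):
            continue
        if params.min_separation_um is not None and not _edges_well_separated(
            cand, params.min_separation_um
        ):
            continue
        tree = cand
        break
    if tree is None:
        raise RuntimeError(
            f"arbor escaped a {canvas_px} px canvas in {_MAX_TRIES} tries; "
            "use a larger canvas or shorter segments"
        )
    render = _render_strokes(
        tree.polylines(),
        canvas_px,
        pixel_size_um,
        _sigma_tot_px(params, pixel_size_um),
        params.amplitude,
    )
    clean = render + params.background
    data = _apply_noise(clean, params, rng)
    scene = ImageScene({channel: data}, pixel_size_um=pixel_size_um)
    truth = GroundTruth(
        trees=[tree],
        tip_points=_tip_records(tree),
        extras={"clean": clean, "origin_um": origin},
    )
    return scene, truth


def _tip_records(tree: NeuriteTree) -> list[dict]:
    root_pos = tree.node_pos(tree.root)
    recs = []
    for n in tree.tips():
        pos = tree.node_pos(n)
        recs.append(
            {
                "pos_um": tuple(pos),
                "distance_um": float(np.hypot(*(pos - root_pos))),
                "node": n,
            }
        )
    return recs


def generate_explant_scene(
    params: GrowthParams,
    core_radius_um: float = 150.0,
    n_axons: int = 10,
    canvas_px: tuple[int, int] = (1024, 1024),
    pixel_size_um: float = 2.0,
    ring_spacing_um: float = 175.0,
    n_rings: int = 20,
    channel: str = "Tubb3",
) -> tuple[ImageScene, GroundTruth]:
    """Render an explant: bright disk core plus radial axon arbors.

    Axons are rooted on the core boundary at evenly spaced angles (with
    jitter) and grow outward.  The truth bundle carries the core mask, all
    axon trees, and per-ring transversal crossing counts of the truth
    polylines computed with the analytic circle–segment oracle.
    """
    rng = np.random.default_rng(params.seed)
    extent = (canvas_px[1] * pixel_size_um, canvas_px[0] * pixel_size_um)
    if 2.0 * core_radius_um > min(extent):
        raise ValueError("core larger than canvas")
    center = np.array([extent[0] / 2.0, extent[1] / 2.0])
    margin = 6.0 * _sigma_tot_px(params, pixel_size_um) * pixel_size_um
    base = np.linspace(0.0, 360.0, n_axons, endpoint=False)
    trees: list[NeuriteTree] = []
    for b in base:
        ang = b + float(rng.normal(0.0, 6.0))
        rad = np.deg2rad(ang)
        root = center + core_radius_um * np.array([np.cos(rad), np.sin(rad)])
        tree = None
        for _ in range(_MAX_TRIES):
            cand = sample_neuron_tree(
                replace(params, n_primary=1),
                rng,
                origin=tuple(root),
                primary_headings_deg=[ang + float(rng.normal(0.0, 5.0))],
            )
            if _tree_in_bounds(cand, extent, margin):
                tree = cand
                break
        if tree is None:
            raise RuntimeError("axon escaped canvas; enlarge canvas or shorten axons")
        trees.append(tree)

    yy, xx = np.mgrid[0 : canvas_px[0], 0 : canvas_px[1]]
    r2 = (xx * pixel_size_um - center[0]) ** 2 + (yy * pixel_size_um - center[1]) ** 2
    core_mask = r2 <= core_radius_um**2
    polylines = [pl for t in trees for pl in t.polylines()]
    stroke = _render_strokes(
        polylines, canvas_px, pixel_size_um, _sigma_tot_px(params, pixel_size_um),
        params.amplitude,
    )
    core_img = ndi.gaussian_filter(
        core_mask.astype(float) * params.amplitude * 1.6,
        params.psf_sigma_um / pixel_size_um,
    )
    clean = stroke + core_img + params.background
    data = _apply_noise(clean, params, rng)
    radii = ring_spacing_um * np.arange(1, n_rings + 1)
    crossings = circle_polyline_crossings(polylines, tuple(center), radii)
    above_bg = clean - params.background
    region_signal = {
        channel: {
            "core": float(above_bg[core_mask].sum()),
            "outside": float(above_bg[~core_mask].sum()),
        }
    }
    scene = ImageScene({channel: data}, pixel_size_um=pixel_size_um)
    truth = GroundTruth(
        trees=trees,
        core_mask=core_mask,
        region_signal=region_signal,
        ring_radii_um=radii,
        ring_crossings=crossings,
        extras={"clean": clean, "center_um": tuple(center)},
    )
    return scene, truth


def generate_nerve_scene(
    trunk_len_um: float,
    tip_depths_um: list[float],
    width_um: float,
    params: GrowthParams,
    canvas_px: tuple[int, int] = (1024, 1024),
    pixel_size_um: float = 1.0,
    channel: str = "Tubb3",
) -> tuple[ImageScene, GroundTruth]:
    """Render a horizontal nerve trunk ramifying into terminal endings.

    The trunk (a bar of full width ``width_um``) runs left to right and ends
    at a single ramification point from which straight terminal branches fan
    out at distinct angles; each branch extends until its *axial* distance
    beyond the ramification point equals the requested tip depth.  Tips
    whose endpoints are closer than 3× the stroke width are flagged as
    unresolvable with a warning.
    """
    rng = np.random.default_rng(params.seed)
    extent = (canvas_px[1] * pixel_size_um, canvas_px[0] * pixel_size_um)
    x0 = 30.0
    yc = extent[1] / 2.0
    xb = x0 + trunk_len_um
    depths = [float(d) for d in tip_depths_um]
    if xb + max(depths, default=0.0) > extent[0] - 30.0:
        raise ValueError("tip depths exceed canvas span")
    n = len(depths)
    if n == 0:
        raise ValueError("need at least one tip depth")
    if n == 1:
        angles = np.array([0.0])
    else:
        # a minimum angular gap keeps neighboring branches resolvable on
        # perpendicular profiles from the first sampling interval on
        half_span = max(40.0, 5.0 * (n - 1))
        angles = np.linspace(-half_span, half_span, n)
    branch_polys = []
    tip_points = []
    g = nx.DiGraph()
    g.add_node(0, pos=(x0, yc), role="root")
    g.add_node(1, pos=(xb, yc), role="branch")
    trunk_poly = np.array([[x0, yc], [xb, yc]])
    g.add_edge(0, 1, length_um=trunk_len_um, order=1, points=trunk_poly)
    for i, (d, a) in enumerate(zip(depths, angles)):
        rad = np.deg2rad(a)
        end = np.array([xb + d, yc + d * np.tan(rad)])
        if not (0 < end[1] < extent[1]):
            raise ValueError("branch fan exceeds canvas height")
        poly = np.array([[xb, yc], end])
        branch_polys.append(poly)
        g.add_node(2 + i, pos=tuple(end), role="tip")
        g.add_edge(1, 2 + i, length_um=polyline_length(poly), order=2, points=poly)
        tip_points.append(
            {"pos_um": tuple(end), "distance_um": d, "node": 2 + i}
        )
    ends = np.array([t["pos_um"] for t in tip_points])
    if n > 1:
        dmat = cdist(ends, ends)
        np.fill_diagonal(dmat, np.inf)
        if dmat.min() < 3.0 * params.line_width_um:
            warnings.warn(
                "tips closer than 3x line width are unresolvable by "
                "profile-based counting",
                stacklevel=2,
            )
    sigma_px = _sigma_tot_px(params, pixel_size_um)
    stroke = _render_strokes(
        branch_polys, canvas_px, pixel_size_um, sigma_px, params.amplitude
    )
    yy, xx = np.mgrid[0 : canvas_px[0], 0 : canvas_px[1]]
    xum, yum = xx * pixel_size_um, yy * pixel_size_um
    trunk_mask = (
        (xum >= x0) & (xum <= xb) & (np.abs(yum - yc) <= width_um / 2.0)
    )
    trunk_img = ndi.gaussian_filter(
        trunk_mask.astype(float) * params.amplitude,
        params.psf_sigma_um / pixel_size_um,
    )
    clean = np.maximum(stroke, trunk_img) + params.background
    data = _apply_noise(clean, params, rng)
    scene = ImageScene({channel: data}, pixel_size_um=pixel_size_um)
    tree = NeuriteTree(graph=g, root=0)
    truth = GroundTruth(
        trees=[tree],
        tip_points=tip_points,
        extras={
            "clean": clean,
            "branch_point_um": (xb, yc),
            "trunk_width_um": width_um,
            "tip_depths_um": depths,
        },
    )
    return scene, truth


def true_tip_count(depths_um, distance_um: float) -> int:
    """Number of terminal branches still present at an axial distance.

    A branch whose tip depth is exactly ``distance_um`` is still counted
    (intervals are closed on the right: a tip at 300 µm is present at the
    300 µm sample).
    """
    return int(sum(1 for d in depths_um if d >= distance_um - 1e-9))


def generate_coloc_scene(
    n_cells: int,
    labeled_fraction: float,
    membrane_contrast: float,
    params: GrowthParams,
    canvas_px: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.5,
    cell_radius_um: float = 6.0,
    ch_mask: str = "GFP",
    ch_measure: str = "bCat",
) -> tuple[ImageScene, GroundTruth]:
    """Two-channel scene: labeled soma disks plus membrane-ring signal.

    Channel ``ch_mask`` holds filled soma disks for a ``labeled_fraction``
    subset of the cells.  Channel ``ch_measure`` is a uniform base level
    everywhere plus a membrane annulus boost of ``(contrast - 1) × base`` on
    every cell, so ``membrane_contrast = 1`` yields an exactly uniform
    measure channel.  Truth records each labeled cell's exact mean of the
    noise-free measure channel over its rendered mask.
    """
    rng = np.random.default_rng(params.seed)
    extent = (canvas_px[1] * pixel_size_um, canvas_px[0] * pixel_size_um)
    margin = cell_radius_um + 6.0
    centers: list[np.ndarray] = []
    for _ in range(20000):
        if len(centers) == n_cells:
            break
        c = rng.uniform([margin, margin], [extent[0] - margin, extent[1] - margin])
        if all(np.hypot(*(c - o)) > 2.6 * cell_radius_um for o in centers):
            centers.append(c)
    if len(centers) < n_cells:
        raise RuntimeError("could not place cells without overlap; enlarge canvas")
    n_labeled = int(round(labeled_fraction * n_cells))
    labeled = set(rng.choice(n_cells, size=n_labeled, replace=False).tolist())

    yy, xx = np.mgrid[0 : canvas_px[0], 0 : canvas_px[1]]
    xum, yum = xx * pixel_size_um, yy * pixel_size_um
    base_b = 0.3 * params.amplitude
    mask_img = np.zeros(canvas_px, dtype=float)
    annulus = np.zeros(canvas_px, dtype=float)
    disk_masks = []
    for i, c in enumerate(centers):
        r = np.hypot(xum - c[0], yum - c[1])
        disk = r <= cell_radius_um
        ring = (r <= cell_radius_um) & (r >= cell_radius_um - 1.5)
        disk_masks.append(disk)
        annulus[ring] = 1.0
        if i in labeled:
            mask_img[disk] = params.amplitude
    psf_px = params.psf_sigma_um / pixel_size_um
    clean_a = ndi.gaussian_filter(mask_img, psf_px) + params.background
    clean_b = base_b + (membrane_contrast - 1.0) * base_b * ndi.gaussian_filter(
        annulus, psf_px
    )
    data_a = _apply_noise(clean_a, params, rng)
    data_b = _apply_noise(clean_b, params, rng)
    cells = []
    for i, c in enumerate(centers):
        if i not in labeled:
            continue
        m = disk_masks[i]
        cells.append(
            {
                "center_um": tuple(c),
                "radius_um": cell_radius_um,
                "true_mean_measure": float(clean_b[m].mean()),
                "mask_area_px": int(m.sum()),
            }
        )
    scene = ImageScene(
        {ch_mask: data_a, ch_measure: data_b}, pixel_size_um=pixel_size_um
    )
    truth = GroundTruth(
        cells=cells,
        extras={
            "clean_mask": clean_a,
            "clean_measure": clean_b,
            "base_level": base_b,
            "n_labeled": n_labeled,
        },
    )
    return scene, truth


def generate_gel_profile(
    band_centers: list[float],
    band_areas: list[float],
    band_sigma: float,
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    n_points: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """1-D lane profile: Gaussian bands on a linear baseline plus noise.

    ``baseline`` is ``(intercept, slope)`` in intensity units per sample.
    Truth stores the exact band areas (the baseline contributes none by
    construction).
    """
    if len(band_centers) != len(band_areas):
        raise ValueError("band_centers and band_areas must match in length")
    if band_sigma <= 0:
        raise ValueError("band_sigma must be > 0")
    rng = np.random.default_rng(seed)
    x = np.arange(n_points, dtype=float)
    b0, b1 = baseline
    prof = b0 + b1 * x
    for c, a in zip(band_centers, band_areas):
        prof += a * np.exp(-0.5 * ((x - c) / band_sigma) ** 2) / (
            np.sqrt(2.0 * np.pi) * band_sigma
        )
    if noise_sd > 0:
        prof = prof + rng.normal(0.0, noise_sd, size=n_points)
    truth = GroundTruth(band_areas=[float(a) for a in band_areas])
    return prof, truth
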