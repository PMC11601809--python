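"""Synthetic atrioventricular valve geometry.

Builds stereotypical mitral (two-leaflet) and tricuspid (three-leaflet)
valve surfaces as lofted parametric quad meshes between a saddle-shaped
elliptic annulus curve and a free-edge curve with commissural dips, plus
papillary tip points below the annulus plane.

Units are mm throughout (internal convention: mm / N / MPa / s).

The default dimensions are toolkit choices (healthy adult scale), not
measurements; override them via the ``annulus_dims`` / ``leaflet_heights``
arguments or the ``valve:`` config block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "ValveModel",
    "AnnulusFrame",
    "OTHER",
    "BODY",
    "FREE_EDGE",
    "make_stereotypical_mv",
    "make_stereotypical_tv",
    "dilate_annulus",
    "annulus_frame",
    "surface_regions",
    "annulus_to_free_edge_coordinate",
]

# region labels returned by surface_regions
OTHER = 0
BODY = 1
FREE_EDGE = 2

DEFAULT_THICKNESS = 0.396  # mm


@dataclass
class ValveModel:
    """Quad-meshed valve surface with labelled features.

    Attributes
    ----------
    nodes : (n, 3) float array, mm
    quads : (m, 4) int array, consistent winding with normals pointing
        to the atrial side
    annulus_nodes : (k,) int array, ordered closed loop
    free_edge_paths : list of int arrays, one ordered path per leaflet;
        consecutive paths join at commissures and together form the free
        edge loop
    leaflet_label : (m,) int array, per-quad leaflet id (0-based)
    papillary_tips : (p, 3) float array
    thickness : scalar, mm
    """

    nodes: np.ndarray
    quads: np.ndarray
    annulus_nodes: np.ndarray
    free_edge_paths: list
    leaflet_label: np.ndarray
    papillary_tips: np.ndarray
    thickness: float = DEFAULT_THICKNESS
    labelled: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_quads(self) -> int:
        return len(self.quads)

    @property
    def n_leaflets(self) -> int:
        return int(self.leaflet_label.max()) + 1 if len(self.leaflet_label) else 0

    @property
    def free_edge_nodes(self) -> np.ndarray:
        """All free-edge node indices in loop order (deduplicated)."""
        seen: dict = {}
        for path in self.free_edge_paths:
            for i in np.asarray(path).tolist():
                seen.setdefault(int(i), None)
        return np.fromiter(seen.keys(), dtype=np.int64)

    def copy(self) -> "ValveModel":
        return replace(
            self,
            nodes=self.nodes.copy(),
            quads=self.quads.copy(),
            annulus_nodes=self.annulus_nodes.copy(),
            free_edge_paths=[np.asarray(p).copy() for p in self.free_edge_paths],
            leaflet_label=self.leaflet_label.copy(),
            papillary_tips=self.papillary_tips.copy(),
            meta=dict(self.meta),
        )

    # -- audits -----------------------------------------------------------
    def edge_use_counts(self):
        """Map of undirected edge -> list of directed uses (+1/-1)."""
        uses: dict = {}
        for quad in self.quads:
            for a, b in zip(quad, np.roll(quad, -1)):
                a, b = int(a), int(b)
                key = (min(a, b), max(a, b))
                uses.setdefault(key, []).append(1 if a < b else -1)
        return uses

    def audit(self) -> None:
        """Raise ValueError if the mesh is non-manifold or inconsistently wound."""
        uses = self.edge_use_counts()
        for key, lst in uses.items():
            if len(lst) > 2:
                raise ValueError(f"non-manifold edge {key}: used {len(lst)} times")
            if len(lst) == 2 and lst[0] == lst[1]:
                raise ValueError(f"inconsistent winding at edge {key}")
        frame = annulus_frame(self)
        # papillary tips must be ventricular
        if len(self.papillary_tips):
            side = (self.papillary_tips - frame.origin) @ frame.normal
            if np.any(side >= 0):
                raise ValueError("papillary tip on atrial side of annulus plane")
        boundary = self.boundary_nodes()
        ann = set(self.annulus_nodes.tolist())
        for i in self.free_edge_nodes:
            if int(i) not in boundary:
                raise ValueError(f"free-edge node {i} is not a boundary node")
            if int(i) in ann:
                raise ValueError(f"free-edge node {i} lies on the annulus")

    def boundary_nodes(self) -> set:
        out = set()
        for (a, b), lst in self.edge_use_counts().items():
            if len(lst) == 1:
                out.add(a)
                out.add(b)
        return out


@dataclass(frozen=True)
class AnnulusFrame:
    """Least-squares annulus plane: origin, atrial-pointing normal, in-plane axes."""

    origin: np.ndarray
    normal: np.ndarray
    in_plane_axes: np.ndarray  # (2, 3)

    def project(self, points: np.ndarray) -> np.ndarray:
        """In-plane 2D coordinates of ``points``."""
        rel = np.atleast_2d(points) - self.origin
        return rel @ self.in_plane_axes.T

    def height(self, points: np.ndarray) -> np.ndarray:
        """Signed distance above the plane (positive = atrial)."""
        return (np.atleast_2d(points) - self.origin) @ self.normal


# ---------------------------------------------------------------------------
# parametric loft
# ---------------------------------------------------------------------------


def _grid_dims(mesh_target_elems: int, circumference: float, height: float):
    """Pick (n_theta, n_s) with n_theta*n_s close to target and ~square elements."""
    aspect = max(circumference / max(height, 1e-9), 1.0)
    n_theta = max(int(round(np.sqrt(mesh_target_elems * aspect))), 8)
    n_s = max(int(round(mesh_target_elems / n_theta)), 2)
    return n_theta, n_s


def _build_loft(
    n_leaflets: int,
    semi_axes,
    saddle_height: float,
    leaflet_heights,
    commissure_height: float,
    mesh_target_elems: int,
    seed: int,
    free_edge_fraction: float = 0.12,
    commissure_edge_fraction: float = 0.52,
    thickness: float = DEFAULT_THICKNESS,
    papillary_radius_frac: float = 0.45,
    papillary_depth: float = 18.0,
) -> ValveModel:
    a, b = float(semi_axes[0]), float(semi_axes[1])
    if a <= 0 or b <= 0:
        raise ValueError("annulus semi-axes must be positive")
    heights = np.asarray(leaflet_heights, dtype=float)
    if len(heights) != n_leaflets:
        raise ValueError(f"expected {n_leaflets} leaflet heights, got {len(heights)}")
    if np.any(heights <= 0):
        raise ValueError("degenerate dimensions: leaflet heights must be positive")
    if mesh_target_elems < 100:
        raise ValueError("mesh_target_elems must be >= 100")

    mean_h = float(np.mean(heights))
    circ = np.pi * (a + b)
    n_theta, n_s = _grid_dims(mesh_target_elems, circ, mean_h)
    # commissures must land exactly on grid columns
    n_theta -= n_theta % n_leaflets

    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    # per-column leaflet id and local sector coordinate u in [0, pi]
    sector = (theta * n_leaflets / (2 * np.pi)).astype(int) % n_leaflets
    u = (theta * n_leaflets / 2.0) % np.pi

    ann_xy = np.stack([a * np.cos(theta), b * np.sin(theta)], axis=1)
    ann_z = saddle_height * np.sin(n_leaflets * theta / 2.0) ** 2

    shape = np.sin(u) ** 1.5
    h_col = commissure_height + (heights[sector] - commissure_height) * shape
    rfrac = commissure_edge_fraction + (free_edge_fraction - commissure_edge_fraction) * np.sin(u) ** 0.8

    s = np.linspace(0.0, 1.0, n_s + 1)[:, None]  # rows: 0 = annulus, n_s = free edge
    radial = 1.0 - s * (1.0 - rfrac[None, :])
    # slight ventricular bow so the loaded surface billows smoothly
    radial = radial - 0.04 * np.sin(np.pi * s) * radial
    x = ann_xy[None, :, 0] * radial
    y = ann_xy[None, :, 1] * radial
    z = ann_z[None, :] - h_col[None, :] * s

    nodes = np.stack([x, y, z], axis=-1).reshape(-1, 3)

    def nid(i, j):
        return i * n_theta + (j % n_theta)

    quads = []
    labels = []
    for i in range(n_s):
        for j in range(n_theta):
            # wound so the computed normal points atrially (toward +z)
            quads.append([nid(i, j), nid(i, j + 1), nid(i + 1, j + 1), nid(i + 1, j)])
            labels.append(int(sector[j]))
    quads = np.asarray(quads, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)

    annulus_nodes = np.arange(n_theta, dtype=np.int64)
    fe_row = n_s * n_theta
    free_edge_paths = []
    cols_per = n_theta // n_leaflets
    for l in range(n_leaflets):
        cols = np.arange(l * cols_per, l * cols_per + cols_per + 1) % n_theta
        free_edge_paths.append(fe_row + cols.astype(np.int64))

    # papillary tips under the commissures
    tips = []
    for l in range(n_leaflets):
        th = 2 * np.pi * l / n_leaflets
        tips.append(
            [
                papillary_radius_frac * a * np.cos(th),
                papillary_radius_frac * b * np.sin(th),
                -papillary_depth,
            ]
        )
    tips = np.asarray(tips, dtype=float)

    model = ValveModel(
        nodes=nodes,
        quads=quads,
        annulus_nodes=annulus_nodes,
        free_edge_paths=free_edge_paths,
        leaflet_label=labels,
        papillary_tips=tips,
        thickness=thickness,
        meta={
            "n_theta": n_theta,
            "n_s": n_s,
            "seed": int(seed),
            "semi_axes": (a, b),
            "saddle_height": float(saddle_height),
            "leaflet_heights": tuple(heights.tolist()),
            "commissure_height": float(commissure_height),
        },
    )
    model.audit()
    return model


def make_stereotypical_mv(
    annulus_dims=(20.0, 15.0, 3.0),
    leaflet_heights=(15.0, 11.0),
    mesh_target_elems: int = 3000,
    seed: int = 0,
    **kwargs,
) -> ValveModel:
    """Stereotypical healthy two-leaflet (mitral) valve.

    ``annulus_dims`` = (semi-axis a, semi-axis b[, saddle height]) in mm.
    Deterministic for fixed inputs.
    """
    dims = tuple(annulus_dims)
    saddle = dims[2] if len(dims) > 2 else 3.0
    kwargs.setdefault("free_edge_fraction", 0.20)
    kwargs.setdefault("commissure_edge_fraction", 0.65)
    return _build_loft(
        2, dims[:2], saddle, leaflet_heights, kwargs.pop("commissure_height", 2.5),
        mesh_target_elems, seed, **kwargs
    )


def make_stereotypical_tv(
    annulus_dims=(21.0, 17.0, 2.5),
    leaflet_heights=(11.0, 10.0, 10.0),
    mesh_target_elems: int = 3000,
    seed: int = 0,
    **kwargs,
) -> ValveModel:
    """Stereotypical three-leaflet (tricuspid) valve with three papillary tips."""
    dims = tuple(annulus_dims)
    saddle = dims[2] if len(dims) > 2 else 2.5
    return _build_loft(
        3, dims[:2], saddle, leaflet_heights, kwargs.pop("commissure_height", 2.5),
        mesh_target_elems, seed, papillary_depth=kwargs.pop("papillary_depth", 16.0),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# frames, coordinates, regions
# ---------------------------------------------------------------------------


def annulus_frame(model: ValveModel) -> AnnulusFrame:
    """Least-squares plane through the annulus nodes.

    The normal is oriented so every papillary tip has negative height
    (ventricular side); without tips it is aligned with +z.
    """
    pts = model.nodes[model.annulus_nodes]
    if len(pts) < 3:
        raise ValueError("need at least 3 annulus nodes")
    origin = pts.mean(axis=0)
    rel = pts - origin
    _, sing, vt = np.linalg.svd(rel, full_matrices=False)
    if sing[1] < 1e-9 * max(sing[0], 1.0):
        raise ValueError("annulus nodes are collinear")
    normal = vt[2]
    if len(model.papillary_tips):
        if np.mean((model.papillary_tips - origin) @ normal) > 0:
            normal = -normal
    elif normal[2] < 0:
        normal = -normal
    e1 = vt[0]
    # deterministic axis signs regardless of node ordering
    k = int(np.argmax(np.abs(e1)))
    if e1[k] < 0:
        e1 = -e1
    e2 = np.cross(normal, e1)
    return AnnulusFrame(origin=origin, normal=normal, in_plane_axes=np.stack([e1, e2]))


def _edge_graph(model: ValveModel):
    q = model.quads
    i = np.concatenate([q[:, 0], q[:, 1], q[:, 2], q[:, 3]])
    j = np.concatenate([q[:, 1], q[:, 2], q[:, 3], q[:, 0]])
    w = np.linalg.norm(model.nodes[i] - model.nodes[j], axis=1)
    n = model.n_nodes
    g = coo_matrix((np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))), shape=(n, n))
    return g.tocsr()

def geodesic_distance(model: ValveModel, sources: np.ndarray) -> np.ndarray:
    """Multi-source graph-geodesic distance along mesh edges (mm)."""
    g = model.meta.get("_graph")
    if g is None:
        g = _edge_graph(model)
        model.meta["_graph"] = g
    d = dijkstra(g, directed=False, indices=np.asarray(sources, dtype=np.int64))
    return d.min(axis=0) if d.ndim == 2 else d


def annulus_to_free_edge_coordinate(model: ValveModel) -> np.ndarray:
    """Normalized coordinate s in [0,1]: 0 at the annulus, 1 at the free edge."""
    d_a = geodesic_distance(model, model.annulus_nodes)
    d_f = geodesic_distance(model, model.free_edge_nodes)
    total = d_a + d_f
    total[total == 0] = 1.0
    return np.clip(d_a / total, 0.0, 1.0)


def surface_regions(model: ValveModel, edge_band: float, body_band_bounds=(0.25, 0.75)) -> np.ndarray:
    """Per-node region labels {OTHER, BODY, FREE_EDGE}.

    FREE_EDGE: nodes within ``edge_band`` (mm, geodesic) of the free edge.
    BODY: nodes whose annulus→free-edge coordinate lies in
    ``body_band_bounds`` and which are not FREE_EDGE.
    """
    lo, hi = body_band_bounds
    if edge_band <= 0 or not (0.0 <= lo < hi <= 1.0):
        raise ValueError("degenerate region bands")
    d_f = geodesic_distance(model, model.free_edge_nodes)
    s = annulus_to_free_edge_coordinate(model)
    in_band = (s >= lo) & (s <= hi)
    in_edge = d_f <= edge_band
    if not np.any(in_edge):
        raise ValueError(f"edge_band={edge_band} produced an empty FREE_EDGE region")
    if not np.any(in_band):
        raise ValueError(f"body_band_bounds={body_band_bounds} produced an empty BODY region")
    labels = np.full(model.n_nodes, OTHER, dtype=np.int64)
    labels[in_band] = BODY
    labels[in_edge] = FREE_EDGE  # FREE_EDGE takes precedence where bands overlap
    return labels


def dilate_annulus(model: ValveModel, factor: float) -> ValveModel:
    """Scale annulus in-plane distances from the centroid by ``factor``.

    Heights (out-of-plane coordinates) of all nodes are preserved, and the
    displacement decays linearly from the annulus (s=0) to the free edge
    (s=1), so leaflet and commissure heights are unchanged.
    """
    if factor <= 0:
        raise ValueError("dilation factor must be positive")
    out = model.copy()
    if factor == 1.0:
        return out
    frame = annulus_frame(model)
    s = annulus_to_free_edge_coordinate(model)
    rel = model.nodes - frame.origin
    h = rel @ frame.normal
    inplane = rel - h[:, None] * frame.normal
    out.nodes = model.nodes + (factor - 1.0) * (1.0 - s)[:, None] * inplane
    out.meta.pop("_graph", None)
    return out
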