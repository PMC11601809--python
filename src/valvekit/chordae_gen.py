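"""Procedural generation of branched chordae tendineae networks.

Each chord runs from the nearest papillary tip toward an insertion center
on the leaflet; with branching, a junction node is placed on the
tip→center line at ``branch_length`` from the center and fans out to
branch tips arranged on a regular polygon of circumradius
``branch_radius`` in the local tangent plane, snapped to mesh nodes.

Primary chords insert along the free edge (density in chords/cm of free
edge arclength); secondary chords insert in the leaflet body (density in
chords/cm^2 of region area).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.spatial.distance import cdist

from .valve_geometry import BODY, ValveModel, surface_regions

log = logging.getLogger(__name__)

__all__ = [
    "CdtClass",
    "ChordParams",
    "ChordaeSet",
    "sample_primary_insertions",
    "sample_secondary_insertions",
    "assign_papillary",
    "layout_branch_tips",
    "build_chordae",
    "chordae_summary",
]


class CdtClass(IntEnum):
    PRIMARY = 0
    SECONDARY = 1


PRIMARY_DENSITY_RANGE = (1.0, 3.0)     # chords/cm
SECONDARY_DENSITY_RANGE = (1.0, 10.0)  # chords/cm^2


@dataclass(frozen=True)
class ChordParams:
    """Parameters of one chordae class (primary or secondary)."""

    cdt_class: CdtClass
    density: float
    branch_length: float = 3.5
    n_branches: int = 3
    branch_radius: float = 1.0
    csa: float = 1.0
    seed: int = 0
    allow_out_of_range: bool = False

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")
        if self.branch_radius < 0 or self.branch_length < 0:
            raise ValueError("branch geometry must be non-negative")
        if self.csa <= 0:
            raise ValueError("csa must be positive")
        rng = (PRIMARY_DENSITY_RANGE if self.cdt_class == CdtClass.PRIMARY
               else SECONDARY_DENSITY_RANGE)
        if not self.allow_out_of_range and not (rng[0] <= self.density <= rng[1]):
            raise ValueError(
                f"{self.cdt_class.name} density {self.density} outside tool range "
                f"{rng}; pass allow_out_of_range=True to override")


@dataclass
class ChordaeSet:
    """Truss segment network anchored at papillary tips.

    Node indices in ``segments`` address the concatenation
    ``[model.nodes, extra_nodes]``; ``n_valve_nodes`` records the split.
    """

    n_valve_nodes: int
    extra_nodes: np.ndarray          # (e, 3): papillary tip nodes then junctions
    segments: np.ndarray             # (s, 2) int
    segment_csa: np.ndarray          # (s,)
    chord_id: np.ndarray             # (s,) int, per segment
    chord_class: np.ndarray          # per chord (c,)
    insertion_centers: np.ndarray    # per chord (c, 3)
    papillary_label: np.ndarray      # per chord (c,)
    papillary_node_index: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def n_chords(self) -> int:
        return len(self.chord_class)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def all_nodes(self, model_nodes: np.ndarray) -> np.ndarray:
        return np.vstack([model_nodes, self.extra_nodes]) if len(self.extra_nodes) else np.asarray(model_nodes)

    def insertion_node_indices(self) -> np.ndarray:
        """Distinct valve-mesh nodes that receive a chord segment."""
        if not len(self.segments):
            return np.empty(0, dtype=np.int64)
        ends = self.segments.ravel()
        return np.unique(ends[ends < self.n_valve_nodes])


# ---------------------------------------------------------------------------
# insertion sampling
# ---------------------------------------------------------------------------


def _polyline_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at_arclength(points: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    s = np.clip(s, 0.0, cum[-1])
    k = np.searchsorted(cum, s, side="right") - 1
    k = min(k, len(points) - 2)
    seg = cum[k + 1] - cum[k]
    t = 0.0 if seg == 0 else (s - cum[k]) / seg
    return (1 - t) * points[k] + t * points[k + 1]


def sample_primary_insertions(model: ValveModel, density: float, seed: int = 0,
                              allow_out_of_range: bool = False) -> np.ndarray:
    """Insertion centers equally spaced along the free edge.

    ``density`` in chords/cm of total free-edge arclength; count =
    round(density * length_cm) with at least one insertion per leaflet.
    A seeded phase offset rotates the equally spaced pattern.
    """
    if not (allow_out_of_range or PRIMARY_DENSITY_RANGE[0] <= density <= PRIMARY_DENSITY_RANGE[1]):
        raise ValueError(f"primary density {density} outside range {PRIMARY_DENSITY_RANGE}")
    paths = [np.asarray(p) for p in model.free_edge_paths if len(p) >= 2]
    if not paths:
        raise ValueError("model has an empty free edge")
    # concatenate leaflet paths into one polyline (loop order)
    pts = [model.nodes[paths[0]]]
    for p in paths[1:]:
        pts.append(model.nodes[p][1:])
    poly = np.vstack(pts)
    closed = np.allclose(poly[0], poly[-1])
    if closed:
        poly = poly[:-1]
        poly = np.vstack([poly, poly[:1]])
    cum = _polyline_arclength(poly)
    length = cum[-1]
    count = max(int(round(density * length / 10.0)), len(paths))
    spacing = length / count
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, spacing) if closed else 0.5 * spacing
    s_vals = (phase + spacing * np.arange(count)) % length if closed else \
        np.minimum(phase + spacing * np.arange(count), length)
    centers = np.array([_point_at_arclength(poly, cum, s) for s in np.sort(s_vals)])

    # guarantee at least one insertion per leaflet
    fe_nodes = [model.nodes[p] for p in paths]
    owners = np.argmin(np.stack([cdist(centers, f).min(axis=1) for f in fe_nodes]), axis=0)
    missing = [l for l in range(len(paths)) if l not in owners]
    if missing:
        extra = [fe_nodes[l][len(fe_nodes[l]) // 2] for l in missing]
        centers = np.vstack([centers, extra])
    return centers


def _node_areas(model: ValveModel) -> np.ndarray:
    p = model.nodes[model.quads]
    n = 0.5 * np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1])
    qa = np.linalg.norm(n, axis=1)
    areas = np.zeros(model.n_nodes)
    np.add.at(areas, model.quads.ravel(), np.repeat(qa / 4.0, 4))
    return areas


def sample_secondary_insertions(model: ValveModel, density: float, region: np.ndarray,
                                seed: int = 0, allow_out_of_range: bool = False) -> np.ndarray:
    """Blue-noise (farthest-point) insertion centers over the BODY region.

    ``density`` in chords/cm^2; count = round(density * region area in cm^2).
    ``region`` is either a per-node label array (BODY selects) or a boolean
    mask. Deterministic for a fixed seed.
    """
    if not (allow_out_of_range or SECONDARY_DENSITY_RANGE[0] <= density <= SECONDARY_DENSITY_RANGE[1]):
        raise ValueError(f"secondary density {density} outside range {SECONDARY_DENSITY_RANGE}")
    region = np.asarray(region)
    mask = region if region.dtype == bool else region == BODY
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError("empty insertion region")
    area_mm2 = float(_node_areas(model)[idx].sum())
    count = int(round(density * area_mm2 / 100.0))
    count = max(count, 1)
    if count > len(idx):
        raise ValueError(f"requested {count} secondary insertions but region has only "
                         f"{len(idx)} nodes")
    pts = model.nodes[idx]
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(len(idx)))]
    d = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    for _ in range(count - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return pts[np.array(chosen)]


def assign_papillary(centers: np.ndarray, model: ValveModel) -> np.ndarray:
    """Euclidean-nearest papillary tip per center; ties go to the lowest label."""
    if len(model.papillary_tips) == 0:
        raise ValueError("model has no papillary tips")
    d = cdist(np.atleast_2d(centers), model.papillary_tips)
    return np.argmin(d, axis=1)  # argmin takes the first (lowest) on ties


# ---------------------------------------------------------------------------
# branch layout
# ---------------------------------------------------------------------------


def _node_normals(model: ValveModel) -> np.ndarray:
    p = model.nodes[model.quads]
    n = 0.5 * np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1])
    acc = np.zeros_like(model.nodes)
    np.add.at(acc, model.quads.ravel(), np.repeat(n, 4, axis=0).reshape(-1, 3) / 4.0)
    norm = np.linalg.norm(acc, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return acc / norm


def layout_branch_tips(model: ValveModel, center: np.ndarray, n_branches: int,
                       branch_radius: float) -> np.ndarray:
    """Mesh-node indices of branch insertion tips around ``center``.

    Tips are the vertices of a regular n-gon of circumradius
    ``branch_radius`` in the local tangent plane, with the first vertex
    aligned toward the annulus direction, snapped to nearest mesh nodes
    and deduplicated (so fewer than ``n_branches`` indices may return on
    coarse meshes).
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    center = np.asarray(center, dtype=float)
    d = np.linalg.norm(model.nodes - center, axis=1)
    nearest = int(np.argmin(d))
    if n_branches == 1:
        return np.array([nearest], dtype=np.int64)

    normal = _node_normals(model)[nearest]
    # orient the polygon toward the annulus (mean annulus point); this only
    # fixes the first-vertex direction, so a centroid suffices
    if len(model.annulus_nodes):
        toward_annulus = model.nodes[model.annulus_nodes].mean(axis=0) - center
    else:
        toward_annulus = np.array([1.0, 0.0, 0.0])
    t1 = toward_annulus - np.dot(toward_annulus, normal) * normal
    if np.linalg.norm(t1) < 1e-12:
        t1 = np.array([1.0, 0.0, 0.0]) - normal[0] * normal
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)

    ang = 2 * np.pi * np.arange(n_branches) / n_branches
    targets = center + branch_radius * (np.cos(ang)[:, None] * t1 + np.sin(ang)[:, None] * t2)
    tips = []
    for tgt in targets:
        i = int(np.argmin(np.linalg.norm(model.nodes - tgt, axis=1)))
        snap_err = np.linalg.norm(model.nodes[i] - tgt)
        if snap_err > branch_radius:
            log.warning("branch tip snapped %.2f mm from its polygon vertex "
                        "(radius %.2f); clamped to leaflet", snap_err, branch_radius)
        if i not in tips:
            tips.append(i)
    return np.array(tips, dtype=np.int64)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def build_chordae(model: ValveModel, params_list, *, edge_band: float = 1.5,
                  body_band_bounds=(0.2, 0.8)) -> ChordaeSet:
    """Generate the full chordae network for one or more parameter sets.

    For each insertion center: a trunk from its nearest papillary tip to a
    junction at ``branch_length`` from the center on the tip→center line,
    then one segment per branch tip. ``n_branches == 1`` or
    ``branch_length == 0`` degenerates to a single tip→insertion segment.
    """
    if isinstance(params_list, ChordParams):
        params_list = [params_list]
    if len(model.papillary_tips) == 0:
        raise ValueError("model has no papillary tips")

    n_valve = model.n_nodes
    extra: list = [tuple(t) for t in model.papillary_tips]
    pap_node_idx = np.arange(len(extra), dtype=np.int64) + n_valve

    segments, seg_csa, seg_chord = [], [], []
    chord_class, centers_rec, pap_rec = [], [], []
    chord_counter = 0
    dedup_events = total_tips = 0

    region_labels = None
    for params in params_list:
        if params.cdt_class == CdtClass.PRIMARY:
            centers = sample_primary_insertions(
                model, params.density, params.seed, params.allow_out_of_range)
        else:
            if region_labels is None:
                region_labels = surface_regions(model, edge_band, body_band_bounds)
            centers = sample_secondary_insertions(
                model, params.density, region_labels, params.seed, params.allow_out_of_range)
        paps = assign_papillary(centers, model)

        for center, pap in zip(centers, paps):
            tip = model.papillary_tips[pap]
            tip_node = int(pap_node_idx[pap])
            dist = float(np.linalg.norm(center - tip))
            if dist <= 1e-12:
                raise ValueError("insertion center coincides with papillary tip")
            bl = params.branch_length
            if bl >= dist:
                log.warning("branch_length %.2f >= tip-center distance %.2f; clamping "
                            "to half distance", bl, dist)
                bl = 0.5 * dist

            if params.n_branches == 1 or bl == 0.0:
                t = int(layout_branch_tips(model, center, 1, params.branch_radius)[0])
                total_tips += 1
                segments.append((tip_node, t))
                seg_csa.append(params.csa)
                seg_chord.append(chord_counter)
            else:
                tips = layout_branch_tips(model, center, params.n_branches, params.branch_radius)
                total_tips += params.n_branches
                dedup_events += params.n_branches - len(tips)
                junction = center + bl * (tip - center) / dist
                j_idx = n_valve + len(extra)
                extra.append(tuple(junction))
                segments.append((tip_node, j_idx))
                seg_csa.append(params.csa)
                seg_chord.append(chord_counter)
                for t in tips:
                    segments.append((j_idx, int(t)))
                    seg_csa.append(params.csa)
                    seg_chord.append(chord_counter)
            chord_class.append(int(params.cdt_class))
            centers_rec.append(center)
            pap_rec.append(int(pap))
            chord_counter += 1

    if total_tips and dedup_events / total_tips > 0.10:
        log.warning("%.0f%% of branch tips snapped to duplicate nodes — insertion "
                    "points are overlapping (density/radius near tool range limit)",
                    100.0 * dedup_events / total_tips)

    return ChordaeSet(
        n_valve_nodes=n_valve,
        extra_nodes=np.asarray(extra, dtype=float),
        segments=np.asarray(segments, dtype=np.int64).reshape(-1, 2),
        segment_csa=np.asarray(seg_csa, dtype=float),
        chord_id=np.asarray(seg_chord, dtype=np.int64),
        chord_class=np.asarray(chord_class, dtype=np.int64),
        insertion_centers=np.asarray(centers_rec, dtype=float).reshape(-1, 3),
        papillary_label=np.asarray(pap_rec, dtype=np.int64),
        papillary_node_index=pap_node_idx,
    )


def chordae_summary(ch: ChordaeSet) -> dict:
    """Counts used by the re-quantification analyses.

    total_csa sums the CSA of insertion-adjacent segments (segments with
    an endpoint on the valve mesh).
    """
    if ch.n_segments == 0:
        return {"n_insertion_points": 0, "total_csa": 0.0, "n_chords": 0, "n_segments": 0}
    at_insertion = np.any(ch.segments < ch.n_valve_nodes, axis=1)
    return {
        "n_insertion_points": int(len(ch.insertion_node_indices())),
        "total_csa": float(ch.segment_csa[at_insertion].sum()),
        "n_chords": int(ch.n_chords),
        "n_segments": int(ch.n_segments),
    }
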