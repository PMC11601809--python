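"""Valve-closure metrics: regurgitant orifice area, contact area,
billowing volume and first-principal-strain summaries.

ROA uses rays parallel to the annulus normal cast from a regular grid over
the annulus projection; with parallel rays, ray–mesh intersection is
exactly 2-D coverage of the grid point by the projected deformed
triangles, computed with an STR-tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely import STRtree
from shapely.geometry import Point, Polygon

from .closure_solver import ClosureResult, _quad_tris
from .mechanics import first_principal_strain
from .valve_geometry import AnnulusFrame, ValveModel

__all__ = [
    "MetricsReport",
    "regurgitant_orifice_area",
    "contact_area",
    "billowing_volume",
    "strain_summary",
    "compute_metrics",
]

DEFAULT_GRID_SPACING = 0.2  # mm
DEFAULT_TRACTION_TOL = 1e-9  # MPa


@dataclass
class MetricsReport:
    roa: float
    contact_area: float
    billowing_volume: float
    strain_summary: dict
    parameter_record: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "roa_mm2": self.roa,
            "ca_mm2": self.contact_area,
            "billow_mm3": self.billowing_volume,
        }
        for k in ("median", "q25", "q75", "min", "max"):
            row[f"strain_{k}"] = self.strain_summary[k]
        return row


def _cross2(u, v):
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


def _deformed_tris(model: ValveModel, positions: np.ndarray) -> np.ndarray:
    tris = _quad_tris(model.quads)
    return positions[: model.n_nodes][tris]


def regurgitant_orifice_area(closure: ClosureResult, model: ValveModel,
                             frame: AnnulusFrame,
                             grid_spacing: float = DEFAULT_GRID_SPACING) -> float:
    """Open area (mm^2) through the deformed valve seen along the annulus normal.

    A grid point inside the projected annulus polygon whose normal-direction
    ray hits no leaflet triangle counts as open; ROA = open count x spacing^2.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    ann2d = frame.project(model.nodes[model.annulus_nodes])
    annulus_poly = Polygon(ann2d)
    if not annulus_poly.is_valid:
        annulus_poly = annulus_poly.buffer(0)

    xmin, ymin, xmax, ymax = annulus_poly.bounds
    gx = np.arange(xmin, xmax + grid_spacing, grid_spacing)
    gy = np.arange(ymin, ymax + grid_spacing, grid_spacing)
    XX, YY = np.meshgrid(gx, gy)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    inside = shapely.contains_xy(annulus_poly, pts[:, 0], pts[:, 1])
    pts = pts[inside]
    if len(pts) == 0:
        raise ValueError("grid covers no annulus-interior points; reduce grid_spacing")

    tris3d = _deformed_tris(model, closure.final_positions)
    tri2d = frame.project(tris3d.reshape(-1, 3)).reshape(-1, 3, 2)
    # drop degenerate (edge-on) projections
    cross = _cross2(tri2d[:, 1] - tri2d[:, 0], tri2d[:, 2] - tri2d[:, 0])
    tri2d = tri2d[np.abs(cross) > 1e-14]
    tri_polys = shapely.polygons(tri2d)
    tree = STRtree(tri_polys)
    point_geoms = shapely.points(pts)
    hit_idx, _ = tree.query(point_geoms, predicate="intersects")
    covered = np.zeros(len(pts), dtype=bool)
    covered[np.unique(hit_idx)] = True
    return float(np.count_nonzero(~covered)) * grid_spacing ** 2


def contact_area(closure: ClosureResult, model: ValveModel,
                 traction_tol: float = DEFAULT_TRACTION_TOL) -> float:
    """Deformed surface area (mm^2) of quads with contact traction above tol."""
    if traction_tol < 0:
        raise ValueError("traction_tol must be >= 0")
    flagged = closure.contact_traction > traction_tol
    if not np.any(flagged):
        return 0.0
    p = closure.final_positions[: model.n_nodes][model.quads[flagged]]
    areas = 0.5 * np.linalg.norm(np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1]), axis=1)
    return float(areas.sum())


def _clip_tri_above(tri, d):
    """Clip one triangle against d=0, keeping d>=0; returns polygon vertex list."""
    out = []
    for k in range(3):
        a, b = tri[k], tri[(k + 1) % 3]
        da, db = d[k], d[(k + 1) % 3]
        if da >= 0:
            out.append((a, da))
        if (da > 0 > db) or (da < 0 < db):
            t = da / (da - db)
            out.append((a + t * (b - a), 0.0))
    return out


def billowing_volume(closure_or_positions, model: ValveModel, frame: AnnulusFrame) -> float:
    """Volume (mm^3) enclosed between the atrial-side part of the deformed
    leaflet surface and the annulus plane (plane-clipped, divergence form).

    Per (clipped) triangle the contribution is signed-projected-area x mean
    height, which integrates the linear height field exactly.
    """
    if isinstance(closure_or_positions, ClosureResult):
        positions = closure_or_positions.final_positions
    else:
        positions = np.asarray(closure_or_positions)
    tris3d = _deformed_tris(model, positions)
    d = (tris3d - frame.origin) @ frame.normal  # (t, 3) heights
    e1, e2 = frame.in_plane_axes

    def contrib(p3, h3):
        u = (p3 - frame.origin) @ np.stack([e1, e2]).T  # (k, 2)
        total = 0.0
        for k in range(1, len(p3) - 1):
            a2 = 0.5 * float(_cross2(u[k] - u[0], u[k + 1] - u[0]))
            total += a2 * float(h3[0] + h3[k] + h3[k + 1]) / 3.0
        return total

    vol = 0.0
    above = d > 0
    n_above = above.sum(axis=1)
    full = n_above == 3
    if np.any(full):
        p = tris3d[full]
        h = d[full]
        u = (p.reshape(-1, 3) - frame.origin) @ np.stack([e1, e2]).T
        u = u.reshape(-1, 3, 2)
        a2 = 0.5 * _cross2(u[:, 1] - u[:, 0], u[:, 2] - u[:, 0])
        vol += float(np.sum(a2 * h.mean(axis=1)))
    mixed = np.flatnonzero((n_above > 0) & (n_above < 3))
    for ti in mixed:
        poly = _clip_tri_above(tris3d[ti], d[ti])
        if len(poly) >= 3:
            pts = np.array([p for p, _ in poly])
            hs = np.array([h for _, h in poly])
            vol += contrib(pts, hs)
    return abs(vol)


def strain_summary(closure: ClosureResult, model: ValveModel | None = None,
                   area_weighted: bool = False) -> dict:
    """Median/quartiles/min/max of per-element first principal strain.

    Percentiles use the inclusive linear-interpolation convention; with
    ``area_weighted`` they are weighted by deformed element area.
    """
    e1 = np.asarray(first_principal_strain(closure.element_states))
    if e1.size == 0:
        raise ValueError("no elements to summarize")
    if area_weighted:
        if model is None:
            raise ValueError("area weighting requires the model")
        p = closure.final_positions[: model.n_nodes][model.quads]
        w = 0.5 * np.linalg.norm(np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1]), axis=1)
        order = np.argsort(e1)
        ev, wv = e1[order], w[order]
        cw = np.cumsum(wv) - 0.5 * wv
        cw /= wv.sum()
        q25, med, q75 = np.interp([0.25, 0.5, 0.75], cw, ev)
    else:
        q25, med, q75 = np.percentile(e1, [25, 50, 75])
    return {
        "median": float(med), "q25": float(q25), "q75": float(q75),
        "min": float(e1.min()), "max": float(e1.max()),
        "convention": "inclusive-linear", "area_weighted": bool(area_weighted),
    }


def compute_metrics(closure: ClosureResult, model: ValveModel, frame: AnnulusFrame,
                    grid_spacing: float = DEFAULT_GRID_SPACING,
                    traction_tol: float = DEFAULT_TRACTION_TOL,
                    parameter_record: dict | None = None) -> MetricsReport:
    """All four closure metrics in one report."""
    return MetricsReport(
        roa=regurgitant_orifice_area(closure, model, frame, grid_spacing),
        contact_area=contact_area(closure, model, traction_tol),
        billowing_volume=billowing_volume(closure, model, frame),
        strain_summary=strain_summary(closure),
        parameter_record=dict(parameter_record or {}, grid_spacing=grid_spacing,
                              traction_tol=traction_tol),
    )
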