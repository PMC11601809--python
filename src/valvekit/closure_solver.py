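"""Damped dynamic relaxation of pressurized valve closure.

Explicit (semi-implicit Euler / central-difference) integration of the
membrane–truss system with mass-proportional damping, a follower pressure
load ramped linearly over ``ramp_time`` and then held, penalty
leaflet-contact, and pinned annulus/papillary nodes. The quasi-static
closed state is taken as the damped long-time limit (termination on
kinetic-energy decay).

Unit system: mm / N / MPa / s / tonne-per-mm^3. 1 mmHg = 1.33322e-4 MPa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import mechanics
from .chordae_gen import ChordaeSet
from .mechanics import MaterialParams, MembraneState
from .valve_geometry import ValveModel

log = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "ClosureResult", "MMHG_TO_MPA",
           "lump_masses", "pressure_forces", "contact_forces", "stable_dt",
           "run_closure"]

MMHG_TO_MPA = 1.33322e-4
KPA_TO_MPA = 1e-3


@dataclass(frozen=True)
class SimulationConfig:
    """Closure-simulation controls.

    ``pressure_peak`` in mmHg (MV preset 100, TV preset 23.7); the ramp is
    linear over ``ramp_time`` and then held. ``damping_c`` is the
    mass-proportional damping rate (s^-1). ``contact_gap`` defaults to
    2x leaflet thickness when None.
    """

    pressure_peak: float = 100.0
    ramp_time: float = 0.005
    dt_min: float = 1e-8
    dt_max: float = 1e-4
    damping_c: float = 5000.0
    contact_penalty: float = 1.0      # MPa per mm^2 penetration-depth-squared
    contact_gap: float | None = None
    max_time: float = 0.025
    ke_tolerance: float = 1e-3
    safety: float = 0.8
    tension_only: bool = False
    kinetic_damping: bool = True      # zero velocities at kinetic-energy peaks
    contact_refresh: int = 20         # steps between contact-candidate rebuilds
    history_stride: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.dt_min <= self.dt_max):
            raise ValueError("need 0 < dt_min <= dt_max")
        if self.pressure_peak < 0:
            raise ValueError("pressure_peak must be >= 0")
        if self.ramp_time <= 0 or self.max_time < self.ramp_time:
            raise ValueError("need 0 < ramp_time <= max_time")

    def with_(self, **kw):
        return replace(self, **kw)


MV_SIM = SimulationConfig(pressure_peak=100.0)
TV_SIM = SimulationConfig(pressure_peak=23.7)


@dataclass
class ClosureResult:
    final_positions: np.ndarray       # (n_total, 3), valve nodes first
    element_states: MembraneState     # per quad
    contact_traction: np.ndarray      # (n_quads,), MPa
    chord_forces: np.ndarray          # (n_segments,), N
    diagnostics: dict = field(default_factory=dict)

    def displacements(self, model: ValveModel) -> np.ndarray:
        return self.final_positions[: model.n_nodes] - model.nodes


# ---------------------------------------------------------------------------
# assembly pieces
# ---------------------------------------------------------------------------


def _scatter_add(out: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """out[idx] += vals, with repeated indices, via bincount (fast path)."""
    n = len(out)
    for c in range(out.shape[1]):
        out[:, c] += np.bincount(idx, weights=vals[:, c], minlength=n)


def _quad_tris(quads: np.ndarray) -> np.ndarray:
    """Split quads into two triangles each; tris 2k and 2k+1 belong to quad k."""
    a, b, c, d = quads.T
    t0 = np.stack([a, b, c], axis=1)
    t1 = np.stack([a, c, d], axis=1)
    return np.concatenate([t0[:, None, :], t1[:, None, :]], axis=1).reshape(-1, 3)


def _tri_ref(nodes: np.ndarray, tris: np.ndarray):
    """Reference inverse Jacobians and areas for CST membrane triangles."""
    p = nodes[tris]
    E1 = p[:, 1] - p[:, 0]
    E2 = p[:, 2] - p[:, 0]
    n = np.cross(E1, E2)
    A0 = 0.5 * np.linalg.norm(n, axis=1)
    if np.any(A0 <= 1e-14):
        raise ValueError("zero-area reference triangle")
    e1 = E1 / np.linalg.norm(E1, axis=1, keepdims=True)
    nn = n / (2.0 * A0)[:, None]
    e2 = np.cross(nn, e1)
    Dm = np.empty((len(tris), 2, 2))
    Dm[:, 0, 0] = np.sum(E1 * e1, 1)
    Dm[:, 0, 1] = np.sum(E2 * e1, 1)
    Dm[:, 1, 0] = 0.0
    Dm[:, 1, 1] = np.sum(E2 * e2, 1)
    return np.linalg.inv(Dm), A0


def _membrane_forces(x, tris, invDm, A0, thickness, mat, out):
    """Accumulate CST membrane internal forces; returns per-tri I1 (for dt).

    Inlined plane-stress incompressible stress evaluation (same formula as
    :func:`valvekit.mechanics.membrane_pk2_stress`, kPa→MPa) for speed.
    """
    p0 = x[tris[:, 0]]
    d = np.empty((len(tris), 3, 2))
    d[:, :, 0] = x[tris[:, 1]] - p0
    d[:, :, 1] = x[tris[:, 2]] - p0
    F = d @ invDm                                                  # (t,3,2)
    C2 = np.einsum("tij,tik->tjk", F, F)
    c00, c01, c11 = C2[:, 0, 0], C2[:, 0, 1], C2[:, 1, 1]
    det = c00 * c11 - c01 * c01
    if np.any(det <= 0):
        raise FloatingPointError("inverted membrane element (det C2 <= 0)")
    idet = 1.0 / det
    I1 = c00 + c11 + idet
    xs = I1 - 3.0
    if mat.c2 * float(xs.max(initial=0.0)) ** 2 > 500.0:
        raise FloatingPointError(
            f"lee_sacks exponential overflow at element {int(np.argmax(xs))}")
    dpsi = (0.5 * mat.c0 + mat.c1 * mat.c2 * xs * np.exp(mat.c2 * xs * xs)) * KPA_TO_MPA
    # S = 2 psi' (I - det^-1 C^-1)   (C^-1 = adj/det)
    S = np.empty_like(C2)
    f = 2.0 * dpsi
    idet2 = idet * idet
    S[:, 0, 0] = f * (1.0 - c11 * idet2)
    S[:, 1, 1] = f * (1.0 - c00 * idet2)
    S[:, 0, 1] = S[:, 1, 0] = f * (c01 * idet2)
    P = F @ S
    G = -(A0 * thickness)[:, None, None] * (P @ np.swapaxes(invDm, 1, 2))
    f1 = G[:, :, 0]
    f2 = G[:, :, 1]
    idx = np.concatenate([tris[:, 1], tris[:, 2], tris[:, 0]])
    _scatter_add(out, idx, np.concatenate([f1, f2, -f1 - f2]))
    return I1, C2


def _truss_forces(x, segments, L0, EA, tension_only, out):
    d = x[segments[:, 1]] - x[segments[:, 0]]
    L = np.linalg.norm(d, axis=1)
    stretch = L / L0
    f = EA * (stretch - 1.0)
    if tension_only:
        f = np.maximum(f, 0.0)
    u = d / L[:, None]
    fv = f[:, None] * u
    _scatter_add(out, np.concatenate([segments[:, 0], segments[:, 1]]),
                 np.concatenate([fv, -fv]))
    return f, stretch


def lump_masses(model: ValveModel, chordae: ChordaeSet | None, mat: MaterialParams) -> np.ndarray:
    """Lumped nodal masses (tonne): shell area x thickness plus truss
    length x CSA, times density, split equally among element nodes."""
    n_total = model.n_nodes + (len(chordae.extra_nodes) if chordae is not None else 0)
    masses = np.zeros(n_total)
    p = model.nodes[model.quads]
    qa = 0.5 * np.linalg.norm(np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1]), axis=1)
    contrib = qa * mat.thickness * mat.tissue_density / 4.0
    np.add.at(masses, model.quads.ravel(), np.repeat(contrib, 4))
    if chordae is not None and chordae.n_segments:
        allx = chordae.all_nodes(model.nodes)
        L = np.linalg.norm(allx[chordae.segments[:, 1]] - allx[chordae.segments[:, 0]], axis=1)
        tc = L * chordae.segment_csa * mat.tissue_density / 2.0
        np.add.at(masses, chordae.segments[:, 0], tc)
        np.add.at(masses, chordae.segments[:, 1], tc)
    return masses


def pressure_forces(model: ValveModel, cur_positions: np.ndarray, p: float) -> np.ndarray:
    """Follower pressure load on the ventricular face (atrial-pointing
    quad normals), p in MPa; per-quad force split equally to its nodes."""
    if p < 0:
        raise ValueError("pressure must be >= 0")
    out = np.zeros_like(cur_positions)
    if p == 0.0:
        return out
    q = model.quads
    pts = cur_positions[q]
    an = 0.5 * np.cross(pts[:, 2] - pts[:, 0], pts[:, 3] - pts[:, 1])  # area*normal
    fv = (p / 4.0) * an
    _scatter_add(out, q.T.ravel(), np.tile(fv, (4, 1)))
    return out


# ---------------------------------------------------------------------------
# contact
# ---------------------------------------------------------------------------


def _point_tri_closest(p, a, b, c):
    """Vectorized closest point on triangles (a,b,c) to points p.

    Returns (closest, bary) with bary = (w_a, w_b, w_c). Ericson's method.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, 1)
    d2 = np.sum(ac * ap, 1)
    bp = p - b
    d3 = np.sum(ab * bp, 1)
    d4 = np.sum(ac * bp, 1)
    cp = p - c
    d5 = np.sum(ab * cp, 1)
    d6 = np.sum(ac * cp, 1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-30, 1e-30, denom)
    v = vb / denom
    w = vc / denom

    out_v = np.clip(v, 0.0, 1.0)
    out_w = np.clip(w, 0.0, 1.0)

    # vertex regions
    reg_a = (d1 <= 0) & (d2 <= 0)
    reg_b = (d3 >= 0) & (d4 <= d3)
    reg_c = (d6 >= 0) & (d5 <= d6)
    # edge regions
    reg_ab = (~reg_a) & (~reg_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    reg_ac = (~reg_a) & (~reg_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    reg_bc = (~reg_b) & (~reg_c) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)

    t_ab = np.where(np.abs(d1 - d3) > 1e-30, d1 / np.maximum(d1 - d3, 1e-30), 0.0)
    t_ac = np.where(np.abs(d2 - d6) > 1e-30, d2 / np.maximum(d2 - d6, 1e-30), 0.0)
    denom_bc = (d4 - d3) + (d5 - d6)
    t_bc = np.where(np.abs(denom_bc) > 1e-30, (d4 - d3) / np.maximum(denom_bc, 1e-30), 0.0)

    out_v = np.where(reg_ab, np.clip(t_ab, 0, 1), out_v)
    out_w = np.where(reg_ab, 0.0, out_w)
    out_v = np.where(reg_ac, 0.0, out_v)
    out_w = np.where(reg_ac, np.clip(t_ac, 0, 1), out_w)
    out_v = np.where(reg_bc, 1.0 - np.clip(t_bc, 0, 1), out_v)
    out_w = np.where(reg_bc, np.clip(t_bc, 0, 1), out_w)
    out_v = np.where(reg_a | reg_c, np.where(reg_a, 0.0, out_v), out_v)
    out_w = np.where(reg_a | reg_b, 0.0, out_w)
    out_v = np.where(reg_b, 1.0, out_v)
    out_w = np.where(reg_c, 1.0, out_w)

    closest = a + out_v[:, None] * ab + out_w[:, None] * ac
    bary = np.stack([1.0 - out_v - out_w, out_v, out_w], axis=1)
    return closest, bary


class _ContactEngine:
    """Node-to-triangle penalty contact with cached candidate pairs."""

    def __init__(self, model: ValveModel, n_total: int, penalty: float, gap: float):
        self.tris = _quad_tris(model.quads)
        self.n_tris = len(self.tris)
        self.n_valve = model.n_nodes
        self.n_total = n_total
        self.penalty = penalty
        self.gap = gap
        self.ref = model.nodes.astype(float)
        # one-ring adjacency matrix (with self-loops) to exclude self-pairs
        from scipy.sparse import coo_matrix
        q = model.quads
        rows, cols = [], []
        for a in range(4):
            for b in range(4):
                rows.append(q[:, a])
                cols.append(q[:, b])
        n = model.n_nodes
        self.adj = coo_matrix(
            (np.ones(16 * len(q), dtype=bool),
             (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)).tocsr()
        self.pairs_n = np.empty(0, dtype=np.int64)
        self.pairs_t = np.empty(0, dtype=np.int64)
        self.rad = np.zeros(len(self.tris))

    def refresh(self, x: np.ndarray, slack: float = 1.0):
        """Rebuild the candidate pair list.

        Pairs are kept only while their current distance is below
        ``(1 + slack) * gap``; the extra band covers motion between
        refreshes. Pairs already within the gap in the reference state
        (geodesic neighbours on the undeformed surface) are excluded.
        """
        xv = x[: self.n_valve]
        cent = xv[self.tris].mean(axis=1)
        rad = np.max(np.linalg.norm(xv[self.tris] - cent[:, None, :], axis=2), axis=1)
        tree = cKDTree(xv)
        groups = tree.query_ball_point(cent, r=(1.0 + slack) * self.gap + rad,
                                       workers=-1, return_sorted=False)
        counts = np.fromiter((len(g) for g in groups), dtype=np.int64, count=len(groups))
        pt = np.repeat(np.arange(len(self.tris)), counts)
        pn = np.concatenate([np.asarray(g, dtype=np.int64) for g in groups if g]) \
            if counts.sum() else np.empty(0, dtype=np.int64)
        if len(pn):
            tri = self.tris[pt]
            excl = (np.asarray(self.adj[pn, tri[:, 0]]).ravel()
                    | np.asarray(self.adj[pn, tri[:, 1]]).ravel()
                    | np.asarray(self.adj[pn, tri[:, 2]]).ravel())
            pn, pt = pn[~excl], pt[~excl]
        if len(pn):
            tri = self.tris[pt]
            closest, _ = _point_tri_closest(self.ref[pn], self.ref[tri[:, 0]],
                                            self.ref[tri[:, 1]], self.ref[tri[:, 2]])
            ref_d = np.linalg.norm(self.ref[pn] - closest, axis=1)
            pn, pt = pn[ref_d >= self.gap], pt[ref_d >= self.gap]
        if len(pn):
            # exact-distance prune: keep only pairs inside the slack band, so
            # the per-step cost tracks the coapting region only
            tri = self.tris[pt]
            closest, _ = _point_tri_closest(xv[pn], xv[tri[:, 0]], xv[tri[:, 1]],
                                            xv[tri[:, 2]])
            d = xv[pn] - closest
            keep = np.einsum("ij,ij->i", d, d) < ((1.0 + slack) * self.gap) ** 2
            pn, pt = pn[keep], pt[keep]
        self.pairs_n = pn
        self.pairs_t = pt
        self.rad = rad

    def forces(self, x: np.ndarray, node_area: np.ndarray):
        """Returns (nodal forces, per-quad traction MPa)."""
        f = np.zeros((self.n_total, 3))
        traction = np.zeros(self.n_tris // 2)
        if len(self.pairs_n) == 0:
            return f, traction
        pn, pt = self.pairs_n, self.pairs_t
        # cheap centroid prefilter before the exact point-triangle test
        xv = x[: self.n_valve]
        cent = xv[self.tris].mean(axis=1)
        dv = xv[pn] - cent[pt]
        near = np.einsum("ij,ij->i", dv, dv) < (self.gap + self.rad[pt]) ** 2
        if not np.any(near):
            return f, traction
        pn, pt = pn[near], pt[near]
        tri = self.tris[pt]
        p = x[pn]
        closest, bary = _point_tri_closest(p, x[tri[:, 0]], x[tri[:, 1]], x[tri[:, 2]])
        dvec = p - closest
        dist = np.linalg.norm(dvec, axis=1)
        active = dist < self.gap
        if not np.any(active):
            return f, traction
        pn, pt, tri = pn[active], pt[active], tri[active]
        dvec, dist, bary = dvec[active], dist[active], bary[active]

        # keep only the nearest candidate triangle per node
        order = np.lexsort((dist, pn))
        pn_o = pn[order]
        first = np.ones(len(pn_o), dtype=bool)
        first[1:] = pn_o[1:] != pn_o[:-1]
        sel = order[first]
        pn, pt, tri = pn[sel], pt[sel], tri[sel]
        dvec, dist, bary = dvec[sel], dist[sel], bary[sel]

        # face normal oriented toward the node
        e1 = x[tri[:, 1]] - x[tri[:, 0]]
        e2 = x[tri[:, 2]] - x[tri[:, 0]]
        n = np.cross(e1, e2)
        nn = np.linalg.norm(n, axis=1)
        n /= np.maximum(nn, 1e-30)[:, None]
        sign = np.sign(np.sum(n * dvec, axis=1))
        sign[sign == 0] = 1.0
        n *= sign[:, None]

        depth = self.gap - dist
        t_mag = self.penalty * depth * depth          # MPa
        fmag = t_mag * node_area[pn]                  # N
        fv = fmag[:, None] * n
        idx = np.concatenate([pn, tri[:, 0], tri[:, 1], tri[:, 2]])
        vals = np.concatenate([fv, -bary[:, 0][:, None] * fv,
                               -bary[:, 1][:, None] * fv, -bary[:, 2][:, None] * fv])
        _scatter_add(f, idx, vals)
        traction += np.bincount(pt // 2, weights=t_mag, minlength=len(traction))
        return f, traction


def contact_forces(cur_positions: np.ndarray, model: ValveModel, penalty: float,
                   gap: float):
    """One-shot contact evaluation (spec surface); returns (forces, per-quad
    traction). ``run_closure`` uses the same engine with candidate caching."""
    if gap <= 0:
        raise ValueError("contact gap must be positive")
    eng = _ContactEngine(model, len(cur_positions), penalty, gap)
    eng.refresh(cur_positions)
    areas = _tributary_node_areas(model, cur_positions)
    return eng.forces(cur_positions, areas)


def _tributary_node_areas(model: ValveModel, x: np.ndarray) -> np.ndarray:
    out = np.zeros(len(x))
    p = x[: model.n_nodes][model.quads]
    qa = 0.5 * np.linalg.norm(np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1]), axis=1)
    np.add.at(out, model.quads.ravel(), np.repeat(qa / 4.0, 4))
    return out


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------


def stable_dt(I1_tri, L_char, mat: MaterialParams, config: SimulationConfig,
              truss_dt: float = np.inf) -> float:
    """CFL-style bound: safety * min(L / dilatational wave speed), clamped
    to [dt_min, dt_max]. Aborts if the requirement falls below dt_min."""
    dpsi = mechanics.lee_sacks_dpsi(I1_tri, mat)
    d2psi = mechanics.lee_sacks_d2psi(I1_tri, mat)
    x = np.maximum(I1_tri - 3.0, 0.0)
    E_eff = (4.0 * dpsi + 8.0 * d2psi * np.maximum(x, 0.5)) * KPA_TO_MPA  # MPa
    c_wave = np.sqrt(E_eff / mat.tissue_density)
    dt = config.safety * float(np.min(L_char / c_wave))
    dt = min(dt, truss_dt)
    if dt < config.dt_min:
        raise RuntimeError(f"stability requires dt={dt:.3e} < dt_min={config.dt_min:.3e}")
    return min(max(dt, config.dt_min), config.dt_max)


def run_closure(model: ValveModel, chordae: ChordaeSet | None, mat: MaterialParams,
                config: SimulationConfig,
                external_forces: np.ndarray | None = None) -> ClosureResult:
    """Damped explicit relaxation to the pressurized closed state.

    Pressure ramps linearly to ``pressure_peak`` over ``ramp_time`` then
    holds; integration stops once kinetic energy has decayed below
    ``ke_tolerance`` x its peak (after the ramp) or at ``max_time``.
    Annulus and papillary-tip nodes are pinned. ``external_forces`` adds a
    constant (dead) nodal load, ramped with the pressure curve.
    """
    n_valve = model.n_nodes
    x0 = chordae.all_nodes(model.nodes).astype(float) if chordae is not None else model.nodes.astype(float)
    n_total = len(x0)
    has_shell = model.n_quads > 0

    pinned = np.zeros(n_total, dtype=bool)
    pinned[model.annulus_nodes] = True
    if chordae is not None and len(chordae.papillary_node_index):
        pinned[chordae.papillary_node_index] = True

    if has_shell:
        tris = _quad_tris(model.quads)
        invDm, A0 = _tri_ref(model.nodes, tris)
        # characteristic length: smallest altitude = 2A / longest edge
        p = model.nodes[tris]
        edges = np.stack([
            np.linalg.norm(p[:, 1] - p[:, 0], axis=1),
            np.linalg.norm(p[:, 2] - p[:, 1], axis=1),
            np.linalg.norm(p[:, 0] - p[:, 2], axis=1),
        ])
        L_char = 2.0 * A0 / edges.max(axis=0)

    has_truss = chordae is not None and chordae.n_segments > 0
    if has_truss:
        segs = chordae.segments
        L0 = np.linalg.norm(x0[segs[:, 1]] - x0[segs[:, 0]], axis=1)
        if np.any(L0 <= 1e-12):
            raise ValueError("zero-length chord segment")
        EA = mat.truss_modulus * chordae.segment_csa

    masses = lump_masses(model, chordae, mat)
    masses = np.maximum(masses, 1e-16)

    gap = config.contact_gap if config.contact_gap is not None else 2.0 * mat.thickness
    contact = _ContactEngine(model, n_total, config.contact_penalty, gap) if has_shell else None

    # truss CFL
    if has_truss:
        c_truss = np.sqrt(mat.truss_modulus / mat.tissue_density)
        truss_dt = config.safety * float(np.min(L0)) / c_truss
    else:
        truss_dt = np.inf

    p_peak = config.pressure_peak * MMHG_TO_MPA

    x = x0.copy()
    v = np.zeros_like(x)
    t = 0.0
    step = 0
    # numerical residual of the internal forces at the reference state
    # (pure roundoff, ~1e-15 N); subtracted so a null load is exactly inert
    f_ref = np.zeros_like(x)
    if has_shell:
        _membrane_forces(x0, tris, invDm, A0, mat.thickness, mat, f_ref)
    if has_truss:
        _truss_forces(x0, segs, L0, EA, config.tension_only, f_ref)
    ke_peak = 0.0
    ke_prev = 0.0
    ke_hist, t_hist, dt_hist = [], [], []
    strain_e_hist, work_hist, ext_work = [], [], 0.0
    termination = "max_time"
    diag_error = None
    contact_traction = np.zeros(model.n_quads)
    node_area = _tributary_node_areas(model, x)

    while t < config.max_time:
        f = -f_ref.copy()
        ramp = min(t / config.ramp_time, 1.0)
        if has_shell:
            I1_tri, _ = _membrane_forces(x, tris, invDm, A0, mat.thickness, mat, f)
        if has_truss:
            _truss_forces(x, segs, L0, EA, config.tension_only, f)
        fp = pressure_forces(model, x[:n_valve], p_peak * ramp) if has_shell \
            else np.zeros((n_valve, 3))
        f[:n_valve] += fp
        if external_forces is not None:
            f += ramp * external_forces
        if has_shell:
            if step % config.contact_refresh == 0:
                contact.refresh(x)
                node_area = _tributary_node_areas(model, x)
            fc, contact_traction = contact.forces(x, node_area)
            f += fc
            dt = stable_dt(I1_tri, L_char, mat, config, truss_dt)
        else:
            dt = min(max(truss_dt, config.dt_min), config.dt_max)

        a = f / masses[:, None]
        damp = np.exp(-config.damping_c * dt)
        v = v * damp + dt * a
        v[pinned] = 0.0
        if config.kinetic_damping:
            # dynamic-relaxation kinetic damping: drop all velocity at a
            # kinetic-energy peak so the system settles onto equilibrium
            ke_now = 0.5 * float(np.einsum("i,ij,ij->", masses, v, v))
            if ke_now < ke_prev and t > config.ramp_time:
                v[:] = 0.0
                ke_prev = 0.0
            else:
                ke_prev = ke_now
        dx = dt * v
        x = x + dx
        ext_work += float(np.sum(fp * dx[:n_valve]))
        if external_forces is not None:
            ext_work += float(np.sum(ramp * external_forces * dx))
        t += dt
        step += 1

        if not np.all(np.isfinite(x)):
            termination = "diverged"
            diag_error = f"NaN/Inf at t={t:.5g}s step {step}"
            x = x - dx  # last stable state
            log.error("closure diverged: %s", diag_error)
            break

        if step % config.history_stride == 0 or t >= config.max_time:
            ke = 0.5 * float(np.sum(masses * np.sum(v * v, axis=1)))
            ke_hist.append(ke)
            t_hist.append(t)
            dt_hist.append(dt)
            se = 0.0
            if has_shell:
                psi_tri = mechanics.lee_sacks_energy(I1_tri, mat) * KPA_TO_MPA
                se += float(np.sum(psi_tri * A0 * mat.thickness))
            if has_truss:
                dL = np.linalg.norm(x[segs[:, 1]] - x[segs[:, 0]], axis=1) - L0
                if config.tension_only:
                    dL = np.maximum(dL, 0.0)
                se += float(np.sum(0.5 * EA / L0 * dL * dL))
            strain_e_hist.append(se)
            work_hist.append(ext_work)
            ke_peak = max(ke_peak, ke)
            # settle for at least 20% of the ramp beyond its end before
            # declaring quasi-static convergence
            if (t >= 1.2 * config.ramp_time and ke_peak > 0
                    and ke < config.ke_tolerance * ke_peak):
                termination = "kinetic_energy_converged"
                break

    if has_shell:
        states = mechanics.element_deformation_gradient(
            model.nodes[model.quads], x[:n_valve][model.quads])
    else:
        states = MembraneState(F=np.empty((0, 3, 2)), C2=np.empty((0, 2, 2)),
                               I1=np.empty(0))

    chord_forces = np.zeros(0)
    if has_truss:
        d = x[segs[:, 1]] - x[segs[:, 0]]
        stretch = np.linalg.norm(d, axis=1) / L0
        chord_forces = EA * (stretch - 1.0)
        if config.tension_only:
            chord_forces = np.maximum(chord_forces, 0.0)

    return ClosureResult(
        final_positions=x,
        element_states=states,
        contact_traction=contact_traction,
        chord_forces=chord_forces,
        diagnostics={
            "time": t,
            "steps": step,
            "termination": termination,
            "error": diag_error,
            "ke_history": np.asarray(ke_hist),
            "t_history": np.asarray(t_hist),
            "dt_history": np.asarray(dt_hist),
            "strain_energy_history": np.asarray(strain_e_hist),
            "external_work_history": np.asarray(work_hist),
            "external_work": ext_work,
            "ke_peak": ke_peak,
            "pinned_max_disp": float(np.abs(x[pinned] - x0[pinned]).max()) if pinned.any() else 0.0,
        },
    )
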