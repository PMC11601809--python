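"""Shared fixtures.

Closure simulations are expensive, so the baseline MV closure is computed
once per session and shared by the solver, metrics and acceptance tests.
Mesh sizes here are reduced relative to production defaults to keep the
suite within CI budgets; the asserted properties are size-independent.
"""

import logging

import numpy as np
import pytest

logging.getLogger("valvekit").setLevel(logging.ERROR)

from valvekit import study_runner as sr  # noqa: E402
from valvekit.closure_solver import SimulationConfig, run_closure  # noqa: E402
from valvekit.mechanics import MV_LEE_SACKS  # noqa: E402
from valvekit.valve_geometry import ValveModel, annulus_frame  # noqa: E402


TEST_MESH_ELEMS = 900


def small_config(mesh_elems: int = TEST_MESH_ELEMS) -> dict:
    cfg = sr.default_config()
    cfg["valve"]["mesh_target_elems"] = mesh_elems
    return cfg


@pytest.fixture(scope="session")
def mv_model():
    return sr.build_valve(small_config())


@pytest.fixture(scope="session")
def mv_chordae(mv_model):
    return sr.build_chordae_set(small_config(), mv_model)


@pytest.fixture(scope="session")
def mv_frame(mv_model):
    return annulus_frame(mv_model)


@pytest.fixture(scope="session")
def mv_closure(mv_model, mv_chordae):
    """Baseline pressurized MV closure (shared; ~20 s)."""
    return run_closure(mv_model, mv_chordae, MV_LEE_SACKS, SimulationConfig())


def make_flat_patch(nx: int, ny: int, lx: float = 10.0, ly: float = 10.0,
                    z: float = 0.0, offset=(0.0, 0.0)) -> ValveModel:
    """Flat rectangular quad patch in the z-plane (atrial normals +z)."""
    xs = np.linspace(0, lx, nx + 1) + offset[0]
    ys = np.linspace(0, ly, ny + 1) + offset[1]
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, float(z))])

    def nid(i, j):
        return i * (ny + 1) + j

    quads = []
    for i in range(nx):
        for j in range(ny):
            quads.append([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)])
    quads = np.asarray(quads, dtype=np.int64)
    # boundary loops: annulus = one edge, free edge = opposite edge
    annulus = np.array([nid(i, 0) for i in range(nx + 1)], dtype=np.int64)
    free_edge = np.array([nid(i, ny) for i in range(nx + 1)], dtype=np.int64)
    return ValveModel(
        nodes=nodes, quads=quads, annulus_nodes=annulus,
        free_edge_paths=[free_edge],
        leaflet_label=np.zeros(len(quads), dtype=np.int64),
        papillary_tips=np.array([[lx / 2 + offset[0], ly / 2 + offset[1], z - 20.0]]),
    )


def make_hemisphere(radius: float, n: int = 48, z0: float = 0.0) -> ValveModel:
    """Hemispherical cap (rim at z=z0), outward-wound quad mesh."""
    phi = np.linspace(0, np.pi / 2, n + 1)  # 0 = pole
    theta = np.linspace(0, 2 * np.pi, 2 * n, endpoint=False)
    nodes = [[0.0, 0.0, z0 + radius]]
    index = {}
    for i, ph in enumerate(phi[1:], start=1):
        for j, th in enumerate(theta):
            index[(i, j)] = len(nodes)
            nodes.append([radius * np.sin(ph) * np.cos(th),
                          radius * np.sin(ph) * np.sin(th),
                          z0 + radius * np.cos(ph)])
    quads = []
    nt = len(theta)
    for i in range(1, n):
        for j in range(nt):
            quads.append([index[(i, j)], index[(i, (j + 1) % nt)],
                          index[(i + 1, (j + 1) % nt)], index[(i + 1, j)]])
    # cap ring around the pole as degenerate quads
    for j in range(nt):
        quads.append([0, index[(1, j)], index[(1, (j + 1) % nt)],
                      index[(1, (j + 1) % nt)]])
    quads = np.asarray(quads, dtype=np.int64)
    rim = np.array([index[(n, j)] for j in range(nt)], dtype=np.int64)
    return ValveModel(
        nodes=np.asarray(nodes), quads=quads, annulus_nodes=rim,
        free_edge_paths=[], leaflet_label=np.zeros(len(quads), dtype=np.int64),
        papillary_tips=np.empty((0, 3)),
    )
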