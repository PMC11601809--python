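"""Constitutive and kinematic kernels.

Membrane: isotropic exponential (Lee–Sacks form) strain energy
``psi = c0/2 (I1-3) + c1/2 (exp(c2 (I1-3)^2) - 1)`` with exact plane-stress
incompressibility (thickness stretch from det of the in-plane right
Cauchy–Green tensor). Chordae: linear truss force, optional tension-only.

Energy/stress kernels work in kPa (the coefficients' native unit); the
solver converts to MPa where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MaterialParams",
    "MembraneState",
    "MV_LEE_SACKS",
    "TV_LEE_SACKS",
    "lee_sacks_energy",
    "lee_sacks_dpsi",
    "lee_sacks_d2psi",
    "membrane_pk2_stress",
    "truss_axial_force",
    "element_deformation_gradient",
    "first_principal_strain",
    "get_material",
]

_EXP_GUARD = 500.0  # max exponent before we refuse to evaluate


@dataclass(frozen=True)
class MaterialParams:
    """Leaflet + chordae material parameters.

    c0, c1 in kPa; c2 dimensionless; bulk_modulus (kPa) is written to the
    FEBio export only — the internal membrane is exactly incompressible.
    truss_modulus in MPa; thickness mm; tissue_density tonne/mm^3;
    damping_c is the mass-proportional damping rate (s^-1).
    """

    c0: float
    c1: float
    c2: float
    bulk_modulus: float
    truss_modulus: float = 150.0
    truss_csa: float = 1.0
    thickness: float = 0.396
    tissue_density: float = 1.04e-9
    damping_c: float = 5000.0

    def __post_init__(self):
        for name in ("c0", "c1", "bulk_modulus", "truss_modulus", "thickness", "tissue_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kw) -> "MaterialParams":
        return replace(self, **kw)


MV_LEE_SACKS = MaterialParams(c0=200.0, c1=2968.4, c2=0.2661, bulk_modulus=5000.0,
                              truss_modulus=150.0, truss_csa=1.0)
TV_LEE_SACKS = MaterialParams(c0=10.0, c1=0.209, c2=9.046, bulk_modulus=10000.0,
                              truss_modulus=150.0, truss_csa=0.44)

_PRESETS = {"mv_lee_sacks": MV_LEE_SACKS, "tv_lee_sacks": TV_LEE_SACKS}


def get_material(name_or_params) -> MaterialParams:
    """Resolve a preset name, mapping of overrides, or pass through params."""
    if isinstance(name_or_params, MaterialParams):
        return name_or_params
    if isinstance(name_or_params, str):
        try:
            return _PRESETS[name_or_params]
        except KeyError:
            raise KeyError(f"unknown material preset {name_or_params!r}; "
                           f"available: {sorted(_PRESETS)}") from None
    if isinstance(name_or_params, dict):
        d = dict(name_or_params)
        base = _PRESETS[d.pop("preset")] if "preset" in d else None
        return base.with_(**d) if base else MaterialParams(**d)
    raise TypeError(f"cannot interpret material {name_or_params!r}")


@dataclass
class MembraneState:
    """Per-element membrane kinematics.

    F : (..., 3, 2) surface deformation gradient (2D reference tangent
        coordinates to 3D current space)
    C2 : (..., 2, 2) in-plane right Cauchy–Green tensor
    I1 : (...,) first invariant including the incompressibility-determined
        thickness stretch, ``tr(C2) + 1/det(C2)``
    """

    F: np.ndarray
    C2: np.ndarray
    I1: np.ndarray


def _check_exponent(x2, c2):
    m = c2 * np.max(x2) if np.size(x2) else 0.0
    if m > _EXP_GUARD:
        idx = int(np.argmax(x2))
        raise FloatingPointError(
            f"lee_sacks exponential overflow at element {idx}: c2*(I1-3)^2 = {m:.3g}")


def lee_sacks_energy(I1, mat: MaterialParams):
    """Strain energy density (kPa). Zero at I1 = 3."""
    I1 = np.asarray(I1, dtype=float)
    if np.any(I1 < 3.0 - 1e-9):
        raise ValueError("I1 < 3 is not physical for an incompressible membrane")
    x = I1 - 3.0
    _check_exponent(x * x, mat.c2)
    psi = 0.5 * mat.c0 * x + 0.5 * mat.c1 * np.expm1(mat.c2 * x * x)
    return psi if psi.ndim else float(psi)


def lee_sacks_dpsi(I1, mat: MaterialParams):
    """d(psi)/d(I1) in kPa."""
    x = np.asarray(I1, dtype=float) - 3.0
    _check_exponent(x * x, mat.c2)
    return 0.5 * mat.c0 + mat.c1 * mat.c2 * x * np.exp(mat.c2 * x * x)


def lee_sacks_d2psi(I1, mat: MaterialParams):
    x = np.asarray(I1, dtype=float) - 3.0
    return mat.c1 * mat.c2 * np.exp(mat.c2 * x * x) * (1.0 + 2.0 * mat.c2 * x * x)


def invariant_I1(C2: np.ndarray) -> np.ndarray:
    """I1 = tr(C2) + 1/det(C2) (incompressible thickness stretch)."""
    C2 = np.asarray(C2, dtype=float)
    det = C2[..., 0, 0] * C2[..., 1, 1] - C2[..., 0, 1] * C2[..., 1, 0]
    return C2[..., 0, 0] + C2[..., 1, 1] + 1.0 / det


def membrane_pk2_stress(C2: np.ndarray, mat: MaterialParams) -> np.ndarray:
    """In-plane 2nd Piola–Kirchhoff stress (kPa), plane stress, incompressible.

    S = 2 psi'(I1) (I - det(C2)^-1 C2^-1), with
    I1 = tr(C2) + 1/det(C2). Symmetric; zero at C2 = I.
    """
    C2 = np.asarray(C2, dtype=float)
    det = C2[..., 0, 0] * C2[..., 1, 1] - C2[..., 0, 1] * C2[..., 1, 0]
    if np.any(det <= 0):
        raise ValueError("singular or inverted C2 (det <= 0)")
    I1 = C2[..., 0, 0] + C2[..., 1, 1] + 1.0 / det
    dpsi = lee_sacks_dpsi(I1, mat)
    inv = np.empty_like(C2)
    inv[..., 0, 0] = C2[..., 1, 1]
    inv[..., 1, 1] = C2[..., 0, 0]
    inv[..., 0, 1] = -C2[..., 0, 1]
    inv[..., 1, 0] = -C2[..., 1, 0]
    inv /= det[..., None, None]
    eye = np.zeros_like(C2)
    eye[..., 0, 0] = eye[..., 1, 1] = 1.0
    return 2.0 * dpsi[..., None, None] * (eye - inv / det[..., None, None])


def truss_axial_force(stretch, E: float, A: float, tension_only: bool = False):
    """Axial force (N) of a linear truss: E*A*(stretch - 1)."""
    stretch = np.asarray(stretch, dtype=float)
    if np.any(stretch <= 0):
        raise ValueError("stretch must be positive")
    if A <= 0:
        raise ValueError("cross-sectional area must be positive")
    f = E * A * (stretch - 1.0)
    if tension_only:
        f = np.maximum(f, 0.0)
    return f if f.ndim else float(f)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

# bilinear quad shape-function derivatives at the centroid
_DN_DXI = np.array([-0.25, 0.25, 0.25, -0.25])
_DN_DETA = np.array([-0.25, -0.25, 0.25, 0.25])


def _tangent_frame(g1, g2):
    """Orthonormal in-plane basis (e1 along g1) for tangent vectors g1, g2."""
    e1 = g1 / np.linalg.norm(g1, axis=-1, keepdims=True)
    n = np.cross(g1, g2)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(nn <= 1e-14):
        raise ValueError("zero-area reference element")
    e2 = np.cross(n / nn, e1)
    return e1, e2


def element_deformation_gradient(ref_coords: np.ndarray, cur_coords: np.ndarray) -> MembraneState:
    """Surface deformation gradient of quad elements at the centroid.

    ``ref_coords``/``cur_coords``: (..., 4, 3). Rigid motions give C2 = I.
    """
    ref = np.asarray(ref_coords, dtype=float)
    cur = np.asarray(cur_coords, dtype=float)
    G1 = np.einsum("k,...kj->...j", _DN_DXI, ref)
    G2 = np.einsum("k,...kj->...j", _DN_DETA, ref)
    g1 = np.einsum("k,...kj->...j", _DN_DXI, cur)
    g2 = np.einsum("k,...kj->...j", _DN_DETA, cur)
    e1, e2 = _tangent_frame(G1, G2)
    # reference Jacobian in local 2D coordinates (2x2, lower-left zero)
    Dm = np.stack(
        [
            np.stack([np.sum(G1 * e1, -1), np.sum(G2 * e1, -1)], -1),
            np.stack([np.sum(G1 * e2, -1), np.sum(G2 * e2, -1)], -1),
        ],
        axis=-2,
    )
    invDm = np.linalg.inv(Dm)
    ds = np.stack([g1, g2], axis=-1)  # (..., 3, 2)
    F = ds @ invDm
    C2 = np.swapaxes(F, -1, -2) @ F
    return MembraneState(F=F, C2=C2, I1=invariant_I1(C2))


def first_principal_strain(state_or_C2) -> np.ndarray:
    """Largest eigenvalue of the in-plane Green–Lagrange strain (C2 - I)/2."""
    C2 = state_or_C2.C2 if isinstance(state_or_C2, MembraneState) else np.asarray(state_or_C2)
    E = 0.5 * (C2 - np.eye(2))
    tr = 0.5 * (E[..., 0, 0] + E[..., 1, 1])
    dev = np.sqrt(0.25 * (E[..., 0, 0] - E[..., 1, 1]) ** 2 + E[..., 0, 1] * E[..., 1, 0])
    out = tr + dev
    return out if np.ndim(out) else float(out)
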