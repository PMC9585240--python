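"""Quasi-static EM fields of a line-current coil over a voxelized nerve.

The induced field is decomposed as E = −(dI/dt)·A/I − ∇φ: the primary
(magnetically induced) part is the vector potential of the coil scaled
by the current slew rate, and the conduction correction −∇φ enforces
charge conservation ∇·(σE) = 0 with zero normal current on the surface
of the bounded conductor (displacement currents dropped; at the pulse
content here ωε/σ ≪ 1 despite the large tissue permittivity).

A and B are evaluated per unit coil current with the exact analytic
finite-segment expressions, so fields are linear in current and in
dI/dt; RMS maps are obtained by scaling with a scalar drive factor
rather than by time-stepping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import cg

from .coil_geometry import MU0, CurrentPath

__all__ = [
    "VoxelGrid",
    "TissueModel",
    "FieldMap",
    "vector_potential",
    "b_field",
    "primary_e_field",
    "conduction_correction",
    "masked_gradient",
    "nerve_block",
    "nerve_cylinder",
    "nerve_ellipse_cylinder",
    "NERVE_SIGMA",
    "NERVE_EPS_R",
]

NERVE_SIGMA = 0.27  # S/m
NERVE_EPS_R = 5133.0


@dataclass(frozen=True)
class VoxelGrid:
    """Uniform cell-centered voxel grid (meters)."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if any(n < 2 for n in self.shape):
            raise ValueError("need at least 2 voxels per axis")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cell-center coordinates along each axis."""
        return tuple(
            self.origin[i] + (np.arange(self.shape[i]) + 0.5) * self.spacing[i]
            for i in range(3)
        )

    def centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel centers."""
        x, y, z = self.axes()
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class TissueModel:
    """Conductivity/permittivity map plus the nerve geometry it encodes."""

    grid: VoxelGrid
    sigma: np.ndarray  # S/m per voxel
    eps_r: np.ndarray
    nerve_shape: Literal["block", "cylinder", "ellipse_cylinder"]
    dimensions: dict = field(default_factory=dict)
    fiber_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.sigma.shape != self.grid.shape:
            raise ValueError("sigma shape must match grid")
        if np.any(self.sigma < 0):
            raise ValueError("conductivity must be non-negative")
        ax = np.asarray(self.fiber_axis, float)
        self.fiber_axis = tuple(ax / np.linalg.norm(ax))

    @property
    def mask(self) -> np.ndarray:
        """Conductive (nerve) voxels."""
        return self.sigma > 0

    @property
    def nerve_volume(self) -> float:
        """Analytic nerve volume (m³) from the stored dimensions."""
        d = self.dimensions
        if self.nerve_shape == "block":
            return d["lx"] * d["ly"] * d["lz"]
        if self.nerve_shape == "cylinder":
            return math.pi * d["radius"] ** 2 * d["length"]
        return math.pi * d["semi_axis_y"] * d["semi_axis_z"] * d["length"]

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Analytic membership test for (n, 3) points (meters)."""
        p = np.asarray(points)
        d = self.dimensions
        if self.nerve_shape == "block":
            return (
                (np.abs(p[:, 0]) <= d["lx"] / 2)
                & (np.abs(p[:, 1]) <= d["ly"] / 2)
                & (p[:, 2] <= 0)
                & (p[:, 2] >= -d["lz"])
            )
        if self.nerve_shape == "cylinder":
            r = d["radius"]
            return (np.abs(p[:, 0]) <= d["length"] / 2) & (
                p[:, 1] ** 2 + (p[:, 2] + r) ** 2 <= r**2
            )
        ay, az = d["semi_axis_y"], d["semi_axis_z"]
        return (np.abs(p[:, 0]) <= d["length"] / 2) & (
            (p[:, 1] / ay) ** 2 + ((p[:, 2] + az) / az) ** 2 <= 1.0
        )


@dataclass
class FieldMap:
    """Vector field samples on a voxel grid (T·m, T, or V/m)."""

    grid: VoxelGrid
    quantity: Literal["A", "B", "E_primary", "E_total"]
    values: np.ndarray  # (nx, ny, nz, 3)

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape + (3,):
            raise ValueError("values must have shape grid.shape + (3,)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.values, axis=-1)


def _nerve_grid(extent_x, extent_y, extent_z, spacing, z_top=0.0):
    sp3 = (spacing, spacing, spacing) if np.isscalar(spacing) else tuple(spacing)
    shape = tuple(
        max(2, int(round(e / s))) for e, s in zip((extent_x, extent_y, extent_z), sp3)
    )
    origin = (-extent_x / 2.0, -extent_y / 2.0, z_top - extent_z)
    return VoxelGrid(origin, sp3, shape)


def nerve_block(
    lx: float = 1.5e-3,
    ly: float = 0.3e-3,
    lz: float = 0.3e-3,
    spacing: float = 5e-6,
    sigma: float = NERVE_SIGMA,
    eps_r: float = NERVE_EPS_R,
) -> TissueModel:
    """Homogeneous rectangular nerve block, top surface at z = 0."""
    grid = _nerve_grid(lx, ly, lz, spacing)
    s = np.full(grid.shape, sigma)
    e = np.full(grid.shape, eps_r)
    return TissueModel(grid, s, e, "block", dict(lx=lx, ly=ly, lz=lz))


def nerve_cylinder(
    radius: float = 150e-6,
    length: float = 1.5e-3,
    spacing: float = 5e-6,
    sigma: float = NERVE_SIGMA,
    eps_r: float = NERVE_EPS_R,
) -> TissueModel:
    """Cylindrical nerve, axis along x, topmost surface point at z = 0."""
    grid = _nerve_grid(length, 2 * radius, 2 * radius, spacing)
    x, y, z = grid.axes()
    Y, Z = np.meshgrid(y, z + radius, indexing="ij")
    inside = (Y**2 + Z**2) <= radius**2
    s = np.where(inside[None, :, :], sigma, 0.0) * np.ones((grid.shape[0], 1, 1))
    e = np.where(s > 0, eps_r, 1.0)
    return TissueModel(grid, s, e, "cylinder", dict(radius=radius, length=length))


def nerve_ellipse_cylinder(
    semi_axis_y: float = 212.1e-6,
    semi_axis_z: float = 106.1e-6,
    length: float = 1.5e-3,
    spacing: float = 5e-6,
    sigma: float = NERVE_SIGMA,
    eps_r: float = NERVE_EPS_R,
) -> TissueModel:
    """Flattened (elliptical-cylinder) nerve, axis along x, top at z = 0.

    Defaults preserve the cross-section area of the 150 µm cylinder with
    a 2:1 aspect ratio (semi-axes 150·√2 × 150/√2 µm).
    """
    grid = _nerve_grid(length, 2 * semi_axis_y, 2 * semi_axis_z, spacing)
    x, y, z = grid.axes()
    Y, Z = np.meshgrid(y, z + semi_axis_z, indexing="ij")
    inside = (Y / semi_axis_y) ** 2 + (Z / semi_axis_z) ** 2 <= 1.0
    s = np.where(inside[None, :, :], sigma, 0.0) * np.ones((grid.shape[0], 1, 1))
    e = np.where(s > 0, eps_r, 1.0)
    return TissueModel(
        grid, s, e, "ellipse_cylinder",
        dict(semi_axis_y=semi_axis_y, semi_axis_z=semi_axis_z, length=length),
    )


def _segment_geometry(path: CurrentPath):
    a, b = path.segments
    dl = b - a
    length = np.linalg.norm(dl, axis=1)
    return a, b, dl, length, dl / length[:, None]


def vector_potential(
    path: CurrentPath,
    grid: VoxelGrid,
    wire_radius: float = 3.5e-6,
    chunk: int = 200_000,
) -> FieldMap:
    """Magnetic vector potential per unit current (T·m/A).

    Exact analytic contribution of each straight segment,
    A = (μ₀/4π)·û·ln[(r₁+s₁)(r₂−s₂)/ρ²], with the perpendicular distance
    ρ clamped at the wire radius so points on/inside the conductor stay
    finite.
    """
    a_pts, b_pts, dl, seg_len, u = _segment_geometry(path)
    pts = grid.centers().reshape(-1, 3)
    out = np.zeros_like(pts)
    for lo in range(0, pts.shape[0], chunk):
        p = pts[lo : lo + chunk]
        acc = np.zeros_like(p)
        for i in range(len(seg_len)):
            d = p - a_pts[i]
            s1 = d @ u[i]
            s2 = s1 - seg_len[i]
            rho2 = np.maximum(np.einsum("ij,ij->i", d, d) - s1**2, 0.0)
            rho2 = np.maximum(rho2, wire_radius**2)
            r1 = np.sqrt(s1**2 + rho2)
            r2 = np.sqrt(s2**2 + rho2)
            # stable log form: (r2+s2)(r2-s2) = rho^2
            val = np.log((r1 + s1) * (r2 - s2) / rho2)
            acc += val[:, None] * u[i]
        out[lo : lo + chunk] = acc
    out *= MU0 / (4.0 * math.pi)
    return FieldMap(grid, "A", out.reshape(grid.shape + (3,)))


def b_field(
    path: CurrentPath,
    grid: VoxelGrid,
    wire_radius: float = 3.5e-6,
    chunk: int = 200_000,
) -> FieldMap:
    """Magnetic flux density per unit current (T/A), exact per segment:
    B = (μ₀/4π)·(û×ρ̂)/ρ·(s₁/r₁ − s₂/r₂)."""
    a_pts, b_pts, dl, seg_len, u = _segment_geometry(path)
    pts = grid.centers().reshape(-1, 3)
    out = np.zeros_like(pts)
    for lo in range(0, pts.shape[0], chunk):
        p = pts[lo : lo + chunk]
        acc = np.zeros_like(p)
        for i in range(len(seg_len)):
            d = p - a_pts[i]
            s1 = d @ u[i]
            s2 = s1 - seg_len[i]
            perp = d - s1[:, None] * u[i]
            rho2 = np.maximum(np.einsum("ij,ij->i", perp, perp), wire_radius**2)
            r1 = np.sqrt(s1**2 + rho2)
            r2 = np.sqrt(s2**2 + rho2)
            coef = (s1 / r1 - s2 / r2) / rho2
            acc += coef[:, None] * np.cross(np.broadcast_to(u[i], p.shape), perp)
        out[lo : lo + chunk] = acc
    out *= MU0 / (4.0 * math.pi)
    return FieldMap(grid, "B", out.reshape(grid.shape + (3,)))


def primary_e_field(A: FieldMap, didt_rms: float) -> FieldMap:
    """E_primary = −(dI/dt)·A for a per-unit-current vector potential."""
    if A.quantity != "A":
        raise ValueError("expected a vector-potential FieldMap")
    return FieldMap(A.grid, "E_primary", -didt_rms * A.values)


def masked_gradient(f: np.ndarray, mask: np.ndarray, spacing) -> np.ndarray:
    """∇f of a scalar voxel field, restricted to ``mask``.

    Central differences where both axis neighbors are inside the mask,
    one-sided at the mask boundary, zero where no masked neighbor exists.
    Returns (nx, ny, nz, 3), zero outside the mask.
    """
    out = np.zeros(f.shape + (3,))
    for ax in range(3):
        h = spacing[ax]
        fm = np.roll(f, 1, axis=ax)
        fp = np.roll(f, -1, axis=ax)
        mm = np.roll(mask, 1, axis=ax)
        mp = np.roll(mask, -1, axis=ax)
        # roll wraps around; kill wrapped entries
        sl = [slice(None)] * 3
        sl[ax] = 0
        mm[tuple(sl)] = False
        sl[ax] = -1
        mp[tuple(sl)] = False
        g = np.zeros_like(f)
        both = mask & mm & mp
        g[both] = (fp[both] - fm[both]) / (2.0 * h)
        lo_only = mask & mm & ~mp
        g[lo_only] = (f[lo_only] - fm[lo_only]) / h
        hi_only = mask & ~mm & mp
        g[hi_only] = (fp[hi_only] - f[hi_only]) / h
        out[..., ax] = g
    return out


def _face_system(tissue: TissueModel):
    """Faces between adjacent conductive voxels: index pairs, axis, conductance."""
    mask = tissue.mask
    sigma = tissue.sigma
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(int(mask.sum()))
    faces = []
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        m = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        i = idx[tuple(sl_lo)][m]
        j = idx[tuple(sl_hi)][m]
        s_lo = sigma[tuple(sl_lo)][m]
        s_hi = sigma[tuple(sl_hi)][m]
        s_f = 2.0 * s_lo * s_hi / (s_lo + s_hi)  # harmonic mean
        faces.append((ax, i, j, s_f, m, tuple(sl_lo), tuple(sl_hi)))
    return idx, faces


def conduction_correction(
    tissue: TissueModel,
    E_primary: FieldMap,
    rtol: float = 1e-8,
    maxiter: int = 20000,
) -> FieldMap:
    """Charge-conservation correction: solve ∇·(σ(E_primary − ∇φ)) = 0.

    Finite-volume discretization on the conductive voxels with zero
    normal total current on the conductor boundary (the boundary faces
    simply carry no flux).  The pure-Neumann system is singular up to an
    additive constant; the right-hand side is projected onto the solvable
    subspace and φ is returned mean-free.  Conjugate gradients with a
    Jacobi preconditioner; raises on non-convergence.
    """
    if E_primary.grid != tissue.grid:
        raise ValueError("field and tissue grids differ")
    mask = tissue.mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no conductive voxels")
    h = tissue.grid.spacing
    idx, faces = _face_system(tissue)
    Ep = E_primary.values

    rows, cols, vals = [], [], []
    b = np.zeros(n)
    for ax, i, j, s_f, m, sl_lo, sl_hi in faces:
        # face area / distance and face-normal primary field (average)
        area = np.prod([h[k] for k in range(3) if k != ax])
        w = s_f * area / h[ax]
        rows += [i, j, i, j]
        cols += [i, j, j, i]
        vals += [w, w, -w, -w]
        e_face = 0.5 * (
            Ep[..., ax][tuple(sl_lo)][m] + Ep[..., ax][tuple(sl_hi)][m]
        )
        flux = s_f * area * e_face  # current i -> j carried by E_primary
        np.add.at(b, i, -flux)
        np.add.at(b, j, flux)
        del flux, e_face
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    b -= b.mean()
    diag = A.diagonal()
    diag[diag == 0] = 1.0
    M = sp.diags(1.0 / diag)
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        phi = np.zeros(n)
    else:
        phi, info = cg(A, b, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
        if info != 0:
            res = np.linalg.norm(A @ phi - b) / bnorm
            raise RuntimeError(
                f"conduction solve did not converge (info={info}, "
                f"relative residual {res:.3e})"
            )
        phi -= phi.mean()

    phi_grid = np.zeros(mask.shape)
    phi_grid[mask] = phi
    grad_phi = masked_gradient(phi_grid, mask, h)
    E_tot = np.where(mask[..., None], Ep - grad_phi, 0.0)
    return FieldMap(tissue.grid, "E_total", E_tot)


def cut_plane_current(
    tissue: TissueModel, E_total: FieldMap, axis: int, index: int
) -> float:
    """Net current (A) through the cut between voxel layers index-1|index
    along ``axis`` — a charge-conservation diagnostic (should be ~0)."""
    mask = tissue.mask
    sigma = tissue.sigma
    h = tissue.grid.spacing
    area = np.prod([h[k] for k in range(3) if k != axis])
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = index - 1
    sl_hi[axis] = index
    m = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
    s_f = (
        2.0 * sigma[tuple(sl_lo)][m] * sigma[tuple(sl_hi)][m]
        / (sigma[tuple(sl_lo)][m] + sigma[tuple(sl_hi)][m])
    )
    e_face = 0.5 * (
        E_total.values[..., axis][tuple(sl_lo)][m]
        + E_total.values[..., axis][tuple(sl_hi)][m]
    )
    return float(np.sum(s_f * e_face * area))
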