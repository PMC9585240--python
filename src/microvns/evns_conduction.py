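"""Electrical VNS through a cuff-electrode pair: conduction solve.

A pair of ring contacts wrapped around the nerve (default separation
1.5 mm) is modeled as ideal equipotential (Dirichlet) surfaces at ±V/2;
the interstitial potential solves ∇·(σ∇φ) = 0 with zero normal current
on the remaining nerve surface, and E = −∇φ.  Voltage-mode solutions
are linear in the drive, so current mode simply rescales the unit
solution until the injected current matches the requested amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import cg

from .em_fields import FieldMap, TissueModel, masked_gradient

__all__ = ["ElectrodePair", "solve_evns", "evns_activation", "EvnsSolution"]


@dataclass(frozen=True)
class ElectrodePair:
    """Cuff (ring) or hook contact pair along the nerve axis (x)."""

    geometry: Literal["cuff_ring", "hook"] = "cuff_ring"
    separation: float = 1.5e-3  # center-to-center, meters
    contact_width: float = 0.25e-3
    drive_mode: Literal["current", "voltage"] = "current"
    amplitude: float = 0.5e-3  # A (current mode) or V (voltage mode)

    def __post_init__(self) -> None:
        if self.separation <= self.contact_width:
            raise ValueError("separation must exceed contact_width")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class EvnsSolution:
    field: FieldMap  # E_total
    phi: np.ndarray
    total_current: float  # A at the applied voltage
    applied_voltage: float  # V across the pair after scaling


def _surface_mask(mask: np.ndarray) -> np.ndarray:
    """Conductive voxels with at least one non-conductive face neighbor."""
    surf = np.zeros_like(mask)
    for ax in range(3):
        for shift in (1, -1):
            nb = np.roll(mask, shift, axis=ax)
            sl = [slice(None)] * 3
            sl[ax] = 0 if shift == 1 else -1
            nb[tuple(sl)] = False
            surf |= mask & ~nb
    return surf


def solve_evns(
    tissue: TissueModel,
    electrodes: ElectrodePair,
    rtol: float = 1e-10,
    maxiter: int = 20000,
) -> EvnsSolution:
    """Solve the cuff-pair conduction problem on the voxelized nerve.

    Contacts are the nerve-surface voxels within ``contact_width`` of the
    two ring planes at x = ±separation/2 (for ``hook`` geometry, only the
    upper half of the circumference).  Raises if either contact set is
    empty or the iteration fails to converge.
    """
    grid = tissue.grid
    mask = tissue.mask
    sigma = tissue.sigma
    x, y, z = grid.axes()
    X = x[:, None, None] * np.ones(grid.shape)
    surf = _surface_mask(mask)
    if electrodes.geometry == "hook":
        Z = np.ones(grid.shape) * z[None, None, :]
        surf = surf & (Z > z.mean())
    half = electrodes.contact_width / 2.0
    contact_a = surf & (np.abs(X - (-electrodes.separation / 2.0)) <= half)
    contact_b = surf & (np.abs(X - (+electrodes.separation / 2.0)) <= half)
    if not contact_a.any() or not contact_b.any():
        raise ValueError("electrode contacts do not intersect the nerve surface")

    v_unit = 1.0  # solve at 1 V across the pair, scale afterwards
    phi_d = np.zeros(grid.shape)
    phi_d[contact_a] = +v_unit / 2.0
    phi_d[contact_b] = -v_unit / 2.0
    dirichlet = contact_a | contact_b
    free = mask & ~dirichlet

    idx = -np.ones(grid.shape, dtype=np.int64)
    n = int(free.sum())
    idx[free] = np.arange(n)
    h = grid.spacing
    rows, cols, vals = [], [], []
    b = np.zeros(n)
    diag = np.zeros(n)
    for ax in range(3):
        area = np.prod([h[k] for k in range(3) if k != ax])
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        pair = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        s_lo = sigma[tuple(sl_lo)][pair]
        s_hi = sigma[tuple(sl_hi)][pair]
        w = (2.0 * s_lo * s_hi / (s_lo + s_hi)) * area / h[ax]
        i_lo = idx[tuple(sl_lo)][pair]
        i_hi = idx[tuple(sl_hi)][pair]
        d_lo = dirichlet[tuple(sl_lo)][pair]
        d_hi = dirichlet[tuple(sl_hi)][pair]
        pv_lo = phi_d[tuple(sl_lo)][pair]
        pv_hi = phi_d[tuple(sl_hi)][pair]
        ff = ~d_lo & ~d_hi
        rows += [i_lo[ff], i_hi[ff], i_lo[ff], i_hi[ff]]
        cols += [i_lo[ff], i_hi[ff], i_hi[ff], i_lo[ff]]
        vals += [w[ff], w[ff], -w[ff], -w[ff]]
        fd = ~d_lo & d_hi  # free cell with Dirichlet neighbor above
        np.add.at(b, i_lo[fd], w[fd] * pv_hi[fd])
        np.add.at(diag, i_lo[fd], w[fd])
        df_ = d_lo & ~d_hi
        np.add.at(b, i_hi[df_], w[df_] * pv_lo[df_])
        np.add.at(diag, i_hi[df_], w[df_])
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    A = A + sp.diags(diag)
    M = sp.diags(1.0 / A.diagonal())
    phi_f, info = cg(A, b, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
    if info != 0:
        res = np.linalg.norm(A @ phi_f - b) / np.linalg.norm(b)
        raise RuntimeError(f"eVNS solve did not converge (residual {res:.3e})")

    phi = phi_d.copy()
    phi[free] = phi_f

    i_a = _contact_current(phi, tissue, contact_a)
    scale = (
        electrodes.amplitude / i_a
        if electrodes.drive_mode == "current"
        else electrodes.amplitude / v_unit
    )
    phi *= scale
    E = -masked_gradient(phi, mask, h)
    E = np.where(mask[..., None], E, 0.0)
    return EvnsSolution(
        field=FieldMap(grid, "E_total", E),
        phi=phi,
        total_current=i_a * scale,
        applied_voltage=v_unit * scale,
    )


def _contact_current(phi: np.ndarray, tissue: TissueModel, contact: np.ndarray) -> float:
    """Total conduction current leaving a contact voxel set (A)."""
    h = tissue.grid.spacing
    mask = tissue.mask
    sigma = tissue.sigma
    total = 0.0
    for ax in range(3):
        area = np.prod([h[k] for k in range(3) if k != ax])
        for shift in (1, -1):
            nb_phi = np.roll(phi, -shift, axis=ax)
            nb_mask = np.roll(mask, -shift, axis=ax)
            nb_contact = np.roll(contact, -shift, axis=ax)
            nb_sigma = np.roll(sigma, -shift, axis=ax)
            sl = [slice(None)] * 3
            sl[ax] = -1 if shift == 1 else 0
            nb_mask[tuple(sl)] = False
            m = contact & nb_mask & ~nb_contact
            s_f = 2.0 * sigma[m] * nb_sigma[m] / (sigma[m] + nb_sigma[m])
            total += float(np.sum(s_f * (phi[m] - nb_phi[m]) / h[ax] * area))
    return total


def evns_activation(
    solution: EvnsSolution,
    tissue: TissueModel,
    af_threshold: float = 1e5,
) -> dict:
    """Activation summary plus a field-uniformity statistic.

    Uniformity is the coefficient of variation of |E| over the nerve
    core between the contacts (inner half of the inter-electrode span);
    eVNS fields are nearly uniform there, µM-VNS fields are not.
    """
    from .activation_metrics import summarize_activation

    summary = summarize_activation(solution.field, tissue, af_threshold)
    mag = solution.field.magnitude
    x = tissue.grid.axes()[0]
    core = tissue.mask & (
        np.abs(x)[:, None, None] < 0.25 * (x.max() - x.min()) * np.ones(tissue.grid.shape)
    )
    vals = mag[core]
    cv = float(vals.std() / vals.mean()) if vals.size else np.nan
    return {"summary": summary, "uniformity_cv": cv,
            "total_current_A": solution.total_current,
            "applied_voltage_V": solution.applied_voltage}
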