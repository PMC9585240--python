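"""Parametric micro-coil geometries as discretized line currents.

Two commercial-style inductor geometries are modeled on the conductor
centerline: a multi-turn solenoid (wound chip inductor) and a planar
spiral (thin-film SMD inductor), both on an 0402 footprint
(1.0 × 0.5 mm).  Interior dimensions of the parts are not public, so
each coil's free parameter (spiral turn pitch; solenoid winding
diameter) is calibrated so that a Neumann-formula inductance estimate
matches the part's nominal value (33 nH spiral, 100 nH solenoid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

MU0 = 4e-7 * math.pi

__all__ = [
    "CoilSpec",
    "CurrentPath",
    "build_solenoid",
    "build_planar_spiral",
    "build_coil",
    "estimate_inductance",
    "calibrate_spiral_pitch",
    "calibrate_solenoid_length",
    "calibrate_solenoid_radius",
    "default_solenoid_spec",
    "default_spiral_spec",
]


@dataclass(frozen=True)
class CoilSpec:
    """Geometric description of a coil.

    ``outer_extent`` is the (length, width) footprint in meters:
    for the solenoid, length is along the winding axis and width is the
    winding diameter; for the planar spiral it is the outermost turn's
    bounding box.  ``orientation`` holds the coil axis (normal of the
    spiral plane / solenoid axis) and an in-plane reference direction.
    """

    kind: Literal["solenoid", "planar_spiral"]
    n_turns: float
    profile: Literal["elliptical", "rounded_rectangular"] = "rounded_rectangular"
    corner_radius: float = 30e-6
    conductor_width: float = 7e-6
    outer_extent: tuple[float, float] = (0.94e-3, 0.44e-3)
    pitch: float = 25e-6
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    in_plane: tuple[float, float, float] = (1.0, 0.0, 0.0)
    nominal_inductance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_turns <= 0:
            raise ValueError("n_turns must be positive")
        if self.conductor_width <= 0:
            raise ValueError("conductor_width must be positive")
        for name in ("axis", "in_plane"):
            v = np.asarray(getattr(self, name), dtype=float)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError(f"{name} must be a non-zero vector")
            object.__setattr__(self, name, tuple(v / n))

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (e1, e2, axis) with e1 the in-plane reference."""
        ax = np.asarray(self.axis)
        e1 = np.asarray(self.in_plane)
        e1 = e1 - np.dot(e1, ax) * ax
        n = np.linalg.norm(e1)
        if n < 1e-12:
            raise ValueError("in_plane is parallel to axis")
        e1 /= n
        e2 = np.cross(ax, e1)
        return e1, e2, ax


@dataclass(frozen=True)
class CurrentPath:
    """An ordered 3-D polyline carrying unit current."""

    points: np.ndarray  # (n, 3) meters
    closed: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
            raise ValueError("points must be (n>=2, 3)")
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive points must be distinct")
        object.__setattr__(self, "points", p)

    @property
    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) of all segments, closing the loop if ``closed``."""
        p = self.points
        if self.closed and not np.allclose(p[0], p[-1]):
            p = np.vstack([p, p[0]])
        return p[:-1], p[1:]

    @property
    def length(self) -> float:
        a, b = self.segments
        return float(np.linalg.norm(b - a, axis=1).sum())

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: Sequence[float] | None = None,
                    about: Sequence[float] | None = None) -> "CurrentPath":
        """Rigid transform: rotate about ``about`` (default centroid), then shift."""
        p = self.points.copy()
        if rotation is not None:
            c = np.mean(p, axis=0) if about is None else np.asarray(about, float)
            p = (p - c) @ np.asarray(rotation, float).T + c
        if translation is not None:
            p = p + np.asarray(translation, float)
        return CurrentPath(p, closed=self.closed)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.points, columns=["x_m", "y_m", "z_m"]).to_csv(
            path, index=False
        )


def default_solenoid_spec(**overrides) -> CoilSpec:
    """21-turn wound chip inductor on the 0402 footprint (nominal 100 nH).

    Close-wound construction: turn pitch = 1.1 x wire diameter, as in
    wire-wound chip parts; the winding diameter is the free parameter
    left for inductance calibration.
    """
    base = dict(
        kind="solenoid",
        n_turns=21.0,
        conductor_width=7e-6,
        outer_extent=(0.84e-3, 0.26e-3),
        pitch=1.1 * 7e-6,
        nominal_inductance=100e-9,
    )
    base.update(overrides)
    return CoilSpec(**base)


def default_spiral_spec(**overrides) -> CoilSpec:
    """8.5-turn thin-film planar spiral, nominal 33 nH."""
    base = dict(
        kind="planar_spiral",
        n_turns=8.5,
        conductor_width=7e-6,
        outer_extent=(0.94e-3, 0.44e-3),
        pitch=20e-6,
        nominal_inductance=33e-9,
    )
    base.update(overrides)
    return CoilSpec(**base)


def build_solenoid(spec: CoilSpec, max_seg: float = 20e-6) -> CurrentPath:
    """Helix of ``n_turns`` about the axis, segments no longer than ``max_seg``."""
    if spec.kind != "solenoid":
        raise ValueError("spec.kind must be 'solenoid'")
    if max_seg <= 0:
        raise ValueError("max_seg must be positive")
    e1, e2, ax = spec.frame()
    length, diameter = spec.outer_extent
    radius = diameter / 2.0
    pitch = spec.pitch if spec.pitch > 0 else length / spec.n_turns
    span = spec.n_turns * pitch
    if span > length * (1 + 1e-9):
        raise ValueError("winding span exceeds the coil length")
    theta_tot = 2.0 * math.pi * spec.n_turns
    # segment length per dtheta: sqrt(r^2 + (pitch/2pi)^2) dtheta
    dl_dtheta = math.hypot(radius, pitch / (2.0 * math.pi))
    n = max(2, int(math.ceil(theta_tot * dl_dtheta / max_seg)) + 1)
    theta = np.linspace(0.0, theta_tot, n)
    axial = (theta / (2.0 * math.pi)) * pitch - span / 2.0
    c = np.asarray(spec.center)
    pts = (
        c
        + np.outer(axial, ax)
        + radius * (np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2))
    )
    return CurrentPath(pts, closed=False)


def _rounded_rect_radius(phi: np.ndarray, a: np.ndarray, b: np.ndarray,
                         rc: float) -> np.ndarray:
    """Distance from center to a rounded-rectangle contour along angle phi.

    Half-extents (a, b), corner radius rc; the contour is the Minkowski
    sum of the (a-rc, b-rc) rectangle and a disk of radius rc.
    """
    c, s = np.cos(phi), np.sin(phi)
    eps = 1e-15
    r_rect = np.minimum(a / np.maximum(np.abs(c), eps),
                        b / np.maximum(np.abs(s), eps))
    x, y = r_rect * c, r_rect * s
    ax_, by_ = np.maximum(a - rc, 0.0), np.maximum(b - rc, 0.0)
    in_corner = (np.abs(x) > ax_) & (np.abs(y) > by_)
    if np.any(in_corner):
        ccx = ax_ * np.sign(c) if np.ndim(ax_) else ax_ * np.sign(c)
        ccy = by_ * np.sign(s) if np.ndim(by_) else by_ * np.sign(s)
        dc = c * ccx + s * ccy
        disc = np.maximum(dc**2 - (ccx**2 + ccy**2) + rc**2, 0.0)
        r_corner = dc + np.sqrt(disc)
        r_rect = np.where(in_corner, r_corner, r_rect)
    return r_rect


def build_planar_spiral(spec: CoilSpec, max_seg: float = 20e-6) -> CurrentPath:
    """Planar spiral on the coil plane, wound inward from ``outer_extent``.

    ``profile="rounded_rectangular"`` (default, matching the SEM
    appearance of thin-film SMD spirals) runs straight legs with rounded
    corners; ``"elliptical"`` is a smooth elliptical Archimedean spiral.
    Each turn the half-extents shrink by ``pitch``.
    """
    if spec.kind != "planar_spiral":
        raise ValueError("spec.kind must be 'planar_spiral'")
    if max_seg <= 0:
        raise ValueError("max_seg must be positive")
    e1, e2, ax = spec.frame()
    a0 = spec.outer_extent[0] / 2.0
    b0 = spec.outer_extent[1] / 2.0
    shrink = spec.pitch / (2.0 * math.pi)  # per radian
    theta_tot = 2.0 * math.pi * spec.n_turns
    if min(a0, b0) - shrink * theta_tot <= spec.conductor_width / 2.0:
        raise ValueError(
            "n_turns x pitch exceeds the outer extent (spiral would collapse)"
        )
    thetas = [0.0]
    while thetas[-1] < theta_tot:
        th = thetas[-1]
        r_eff = max(a0 - shrink * th, b0 - shrink * th, 1e-9)
        dth = max_seg / math.hypot(r_eff, shrink)
        thetas.append(min(th + dth, theta_tot))
    theta = np.asarray(thetas)
    a = a0 - shrink * theta
    b = b0 - shrink * theta
    if spec.profile == "elliptical":
        u = a * np.cos(theta)
        v = b * np.sin(theta)
    else:
        rc = min(spec.corner_radius, float(b.min()) * 0.9)
        r = _rounded_rect_radius(theta, a, b, rc)
        u = r * np.cos(theta)
        v = r * np.sin(theta)
    c = np.asarray(spec.center)
    pts = c + np.outer(u, e1) + np.outer(v, e2)
    return CurrentPath(pts, closed=False)


def build_coil(spec: CoilSpec, max_seg: float = 20e-6) -> CurrentPath:
    if spec.kind == "solenoid":
        return build_solenoid(spec, max_seg)
    return build_planar_spiral(spec, max_seg)


def estimate_inductance(path: CurrentPath, wire_radius: float) -> float:
    """Neumann double-sum inductance of a (near-)closed line current.

    Mutual terms use segment midpoints; the singular self term of each
    straight segment is the external self-inductance
    μ₀·l/(2π)·(ln(2l/a) − 1) of a round wire of radius ``a``.
    """
    if wire_radius <= 0:
        raise ValueError("wire_radius must be positive")
    a_pts, b_pts = path.segments
    dl = b_pts - a_pts
    seg_len = np.linalg.norm(dl, axis=1)
    if np.any(seg_len == 0):
        raise ValueError("degenerate zero-length segment")
    mid = 0.5 * (a_pts + b_pts)
    diff = mid[:, None, :] - mid[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    dots = dl @ dl.T
    np.fill_diagonal(r, 1.0)
    mutual = dots / r
    np.fill_diagonal(mutual, 0.0)
    # midpoint 1/r is poor for close pairs (notably segments sharing an
    # endpoint); redo those with an 8x8 sub-filament double sum
    nsub = 8
    lsum = seg_len[:, None] + seg_len[None, :]
    near = (r < 2.0 * lsum) & ~np.eye(len(seg_len), dtype=bool)
    if np.any(near):
        frac = (np.arange(nsub) + 0.5) / nsub
        for i, j in zip(*np.where(near)):
            if j < i:
                continue
            pi = a_pts[i] + np.outer(frac, dl[i])
            pj = a_pts[j] + np.outer(frac, dl[j])
            rr = np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=2)
            rr = np.maximum(rr, wire_radius)
            m = (np.dot(dl[i], dl[j]) / nsub**2) * np.sum(1.0 / rr)
            mutual[i, j] = mutual[j, i] = m
    L = (MU0 / (4.0 * math.pi)) * mutual.sum()
    L += (MU0 / (2.0 * math.pi)) * np.sum(
        seg_len * (np.log(2.0 * seg_len / wire_radius) - 1.0)
    )
    return float(L)


def calibrate_spiral_pitch(
    spec: CoilSpec,
    target_inductance: Optional[float] = None,
    wire_radius: Optional[float] = None,
    max_seg: float = 30e-6,
) -> CoilSpec:
    """Solve for the turn pitch so the spiral's inductance estimate hits
    the nominal part value (monotone decreasing in pitch at fixed outer
    extent).  Returns the spec unchanged if no target is available."""
    target = target_inductance or spec.nominal_inductance
    if target is None:
        return spec
    a = wire_radius if wire_radius is not None else spec.conductor_width / 2.0

    theta_tot = 2.0 * math.pi * spec.n_turns
    b0 = min(spec.outer_extent) / 2.0
    pitch_max = (b0 - spec.conductor_width) * 2.0 * math.pi / theta_tot * 0.98
    pitch_min = spec.conductor_width * 1.05

    def f(pitch: float) -> float:
        s = replace(spec, pitch=pitch)
        return estimate_inductance(build_planar_spiral(s, max_seg), a) - target

    lo, hi = f(pitch_min), f(pitch_max)
    if lo * hi > 0:
        # target outside the attainable range: keep the closest endpoint
        pitch = pitch_min if abs(lo) < abs(hi) else pitch_max
        return replace(spec, pitch=pitch)
    pitch = brentq(f, pitch_min, pitch_max, xtol=1e-8)
    return replace(spec, pitch=float(pitch))


def calibrate_solenoid_radius(
    spec: CoilSpec,
    target_inductance: Optional[float] = None,
    wire_radius: Optional[float] = None,
    max_seg: float = 20e-6,
) -> CoilSpec:
    """Solve for the winding diameter so the solenoid's inductance
    estimate matches the nominal part value (close-wound pitch is kept;
    inductance grows with winding radius).  The winding stays inside the
    package cross-section."""
    target = target_inductance or spec.nominal_inductance
    if target is None:
        return spec
    a = wire_radius if wire_radius is not None else spec.conductor_width / 2.0
    dia_max = spec.outer_extent[1]
    dia_min = 10 * spec.conductor_width

    def f(dia: float) -> float:
        s = replace(spec, outer_extent=(spec.outer_extent[0], dia))
        return estimate_inductance(build_solenoid(s, max_seg), a) - target

    lo, hi = f(dia_min), f(dia_max)
    if lo * hi > 0:
        dia = dia_min if abs(lo) < abs(hi) else dia_max
    else:
        dia = brentq(f, dia_min, dia_max, xtol=1e-9)
    return replace(spec, outer_extent=(spec.outer_extent[0], float(dia)))


def calibrate_solenoid_length(
    spec: CoilSpec,
    target_inductance: Optional[float] = None,
    wire_radius: Optional[float] = None,
    max_seg: float = 30e-6,
) -> CoilSpec:
    """Solve for the winding length (pitch) so the solenoid's inductance
    estimate matches the nominal part value at fixed winding radius
    (inductance grows as the winding is compressed)."""
    target = target_inductance or spec.nominal_inductance
    if target is None:
        return spec
    a = wire_radius if wire_radius is not None else spec.conductor_width / 2.0
    len_max = spec.outer_extent[0]
    len_min = spec.n_turns * spec.conductor_width * 1.1

    def f(length: float) -> float:
        s = replace(spec, pitch=length / spec.n_turns)
        return estimate_inductance(build_solenoid(s, max_seg), a) - target

    lo, hi = f(len_min), f(len_max)
    if lo * hi > 0:
        length = len_min if abs(lo) < abs(hi) else len_max
    else:
        length = brentq(f, len_min, len_max, xtol=1e-8)
    return replace(spec, pitch=float(length) / spec.n_turns)
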