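"""Axisymmetric vessel geometry: stenosed phantoms, two-view projection and
two-view reconstruction.

The lumen model is a rigid, axisymmetric tube described by an arclength
parameter ``s`` (mm), a 3D centerline and a radius profile ``r(s)`` (mm).
Synthetic "angiographic" views are orthographic projections of the centerline
with the local silhouette half-width; a 3D lumen is recovered from two views
whose directions are at least 30 degrees apart, with point correspondence by
normalized arclength and the radius taken as the mean of the two half-widths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

MIN_SEPARATION_DEG = 30.0
_SPACING_TOL_MM = 1e-6


class GeometryError(ValueError):
    """Invalid vessel geometry or stenosis specification."""


class InsufficientSeparationError(GeometryError):
    """The two projection directions are less than 30 degrees apart."""


class ReconstructionError(GeometryError):
    """Two-view reconstruction failed (e.g. unmatched polyline extents)."""


@dataclass(frozen=True)
class StenosisSpec:
    """Parametric stenosis: reference radius ``r0``, vessel length ``L``,
    stenosis centre ``s*``, stenosis length ``l`` and severity as percentage
    *diameter* reduction (the visual angiographic grading convention)."""

    r0_mm: float
    length_mm: float
    centre_mm: float
    stenosis_length_mm: float
    severity_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity_pct < 100.0):
            raise GeometryError(
                f"severity must be in [0, 100), got {self.severity_pct}")
        if not (0.0 < self.stenosis_length_mm < self.length_mm):
            raise GeometryError("stenosis length must satisfy 0 < l < L")
        if not (0.0 < self.centre_mm < self.length_mm):
            raise GeometryError("stenosis centre must lie inside the vessel")
        if self.r0_mm <= 0.0:
            raise GeometryError("reference radius must be positive")

    @property
    def min_radius_mm(self) -> float:
        return self.r0_mm * (1.0 - self.severity_pct / 100.0)


@dataclass
class VesselGeometry:
    """Axisymmetric rigid lumen: arclength samples (mm), 3D centerline points
    (mm) and the radius profile r(s) (mm)."""

    s_mm: np.ndarray
    centerline_mm: np.ndarray
    r_mm: np.ndarray

    def __post_init__(self) -> None:
        self.s_mm = np.asarray(self.s_mm, dtype=float)
        self.centerline_mm = np.asarray(self.centerline_mm, dtype=float)
        self.r_mm = np.asarray(self.r_mm, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.s_mm.size
        if n < 10:
            raise GeometryError(f"need at least 10 samples, got {n}")
        if self.centerline_mm.shape != (n, 3) or self.r_mm.shape != (n,):
            raise GeometryError("inconsistent array shapes")
        if not np.all(np.isfinite(self.s_mm)) or not np.all(
                np.isfinite(self.centerline_mm)) or not np.all(
                np.isfinite(self.r_mm)):
            raise GeometryError("non-finite values in geometry")
        if self.s_mm[0] != 0.0 or np.any(np.diff(self.s_mm) <= 0.0):
            raise GeometryError("arclength must increase strictly from 0")
        if np.any(self.r_mm <= 0.0):
            raise GeometryError("radius must be positive everywhere")
        spacing = np.linalg.norm(np.diff(self.centerline_mm, axis=0), axis=1)
        if np.max(np.abs(spacing - np.diff(self.s_mm))) > _SPACING_TOL_MM:
            raise GeometryError(
                "centerline spacing inconsistent with arclength increments")

    @property
    def n_samples(self) -> int:
        return self.s_mm.size

    @property
    def length_mm(self) -> float:
        return float(self.s_mm[-1])

    @property
    def min_radius_mm(self) -> float:
        return float(np.min(self.r_mm))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "s_mm": self.s_mm,
            "x_mm": self.centerline_mm[:, 0],
            "y_mm": self.centerline_mm[:, 1],
            "z_mm": self.centerline_mm[:, 2],
            "r_mm": self.r_mm,
        })

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "VesselGeometry":
        df = pd.read_csv(path, comment="#")
        return cls(
            s_mm=df["s_mm"].to_numpy(),
            centerline_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            r_mm=df["r_mm"].to_numpy(),
        )


@dataclass
class ProjectionView:
    """One synthetic angiographic view: projection angles (degrees), the
    projected 2D centerline polyline (mm) and the silhouette half-width
    profile (mm) along it."""

    view_id: str
    angles_deg: tuple[float, float]
    polyline_mm: np.ndarray
    half_width_mm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.polyline_mm = np.asarray(self.polyline_mm, dtype=float)
        self.half_width_mm = np.asarray(self.half_width_mm, dtype=float)
        if self.polyline_mm.ndim != 2 or self.polyline_mm.shape[1] != 2:
            raise GeometryError("polyline must be (n, 2)")
        if self.half_width_mm.shape != (self.polyline_mm.shape[0],):
            raise GeometryError("half-width length mismatch")

    @property
    def direction(self) -> np.ndarray:
        return view_direction(*self.angles_deg)

    def arclength_mm(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.polyline_mm, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def to_csv(self, path, header_comment: str | None = None) -> None:
        t = self.arclength_mm()
        total = t[-1] if t[-1] > 0 else 1.0
        df = pd.DataFrame({
            "t": t / total,
            "u_mm": self.polyline_mm[:, 0],
            "v_mm": self.polyline_mm[:, 1],
            "w_mm": self.half_width_mm,
        })
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False, float_format="%.10g")

    def sidecar(self) -> dict:
        return {"view_id": self.view_id,
                "angles_deg": list(self.angles_deg)}

    def write(self, csv_path, json_path,
              header_comment: str | None = None) -> None:
        self.to_csv(csv_path, header_comment)
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(self.sidecar(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, csv_path, json_path) -> "ProjectionView":
        df = pd.read_csv(csv_path, comment="#")
        with open(json_path, encoding="utf-8") as fh:
            side = json.load(fh)
        return cls(
            view_id=side["view_id"],
            angles_deg=tuple(side["angles_deg"]),
            polyline_mm=df[["u_mm", "v_mm"]].to_numpy(),
            half_width_mm=df["w_mm"].to_numpy(),
        )


def view_direction(alpha_deg: float, beta_deg: float) -> np.ndarray:
    """Unit projection direction for C-arm-style angles.

    ``alpha`` rotates about the patient (z) axis, ``beta`` elevates out of
    the x-y plane; (0, 0) looks along +x, (90, 0) along +y.
    """
    a = np.deg2rad(alpha_deg)
    b = np.deg2rad(beta_deg)
    return np.array([np.cos(b) * np.cos(a), np.cos(b) * np.sin(a), np.sin(b)])


def view_basis(alpha_deg: float, beta_deg: float):
    """Projection direction plus the in-plane (u, v) image basis."""
    d = view_direction(alpha_deg, beta_deg)
    zhat = np.array([0.0, 0.0, 1.0])
    ev = zhat - np.dot(zhat, d) * d
    nv = np.linalg.norm(ev)
    if nv < 1e-12:  # looking straight down the z axis
        ev = np.array([1.0, 0.0, 0.0]) - d[0] * d
        nv = np.linalg.norm(ev)
    ev = ev / nv
    eu = np.cross(ev, d)
    return d, eu, ev


def view_separation_deg(angles_a, angles_b) -> float:
    """Acute angle (degrees) between the two projection lines."""
    da = view_direction(*angles_a)
    db = view_direction(*angles_b)
    return float(np.degrees(np.arccos(np.clip(abs(np.dot(da, db)), 0.0, 1.0))))


def make_stenosed_phantom(spec: StenosisSpec, n_samples: int) -> VesselGeometry:
    """Straight-axis phantom with a raised-cosine stenosis.

    Inside the stenotic segment ``|s - s*| <= l/2`` the radius is
    ``r0 - (sigma/100) * r0 * 0.5 * (1 + cos(2*pi*(s - s*)/l))``, so the
    minimum ``r0 * (1 - sigma/100)`` is attained exactly at ``s*``; elsewhere
    the radius is ``r0``. The axis lies along z.
    """
    if n_samples < 10:
        raise GeometryError("n_samples must be >= 10")
    s = np.linspace(0.0, spec.length_mm, n_samples)
    r = np.full(n_samples, spec.r0_mm)
    inside = np.abs(s - spec.centre_mm) <= spec.stenosis_length_mm / 2.0
    depth = spec.severity_pct / 100.0 * spec.r0_mm
    bump = 0.5 * (1.0 + np.cos(
        2.0 * np.pi * (s[inside] - spec.centre_mm) / spec.stenosis_length_mm))
    r[inside] = spec.r0_mm - depth * bump
    centerline = np.zeros((n_samples, 3))
    centerline[:, 2] = s
    return VesselGeometry(s_mm=s, centerline_mm=centerline, r_mm=r)


def project_geometry(geom: VesselGeometry,
                     angles_deg: tuple[float, float],
                     noise_sd_mm: float = 0.0,
                     rng: np.random.Generator | None = None,
                     view_id: str = "view") -> ProjectionView:
    """Orthographic projection of an axisymmetric lumen.

    The centerline is projected onto the plane normal to the view direction;
    the silhouette half-width at each sample equals the true local radius
    (axisymmetry), optionally perturbed by additive Gaussian noise of the
    given standard deviation.
    """
    _, eu, ev = view_basis(*angles_deg)
    pts = geom.centerline_mm
    polyline = np.column_stack([pts @ eu, pts @ ev])
    widths = geom.r_mm.copy()
    if noise_sd_mm > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        widths = widths + rng.normal(0.0, noise_sd_mm, size=widths.shape)
    return ProjectionView(view_id=view_id, angles_deg=tuple(angles_deg),
                          polyline_mm=polyline, half_width_mm=widths)


def _auto_window(n: int) -> int:
    w = max(5, n // 14)
    if w % 2 == 0:
        w += 1
    return w


def reconstruct_from_two_views(a: ProjectionView, b: ProjectionView,
                               n_samples: int | None = None,
                               smooth_window: int | None = None,
                               ) -> VesselGeometry:
    """Triangulate an axisymmetric lumen from two calibrated views.

    Point correspondence between the two polylines is by normalized
    arclength; each 3D centerline point is the least-squares intersection of
    the two back-projection constraints, and the radius is the arithmetic
    mean of the two silhouette half-widths (unbiased under axisymmetry),
    lightly Savitzky-Golay smoothed.

    Raises
    ------
    InsufficientSeparationError
        if the view directions are less than 30 degrees apart.
    ReconstructionError
        if the polylines cannot be matched (degenerate extents or too few
        points).
    """
    sep = view_separation_deg(a.angles_deg, b.angles_deg)
    if sep < MIN_SEPARATION_DEG:
        raise InsufficientSeparationError(
            f"view separation {sep:.1f} deg < {MIN_SEPARATION_DEG:.0f} deg")
    if a.polyline_mm.shape[0] < 10 or b.polyline_mm.shape[0] < 10:
        raise ReconstructionError("projections have fewer than 10 points")
    ta, tb = a.arclength_mm(), b.arclength_mm()
    if ta[-1] <= 0.0 or tb[-1] <= 0.0:
        raise ReconstructionError("degenerate (zero-length) projected polyline")
    ratio = ta[-1] / tb[-1]
    if ratio > 3.0 or ratio < 1.0 / 3.0:
        raise ReconstructionError(
            f"unmatched polyline extents (length ratio {ratio:.2f})")

    if n_samples is None:
        n_samples = max(a.polyline_mm.shape[0], b.polyline_mm.shape[0])
    t = np.linspace(0.0, 1.0, n_samples)

    def resample(view: ProjectionView, tt: np.ndarray):
        tn = tt / tt[-1]
        u = np.interp(t, tn, view.polyline_mm[:, 0])
        v = np.interp(t, tn, view.polyline_mm[:, 1])
        w = np.interp(t, tn, view.half_width_mm)
        return u, v, w

    ua, va, wa = resample(a, ta)
    ub, vb, wb = resample(b, tb)

    _, eua, eva = view_basis(*a.angles_deg)
    _, eub, evb = view_basis(*b.angles_deg)
    A = np.vstack([eua, eva, eub, evb])          # (4, 3)
    pinv = np.linalg.pinv(A)                      # (3, 4)
    rhs = np.vstack([ua, va, ub, vb])             # (4, n)
    centerline = (pinv @ rhs).T                   # (n, 3)

    radius = 0.5 * (wa + wb)
    if smooth_window is None:
        smooth_window = _auto_window(n_samples)
    if smooth_window >= 5 and n_samples > smooth_window:
        radius = savgol_filter(radius, smooth_window, polyorder=2)

    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    if np.any(seg <= 0.0):
        raise ReconstructionError("triangulated centerline is degenerate")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return VesselGeometry(s_mm=s, centerline_mm=centerline, r_mm=radius)
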