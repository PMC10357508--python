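"""Steady flow through a rigid axisymmetric lumen under a pressure gradient.

Two backends share one contract (pressures in mmHg in, absolute flow in
ml/min out):

* ``reduced_order`` (default) — a quadratic pressure-drop model
  ``dP = a*Q + b*Q**2`` whose viscous coefficient ``a`` is the Poiseuille
  integral of the radius profile and whose inertial coefficient ``b`` is a
  Young-Tsai-type separation loss at the stenosis throat.
* ``axisymmetric`` — a stream-function/vorticity discretization of the
  steady incompressible Newtonian Navier-Stokes equations on a body-fitted
  axisymmetric grid (see :mod:`coroflow.axisym`), used as the internal
  high-fidelity oracle.

Interface units are mmHg / ml/min / mm; everything internal is SI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VesselGeometry

MMHG_TO_PA = 133.322
MLMIN_TO_M3S = 1e-6 / 60.0

#: conversion factor for a linear coefficient Pa/(m^3/s) -> mmHg/(ml/min)
_A_CONV = MLMIN_TO_M3S / MMHG_TO_PA
#: conversion factor for a quadratic coefficient Pa/(m^3/s)^2 -> mmHg/(ml/min)^2
_B_CONV = MLMIN_TO_M3S ** 2 / MMHG_TO_PA


class FlowError(ValueError):
    pass


class InadequateGradientError(FlowError):
    """Pa <= Pd: no epicardial pressure gradient to drive the computation."""


class ConvergenceError(RuntimeError):
    """Solver failed to reach the configured residual; carries the partial
    :class:`FlowResult` in ``.result``."""

    def __init__(self, message: str, result: "FlowResult | None" = None):
        super().__init__(message)
        self.result = result


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood analogue: dynamic viscosity (Pa s), density (kg/m^3)."""

    mu_pa_s: float = 0.0035
    rho_kg_m3: float = 1056.0

    def __post_init__(self) -> None:
        if self.mu_pa_s <= 0 or self.rho_kg_m3 <= 0:
            raise FlowError("viscosity and density must be positive")

    @property
    def nu_m2_s(self) -> float:
        return self.mu_pa_s / self.rho_kg_m3


@dataclass(frozen=True)
class SolverConfig:
    backend: str = "reduced_order"
    nx: int = 128
    nr: int = 32
    tol: float = 1e-6
    max_iter: int = 10_000
    K_e: float = 1.52

    def __post_init__(self) -> None:
        if self.backend not in ("reduced_order", "axisymmetric"):
            raise FlowError(f"unknown backend {self.backend!r}")
        if self.nx < 16 or self.nr < 8:
            raise FlowError("grid resolution must be at least 16x8")
        if self.tol <= 0:
            raise FlowError("tolerance must be positive")
        if self.max_iter < 1:
            raise FlowError("max_iter must be >= 1")


@dataclass
class FlowResult:
    """Absolute volumetric flow plus solver diagnostics."""

    q_ml_min: float
    backend: str
    converged: bool
    residual: float
    iterations: int
    reynolds: float


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert pressure from mmHg to pascals (factor 133.322)."""
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA


def viscous_coefficient(geom: VesselGeometry,
                        fluid: FluidProperties) -> float:
    """Linear pressure-drop coefficient ``a`` in mmHg per (ml/min).

    ``a = integral of 8*mu / (pi * r(s)^4) ds`` (trapezoidal quadrature);
    exactly the Poiseuille resistance for a constant-radius tube.
    """
    r_m = geom.r_mm * 1e-3
    s_m = geom.s_mm * 1e-3
    integrand = 8.0 * fluid.mu_pa_s / (np.pi * r_m ** 4)
    a_si = float(np.trapezoid(integrand, s_m))
    return a_si * _A_CONV


def expansion_coefficient(geom: VesselGeometry, fluid: FluidProperties,
                          K_e: float = 1.52) -> float:
    """Quadratic separation-loss coefficient ``b`` in mmHg per (ml/min)^2.

    ``b = K_e * rho/2 * (1/A_min - 1/A_out)^2`` with the minimal and distal
    cross-sectional areas; zero for an unstenosed tube.
    """
    r_m = geom.r_mm * 1e-3
    area = np.pi * r_m ** 2
    a_min = float(np.min(area))
    a_out = float(area[-1])
    if a_min >= a_out:
        return 0.0
    b_si = K_e * fluid.rho_kg_m3 / 2.0 * (1.0 / a_min - 1.0 / a_out) ** 2
    return b_si * _B_CONV


def reynolds_at_throat(geom: VesselGeometry, fluid: FluidProperties,
                       q_ml_min: float) -> float:
    """Reynolds number at the minimal lumen, Re = rho*u*D/mu."""
    r_min_m = geom.min_radius_mm * 1e-3
    q_si = q_ml_min * MLMIN_TO_M3S
    return 2.0 * fluid.rho_kg_m3 * q_si / (np.pi * r_min_m * fluid.mu_pa_s)


def _solve_quadratic(a: float, b: float, dp: float) -> float:
    """Unique positive root of b*Q^2 + a*Q = dp (a > 0, b >= 0, dp > 0),
    in the cancellation-free form 2*dp / (a + sqrt(a^2 + 4*b*dp))."""
    return 2.0 * dp / (a + np.sqrt(a * a + 4.0 * b * dp))


def solve_flow(geom: VesselGeometry, pa_mmhg: float, pd_mmhg: float,
               fluid: FluidProperties | None = None,
               cfg: SolverConfig | None = None) -> FlowResult:
    """Compute the steady flow driven by prescribing Pa at the inlet and Pd
    at the outlet of the reconstruction.

    Raises :class:`InadequateGradientError` when ``Pa <= Pd`` and
    :class:`ConvergenceError` when the iterative backend does not reach its
    residual within the iteration budget.
    """
    fluid = fluid or FluidProperties()
    cfg = cfg or SolverConfig()
    if pa_mmhg <= pd_mmhg:
        raise InadequateGradientError(
            f"Pa ({pa_mmhg} mmHg) must exceed Pd ({pd_mmhg} mmHg)")
    if pd_mmhg <= 0:
        raise FlowError("pressures must be positive")
    dp = pa_mmhg - pd_mmhg

    a = viscous_coefficient(geom, fluid)
    b = expansion_coefficient(geom, fluid, cfg.K_e)
    q_reduced = _solve_quadratic(a, b, dp)

    if cfg.backend == "reduced_order":
        residual = abs(a * q_reduced + b * q_reduced ** 2 - dp) / dp
        return FlowResult(
            q_ml_min=float(q_reduced), backend="reduced_order",
            converged=True, residual=float(residual), iterations=0,
            reynolds=reynolds_at_throat(geom, fluid, q_reduced))

    from .axisym import AxisymmetricSolver

    solver = AxisymmetricSolver(geom, fluid, cfg)
    q, iterations, residual, converged = solver.solve_for_pressure_drop(
        dp, q_init_ml_min=q_reduced)
    result = FlowResult(
        q_ml_min=float(q), backend="axisymmetric", converged=converged,
        residual=float(residual), iterations=iterations,
        reynolds=reynolds_at_throat(geom, fluid, q))
    if not converged:
        raise ConvergenceError(
            f"axisymmetric solver residual {residual:.3e} did not reach "
            f"{cfg.tol:.1e} within {cfg.max_iter} iterations", result)
    return result
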