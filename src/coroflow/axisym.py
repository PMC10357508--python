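"""Steady axisymmetric Navier-Stokes solver (stream-function / vorticity).

The incompressible steady momentum and continuity equations for a Newtonian
fluid are solved in the axisymmetric stream-function / vorticity form on a
body-fitted grid: the physical domain 0 <= rho <= R(x), 0 <= x <= L is
mapped to the unit rectangle with xi = x, eta = rho / R(x).  Continuity is
satisfied identically by the Stokes stream function psi
(u = psi_rho / rho, v = -psi_x / rho); the azimuthal vorticity
omega = v_x - u_rho satisfies the steady transport equation

    u w_x + v w_rho - v w / rho = nu (w_xx + w_rho rho + w_rho / rho - w/rho^2)

and is coupled to psi through E^2 psi = -rho * omega, where
E^2 = d_xx + d_rhorho - (1/rho) d_rho.

Discretization: second-order central differences on the mapped grid;
convection uses a hybrid scheme that blends smoothly from central
differencing to first-order upwinding as the local cell Peclet number
grows, assembled fully implicitly.  The vorticity solve is under-relaxed
implicitly (diagonal boosting); wall vorticity uses Jensen's second-order
formula with its own relaxation; the no-slip and axis conditions are exact.  The flow rate Q enters through the stream-function
boundary values (psi_wall - psi_axis = Q / 2 pi); the pressure drop for a
given Q is recovered from the discrete mechanical-energy balance
(viscous dissipation plus kinetic-energy flux difference), and an outer
secant iteration adjusts Q until the prescribed inlet/outlet pressure
difference is met.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.sparse import csr_matrix, diags
from scipy.sparse.linalg import splu

from .flow_solver import (FluidProperties, SolverConfig, MLMIN_TO_M3S,
                          MMHG_TO_PA)
from .geometry import VesselGeometry


@dataclass
class FieldSolution:
    """Converged (or partial) inner solve at fixed flow rate."""

    q_ml_min: float
    dp_mmhg: float
    psi: np.ndarray          # (nx+1, nr+1), SI
    omega: np.ndarray
    u: np.ndarray            # axial velocity, m/s
    v: np.ndarray            # radial velocity, m/s
    iterations: int
    residual: float
    converged: bool


class AxisymmetricSolver:
    """Body-fitted stream-function/vorticity solver for one lumen."""

    def __init__(self, geom: VesselGeometry, fluid: FluidProperties,
                 cfg: SolverConfig):
        self.fluid = fluid
        self.cfg = cfg
        nx, nr = cfg.nx, cfg.nr
        self.nx, self.nr = nx, nr

        s_m = geom.s_mm * 1e-3
        r_m = geom.r_mm * 1e-3
        spline = CubicSpline(s_m, r_m)
        self.L = float(s_m[-1])
        self.xi = np.linspace(0.0, self.L, nx + 1)
        self.eta = np.linspace(0.0, 1.0, nr + 1)
        self.dxi = self.L / nx
        self.deta = 1.0 / nr
        self.R = spline(self.xi)
        self.Rp = spline(self.xi, 1)
        self.Rpp = spline(self.xi, 2)
        if np.any(self.R <= 0):
            raise ValueError("radius profile must stay positive")

        E, H = np.meshgrid(self.xi, self.eta, indexing="ij")
        self.ETA = H
        R2 = self.R[:, None]
        Rp2 = self.Rp[:, None]
        Rpp2 = self.Rpp[:, None]
        # df/dx = df/dxi + A df/deta on the mapped grid
        self.A = -H * Rp2 / R2
        # coefficient of df/deta arising from d2f/dx2
        self.Aterm = -H * Rpp2 / R2 + 2.0 * H * Rp2 ** 2 / R2 ** 2
        self.rho_grid = H * R2                     # physical radius of nodes
        self._n_eta = nr + 1
        self._N = (nx + 1) * (nr + 1)
        self._psi_lu = splu(self._build_psi_matrix().tocsc())

    # ---------------------------------------------------------------- grids
    def _idx(self, i, j):
        return i * self._n_eta + j

    def _interior(self):
        i = np.arange(1, self.nx)
        j = np.arange(1, self.nr)
        I, J = np.meshgrid(i, j, indexing="ij")
        return I, J

    def _boundary_rows(self, rows, cols, vals):
        """Identity rows for Dirichlet boundaries, backward-difference rows
        for the outlet Neumann condition (shared by psi and omega)."""
        nx, nr = self.nx, self.nr
        # axis (j=0) and wall (j=nr): Dirichlet, all i
        for j in (0, nr):
            i = np.arange(nx + 1)
            rows.append(self._idx(i, j))
            cols.append(self._idx(i, j))
            vals.append(np.ones(nx + 1))
        # inlet (i=0): Dirichlet, interior j
        j = np.arange(1, nr)
        rows.append(self._idx(0, j))
        cols.append(self._idx(0, j))
        vals.append(np.ones(nr - 1))
        # outlet (i=nx): d/dxi = 0, interior j
        rows.append(self._idx(nx, j))
        cols.append(self._idx(nx, j))
        vals.append(np.ones(nr - 1))
        rows.append(self._idx(nx, j))
        cols.append(self._idx(nx - 1, j))
        vals.append(-np.ones(nr - 1))

    def _assemble(self, stencil):
        """Build the full sparse operator from interior stencil arrays."""
        I, J = self._interior()
        rows, cols, vals = [], [], []
        for (di, dj), coef in stencil.items():
            rows.append(self._idx(I, J).ravel())
            cols.append(self._idx(I + di, J + dj).ravel())
            vals.append(coef.ravel())
        self._boundary_rows(rows, cols, vals)
        rows = np.concatenate([np.asarray(r).ravel() for r in rows])
        cols = np.concatenate([np.asarray(c).ravel() for c in cols])
        vals = np.concatenate([np.asarray(v).ravel() for v in vals])
        return csr_matrix((vals, (rows, cols)), shape=(self._N, self._N))

    def _second_order_stencil(self, eta_first_coef, diag_extra):
        """Stencil for  f_xx + f_rhorho +/- ... expressed on the mapped grid:
        f_xixi + 2A f_xieta + (A^2 + 1/R^2) f_etaeta
        + eta_first_coef * f_eta + diag_extra * f   (interior nodes)."""
        I, J = self._interior()
        A = self.A[I, J]
        R = self.R[:, None][I, np.zeros_like(J)]
        dxi, deta = self.dxi, self.deta
        cxx = np.ones_like(A) / dxi ** 2
        ccr = 2.0 * A / (4.0 * dxi * deta)
        cee = (A ** 2 + 1.0 / R ** 2) / deta ** 2
        ce1 = eta_first_coef[I, J] / (2.0 * deta)
        st = {
            (1, 0): cxx.copy(),
            (-1, 0): cxx.copy(),
            (0, 1): cee + ce1,
            (0, -1): cee - ce1,
            (0, 0): -2.0 * cxx - 2.0 * cee + diag_extra[I, J],
            (1, 1): ccr.copy(),
            (-1, -1): ccr.copy(),
            (1, -1): -ccr,
            (-1, 1): -ccr,
        }
        return st

    def _build_psi_matrix(self):
        # E^2 f = f_xx + f_rhorho - (1/rho) f_rho
        eta_first = self.Aterm - 1.0 / (np.maximum(self.ETA, 1e-300)
                                        * self.R[:, None] ** 2)
        return self._assemble(
            self._second_order_stencil(eta_first, np.zeros_like(self.A)))

    def _build_omega_matrix(self, u, v):
        """Transport operator  Conv(w) - (v/rho) w - nu D(w), with hybrid
        convection: central differences where the cell Peclet number is
        at most 2, first-order upwind elsewhere (fully implicit)."""
        nu = self.fluid.nu_m2_s
        I, J = self._interior()
        # D f = f_xx + f_rhorho + (1/rho) f_rho - f / rho^2
        with np.errstate(divide="ignore"):
            inv_rho_R2 = 1.0 / (np.maximum(self.ETA, 1e-300)
                                * self.R[:, None] ** 2)
            diag_extra = -1.0 / np.maximum(self.rho_grid, 1e-300) ** 2
        eta_first = self.Aterm + inv_rho_R2
        diff = self._second_order_stencil(eta_first, diag_extra)
        st = {key: -nu * val for key, val in diff.items()}

        cxi = u[I, J]
        ceta = (u * self.A + v / self.R[:, None])[I, J]
        dxi, deta = self.dxi, self.deta
        nu_xi = nu                                  # f_xixi coefficient
        nu_eta = nu * (self.A ** 2 + 1.0 / self.R[:, None] ** 2)[I, J]
        # smooth central->upwind blend in the cell Peclet number (theta = 0
        # pure central, -> 1 pure upwind); continuity in the velocity field
        # keeps the Picard map free of switching limit cycles
        pe_xi = np.abs(cxi) * dxi / (2.0 * nu_xi)
        pe_eta = np.abs(ceta) * deta / (2.0 * nu_eta)
        th_xi = pe_xi ** 2 / (1.0 + pe_xi ** 2)
        th_eta = pe_eta ** 2 / (1.0 + pe_eta ** 2)

        cxp = th_xi * np.maximum(cxi, 0.0)
        cxm = th_xi * np.minimum(cxi, 0.0)
        cxc = (1.0 - th_xi) * cxi
        cep = th_eta * np.maximum(ceta, 0.0)
        cem = th_eta * np.minimum(ceta, 0.0)
        cec = (1.0 - th_eta) * ceta

        st[(0, 0)] = st[(0, 0)] + (cxp - cxm) / dxi + (cep - cem) / deta \
            - (v / np.maximum(self.rho_grid, 1e-300))[I, J]
        st[(-1, 0)] = st[(-1, 0)] - cxp / dxi - cxc / (2.0 * dxi)
        st[(1, 0)] = st[(1, 0)] + cxm / dxi + cxc / (2.0 * dxi)
        st[(0, -1)] = st[(0, -1)] - cep / deta - cec / (2.0 * deta)
        st[(0, 1)] = st[(0, 1)] + cem / deta + cec / (2.0 * deta)
        return self._assemble(st)

    # ------------------------------------------------------------ kinematics
    def _velocities(self, psi):
        """Node velocities from the stream function (no-slip wall, regular
        axis limit u = 2 psi(eta1) / (eta1 R)^2)."""
        R = self.R[:, None]
        psi_eta = np.gradient(psi, self.deta, axis=1)
        psi_xi = np.gradient(psi, self.dxi, axis=0)
        eta_safe = np.maximum(self.ETA, 1e-300)
        with np.errstate(over="ignore"):
            u = psi_eta / (eta_safe * R ** 2)
            v = -(psi_xi + self.A * psi_eta) / (eta_safe * R)
        u[:, 0] = 2.0 * psi[:, 1] / (self.eta[1] * self.R) ** 2
        u[:, -1] = 0.0
        v[:, 0] = 0.0
        v[:, -1] = 0.0
        return u, v

    def _wall_vorticity(self, psi):
        # one-sided second derivative using psi_eta(wall) = 0 (no slip)
        d2 = (8.0 * psi[:, -2] - psi[:, -3] - 7.0 * psi[:, -1]) \
            / (2.0 * self.deta ** 2)
        return -(1.0 + self.Rp ** 2) / self.R ** 3 * d2

    def _poiseuille_fields(self, q_si):
        """Locally developed initial guess at flow rate q (SI)."""
        psi = (q_si / np.pi) * (self.ETA ** 2 - 0.5 * self.ETA ** 4)
        um = q_si / (np.pi * self.R ** 2)
        omega = 4.0 * um[:, None] * self.ETA / self.R[:, None]
        return psi, omega

    # ---------------------------------------------------------- inner solve
    def solve_at_flow(self, q_ml_min: float,
                      omega0: np.ndarray | None = None,
                      alpha: float = 0.65, lam: float = 0.2,
                      residual_history: list | None = None) -> FieldSolution:
        """Picard iteration at fixed flow rate; returns fields and the
        recovered pressure drop.

        ``alpha`` is the implicit (diagonal-boost) under-relaxation factor of
        the vorticity solve, ``lam`` the wall-vorticity relaxation; both are
        halved automatically if the iteration blows up.
        """
        q_si = q_ml_min * MLMIN_TO_M3S
        psi, omega = self._poiseuille_fields(q_si)
        if omega0 is not None:
            omega = omega0.copy()
        nx, nr = self.nx, self.nr
        dxi, deta = self.dxi, self.deta

        psi_rhs_base = np.zeros((nx + 1, nr + 1))
        psi_rhs_base[:, 0] = 0.0
        psi_rhs_base[:, -1] = q_si / (2.0 * np.pi)
        psi_rhs_base[0, 1:-1] = (q_si / np.pi) * (
            self.eta[1:-1] ** 2 - 0.5 * self.eta[1:-1] ** 4)
        um0 = q_si / (np.pi * self.R[0] ** 2)
        omega_inlet = 4.0 * um0 * self.eta[1:-1] / self.R[0]

        residual = np.inf
        prev_residual = np.inf
        worse = 0
        it = 0
        converged = False
        for it in range(1, self.cfg.max_iter + 1):
            rhs = psi_rhs_base.copy()
            rhs[1:-1, 1:-1] = -self.rho_grid[1:-1, 1:-1] * omega[1:-1, 1:-1]
            rhs[-1, 1:-1] = 0.0
            psi = self._psi_lu.solve(rhs.ravel()).reshape(nx + 1, nr + 1)

            u, v = self._velocities(psi)
            w_wall = self._wall_vorticity(psi)
            omega[:, -1] = (1.0 - lam) * omega[:, -1] + lam * w_wall

            mat = self._build_omega_matrix(u, v)
            rhs_w = np.zeros((nx + 1, nr + 1))
            rhs_w[0, 1:-1] = omega_inlet
            rhs_w[:, -1] = omega[:, -1]
            rhs_w[-1, 1:-1] = 0.0

            # implicit under-relaxation: boost the diagonal, feed the boost
            # times the previous iterate back on the right-hand side
            boost = (1.0 - alpha) / alpha * np.abs(mat.diagonal())
            omega_new = splu((mat + diags(boost)).tocsc()).solve(
                rhs_w.ravel() + boost * omega.ravel()) \
                .reshape(nx + 1, nr + 1)
            delta = omega_new - omega
            omega = omega_new

            scale = np.max(np.abs(omega)) + 1e-300
            residual = float(np.max(np.abs(delta)) / scale)
            if residual_history is not None:
                residual_history.append(residual)
            if not np.isfinite(residual) or residual > 1e4:
                # blown up: restart from the developed-flow guess with
                # stronger damping
                psi, omega = self._poiseuille_fields(q_si)
                alpha = max(alpha * 0.5, 0.05)
                lam = max(lam * 0.5, 0.01)
                prev_residual = np.inf
                worse = 0
                continue
            if residual < self.cfg.tol:
                converged = True
                break
            # near the fixed point a marginally damped oscillatory mode can
            # sustain a small residual floor; latch onto heavy damping to
            # suppress it once the transient has decayed
            if residual < 50.0 * self.cfg.tol:
                alpha = min(alpha, 0.3)
                lam = min(lam, 0.05)
            if residual > prev_residual:
                worse += 1
                if worse >= 30:
                    alpha = max(alpha * 0.5, 0.05)
                    lam = max(lam * 0.5, 0.01)
                    worse = 0
            else:
                worse = 0
            prev_residual = residual

        u, v = self._velocities(psi)
        dp_pa = self._pressure_drop(u, v, q_si)
        return FieldSolution(
            q_ml_min=q_ml_min, dp_mmhg=dp_pa / MMHG_TO_PA, psi=psi,
            omega=omega, u=u, v=v, iterations=it, residual=residual,
            converged=converged)

    def _pressure_drop(self, u, v, q_si):
        """Discrete mechanical-energy balance:
        dP * Q = dissipation + KE flux out - KE flux in."""
        mu = self.fluid.mu_pa_s
        rho_f = self.fluid.rho_kg_m3
        R = self.R[:, None]
        A = self.A

        def ddx(f):
            return np.gradient(f, self.dxi, axis=0) \
                + A * np.gradient(f, self.deta, axis=1)

        def ddrho(f):
            return np.gradient(f, self.deta, axis=1) / R

        u_x, u_r = ddx(u), ddrho(u)
        v_x, v_r = ddx(v), ddrho(v)
        v_over_rho = np.zeros_like(v)
        v_over_rho[:, 1:] = v[:, 1:] / self.rho_grid[:, 1:]
        v_over_rho[:, 0] = v_r[:, 0]
        phi = 2.0 * (u_x ** 2 + v_r ** 2 + v_over_rho ** 2) \
            + (u_r + v_x) ** 2
        w = phi * self.ETA * R ** 2
        dissipation = mu * 2.0 * np.pi * np.trapezoid(
            np.trapezoid(w, self.eta, axis=1), self.xi)

        def ke_flux(i):
            integrand = u[i, :] ** 3 * self.eta * self.R[i] ** 2
            return np.pi * rho_f * np.trapezoid(integrand, self.eta)

        return (dissipation + ke_flux(-1) - ke_flux(0)) / q_si

    # ---------------------------------------------------------- outer solve
    def solve_for_pressure_drop(self, dp_mmhg: float, q_init_ml_min: float,
                                max_outer: int = 30):
        """Secant iteration on Q so the recovered pressure drop matches the
        prescribed one.  Returns (q_ml_min, total_iterations, residual,
        converged)."""
        target = dp_mmhg
        total_iter = 0
        q0 = max(q_init_ml_min, 1e-9)
        sol0 = self.solve_at_flow(q0)
        total_iter += sol0.iterations
        if not sol0.converged:
            return q0, total_iter, sol0.residual, False
        f0 = sol0.dp_mmhg - target
        # first update by linear rescaling (dp is nearly a*q + b*q^2)
        q1 = q0 * target / max(sol0.dp_mmhg, 1e-300)
        omega_warm = sol0.omega * (q1 / q0)
        last = sol0
        for _ in range(max_outer):
            sol1 = self.solve_at_flow(q1, omega0=omega_warm)
            total_iter += sol1.iterations
            if not sol1.converged:
                return q1, total_iter, sol1.residual, False
            f1 = sol1.dp_mmhg - target
            last = sol1
            if abs(f1) / target < 5.0 * self.cfg.tol \
                    or abs(q1 - q0) / q1 < 1e-9:
                return q1, total_iter, sol1.residual, True
            denom = f1 - f0
            if denom == 0.0:
                return q1, total_iter, sol1.residual, True
            q2 = q1 - f1 * (q1 - q0) / denom
            if q2 <= 0.0:
                q2 = 0.5 * q1
            q0, f0 = q1, f1
            omega_warm = sol1.omega * (q2 / q1)
            q1 = q2
        return q1, total_iter, last.residual, False
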