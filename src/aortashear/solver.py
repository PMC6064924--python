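"""Unsteady incompressible laminar flow in an idealized branched 2-D channel.

The vessel is modeled as a plane channel of height ``h`` and length ``L``
with small outflow openings ("ostia") in its walls, a desk-scale stand-in
for a descending aorta with intercostal branch mouths.  The solver is a
finite-volume projection method on a uniform staggered (MAC) grid:

* QUICK (quadratic upwind) advection, explicit Adams–Bashforth 2;
* Crank–Nicolson (second-order implicit) viscous terms;
* incremental pressure-correction projection with a direct sparse solve of
  the pressure Poisson equation, so the discrete velocity field is
  divergence-free to machine precision after every step.

Boundary conditions follow the branched-vessel protocol: a prescribed
time-dependent inlet velocity profile (Dirichlet) whose mean follows a
periodic waveform; outflow velocities at the main outlet and at every
ostium scaled each step so each exit carries its prescribed fraction of the
instantaneous inflow; no-slip on all walls.  The model is laminar,
Newtonian and rigid-walled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .metrics import WallShearRecord
from .oracles import FluidProperties
from .waveform import BezierWaveform, evaluate_waveform

QUADRANTS = ("left_upper", "right_upper", "left_lower", "right_lower")


class GeometryError(ValueError):
    """Invalid channel geometry."""


class SolverError(RuntimeError):
    """Solver failure (instability or linear-solve breakdown)."""


@dataclass(frozen=True)
class Ostium:
    """A small wall opening: side ``"lower"``/``"upper"``, axial center, width (m)."""

    side: str
    x_center: float
    width: float


@dataclass(frozen=True)
class ChannelGeometry:
    """Idealized 2-D branched channel with grid resolution.

    ``branch_length`` is descriptive metadata: ostia are represented as
    outflow openings in the wall boundary; the branch lumens themselves are
    not meshed.
    """

    length_L: float
    height_h: float
    ostia: tuple
    grid_nx: int
    grid_ny: int
    branch_length: float = 0.0

    def __post_init__(self) -> None:
        if min(self.length_L, self.height_h) <= 0:
            raise GeometryError("channel dimensions must be positive")
        if self.grid_nx < 4 or self.grid_ny < 4:
            raise GeometryError("grid must be at least 4x4")
        object.__setattr__(self, "ostia", tuple(self.ostia))
        for o in self.ostia:
            if o.side not in ("lower", "upper"):
                raise GeometryError(f"unknown wall side {o.side!r}")
            if o.width <= 0 or o.width >= self.height_h / 4:
                raise GeometryError("ostium width must be positive and < h/4")
            if o.x_center - o.width / 2 <= self.dx or o.x_center + o.width / 2 >= self.length_L - self.dx:
                raise GeometryError("ostium must lie strictly inside the channel")
        for side in ("lower", "upper"):
            spans = sorted(self.ostium_faces(side))
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 <= a1:
                    raise GeometryError("ostia overlap on the same wall")

    @property
    def dx(self) -> float:
        return self.length_L / self.grid_nx

    @property
    def dy(self) -> float:
        return self.height_h / self.grid_ny

    def ostium_faces(self, side: str) -> list:
        """Index ranges ``(i0, i1)`` of wall v-faces open for each ostium on ``side``."""
        out = []
        for o in self.ostia:
            if o.side != side:
                continue
            n_f = max(1, round(o.width / self.dx))
            i0 = int(round(o.x_center / self.dx - n_f / 2))
            i0 = min(max(i0, 1), self.grid_nx - 1 - n_f)
            out.append((i0, i0 + n_f))
        return out

    def boundary_face_labels(self) -> dict:
        """Classify every boundary face exactly once.

        Returns ``{"left": (ny,), "right": (ny,), "lower": (nx,),
        "upper": (nx,)}`` label arrays: ``inlet``, ``outlet``, ``wall`` or
        ``ostium_<k>``.
        """
        labels = {
            "left": np.full(self.grid_ny, "inlet", dtype=object),
            "right": np.full(self.grid_ny, "outlet", dtype=object),
            "lower": np.full(self.grid_nx, "wall", dtype=object),
            "upper": np.full(self.grid_nx, "wall", dtype=object),
        }
        for k, o in enumerate(self.ostia):
            (i0, i1) = self._faces_of(k)
            labels[o.side][i0:i1] = f"ostium_{k}"
        return labels

    def _faces_of(self, k: int) -> tuple:
        o = self.ostia[k]
        n_f = max(1, round(o.width / self.dx))
        i0 = int(round(o.x_center / self.dx - n_f / 2))
        i0 = min(max(i0, 1), self.grid_nx - 1 - n_f)
        return (i0, i0 + n_f)

    def ostium_quadrant(self, k: int) -> str:
        """Quadrant label of ostium ``k``.

        Wall side maps to the left/right pair (lower wall = "left", upper
        wall = "right"); the proximal half of the channel maps to "upper",
        the distal half to "lower".
        """
        o = self.ostia[k]
        lr = "left" if o.side == "lower" else "right"
        ud = "upper" if o.x_center < self.length_L / 2 else "lower"
        return f"{lr}_{ud}"


def default_ostia(
    length_L: float, height_h: float, n_pairs: int = 6, width: float = None
) -> tuple:
    """Six axial pairs of ostia on opposite walls (12 openings)."""
    if width is None:
        width = 0.18 * height_h
    x0, x1 = 0.2 * length_L, 0.85 * length_L
    xs = np.linspace(x0, x1, n_pairs)
    ostia = []
    for x in xs:
        ostia.append(Ostium("lower", float(x), width))
        ostia.append(Ostium("upper", float(x), width))
    return tuple(ostia)


def build_channel(config: dict) -> ChannelGeometry:
    """Build a :class:`ChannelGeometry` from a plain config mapping.

    Keys: ``length_L``, ``height_h``, ``grid_nx``, ``grid_ny``, optional
    ``branch_length`` and ``ostia`` (list of ``[side, x_center, width]``;
    the string ``"default"`` places 12 ostia in 6 axial pairs).
    """
    ostia = config.get("ostia", ())
    if isinstance(ostia, str):
        if ostia != "default":
            raise GeometryError(f"unknown ostia preset {ostia!r}")
        ostia = default_ostia(config["length_L"], config["height_h"])
    else:
        ostia = tuple(
            o if isinstance(o, Ostium) else Ostium(o[0], float(o[1]), float(o[2]))
            for o in ostia
        )
    return ChannelGeometry(
        length_L=float(config["length_L"]),
        height_h=float(config["height_h"]),
        ostia=ostia,
        grid_nx=int(config["grid_nx"]),
        grid_ny=int(config["grid_ny"]),
        branch_length=float(config.get("branch_length", 0.0)),
    )


@dataclass(frozen=True)
class OutletSplit:
    """Outflow fractions by exit name; normalized to sum exactly to 1."""

    fractions: dict

    def __post_init__(self) -> None:
        f = dict(self.fractions)
        if not f or any(v <= 0 for v in f.values()):
            raise GeometryError("all split fractions must be positive")
        object.__setattr__(self, "fractions", f)

    def normalized(self) -> dict:
        tot = sum(self.fractions.values())
        out = {k: v / tot for k, v in self.fractions.items()}
        # force exact unit sum (assign the roundoff residue to the largest exit)
        err = 1.0 - sum(out.values())
        kmax = max(out, key=out.get)
        out[kmax] += err
        return out

    @classmethod
    def paper_default(cls, n_ostia: int = 12) -> "OutletSplit":
        """Raw splits of the branched-aorta protocol restricted to this
        geometry: descending-aorta outlet 69.8% and 0.14% per ostium
        (the arch branches are absent from the single-channel idealization);
        fractions are renormalized among the exits present."""
        f = {"main": 0.698}
        for k in range(n_ostia):
            f[f"ostium_{k}"] = 0.0014
        return cls(f)


@dataclass
class FlowState:
    """Staggered-grid state: u (nx+1, ny), v (nx, ny+1), p (nx, ny)."""

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    time: float = 0.0
    cycle_index: int = 0
    prev_adv: tuple | None = None
    max_divergence: float = 0.0
    mass_error: float = 0.0


def _quick_faces_1d(phi: np.ndarray, vel: np.ndarray, axis: int) -> np.ndarray:
    """QUICK-interpolated face values between consecutive nodes along ``axis``.

    ``phi`` has N nodes along axis; returns N-1 face values advected with
    face velocity ``vel`` (same shape as output).  Faces without a
    far-upwind node fall back to central averaging.
    """
    phi = np.moveaxis(phi, axis, 0)
    vel = np.moveaxis(vel, axis, 0)
    L, R = phi[:-1], phi[1:]
    face = 0.5 * (L + R)
    if phi.shape[0] >= 4:
        LL, RR = phi[:-3], phi[3:]
        pos = 0.75 * phi[1:-2] + 0.375 * phi[2:-1] - 0.125 * LL
        neg = 0.75 * phi[2:-1] + 0.375 * phi[1:-2] - 0.125 * RR
        face[1:-1] = np.where(vel[1:-1] >= 0.0, pos, neg)
    return np.moveaxis(face, 0, axis)


class ChannelSolver:
    """Caches the constant implicit operators for one (geometry, fluid, dt)."""

    def __init__(
        self,
        geometry: ChannelGeometry,
        props: FluidProperties,
        splits: OutletSplit,
        dt: float,
        inlet_profile,
        outlet_profile: str = "scaled",
    ):
        if dt <= 0:
            raise SolverError("dt must be positive")
        if outlet_profile not in ("plug", "scaled"):
            raise SolverError(f"unknown outlet profile {outlet_profile!r}")
        self.geo = geometry
        self.props = props
        self.dt = dt
        self.inlet_profile = inlet_profile  # callable t -> u[0, :] (ny,)
        self.outlet_profile = outlet_profile
        self.nx, self.ny = geometry.grid_nx, geometry.grid_ny
        self.dx, self.dy = geometry.dx, geometry.dy
        self.nu = props.kinematic_viscosity

        fr = splits.normalized()
        if "main" not in fr:
            raise GeometryError("splits must name a 'main' outlet")
        expected = {"main"} | {f"ostium_{k}" for k in range(len(geometry.ostia))}
        if set(fr) != expected:
            raise GeometryError(f"splits must name exactly {sorted(expected)}")
        self.split_main = fr["main"]
        self.split_ostium = [fr[f"ostium_{k}"] for k in range(len(geometry.ostia))]

        self._lu_u = splu(self._momentum_matrix("u"))
        self._lu_v = splu(self._momentum_matrix("v"))
        self._lu_p = splu(self._pressure_matrix())

    # ---- operator assembly -------------------------------------------------

    def _momentum_matrix(self, which: str) -> sp.csc_matrix:
        dx2, dy2 = self.dx**2, self.dy**2
        if which == "u":
            mx, my = self.nx - 1, self.ny
            half_dirichlet = "y"  # walls at half-cell distance in y
        else:
            mx, my = self.nx, self.ny - 1
            half_dirichlet = "x"  # inlet/outlet planes at half-cell distance in x
        N = mx * my

        def idx(i, j):
            return i * my + j

        rows, cols, vals = [], [], []
        a = 0.5 * self.nu  # Crank-Nicolson
        # The zero boundary value lying half a cell outside the first node
        # uses a quadratic ghost (exact for parabolic profiles):
        # d2u/dn2 ~ (4/3 u_1 - 4 u_0)/h^2, i.e. diag 4, neighbor -4/3.
        for i in range(mx):
            for j in range(my):
                k = idx(i, j)
                diag = 1.0 / self.dt
                # x neighbors
                for di in (-1, 1):
                    ii = i + di
                    if 0 <= ii < mx:
                        rows.append(k), cols.append(idx(ii, j)), vals.append(-a / dx2)
                        diag += a / dx2
                    elif half_dirichlet == "x":
                        diag += 3.0 * a / dx2
                        rows.append(k), cols.append(idx(i - di, j)), vals.append(-a / (3.0 * dx2))
                    else:
                        diag += a / dx2  # Dirichlet node on boundary -> RHS
                # y neighbors
                for dj in (-1, 1):
                    jj = j + dj
                    if 0 <= jj < my:
                        rows.append(k), cols.append(idx(i, jj)), vals.append(-a / dy2)
                        diag += a / dy2
                    elif half_dirichlet == "y":
                        diag += 3.0 * a / dy2
                        rows.append(k), cols.append(idx(i, j - dj)), vals.append(-a / (3.0 * dy2))
                    else:
                        diag += a / dy2
                rows.append(k), cols.append(k), vals.append(diag)
        return sp.csc_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(N, N)))

    def _pressure_matrix(self) -> sp.csc_matrix:
        nx, ny = self.nx, self.ny
        dx2, dy2 = self.dx**2, self.dy**2

        def idx(i, j):
            return i * ny + j

        rows, cols, vals = [], [], []
        for i in range(nx):
            for j in range(ny):
                k = idx(i, j)
                if k == 0:  # pin the pressure nullspace (scaled like the other rows)
                    rows.append(0), cols.append(0), vals.append(2.0 / dx2 + 2.0 / dy2)
                    continue
                diag = 0.0
                for di, dj, h2 in ((-1, 0, dx2), (1, 0, dx2), (0, -1, dy2), (0, 1, dy2)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nx and 0 <= jj < ny:
                        rows.append(k), cols.append(idx(ii, jj)), vals.append(1.0 / h2)
                        diag -= 1.0 / h2
                rows.append(k), cols.append(k), vals.append(diag)
        return sp.csc_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(nx * ny, nx * ny)))

    # ---- boundary values ---------------------------------------------------

    def boundary_values(self, t: float, state: FlowState | None = None):
        """Inlet profile, main-outlet profile and per-ostium wall velocity at ``t``.

        The main outlet carries exactly ``split_main`` of the instantaneous
        inflow: either as a plug profile, or ("scaled") as the zero-gradient
        extrapolation of the neighboring interior profile rescaled to that
        flux, which avoids imposing an artificial profile shape on
        straight-channel validation runs.
        """
        u_in = np.asarray(self.inlet_profile(t), dtype=float)
        if u_in.shape != (self.ny,):
            raise SolverError("inlet profile must return (ny,) values")
        Q = float(np.sum(u_in) * self.dy)
        q_main = self.split_main * Q
        u_out = np.full(self.ny, q_main / (self.ny * self.dy))
        if self.outlet_profile == "scaled" and state is not None:
            prof = state.u[-2, :]
            q_prof = float(np.sum(prof) * self.dy)
            if abs(q_prof) > 1e-14 * max(abs(Q), 1.0):
                u_out = prof * (q_main / q_prof)
        v_lower = np.zeros(self.nx)
        v_upper = np.zeros(self.nx)
        for k, o in enumerate(self.geo.ostia):
            i0, i1 = self.geo._faces_of(k)
            q_k = self.split_ostium[k] * Q
            vel = q_k / ((i1 - i0) * self.dx)
            if o.side == "lower":
                v_lower[i0:i1] = -vel
            else:
                v_upper[i0:i1] = vel
        return u_in, u_out, v_lower, v_upper, Q

    def initial_state(self) -> FlowState:
        u = np.zeros((self.nx + 1, self.ny))
        v = np.zeros((self.nx, self.ny + 1))
        p = np.zeros((self.nx, self.ny))
        u_in, u_out, v_lo, v_up, _ = self.boundary_values(0.0)
        u[0, :], u[-1, :] = u_in, u_out
        v[:, 0], v[:, -1] = v_lo, v_up
        return FlowState(u=u, v=v, p=p, time=0.0)

    # ---- spatial operators -------------------------------------------------

    def _advection(self, u: np.ndarray, v: np.ndarray):
        nx, ny, dx, dy = self.nx, self.ny, self.dx, self.dy
        # --- u momentum: d(uu)/dx + d(vu)/dy at interior u nodes (1..nx-1, :)
        uc = 0.5 * (u[:-1, :] + u[1:, :])  # (nx, ny) at cell centers
        fx = uc * _quick_faces_1d(u, uc, axis=0)  # (nx, ny)
        vf = 0.5 * (v[:-1, :] + v[1:, :])  # (nx-1, ny+1) at u-CV y-faces, i=1..nx-1
        u_int_cols = u[1:-1, :]  # (nx-1, ny)
        fy = np.zeros((nx - 1, ny + 1))
        fy_inner = vf[:, 1:-1] * _quick_faces_1d(u_int_cols, vf[:, 1:-1], axis=1)
        fy[:, 1:-1] = fy_inner
        # wall faces: tangential u = 0 there (no-slip / plug openings) -> zero flux
        adv_u = (fx[1:, :] - fx[:-1, :]) / dx + (fy[:, 1:] - fy[:, :-1]) / dy

        # --- v momentum: d(uv)/dx + d(vv)/dy at interior v nodes (:, 1..ny-1)
        uf = 0.5 * (u[:, :-1] + u[:, 1:])  # (nx+1, ny-1) at v-CV x-faces
        v_int_rows = v[:, 1:-1]  # (nx, ny-1)
        gx = np.zeros((nx + 1, ny - 1))
        gx[1:-1, :] = uf[1:-1, :] * _quick_faces_1d(v_int_rows, uf[1:-1, :], axis=0)
        # inlet/outlet planes: v = 0 there -> zero flux
        vc = 0.5 * (v[:, :-1] + v[:, 1:])  # (nx, ny) at cell centers
        gy = vc * _quick_faces_1d(v, vc, axis=1)  # (nx, ny)
        adv_v = (gx[1:, :] - gx[:-1, :]) / dx + (gy[:, 1:] - gy[:, :-1]) / dy
        return adv_u, adv_v

    def _laplacian_u(self, u: np.ndarray) -> np.ndarray:
        """5-point Laplacian at interior u nodes; no-slip walls enter through
        a quadratic ghost (second-order wall shear)."""
        dx2, dy2 = self.dx**2, self.dy**2
        ui = u[1:-1, :]
        lap = (u[2:, :] - 2 * ui + u[:-2, :]) / dx2
        yy = np.empty_like(ui)
        yy[:, 1:-1] = (ui[:, 2:] - 2 * ui[:, 1:-1] + ui[:, :-2]) / dy2
        yy[:, 0] = (4.0 / 3.0 * ui[:, 1] - 4.0 * ui[:, 0]) / dy2
        yy[:, -1] = (4.0 / 3.0 * ui[:, -2] - 4.0 * ui[:, -1]) / dy2
        return lap + yy

    def _laplacian_v(self, v: np.ndarray) -> np.ndarray:
        """5-point Laplacian at interior v nodes; v = 0 on the inlet/outlet
        planes enters through the same quadratic ghost."""
        dx2, dy2 = self.dx**2, self.dy**2
        vi = v[:, 1:-1]
        lap = (v[:, 2:] - 2 * vi + v[:, :-2]) / dy2
        xx = np.empty_like(vi)
        xx[1:-1, :] = (vi[2:, :] - 2 * vi[1:-1, :] + vi[:-2, :]) / dx2
        xx[0, :] = (4.0 / 3.0 * vi[1, :] - 4.0 * vi[0, :]) / dx2
        xx[-1, :] = (4.0 / 3.0 * vi[-2, :] - 4.0 * vi[-1, :]) / dx2
        return lap + xx

    # ---- time step ---------------------------------------------------------

    def step(self, state: FlowState) -> FlowState:
        """Advance one time step (AB2/CN projection)."""
        nx, ny, dx, dy, dt = self.nx, self.ny, self.dx, self.dy, self.dt
        rho = self.props.density_rho
        u, v, p = state.u, state.v, state.p
        t_new = state.time + dt

        cfl = np.max(np.abs(u)) * dt / dx + np.max(np.abs(v)) * dt / dy
        if cfl > 1.0:
            raise SolverError(f"CFL violation: advective CFL = {cfl:.2f} > 1 at t={state.time:.4g}")

        adv_u, adv_v = self._advection(u, v)
        if state.prev_adv is None:
            ex_u, ex_v = adv_u, adv_v  # first step: forward Euler
        else:
            pu, pv = state.prev_adv
            ex_u, ex_v = 1.5 * adv_u - 0.5 * pu, 1.5 * adv_v - 0.5 * pv

        u_in1, u_out1, v_lo1, v_up1, Q1 = self.boundary_values(t_new, state)

        a = 0.5 * self.nu
        # u predictor
        rhs_u = (
            u[1:-1, :] / dt
            - ex_u
            - (p[1:, :] - p[:-1, :]) / (dx * rho)
            + a * self._laplacian_u(u)
        )
        rhs_u[0, :] += a * u_in1 / dx**2
        rhs_u[-1, :] += a * u_out1 / dx**2
        u_star = self._lu_u.solve(rhs_u.ravel()).reshape(nx - 1, ny)

        # v predictor
        rhs_v = (
            v[:, 1:-1] / dt
            - ex_v
            - (p[:, 1:] - p[:, :-1]) / (dy * rho)
            + a * self._laplacian_v(v)
        )
        rhs_v[:, 0] += a * v_lo1 / dy**2
        rhs_v[:, -1] += a * v_up1 / dy**2
        v_star = self._lu_v.solve(rhs_v.ravel()).reshape(nx, ny - 1)

        # assemble full-face predictor with boundary values at t_new
        uf = np.empty((nx + 1, ny))
        uf[0, :], uf[-1, :], uf[1:-1, :] = u_in1, u_out1, u_star
        vf = np.empty((nx, ny + 1))
        vf[:, 0], vf[:, -1], vf[:, 1:-1] = v_lo1, v_up1, v_star

        div = (uf[1:, :] - uf[:-1, :]) / dx + (vf[:, 1:] - vf[:, :-1]) / dy
        rhs_p = (rho / dt) * div
        rhs_p -= rhs_p.mean()  # Neumann compatibility against roundoff
        flat = rhs_p.ravel().copy()
        flat[0] = 0.0  # pinned cell
        phi = self._lu_p.solve(flat).reshape(nx, ny)
        if not np.all(np.isfinite(phi)):
            raise SolverError("pressure solve produced non-finite values")

        uf[1:-1, :] -= (dt / rho) * (phi[1:, :] - phi[:-1, :]) / dx
        vf[:, 1:-1] -= (dt / rho) * (phi[:, 1:] - phi[:, :-1]) / dy
        p_new = p + phi

        div_new = (uf[1:, :] - uf[:-1, :]) / dx + (vf[:, 1:] - vf[:, :-1]) / dy
        outflow = float(np.sum(uf[-1, :]) * dy - np.sum(vf[:, 0]) * dx + np.sum(vf[:, -1]) * dx)
        # subtract wall faces (zero) implicitly; ostium faces included above
        mass_err = abs(outflow - Q1) / max(abs(Q1), 1e-300)

        return FlowState(
            u=uf,
            v=vf,
            p=p_new,
            time=t_new,
            cycle_index=state.cycle_index,
            prev_adv=(adv_u, adv_v),
            max_divergence=float(np.max(np.abs(div_new))),
            mass_error=mass_err,
        )

    def ostium_flux_errors(self, state: FlowState) -> np.ndarray:
        """Relative error of each ostium's outflow vs its split of the inflow."""
        Q = float(np.sum(state.u[0, :]) * self.dy)
        errs = []
        for k, o in enumerate(self.geo.ostia):
            i0, i1 = self.geo._faces_of(k)
            if o.side == "lower":
                q = -float(np.sum(state.v[i0:i1, 0]) * self.dx)
            else:
                q = float(np.sum(state.v[i0:i1, -1]) * self.dx)
            target = self.split_ostium[k] * Q
            errs.append(abs(q - target) / max(abs(target), 1e-300))
        return np.array(errs)


# ---- inlet profiles --------------------------------------------------------


def parabolic_inlet(geometry: ChannelGeometry, mean_fn):
    """Parabolic profile scaled so the instantaneous mean equals ``mean_fn(t)``."""
    y = (np.arange(geometry.grid_ny) + 0.5) * geometry.dy
    shape = 6.0 * (y / geometry.height_h) * (1.0 - y / geometry.height_h)

    def profile(t: float) -> np.ndarray:
        return mean_fn(t) * shape

    return profile


def plug_inlet(geometry: ChannelGeometry, mean_fn):
    def profile(t: float) -> np.ndarray:
        return np.full(geometry.grid_ny, mean_fn(t))

    return profile


def womersley_inlet(geometry: ChannelGeometry, grad, props: FluidProperties):
    """Exact pulsatile channel profile for a harmonic pressure gradient."""
    from .oracles import channel_womersley_velocity

    y = (np.arange(geometry.grid_ny) + 0.5) * geometry.dy - geometry.height_h / 2.0

    def profile(t: float) -> np.ndarray:
        return channel_womersley_velocity(grad, geometry.height_h, props, y, t)

    return profile


def _mean_fn_from_inlet(inlet):
    if isinstance(inlet, BezierWaveform):
        return lambda t: evaluate_waveform(inlet, t)
    if callable(inlet):
        return inlet
    val = float(inlet)
    return lambda t: val


def make_solver(
    geometry: ChannelGeometry,
    props: FluidProperties,
    inlet,
    splits: OutletSplit,
    dt: float,
    inlet_profile: str = "parabolic",
    gradient=None,
    outlet_profile: str = "scaled",
) -> ChannelSolver:
    if inlet_profile == "parabolic":
        prof = parabolic_inlet(geometry, _mean_fn_from_inlet(inlet))
    elif inlet_profile == "plug":
        prof = plug_inlet(geometry, _mean_fn_from_inlet(inlet))
    elif inlet_profile == "womersley":
        if gradient is None:
            raise SolverError("womersley inlet profile needs a pressure-gradient spec")
        prof = womersley_inlet(geometry, gradient, props)
    else:
        raise SolverError(f"unknown inlet profile {inlet_profile!r}")
    return ChannelSolver(geometry, props, splits, dt, prof, outlet_profile)


def advance_step(
    state: FlowState,
    geometry: ChannelGeometry,
    props: FluidProperties,
    inlet,
    splits: OutletSplit,
    dt: float,
    inlet_profile: str = "parabolic",
    gradient=None,
    outlet_profile: str = "scaled",
) -> FlowState:
    """One projection step (convenience wrapper; re-assembles operators).

    For time marching use :func:`make_solver` / :meth:`ChannelSolver.step`,
    which cache the factorized implicit operators.
    """
    solver = make_solver(
        geometry, props, inlet, splits, dt, inlet_profile, gradient, outlet_profile
    )
    return solver.step(state)


# ---- wall shear extraction -------------------------------------------------


def extract_wall_shear(
    state: FlowState, geometry: ChannelGeometry, props: FluidProperties
) -> pd.DataFrame:
    """Instantaneous WSS vectors at wall points.

    One row per wall u-station on each wall (ostium openings excluded):
    columns x, y, side, normal components and the wall-tangential shear
    vector (tau_x, tau_y).  The wall gradient uses a one-sided second-order
    difference through the no-slip wall value.
    """
    if geometry.grid_ny < 2:
        raise GeometryError("wall shear needs at least 2 transverse cells")
    eta = props.dynamic_viscosity_eta
    dy = geometry.dy
    u = state.u
    nx = geometry.grid_nx
    idx = np.arange(1, nx)  # interior u stations
    open_lower = np.zeros(nx + 1, dtype=bool)
    open_upper = np.zeros(nx + 1, dtype=bool)
    for k, o in enumerate(geometry.ostia):
        i0, i1 = geometry._faces_of(k)
        tgt = open_lower if o.side == "lower" else open_upper
        tgt[i0 : i1 + 1] = True  # stations touching an open face
    rows = []
    tau_lo = eta * (9.0 * u[idx, 0] - u[idx, 1]) / (3.0 * dy)
    tau_up = eta * (9.0 * u[idx, -1] - u[idx, -2]) / (3.0 * dy)
    x = idx * geometry.dx
    for side, tau, yv, nyv, mask in (
        ("lower", tau_lo, 0.0, -1.0, open_lower[idx]),
        ("upper", tau_up, geometry.height_h, 1.0, open_upper[idx]),
    ):
        keep = ~mask
        rows.append(
            pd.DataFrame(
                {
                    "x": x[keep],
                    "y": yv,
                    "side": side,
                    "nx": 0.0,
                    "ny": nyv,
                    "tau_x": tau[keep],
                    "tau_y": 0.0,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _wall_point_regions(geometry: ChannelGeometry, region_width_factor: float) -> pd.DataFrame:
    """Static wall-point table with ostium-region labels.

    A wall point belongs to an ostium's region when it lies within
    ``region_width_factor`` ostium-widths of the ostium mouth center on the
    same wall; regions carry the quadrant label of their ostium.
    """
    nx = geometry.grid_nx
    idx = np.arange(1, nx)
    x = idx * geometry.dx
    frames = []
    for side, yv, nyv in (("lower", 0.0, -1.0), ("upper", geometry.height_h, 1.0)):
        open_mask = np.zeros(nx + 1, dtype=bool)
        region = np.full(idx.size, "non-ostial", dtype=object)
        for k, o in enumerate(geometry.ostia):
            i0, i1 = geometry._faces_of(k)
            if o.side != side:
                continue
            open_mask[i0 : i1 + 1] = True
            near = np.abs(x - o.x_center) <= region_width_factor * o.width
            region[near] = geometry.ostium_quadrant(k)
        keep = ~open_mask[idx]
        frames.append(
            pd.DataFrame(
                {"i": idx[keep], "x": x[keep], "y": yv, "side": side, "ny": nyv,
                 "region": region[keep]}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["point_id"] = np.arange(len(df))
    return df


def run_cycles(
    geometry: ChannelGeometry,
    props: FluidProperties,
    inlet,
    splits: OutletSplit,
    n_cycles: int = 3,
    steps_per_cycle: int = 1000,
    period_T: float = None,
    inlet_profile: str = "parabolic",
    gradient=None,
    outlet_profile: str = "scaled",
    region_width_factor: float = 1.5,
    embed_3d: bool = True,
):
    """Run ``n_cycles`` cardiac cycles from rest and record the final cycle.

    Time step is ``period_T / steps_per_cycle`` (the protocol default is
    1/1000th of the cycle time and 3 cycles, evaluating the last).  Returns
    ``(records, diagnostics)`` where ``records`` are per-wall-point
    :class:`~aortashear.metrics.WallShearRecord` series over the final cycle
    (embedded in 3-D with tau_z = 0 by default, so all three shear metrics
    are computable) and ``diagnostics`` collects per-step conservation
    measures and the RMS wall-shear change between the last two cycles.
    """
    if n_cycles < 2:
        raise SolverError("need at least one warm-up cycle (n_cycles >= 2)")
    if steps_per_cycle < 8:
        raise SolverError("steps_per_cycle must be >= 8")
    if period_T is None:
        if isinstance(inlet, BezierWaveform):
            period_T = inlet.period_T
        else:
            raise SolverError("period_T required when inlet is not a waveform")
    dt = period_T / steps_per_cycle
    solver = make_solver(
        geometry, props, inlet, splits, dt, inlet_profile, gradient, outlet_profile
    )
    state = solver.initial_state()

    points = _wall_point_regions(geometry, region_width_factor)
    eta = props.dynamic_viscosity_eta
    dy = geometry.dy

    def wall_tau(st: FlowState) -> np.ndarray:
        lo = eta * (9.0 * st.u[:, 0] - st.u[:, 1]) / (3.0 * dy)
        up = eta * (9.0 * st.u[:, -1] - st.u[:, -2]) / (3.0 * dy)
        out = np.where(points["side"].to_numpy() == "lower",
                       lo[points["i"].to_numpy()], up[points["i"].to_numpy()])
        return out

    n_pts = len(points)
    tau_prev_cycle = np.zeros((steps_per_cycle, n_pts))
    tau_last_cycle = np.zeros((steps_per_cycle, n_pts))
    max_div = 0.0
    max_mass_err = 0.0
    max_ostium_err = 0.0
    for cyc in range(n_cycles):
        for k in range(steps_per_cycle):
            # record the state at cycle phase k*dt (before stepping)
            if cyc == n_cycles - 2:
                tau_prev_cycle[k] = wall_tau(state)
            elif cyc == n_cycles - 1:
                tau_last_cycle[k] = wall_tau(state)
            state = solver.step(state)
            max_div = max(max_div, state.max_divergence)
            max_mass_err = max(max_mass_err, state.mass_error)
            if geometry.ostia:
                max_ostium_err = max(max_ostium_err, float(np.max(solver.ostium_flux_errors(state))))
        state.cycle_index = cyc + 1

    rms_last = np.sqrt(np.mean(tau_last_cycle**2))
    cycle_rms_change = float(
        np.sqrt(np.mean((tau_last_cycle - tau_prev_cycle) ** 2)) / max(rms_last, 1e-300)
    )

    times = np.arange(steps_per_cycle) * dt  # cycle phase of each recorded sample
    records = []
    for j, row in points.iterrows():
        if embed_3d:
            pos = np.array([row["x"], row["y"], 0.0])
            normal = np.array([0.0, row["ny"], 0.0])
            tau = np.zeros((steps_per_cycle, 3))
            tau[:, 0] = tau_last_cycle[:, j]
        else:
            pos = np.array([row["x"], row["y"]])
            normal = np.array([0.0, row["ny"]])
            tau = np.zeros((steps_per_cycle, 2))
            tau[:, 0] = tau_last_cycle[:, j]
        records.append(
            WallShearRecord(
                point_id=int(row["point_id"]),
                position=pos,
                outward_normal=normal,
                region_label=str(row["region"]),
                times=times,
                tau_vectors=tau,
                period_T=period_T,
            )
        )
    diagnostics = {
        "max_divergence": max_div,
        "max_mass_error": max_mass_err,
        "max_ostium_flux_error": max_ostium_err,
        "cycle_rms_change": cycle_rms_change,
        "dt": dt,
        "n_wall_points": n_pts,
        "final_state": state,
    }
    return records, diagnostics


def run_to_steady(
    geometry: ChannelGeometry,
    props: FluidProperties,
    mean_velocity: float,
    splits: OutletSplit,
    dt: float = None,
    tol: float = 1e-10,
    max_steps: int = 50_000,
    inlet_profile: str = "parabolic",
    outlet_profile: str = "scaled",
) -> tuple[FlowState, ChannelSolver]:
    """March a constant-inlet run to steady state.

    Stops when the per-step relative velocity change drops below ``tol``;
    raises :class:`SolverError` if ``max_steps`` is exhausted first.
    """
    if dt is None:
        peak = 1.5 * abs(mean_velocity) + 1e-12
        dt = 0.3 * geometry.dx / peak
    # ramp the inlet over the first steps to avoid an impulsive start
    t_ramp = 100.0 * dt
    U = float(mean_velocity)

    def mean_fn(t: float) -> float:
        return U * min(1.0, t / t_ramp)

    solver = make_solver(
        geometry, props, mean_fn, splits, dt, inlet_profile,
        outlet_profile=outlet_profile,
    )
    state = solver.initial_state()
    scale = max(abs(mean_velocity), 1e-12)
    for k in range(max_steps):
        new = solver.step(state)
        if k % 20 == 0:
            change = max(
                np.max(np.abs(new.u - state.u)), np.max(np.abs(new.v - state.v))
            ) / scale
            if change < tol:
                return new, solver
        state = new
    raise SolverError(f"no steady state within {max_steps} steps (tol={tol:g})")
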