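"""Prescribed-flow steady advection-diffusion PM2.5 fields.

The airflow of each airflow-organization state is a depth-averaged potential
flow: supply outlets inject air, return outlets extract it, and portal fluxes
(exits, stairs, open PSD segments) are signed per state so that global mass
balance closes by construction.  The concentration field then solves

    u . grad C  =  D_eff laplacian C  +  S / (cell area x floor height)

with a first-order upwind finite-volume discretization (monotone, so the
field obeys a discrete maximum principle), Dirichlet-equivalent inflow
concentrations carried by the injected air (supply air at mu_sup, exit inflow
at mu_out) and zero-gradient outflow.  This is a deliberately reduced
stand-in for a full CFD treatment: turbulent mixing collapses to one
effective diffusivity and the breathing plane is treated as a 2-D layer, with
the floor height entering only through source dilution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .station import (CLOSED, CONCOURSE, OPEN, WALL, AirflowState,
                      BoundaryConditions, Grid2D, StationGeometry)


@dataclass
class FlowField:
    """Face-based divergence-free velocity field on one floor grid.

    ``uf`` holds x-face velocities (n_rows+1, n_cols), ``vf`` y-face
    velocities (n_rows, n_cols+1); positive along +x/+y.  ``inj``/``ext``
    are per-cell volumetric injection/extraction (m^3/s, both >= 0) and
    ``inj_conc`` the concentration carried by injected air (ug/m^3).
    """

    grid: Grid2D
    state: AirflowState
    uf: np.ndarray
    vf: np.ndarray
    inj: np.ndarray
    ext: np.ndarray
    inj_conc: np.ndarray

    @classmethod
    def zeros(cls, grid: Grid2D, state: AirflowState) -> "FlowField":
        shape = grid.shape
        return cls(grid, state,
                   uf=np.zeros((shape[0] + 1, shape[1])),
                   vf=np.zeros((shape[0], shape[1] + 1)),
                   inj=np.zeros(shape), ext=np.zeros(shape),
                   inj_conc=np.zeros(shape))

    def cell_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        u = 0.5 * (self.uf[:-1, :] + self.uf[1:, :])
        v = 0.5 * (self.vf[:, :-1] + self.vf[:, 1:])
        return u, v

    def divergence(self) -> np.ndarray:
        """Discrete per-cell net outflow (m^3/s); equals inj - ext."""
        h, H = self.grid.cell_size, self.grid.floor_height
        return ((self.uf[1:, :] - self.uf[:-1, :])
                + (self.vf[:, 1:] - self.vf[:, :-1])) * h * H

    def portal_net_flux(self, portal_id: str) -> float:
        """Net volumetric flux through a portal, positive outward (m^3/s)."""
        cells = self.grid.portal_cells[portal_id]
        idx = tuple(cells.T)
        return float(self.ext[idx].sum() - self.inj[idx].sum())


def _solve_potential(grid: Grid2D, q: np.ndarray, tol: float = 1e-10):
    """Solve the Neumann Poisson problem sum_faces H (phi_i - phi_nb) = q_i."""
    walk = grid.walkable_mask()
    n = int(walk.sum())
    idx = -np.ones(grid.shape, int)
    idx[walk] = np.arange(n)
    H = grid.floor_height
    rows, cols, vals = [], [], []
    for di, dj in ((1, 0), (0, 1)):
        pair = walk[: grid.n_rows - di, : grid.n_cols - dj] & walk[di:, dj:]
        ii, jj = np.nonzero(pair)
        p = idx[ii, jj]
        r = idx[ii + di, jj + dj]
        for s, t in ((p, r), (r, p)):
            rows.extend([s, s])
            cols.extend([s, t])
            vals.extend([np.full(len(s), H), np.full(len(s), -H)])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    b = q[walk].astype(float)
    if abs(b.sum()) > 1e-9 * max(np.abs(b).max(), 1e-30):
        raise ValueError("net flux does not balance; potential flow undefined")
    # pin the first unknown to remove the Neumann null space
    A = A.tolil()
    A[0, :] = 0.0
    A[0, 0] = 1.0
    b = b.copy()
    b[0] = 0.0
    phi_w = spsolve(A.tocsr(), b)
    phi = np.zeros(grid.shape)
    phi[walk] = phi_w
    res = np.abs(A @ phi_w - b).max()
    if not np.isfinite(res) or res > max(1e-6, tol * max(abs(b).max(), 1.0)):
        raise RuntimeError(f"potential solve residual {res:.3g} too large")
    return phi, walk


def _face_velocities(grid: Grid2D, phi: np.ndarray, walk: np.ndarray):
    h = grid.cell_size
    uf = np.zeros((grid.n_rows + 1, grid.n_cols))
    vf = np.zeros((grid.n_rows, grid.n_cols + 1))
    inner = walk[:-1, :] & walk[1:, :]
    uf[1:-1, :][inner] = ((phi[:-1, :] - phi[1:, :]) / h)[inner]
    inner = walk[:, :-1] & walk[:, 1:]
    vf[:, 1:-1][inner] = ((phi[:, :-1] - phi[:, 1:]) / h)[inner]
    return uf, vf


@dataclass
class FlowOptions:
    """Aggregate-flow plumbing knobs for the stand-in solver."""

    return_fraction: float = 0.5        # share of supply extracted at returns
    open_exit_inflow_m3s: float = 6.0   # concourse OPEN: total inflow at exits
    stair_inflow_conc: float | None = None  # ug/m^3 carried by stair inflow


def _spread(cells: np.ndarray, total: float, arr: np.ndarray):
    if len(cells) == 0:
        raise ValueError("no cells to carry flux")
    arr[tuple(cells.T)] += total / len(cells)


def build_flow(grid: Grid2D, geometry: StationGeometry, state: AirflowState,
               bc: BoundaryConditions | None = None,
               options: FlowOptions | None = None) -> FlowField:
    """Potential-flow field for one floor and airflow-organization state."""
    bc = bc or geometry.bc
    opts = options or FlowOptions()
    if state.floor != grid.floor:
        raise ValueError("state floor does not match grid floor")
    g = geometry

    def _supply_total(floor):
        w, d = g.outlet_size[floor]
        v = bc.v_c if floor == CONCOURSE else bc.v_p
        return len(g.supply_outlets[floor]) * w * d * v

    inj = np.zeros(grid.shape)
    ext = np.zeros(grid.shape)
    inj_conc = np.zeros(grid.shape)

    q_sup = _supply_total(grid.floor)
    _spread(grid.supply_cells, q_sup, inj)
    inj_conc[tuple(grid.supply_cells.T)] = bc.mu_sup
    q_ret = opts.return_fraction * q_sup
    _spread(grid.return_cells, q_ret, ext)

    stair_cells = np.concatenate([
        grid.portal_cells[p.id]
        for p in g.portals_on(grid.floor) if p.role in ("stair", "escalator")
    ])
    exit_cells = (np.concatenate([grid.portal_cells[p.id]
                                  for p in g.portals_on(CONCOURSE, "exit")])
                  if grid.floor == CONCOURSE else None)
    stair_conc = opts.stair_inflow_conc if opts.stair_inflow_conc is not None \
        else bc.mu_sup

    if grid.floor == CONCOURSE:
        if state.label == CLOSED:
            # platform excess rises through the stairs; all vents out the exits
            q_stair = (1 - opts.return_fraction) * _supply_total("platform")
            _spread(stair_cells, q_stair, inj)
            inj_conc[tuple(stair_cells.T)] = stair_conc
            _spread(exit_cells, q_sup + q_stair - q_ret, ext)
        else:  # OPEN: outdoor air in through the exits, down the stairs
            q_exit = opts.open_exit_inflow_m3s
            _spread(exit_cells, q_exit, inj)
            inj_conc[tuple(exit_cells.T)] = bc.mu_out
            _spread(stair_cells, q_sup + q_exit - q_ret, ext)
    else:  # platform
        if state.label == CLOSED:
            _spread(stair_cells, q_sup - q_ret, ext)
        else:
            side = "AB" if state.label == "AB_OPEN" else "CD"
            q_stair = (_supply_total(CONCOURSE) + opts.open_exit_inflow_m3s
                       - opts.return_fraction * _supply_total(CONCOURSE))
            _spread(stair_cells, q_stair, inj)
            inj_conc[tuple(stair_cells.T)] = stair_conc
            psd = next(p for p in g.portals_on("platform", "psd")
                       if p.meta["side"] == side)
            _spread(grid.portal_cells[psd.id], q_sup + q_stair - q_ret, ext)

    phi, walk = _solve_potential(grid, inj - ext)
    uf, vf = _face_velocities(grid, phi, walk)
    return FlowField(grid, state, uf, vf, inj, ext, inj_conc)


@dataclass
class ConcentrationField:
    grid: Grid2D
    state: AirflowState
    values: np.ndarray  # ug/m^3, NaN at wall cells
    residual: float

    def value_at(self, x, y):
        i, j = self.grid.cell_of(x, y)
        return self.values[i, j]


def solve_steady(flow: FlowField, sources=(), bc: BoundaryConditions | None = None,
                 diffusivity: float = 0.1, tol: float = 1e-8,
                 dirichlet: dict | None = None,
                 extra_cell_sources: np.ndarray | None = None) -> ConcentrationField:
    """Steady PM2.5 field for one flow state.

    ``sources`` are ParticleSource-like objects (x, y, rate_mg_per_h);
    ``extra_cell_sources`` an optional per-cell ug/s array (equipment);
    ``dirichlet`` optionally pins cells to fixed concentrations (test
    harness for pure-diffusion problems).
    """
    if diffusivity <= 0:
        raise ValueError("diffusivity must be > 0")
    grid = flow.grid
    walk = grid.walkable_mask()
    n = int(walk.sum())
    idx = -np.ones(grid.shape, int)
    idx[walk] = np.arange(n)
    h, H = grid.cell_size, grid.floor_height
    dcoef = diffusivity * H

    rows, cols, vals = [], [], []
    b = np.zeros(n)

    def _add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    # faces between neighbouring walkable cells
    for di, dj, fv in ((1, 0, flow.uf[1:-1, :]), (0, 1, flow.vf[:, 1:-1])):
        pair = walk[: grid.n_rows - di, : grid.n_cols - dj] & walk[di:, dj:]
        ii, jj = np.nonzero(pair)
        p = idx[ii, jj]
        r = idx[ii + di, jj + dj]
        F = fv[ii, jj] * h * H  # m^3/s positive from p toward r
        Fp = np.maximum(F, 0.0)
        Fm = np.maximum(-F, 0.0)
        # upwind advection
        _add(p, p, Fp)
        _add(r, p, -Fp)
        _add(r, r, Fm)
        _add(p, r, -Fm)
        # diffusion (both directions)
        _add(p, p, np.full(len(p), dcoef))
        _add(p, r, np.full(len(p), -dcoef))
        _add(r, r, np.full(len(p), dcoef))
        _add(r, p, np.full(len(p), -dcoef))

    # domain-boundary faces: zero-gradient outflow, inflow at the cell's
    # injected-air concentration
    def _boundary(cells_i, cells_j, fv, outward_sign):
        k = idx[cells_i, cells_j]
        ok = k >= 0
        F = fv * h * H * outward_sign  # > 0 means outflow
        Fo = np.maximum(F, 0.0)[ok]
        Fi = np.maximum(-F, 0.0)[ok]
        _add(k[ok], k[ok], Fo)
        b[k[ok]] += Fi * flow.inj_conc[cells_i, cells_j][ok]

    jr = np.arange(grid.n_cols)
    ir = np.arange(grid.n_rows)
    _boundary(np.zeros_like(jr), jr, flow.uf[0, :], -1.0)
    _boundary(np.full_like(jr, grid.n_rows - 1), jr, flow.uf[-1, :], 1.0)
    _boundary(ir, np.zeros_like(ir), flow.vf[:, 0], -1.0)
    _boundary(ir, np.full_like(ir, grid.n_cols - 1), flow.vf[:, -1], 1.0)

    # injection / extraction
    ii, jj = np.nonzero(walk)
    cell = idx[ii, jj]
    b[cell] += flow.inj[ii, jj] * flow.inj_conc[ii, jj]
    _add(cell, cell, flow.ext[ii, jj].astype(float))

    # particulate sources, mg/h -> ug/s, spread over the emission footprint
    for s in sources:
        rate = s.rate_mg_per_h * 1000.0 / 3600.0
        radius = getattr(s, "radius_m", 0.0)
        if radius > 0:
            cx, cy = grid.cell_centers()
            near = walk & (np.hypot(cx - s.x, cy - s.y) <= radius)
        else:
            near = np.zeros(grid.shape, bool)
        if near.any():
            b[idx[near]] += rate / near.sum()
        else:
            i, j = grid.cell_of(s.x, s.y)
            if not walk[i, j]:
                raise ValueError("source placed on a wall cell")
            b[idx[i, j]] += rate
    if extra_cell_sources is not None:
        b[cell] += extra_cell_sources[ii, jj]

    rows = np.concatenate([np.atleast_1d(r) for r in rows])
    cols = np.concatenate([np.atleast_1d(c) for c in cols])
    vals = np.concatenate([np.atleast_1d(v).astype(float) for v in vals])
    A = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    if dirichlet:
        A = A.tolil()
        for (i, j), value in dirichlet.items():
            k = idx[i, j]
            if k < 0:
                raise ValueError("Dirichlet cell is not walkable")
            A.rows[k] = [k]
            A.data[k] = [1.0]
            b[k] = value
        A = A.tocsr()

    c = spsolve(A, b)
    if not np.all(np.isfinite(c)):
        raise RuntimeError("concentration solve diverged")
    scale = max(np.abs(b).max(), 1.0)
    residual = float(np.abs(A @ c - b).max() / scale)
    if residual > max(tol, 1e-8):
        raise RuntimeError(f"concentration residual {residual:.3g} > tol")
    if c.min() < -1e-8 * max(abs(c).max(), 1.0):
        raise RuntimeError("negative concentration: scheme not monotone here")
    c = np.maximum(c, 0.0)
    values = np.full(grid.shape, np.nan)
    values[walk] = c
    return ConcentrationField(grid, flow.state, values, residual)


def floor_mean(fieldobj: ConcentrationField, mask: np.ndarray | None = None) -> float:
    """Arithmetic mean concentration over masked walkable cells."""
    walk = fieldobj.grid.walkable_mask()
    m = walk if mask is None else (mask & walk)
    if not m.any():
        raise ValueError("empty mask")
    return float(np.nanmean(fieldobj.values[m]))


def equipment_cell_sources(grid: Grid2D, geometry: StationGeometry,
                           bc: BoundaryConditions) -> np.ndarray:
    """Equipment emission (ug/s per cell) spread over gate and ticket cells."""
    arr = np.zeros(grid.shape)
    cells = [grid.portal_cells[p.id]
             for p in geometry.portals_on(grid.floor)
             if p.role in ("gate_in", "gate_out", "ticket")]
    if not cells:
        return arr
    cells = np.concatenate(cells)
    arr[tuple(cells.T)] = bc.r_eq * 1e9 / len(cells)  # kg/s -> ug/s
    return arr
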