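"""Synthetic ground truth standing in for field measurements.

The "real" time-averaged concentration at a location is modelled as a
spatially weighted blend of the per-state steady fields: near the exits and
passageways the field tracks the PSD-open state (outdoor air intrudes there
whenever the doors open), while deep inside the floor it tracks the closed
state, weighted by the fraction of each headway the doors stand open.  On
the platform the analogue ramps each open-side weight toward the respective
PSD wall.  An optional exponent gamma makes the blend a power mean, giving
the surrogate stage a genuinely nonlinear target; instrument realism is a
multiplicative Gaussian noise per 1-s draw and quantization to the 0.1
ug/m^3 sensitivity step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dispersion import ConcentrationField
from .station import CONCOURSE, FLOOR_CODES, PLATFORM, Grid2D, StationGeometry, airflow_states

#: canonical column name per state label
STATE_COLUMNS = {"CLOSED": "sim_closed", "OPEN": "sim_open",
                 "AB_OPEN": "sim_ab_open", "CD_OPEN": "sim_cd_open"}


@dataclass
class BlendModel:
    """Per-cell convex weights over the airflow-organization states."""

    floor: str
    states: tuple[str, ...]
    weights: np.ndarray  # (n_states, n_rows, n_cols), sums to 1 per cell
    grid: Grid2D
    gamma: float = 0.0
    noise_sd: float = 0.0
    quantization: float = 0.1

    def __post_init__(self):
        s = self.weights.sum(axis=0)
        if np.any(self.weights < -1e-12) or np.any(np.abs(s - 1.0) > 1e-9):
            raise ValueError("blend weights must be >= 0 and sum to 1 per cell")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def weights_at(self, x, y) -> np.ndarray:
        i, j = self.grid.cell_of(x, y)
        return self.weights[:, i, j]


def _logistic_ramp(dist, d0, scale):
    return 1.0 / (1.0 + np.exp((dist - d0) / scale))


def default_blend(grid: Grid2D, geometry: StationGeometry,
                  headway_s: float = 360.0, dwell_s: float = 30.0,
                  gamma: float = 0.0, noise_sd: float = 0.0,
                  quantization: float = 0.1,
                  ramp_reach_m: float = 10.0,
                  ramp_scale_m: float = 2.5,
                  fields_by_state: dict | None = None) -> BlendModel:
    """Blend weights for one floor from the train timetable geometry.

    The base open-state weight is the PSD-open time fraction dwell/headway.
    On the concourse, when the per-state fields are supplied, the open-state
    weight ramps logistically in the open-state outdoor-air tracer (the
    normalized elevation of the open-state field): where outdoor air actually
    penetrates while the doors stand open — the passageways — the measured
    field tracks the open state, and the interior tracks the closed state.
    Without fields, a logistic ramp over distance to the exits is used
    instead.  On the platform each open-side weight ramps toward its PSD
    wall.
    """
    if not 0 < dwell_s < headway_s:
        raise ValueError("dwell must satisfy 0 < dwell < headway")
    f_open = dwell_s / headway_s
    states = airflow_states(grid.floor)
    cx, cy = grid.cell_centers()
    if grid.floor == CONCOURSE:
        if fields_by_state is not None:
            c_open = fields_by_state["OPEN"].values
            walk = grid.walkable_mask()
            lo, hi = np.nanpercentile(c_open[walk], [5.0, 95.0])
            tracer = np.clip((np.nan_to_num(c_open, nan=lo) - lo)
                             / max(hi - lo, 1e-9), 0.0, 1.0)
            ramp = _logistic_ramp(0.5 - tracer, 0.0, 0.15)
        else:
            anchors = np.array([geometry.portal(p.id).center
                                for p in geometry.portals_on(CONCOURSE, "exit")])
            dist = np.min(np.sqrt((cx[..., None] - anchors[:, 0]) ** 2
                                  + (cy[..., None] - anchors[:, 1]) ** 2),
                          axis=-1)
            ramp = _logistic_ramp(dist, ramp_reach_m, ramp_scale_m)
        w_open = f_open + (1 - f_open) * ramp
        weights = np.stack([1.0 - w_open, w_open])
    else:
        if fields_by_state is not None:
            # the open-side sweep depresses concentration toward the open
            # PSD wall, so the CD-minus-AB field difference is a monotone
            # proxy for proximity to the AB side (and vice versa)
            diff = (fields_by_state["CD_OPEN"].values
                    - fields_by_state["AB_OPEN"].values)
            walk = grid.walkable_mask()
            lo, hi = np.nanpercentile(diff[walk], [5.0, 95.0])
            t = np.clip((np.nan_to_num(diff, nan=lo) - lo)
                        / max(hi - lo, 1e-9), 0.0, 1.0)
            r_ab = _logistic_ramp(0.5 - t, 0.0, 0.15)
            r_cd = _logistic_ramp(t - 0.5, 0.0, 0.15)
        else:
            d_ab = grid.floor_width - cy
            d_cd = cy
            r_ab = _logistic_ramp(d_ab, ramp_reach_m / 2, ramp_scale_m)
            r_cd = _logistic_ramp(d_cd, ramp_reach_m / 2, ramp_scale_m)
        w_ab = f_open + (0.5 - f_open) * r_ab
        w_cd = f_open + (0.5 - f_open) * r_cd
        weights = np.stack([1.0 - w_ab - w_cd, w_ab, w_cd])
    return BlendModel(floor=grid.floor, states=states, weights=weights,
                      grid=grid, gamma=gamma, noise_sd=noise_sd,
                      quantization=quantization)


def _blend_values(fields_by_state: dict, blend: BlendModel, x, y) -> np.ndarray:
    for s in blend.states:
        if s not in fields_by_state:
            raise KeyError(f"missing field for state {s}")
    i, j = blend.grid.cell_of(x, y)
    c = np.stack([np.asarray(fields_by_state[s].values[i, j], float)
                  for s in blend.states])
    w = blend.weights[:, i, j]
    g = blend.gamma
    if g == 0.0:
        return np.sum(w * c, axis=0)
    return np.sum(w * np.power(c, 1.0 + g), axis=0) ** (1.0 / (1.0 + g))


def synthesize_measured(fields_by_state: dict, blend: BlendModel, location,
                        rng: np.random.Generator | None = None,
                        n_draws: int = 1):
    """Instrument-like 1-s draws of the blended truth at a location.

    Returns a scalar for ``n_draws == 1``, else an array.  With a ``rng`` the
    draws carry multiplicative Gaussian noise; every draw is quantized to the
    instrument step and clipped at zero.
    """
    x, y = location
    base = _blend_values(fields_by_state, blend, x, y)
    vals = np.full(n_draws, float(base))
    if rng is not None and blend.noise_sd > 0:
        vals = vals * (1.0 + rng.normal(0.0, blend.noise_sd, n_draws))
    q = blend.quantization
    if q > 0:
        vals = np.round(vals / q) * q
    vals = np.maximum(vals, 0.0)
    return float(vals[0]) if n_draws == 1 else vals


def truth_at(fields_by_state: dict, blend: BlendModel, x, y) -> np.ndarray:
    """Noise-free, unquantized blended truth (vectorized over positions)."""
    return _blend_values(fields_by_state, blend, x, y)


def synthesize_sample_table(plan, fields_by_state: dict, blend: BlendModel,
                            rng: np.random.Generator,
                            sample_seconds: int = 600) -> pd.DataFrame:
    """Sample table for one floor: per-state simulated inputs + measured output.

    The measured value is the mean of ``sample_seconds`` one-second
    instrument draws (the ten-minute stationary sampling protocol).
    """
    pts = plan.on_floor(blend.floor) if hasattr(plan, "on_floor") else plan
    rows = []
    grid = blend.grid
    for _, p in pts.iterrows():
        if not (0 <= p.x_m <= grid.floor_length and 0 <= p.y_m <= grid.floor_width):
            raise ValueError(f"plan point {p.point_id} outside the field grid")
        i, j = grid.cell_of(p.x_m, p.y_m)
        row = {"point_id": int(p.point_id), "floor": blend.floor,
               "zone": p.zone, "x_m": p.x_m, "y_m": p.y_m}
        for s in blend.states:
            row[STATE_COLUMNS[s]] = float(fields_by_state[s].values[i, j])
        draws = synthesize_measured(fields_by_state, blend, (p.x_m, p.y_m),
                                    rng=rng, n_draws=sample_seconds)
        row["measured"] = float(np.mean(draws))
        rows.append(row)
    return pd.DataFrame(rows)


def synthesize_mobile_curve(trajectory, fields_by_floor_state: dict,
                            blends: dict, rng: np.random.Generator | None = None
                            ) -> pd.DataFrame:
    """1-s mobile-sampling concentration curve along a trajectory.

    ``fields_by_floor_state`` maps floor -> {state: ConcentrationField};
    ``blends`` maps floor -> BlendModel.
    """
    code_to_floor = {v: k for k, v in FLOOR_CODES.items()}
    conc = np.empty(len(trajectory.t))
    for floor_code in np.unique(trajectory.floor):
        floor = code_to_floor[int(floor_code)]
        sel = trajectory.floor == floor_code
        blend = blends[floor]
        base = _blend_values(fields_by_floor_state[floor], blend,
                             trajectory.x[sel], trajectory.y[sel])
        if rng is not None and blend.noise_sd > 0:
            base = base * (1.0 + rng.normal(0.0, blend.noise_sd, base.shape))
        q = blend.quantization
        if q > 0:
            base = np.round(base / q) * q
        conc[sel] = np.maximum(base, 0.0)
    return pd.DataFrame({"ped_id": trajectory.ped_id, "t_s": trajectory.t,
                         "conc_ugm3": conc})
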