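"""Exposure calculators: trajectory integration vs microenvironment averaging.

The integration method accumulates E = sum_t C(t) * 1 s along a pedestrian's
1-s trajectory, with C(t) predicted by the region surrogate from the
per-state simulated concentrations at the pedestrian's position (positions
are piecewise-constant per second; no sub-second interpolation).  The
average-concentration method treats each floor as one microenvironment:
E = sum_i avg(C_i) * T_i.  In the limit where the surrogate returns each
microenvironment's mean everywhere, the two coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .station import FLOOR_CODES
from .surrogate import RegionMap, SurrogateModel

INTEGRATION = "integration"
AVERAGE = "average"

_CODE_TO_FLOOR = {v: k for k, v in FLOOR_CODES.items()}


@dataclass
class ExposureResult:
    ped_id: int | None
    direction: str | None
    method: str
    E_total: float  # ug.s/m^3
    E_by_floor: dict = field(default_factory=dict)
    time_by_floor: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.E_total < 0:
            raise ValueError("exposure must be >= 0")


def integrate_exposure(trajectory, bank: dict, region_maps: dict,
                       fields_by_floor_state: dict) -> ExposureResult:
    """Eq.-(1)-style 1-s cumulative exposure via the surrogate bank.

    ``region_maps`` maps floor -> RegionMap, ``fields_by_floor_state`` maps
    floor -> {state: ConcentrationField}; state order per floor follows
    ``station.airflow_states``.
    """
    E_by_floor: dict[str, float] = {}
    t_by_floor: dict[str, float] = {}
    for code in np.unique(trajectory.floor):
        floor = _CODE_TO_FLOOR[int(code)]
        sel = trajectory.floor == code
        x, y = trajectory.x[sel], trajectory.y[sel]
        rmap: RegionMap = region_maps[floor]
        grid = rmap.grid
        i, j = grid.cell_of(x, y)
        fields = fields_by_floor_state[floor]
        from .station import airflow_states
        sims = np.column_stack([fields[s].values[i, j]
                                for s in airflow_states(floor)])
        regions = rmap.labels[i, j]
        conc = np.empty(len(x))
        for region in np.unique(regions):
            m: SurrogateModel = bank[str(region)]
            msel = regions == region
            conc[msel] = np.maximum(m.predict(sims[msel]), 0.0)
        E_by_floor[floor] = float(conc.sum())  # dt = 1 s
        t_by_floor[floor] = float(sel.sum())
    return ExposureResult(
        ped_id=trajectory.ped_id, direction=trajectory.direction,
        method=INTEGRATION, E_total=float(sum(E_by_floor.values())),
        E_by_floor=E_by_floor, time_by_floor=t_by_floor)


def truth_exposure(trajectory, fields_by_floor_state: dict, blends: dict
                   ) -> ExposureResult:
    """Exposure against the known blended truth (noise-free reference)."""
    from .synthesis import truth_at

    E_by_floor: dict[str, float] = {}
    t_by_floor: dict[str, float] = {}
    for code in np.unique(trajectory.floor):
        floor = _CODE_TO_FLOOR[int(code)]
        sel = trajectory.floor == code
        c = truth_at(fields_by_floor_state[floor], blends[floor],
                     trajectory.x[sel], trajectory.y[sel])
        E_by_floor[floor] = float(np.sum(c))
        t_by_floor[floor] = float(sel.sum())
    return ExposureResult(
        ped_id=trajectory.ped_id, direction=trajectory.direction,
        method="truth", E_total=float(sum(E_by_floor.values())),
        E_by_floor=E_by_floor, time_by_floor=t_by_floor)


def average_method(mean_conc_by_env: dict, residence_by_env: dict,
                   ped_id=None, direction=None) -> ExposureResult:
    """Microenvironment-average exposure E = sum avg(C_i) * T_i."""
    if set(mean_conc_by_env) != set(residence_by_env):
        raise ValueError("microenvironment key sets differ")
    E_by_floor = {env: mean_conc_by_env[env] * residence_by_env[env]
                  for env in mean_conc_by_env}
    return ExposureResult(
        ped_id=ped_id, direction=direction, method=AVERAGE,
        E_total=float(sum(E_by_floor.values())), E_by_floor=E_by_floor,
        time_by_floor=dict(residence_by_env))


def relative_error(calculated: float, measured: float) -> float:
    """|calculated - measured| / measured, in percent."""
    if measured <= 0:
        raise ValueError("measured reference must be > 0")
    return abs(calculated - measured) / measured * 100.0


def cohort_exposure(trajectories, bank, region_maps, fields_by_floor_state,
                    n_sample: int = 50, seed: int = 0,
                    blends: dict | None = None) -> dict:
    """Random per-direction cohorts with integration (and optional truth) E.

    Returns {direction: {"results": DataFrame, "mean": .., "sd": ..,
    "mean_by_floor": .., "sample": [Trajectory, ...]}}.
    """
    by_dir: dict[str, list] = {}
    for tr in trajectories:
        by_dir.setdefault(tr.direction, []).append(tr)
    rng = np.random.default_rng(seed)
    out = {}
    for direction in sorted(by_dir):
        trs = by_dir[direction]
        if len(trs) < n_sample:
            raise ValueError(
                f"need >= {n_sample} {direction} trajectories, have {len(trs)}")
        pick = rng.choice(len(trs), size=n_sample, replace=False)
        sample = [trs[k] for k in sorted(pick)]
        rows = []
        for tr in sample:
            r = integrate_exposure(tr, bank, region_maps, fields_by_floor_state)
            row = {"ped_id": tr.ped_id, "direction": direction,
                   "E_total": r.E_total,
                   **{f"E_{f}": r.E_by_floor.get(f, 0.0) for f in FLOOR_CODES},
                   **{f"t_{f}": r.time_by_floor.get(f, 0.0) for f in FLOOR_CODES}}
            if blends is not None:
                row["E_truth"] = truth_exposure(
                    tr, fields_by_floor_state, blends).E_total
            rows.append(row)
        df = pd.DataFrame(rows)
        out[direction] = {
            "results": df,
            "mean": float(df.E_total.mean()),
            "sd": float(df.E_total.std(ddof=0)),
            "mean_by_floor": {f: float(df[f"E_{f}"].mean())
                              for f in FLOOR_CODES},
            "mean_time_by_floor": {f: float(df[f"t_{f}"].mean())
                                   for f in FLOOR_CODES},
            "sample": sample,
        }
    return out


@dataclass
class ComparisonReport:
    measured: dict      # direction -> reference exposure
    methods: dict       # method -> {direction -> exposure}
    errors: dict        # method -> {direction -> relative error %}
    error_ratio: dict   # direction -> avg-method error / integration error

    def to_text(self) -> str:
        dirs = sorted(self.measured)
        lines = ["{:<28}".format("") + "".join(f"{d:>14}" for d in dirs)]
        lines.append("{:<28}".format("Measured exposure")
                     + "".join(f"{self.measured[d]:>14.1f}" for d in dirs))
        for m in self.methods:
            lines.append("{:<28}".format(f"{m.capitalize()} method")
                         + "".join(f"{self.methods[m][d]:>14.1f}" for d in dirs))
            lines.append("{:<28}".format("  relative error (%)")
                         + "".join(f"{self.errors[m][d]:>14.2f}" for d in dirs))
        lines.append("{:<28}".format("Error ratio (avg/int)")
                     + "".join(f"{self.error_ratio[d]:>14.2f}" for d in dirs))
        return "\n".join(lines)


def compare_methods(measured_ref: dict, integration_results: dict,
                    average_results: dict) -> ComparisonReport:
    """Relative errors per method per direction and their ratio."""
    methods = {INTEGRATION: integration_results, AVERAGE: average_results}
    errors = {m: {d: relative_error(v[d], measured_ref[d])
                  for d in measured_ref}
              for m, v in methods.items()}
    ratio = {}
    for d in measured_ref:
        e_int = errors[INTEGRATION][d]
        ratio[d] = errors[AVERAGE][d] / e_int if e_int > 0 else float("inf")
    return ComparisonReport(measured=dict(measured_ref), methods=methods,
                            errors=errors, error_ratio=ratio)
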