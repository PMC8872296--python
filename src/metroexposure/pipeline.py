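"""One-command reproduction of the full synthetic exposure study.

``run_full`` chains the seven stages: pedestrian simulation -> congestion
sources -> per-state flow and concentration fields -> OLHS sampling design ->
synthetic measurement tables -> clustered SVR surrogates (PSO-tuned) ->
per-pedestrian exposure integration and the method comparison against the
known synthetic truth.  A single master seed spawns one named RNG stream per
stochastic stage, so a run is fully determined by its config.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dispersion, exposure, pedestrians, reference, sampling, station, surrogate, synthesis
from .fieldio import write_letter_matrix, write_matrix
from .station import AB_OPEN, CD_OPEN, CLOSED, CONCOURSE, OPEN, PLATFORM, AirflowState, airflow_states


@dataclass
class RunConfig:
    station_config: str | None = None   # path; None = built-in default
    duration_s: float = 1200.0
    cell_size_m: float = 0.4
    density_cell_m: float = 2.0
    diffusivity_m2s: float = 0.1
    return_fraction: float = 0.5
    open_exit_inflow_m3s: float = 6.0
    headway_s: float = 360.0
    dwell_s: float = 30.0
    gamma: float = 0.0
    noise_sd: float = 0.05
    quantization: float = 0.1
    sample_seconds: int = 600
    svr_epsilon: float = 0.1
    pso_swarm: int = 14
    pso_iters: int = 20
    n_cohort: int = 50
    source_level: str = "C"
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunResult:
    config: RunConfig
    geometry: station.StationGeometry
    grids: dict
    trajectories: pedestrians.SimulationResult
    residence: dict
    sources: list
    fields: dict           # floor -> {state: ConcentrationField}
    state_means: dict      # (floor, state) -> ug/m^3
    plan: sampling.SamplePlan
    blends: dict
    tables: dict           # floor -> sample DataFrame
    bank: dict             # region -> SurrogateModel
    region_maps: dict
    surrogate_scores: dict  # region -> {"train_r2","test_r2","lam","sigma","n_train","n_test"}
    cohorts: dict
    comparison: exposure.ComparisonReport
    headline_fraction: float
    manifest: dict


def _streams(master_seed: int) -> dict:
    names = ("pedestrians", "sampling", "measurement", "surrogate", "cohort")
    ss = np.random.SeedSequence(master_seed)
    return dict(zip(names, ss.spawn(len(names))))


def build_surrogates(tables: dict, seed_seq, epsilon: float,
                     pso_swarm: int, pso_iters: int,
                     concourse_grid=None) -> tuple[dict, dict, np.ndarray]:
    """Cluster, split, tune and fit the region surrogates.

    Returns (bank, scores, concourse AB labels aligned with the concourse
    table rows).
    """
    rng = np.random.default_rng(seed_seq)

    def _seed():
        return int(rng.integers(2 ** 31 - 1))

    conc = tables[CONCOURSE]
    labels = surrogate.kmeans_partition(conc, k=2, seed=_seed())
    ab = surrogate.ab_labels(conc, labels)

    regions = {
        "A": conc[ab == "A"].reset_index(drop=True),
        "B": conc[ab == "B"].reset_index(drop=True),
        "platform": tables[PLATFORM],
    }
    n_test = {"A": 3, "B": 4, "platform": 4}
    bank, scores = {}, {}
    for region, table in regions.items():
        cols = surrogate.input_columns(table)
        train, test = surrogate.split_train_test(
            table, n_test[region], seed=_seed())
        Xtr, ytr = train[cols].to_numpy(), train.measured.to_numpy()
        tune = surrogate.pso_tune(
            Xtr, ytr, swarm=pso_swarm, iters=pso_iters, seed=_seed(),
            epsilon=epsilon)
        model = surrogate.train_svr(
            Xtr, ytr, tune.lam, tune.sigma, epsilon, region=region,
            meta={"n_train": len(train), "n_test": len(test),
                  "cv_r2": tune.score})
        Xte, yte = test[cols].to_numpy(), test.measured.to_numpy()
        bank[region] = model
        scores[region] = {
            "lam": tune.lam, "sigma": tune.sigma,
            "train_r2": surrogate.r_squared(ytr, model.predict(Xtr)),
            "test_r2": surrogate.r_squared(yte, model.predict(Xte)),
            "n_train": len(train), "n_test": len(test),
        }
    return bank, scores, ab


def run_full(config: RunConfig | None = None, write: bool = True) -> RunResult:
    """Execute all stages; optionally write the artifact directory."""
    cfg = config or RunConfig()
    t_start = time.time()
    streams = _streams(cfg.seed)
    timings = {}

    def _tick(stage):
        timings[stage] = round(time.time() - t_start, 2)

    # 1. station + grids
    if cfg.station_config:
        geometry = station.StationGeometry.load(cfg.station_config)
    else:
        geometry = station.build_default_station()
    bc = geometry.bc
    grids = station.rasterize(geometry, cfg.cell_size_m)
    density_grids = station.rasterize(geometry, cfg.density_cell_m)
    _tick("station")

    # 2. pedestrian flow
    demand = pedestrians.DemandSpec(headway_s=cfg.headway_s)
    sim = pedestrians.simulate_trajectories(
        demand, geometry, duration=cfg.duration_s,
        seed=streams["pedestrians"])
    residence = pedestrians.residence_stats(sim)
    _tick("pedestrians")

    # 3. densities and particulate sources
    sources = []
    density_fields = {}
    for floor in (CONCOURSE, PLATFORM):
        dens = pedestrians.density_map(sim, density_grids[floor],
                                       (0.0, cfg.duration_s))
        density_fields[floor] = dens
        sources.extend(pedestrians.derive_sources(dens, bc, cfg.source_level))
    _tick("density")

    # 4. per-state flow + concentration fields (platform CLOSED feeds the
    # concourse CLOSED stair inflow; concourse OPEN feeds the open-platform
    # stair inflow)
    fields: dict = {CONCOURSE: {}, PLATFORM: {}}
    state_means: dict = {}

    def _solve(floor, label, stair_conc=None):
        opts = dispersion.FlowOptions(
            return_fraction=cfg.return_fraction,
            open_exit_inflow_m3s=cfg.open_exit_inflow_m3s,
            stair_inflow_conc=stair_conc)
        flow = dispersion.build_flow(grids[floor], geometry,
                                     AirflowState(floor, label), bc, opts)
        floor_sources = [s for s in sources if s.floor == floor]
        extra = dispersion.equipment_cell_sources(grids[floor], geometry, bc)
        f = dispersion.solve_steady(flow, floor_sources, bc,
                                    diffusivity=cfg.diffusivity_m2s,
                                    extra_cell_sources=extra)
        fields[floor][label] = f
        state_means[(floor, label)] = dispersion.floor_mean(f)
        return f

    _solve(PLATFORM, CLOSED)
    _solve(CONCOURSE, CLOSED, stair_conc=state_means[(PLATFORM, CLOSED)])
    _solve(CONCOURSE, OPEN)
    for label in (AB_OPEN, CD_OPEN):
        _solve(PLATFORM, label, stair_conc=state_means[(CONCOURSE, OPEN)])
    _tick("fields")

    # 5. sampling design
    plan = sampling.design_station_samples(
        geometry, seed=int(np.random.default_rng(
            streams["sampling"]).integers(2 ** 31 - 1)))
    _tick("sampling")

    # 6. synthetic measurement tables
    meas_rng = np.random.default_rng(streams["measurement"])
    blends = {
        floor: synthesis.default_blend(
            grids[floor], geometry, headway_s=cfg.headway_s,
            dwell_s=cfg.dwell_s, gamma=cfg.gamma, noise_sd=cfg.noise_sd,
            quantization=cfg.quantization, fields_by_state=fields[floor])
        for floor in (CONCOURSE, PLATFORM)
    }
    tables = {
        floor: synthesis.synthesize_sample_table(
            plan, fields[floor], blends[floor], meas_rng,
            sample_seconds=cfg.sample_seconds)
        for floor in (CONCOURSE, PLATFORM)
    }
    _tick("measurement")

    # 7. surrogates + region maps
    bank, scores, ab = build_surrogates(
        tables, streams["surrogate"], cfg.svr_epsilon,
        cfg.pso_swarm, cfg.pso_iters)
    conc_tab = tables[CONCOURSE]
    region_maps = {
        CONCOURSE: surrogate.build_region_map(
            grids[CONCOURSE], conc_tab[["x_m", "y_m"]].to_numpy(), ab),
        PLATFORM: surrogate.platform_region_map(grids[PLATFORM]),
    }
    _tick("surrogate")

    # 8. cohort exposure: integration vs truth vs averaging
    cohorts = exposure.cohort_exposure(
        sim, bank, region_maps, fields, n_sample=cfg.n_cohort,
        seed=int(np.random.default_rng(streams["cohort"]).integers(2 ** 31 - 1)),
        blends=blends)

    # microenvironment means: equal-weight mean of the per-state floor means
    env_mean = {
        floor: float(np.mean([state_means[(floor, s)]
                              for s in airflow_states(floor)]))
        for floor in (CONCOURSE, PLATFORM)
    }
    measured_ref, int_res, avg_res = {}, {}, {}
    wins = 0
    total = 0
    for direction, c in cohorts.items():
        df = c["results"]
        measured_ref[direction] = float(df.E_truth.mean())
        int_res[direction] = float(df.E_total.mean())
        e_avg = np.array([
            sum(env_mean[f] * row[f"t_{f}"] for f in (CONCOURSE, PLATFORM))
            for _, row in df.iterrows()
        ])
        avg_res[direction] = float(e_avg.mean())
        wins += int(np.sum(np.abs(df.E_total - df.E_truth)
                           <= np.abs(e_avg - df.E_truth)))
        total += len(df)
        c["results"] = df.assign(E_average=e_avg)
    comparison = exposure.compare_methods(measured_ref, int_res, avg_res)
    headline_fraction = wins / total
    _tick("exposure")

    manifest = {
        "config": cfg.to_dict(),
        "seed_streams": {k: int(v.generate_state(1)[0] % (2 ** 31))
                         for k, v in _streams(cfg.seed).items()},
        "timings_s": timings,
        "n_trajectories": len(sim),
        "n_dropped": len(sim.dropped),
        "surrogate_scores": scores,
        "state_means": {f"{fl}:{st}": v for (fl, st), v in state_means.items()},
        "headline_fraction": headline_fraction,
    }
    result = RunResult(
        config=cfg, geometry=geometry, grids=grids, trajectories=sim,
        residence=residence, sources=sources, fields=fields,
        state_means=state_means, plan=plan, blends=blends, tables=tables,
        bank=bank, region_maps=region_maps, surrogate_scores=scores,
        cohorts=cohorts, comparison=comparison,
        headline_fraction=headline_fraction, manifest=manifest)
    if write and cfg.outdir:
        write_artifacts(result, Path(cfg.outdir))
    return result


# ---------------------------------------------------------------------------
# artifact writing

def _traj_frame(sim) -> pd.DataFrame:
    code_to_floor = {v: k for k, v in station.FLOOR_CODES.items()}
    parts = []
    for tr in sim:
        parts.append(pd.DataFrame({
            "ped_id": tr.ped_id, "direction": tr.direction, "t_s": tr.t,
            "floor": [code_to_floor[int(c)] for c in tr.floor],
            "x_m": np.round(tr.x, 4), "y_m": np.round(tr.y, 4)}))
    return pd.concat(parts, ignore_index=True)


def write_artifacts(result: RunResult, outdir: Path) -> dict:
    """Write the artifact directory; returns name -> sha256 digest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digests = {}

    def _digest(path):
        digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    result.geometry.save(outdir / "station.yaml")
    _digest(outdir / "station.yaml")

    tf = _traj_frame(result.trajectories)
    tf.to_csv(outdir / "trajectories.csv", index=False,
              float_format="%.4f")
    _digest(outdir / "trajectories.csv")

    pd.DataFrame([{"x_m": s.x, "y_m": s.y, "floor": s.floor,
                   "persons": s.persons, "rate_mg_per_h": s.rate_mg_per_h}
                  for s in result.sources]).to_csv(
        outdir / "sources.csv", index=False, float_format="%.5f")
    _digest(outdir / "sources.csv")

    for floor, by_state in result.fields.items():
        for label, f in by_state.items():
            p = outdir / f"field_{floor}_{label}.tsv"
            write_matrix(p, np.nan_to_num(f.values), {
                "floor": floor, "state": label, "units": "ug/m^3",
                "cell_size_m": f.grid.cell_size, "residual": f.residual})
            _digest(p)

    result.plan.points.to_csv(outdir / "sample_plan.csv", index=False,
                              float_format="%.4f")
    _digest(outdir / "sample_plan.csv")
    for floor, table in result.tables.items():
        p = outdir / f"samples_{floor}.csv"
        table.to_csv(p, index=False, float_format="%.4f")
        _digest(p)

    with open(outdir / "surrogates.json", "w") as fh:
        json.dump({r: m.to_dict() for r, m in result.bank.items()}, fh,
                  indent=1, sort_keys=True)
    _digest(outdir / "surrogates.json")

    write_letter_matrix(outdir / "regions_concourse.txt",
                        result.region_maps[CONCOURSE].labels)
    _digest(outdir / "regions_concourse.txt")

    for direction, c in result.cohorts.items():
        p = outdir / f"exposure_{direction}.csv"
        c["results"].to_csv(p, index=False, float_format="%.3f")
        _digest(p)

    report = {
        "measured": result.comparison.measured,
        "methods": result.comparison.methods,
        "relative_errors_pct": result.comparison.errors,
        "error_ratio": result.comparison.error_ratio,
        "headline_fraction": result.headline_fraction,
        "residence": result.residence,
        "surrogate_scores": result.surrogate_scores,
        "state_means": {f"{fl}:{st}": v
                        for (fl, st), v in result.state_means.items()},
    }
    with open(outdir / "comparison.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    _digest(outdir / "comparison.json")
    with open(outdir / "comparison.txt", "w") as fh:
        fh.write(result.comparison.to_text() + "\n")
    _digest(outdir / "comparison.txt")

    result.manifest["sha256"] = digests
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
    return digests


def verify_tables(report_dir=None) -> list[dict]:
    """Recompute the published worked-example numbers; optionally write a
    listing under ``report_dir``."""
    checks = reference.verify_worked_examples()
    if report_dir is not None:
        p = Path(report_dir)
        p.mkdir(parents=True, exist_ok=True)
        with open(p / "verify_tables.json", "w") as fh:
            json.dump(checks, fh, indent=1)
    return checks
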