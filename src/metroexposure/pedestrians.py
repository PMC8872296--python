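"""Agent-based pedestrian flow: 1-s trajectories, densities, service levels,
residence statistics and pedestrian particulate sources.

The movement model is waypoint-graph based: agents walk portal-to-portal
along straight legs at an individually sampled speed, wait in FIFO queues at
service nodes (ticket machines, security, fare gates), choose between stairs
and escalator by minimizing the perceived route cost

    Cost = W_D * (D_G / V) + W_q * Q + W_L * L

(distance term, expected queue time, geometric-component cost), and board the
first train arriving at their platform side after they reach a waiting
position.  Boarding agents are schedule-aware: each targets a train and
enters the station a random margin plus a per-exit walk estimate before it,
which is what keeps mean boarding residence well below the headway.  Output
positions are recorded once per second.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .station import (CONCOURSE, FLOOR_CODES, PLATFORM, BoundaryConditions,
                      Grid2D, StationGeometry)

BOARDING = "boarding"
ALIGHTING = "alighting"

# IATA waiting-level density thresholds (person/m^2), closed upper bounds.
_SERVICE_LEVELS = (("A", 0.370), ("B", 0.435), ("C", 0.526),
                   ("D", 0.667), ("E", 1.0))
_LEVEL_ORDER = "ABCDEF"


@dataclass
class DemandSpec:
    """Off-peak hourly demand at the default station.

    ``boarding_per_hour`` / ``alighting_per_hour`` are keyed by platform side
    (the upward direction serves the CD side, the downward the AB side).
    """

    boarding_per_hour: dict = field(
        default_factory=lambda: {"CD": 2143, "AB": 789})
    alighting_per_hour: dict = field(
        default_factory=lambda: {"CD": 951, "AB": 918})
    card_fraction: float = 0.80
    exit_ratio: dict = field(
        default_factory=lambda: {"A": 3.5, "B": 2.0, "C": 1.0, "D": 3.5})
    headway_s: float = 360.0

    def __post_init__(self):
        for d in (self.boarding_per_hour, self.alighting_per_hour):
            if any(v < 0 for v in d.values()):
                raise ValueError("demand counts must be >= 0")
        if not 0 <= self.card_fraction <= 1:
            raise ValueError("card_fraction must lie in [0, 1]")
        if any(v < 0 for v in self.exit_ratio.values()):
            raise ValueError("exit ratios must be >= 0")

    def exit_probs(self) -> tuple[list[str], np.ndarray]:
        keys = sorted(self.exit_ratio)
        w = np.array([self.exit_ratio[k] for k in keys], float)
        return keys, w / w.sum()


@dataclass
class SpeedModel:
    """Truncated-normal walking speed.

    ``spread`` is read as a standard deviation by default; set
    ``interpretation="variance"`` for the literal-variance reading.
    """

    mean: float = 1.25
    spread: float = 0.2
    interpretation: str = "sd"  # "sd" | "variance"
    bounds: tuple[float, float] = (0.3, 2.5)

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("mean speed must be > 0")
        if self.spread < 0:
            raise ValueError("spread must be >= 0")
        if self.interpretation not in ("sd", "variance"):
            raise ValueError("interpretation must be 'sd' or 'variance'")

    @property
    def sd(self) -> float:
        return self.spread if self.interpretation == "sd" else math.sqrt(self.spread)


def sample_speed(model: SpeedModel, rng: np.random.Generator, size=None):
    """Draw walking speeds (m/s) from the truncated normal model."""
    sd = model.sd
    if sd == 0:
        return model.mean if size is None else np.full(size, model.mean)
    lo, hi = model.bounds
    a, b = (lo - model.mean) / sd, (hi - model.mean) / sd
    return stats.truncnorm.rvs(a, b, loc=model.mean, scale=sd,
                               size=size, random_state=rng)


@dataclass
class RouteCostWeights:
    w_distance: float = 1.0
    w_queue: float = 1.0
    w_component: float = 1.0
    component_costs: dict = field(
        default_factory=lambda: {"stairs": 25.0, "escalator": 8.0})

    def __post_init__(self):
        if min(self.w_distance, self.w_queue, self.w_component) < 0:
            raise ValueError("route-cost weights must be >= 0")


def route_cost(distance_to_goal: float, speed: float, queue_time: float,
               component_cost: float, weights: RouteCostWeights) -> float:
    """Perceived route cost in seconds."""
    if speed <= 0:
        raise ValueError("speed must be > 0")
    if min(distance_to_goal, queue_time, component_cost) < 0:
        raise ValueError("cost inputs must be >= 0")
    return (weights.w_distance * distance_to_goal / speed
            + weights.w_queue * queue_time
            + weights.w_component * component_cost)


@dataclass
class QueueConfig:
    """Service nodes: (number of parallel servers, service time s)."""

    security: tuple[int, float] = (4, 2.0)
    gate_in: tuple[int, float] = (4, 1.5)
    gate_out: tuple[int, float] = (4, 1.5)
    ticket: tuple[int, float] = (4, 20.0)
    escalator_board_s: float = 0.5
    escalator_ride_s: float = 18.0
    stair_length_m: float = 14.0
    queue_spacing_m: float = 0.6
    arrival_margin_s: tuple[float, float] = (15.0, 100.0)
    platform_leg_est_m: float = 25.0
    walk_estimate_pad_s: float = 15.0
    alight_egress_spread_s: float = 20.0


@dataclass
class Trajectory:
    """One pedestrian's per-second track (floor codes per station.FLOOR_CODES)."""

    ped_id: int
    direction: str
    entry_portal: str
    exit_portal: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    floor: np.ndarray  # int8 codes

    @property
    def residence_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def seconds_on(self, floor_name: str) -> int:
        return int(np.sum(self.floor == FLOOR_CODES[floor_name]))


class SimulationResult(list):
    """Sequence of trajectories with bookkeeping for dropped agents."""

    def __init__(self, trajectories, dropped=None, spawned=None):
        super().__init__(trajectories)
        self.dropped = list(dropped or [])
        self.spawned = spawned if spawned is not None else len(self)


@dataclass
class DensityField:
    grid: Grid2D
    values: np.ndarray  # persons/m^2
    window: tuple[float, float]


@dataclass
class ParticleSource:
    x: float
    y: float
    floor: str
    persons: float
    rate_mg_per_h: float
    radius_m: float = 0.0  # emission footprint (crowd area equivalent circle)


# ---------------------------------------------------------------------------
# queue bookkeeping

def _fifo_multiserver(arrivals: np.ndarray, n_servers: int, service: float):
    """FIFO service with parallel identical servers.

    Returns (start, depart, queue_len_at_arrival) in arrival order.  Service
    starts are enforced non-decreasing in arrival order, so no agent overtakes
    another inside the queue.
    """
    import heapq

    order = np.argsort(arrivals, kind="stable")
    free = [0.0] * n_servers
    heapq.heapify(free)
    start = np.empty_like(arrivals)
    depart = np.empty_like(arrivals)
    qlen = np.zeros(len(arrivals), dtype=int)
    starts_sorted: list[float] = []
    prev_start = -math.inf
    import bisect

    for rank, idx in enumerate(order):
        a = arrivals[idx]
        s = max(a, heapq.heappop(free), prev_start)
        d = s + service
        heapq.heappush(free, d)
        qlen[idx] = rank - bisect.bisect_right(starts_sorted, a)
        bisect.insort(starts_sorted, s)
        start[idx] = s
        depart[idx] = d
        prev_start = s
    return start, depart, qlen


# ---------------------------------------------------------------------------
# itinerary construction

@dataclass
class _Leg:
    t0: float
    t1: float
    p0: tuple[float, float]
    p1: tuple[float, float]
    floor: int


class _Itinerary:
    """Mutable list of legs with a moving clock."""

    def __init__(self, t0: float, pos, floor: int, speed: float):
        self.t = t0
        self.pos = pos
        self.floor = floor
        self.speed = speed
        self.legs: list[_Leg] = []

    def walk_to(self, pos) -> None:
        d = math.dist(self.pos, pos)
        if d == 0:
            return
        t1 = self.t + d / self.speed
        self.legs.append(_Leg(self.t, t1, self.pos, pos, self.floor))
        self.t, self.pos = t1, pos

    def wait_until(self, t1: float) -> None:
        if t1 <= self.t:
            return
        self.legs.append(_Leg(self.t, t1, self.pos, self.pos, self.floor))
        self.t = t1

    def transfer(self, pos, floor: int, duration: float) -> None:
        """Stair/escalator link: frame change with a timed vertical transit."""
        t1 = self.t + duration
        mid = 0.5 * (self.t + t1)
        self.legs.append(_Leg(self.t, mid, self.pos, self.pos, self.floor))
        self.legs.append(_Leg(mid, t1, pos, pos, floor))
        self.t, self.pos, self.floor = t1, pos, floor


def _sample_positions(legs: list[_Leg]):
    t0, t1 = legs[0].t0, legs[-1].t1
    ts = np.arange(math.ceil(t0), math.floor(t1) + 1, dtype=np.int64)
    if len(ts) == 0:
        return ts, np.empty(0), np.empty(0), np.empty(0, np.int8)
    starts = np.array([g.t0 for g in legs])
    idx = np.clip(np.searchsorted(starts, ts, side="right") - 1, 0, len(legs) - 1)
    x = np.empty(len(ts))
    y = np.empty(len(ts))
    fl = np.empty(len(ts), np.int8)
    for k, (t, i) in enumerate(zip(ts, idx)):
        g = legs[i]
        dur = g.t1 - g.t0
        f = 0.0 if dur <= 0 else min(max((t - g.t0) / dur, 0.0), 1.0)
        x[k] = g.p0[0] + f * (g.p1[0] - g.p0[0])
        y[k] = g.p0[1] + f * (g.p1[1] - g.p0[1])
        fl[k] = g.floor
    return ts, x, y, fl


# ---------------------------------------------------------------------------
# the simulator

def _train_times(first: float, headway: float, until: float) -> np.ndarray:
    n = max(1, int(math.ceil((until - first) / headway)) + 1)
    return first + headway * np.arange(n)


def simulate_trajectories(
    demand: DemandSpec,
    geometry: StationGeometry,
    weights: RouteCostWeights | None = None,
    speed: SpeedModel | None = None,
    duration: float = 1200.0,
    seed: int | np.random.SeedSequence = 0,
    queues: QueueConfig | None = None,
) -> SimulationResult:
    """Simulate boarding and alighting pedestrians at 1-s resolution.

    Deterministic for a fixed seed; one named RNG stream per subsystem
    (speeds, choices, arrivals).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    weights = weights or RouteCostWeights()
    speed = speed or SpeedModel()
    queues = queues or QueueConfig()
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    r_speed, r_choice, r_arrival = [np.random.default_rng(s)
                                    for s in ss.spawn(3)]

    g = geometry
    exits = {p.meta["label"]: p for p in g.portals_on(CONCOURSE, "exit")}
    security = g.portal("security").center
    gates_in = g.portal("gates_in").center
    gates_out = g.portal("gates_out").center
    stair_c = g.portal("stair_c").center
    esc_c = g.portal("escalator_c").center
    stair_p = g.portal("stair_p").center
    esc_p = g.portal("escalator_p").center
    tickets = {"north": g.portal("ticket_north").center,
               "south": g.portal("ticket_south").center}
    psd = {p.meta["side"]: p for p in g.portals_on(PLATFORM, "psd")}
    wait_y = {"AB": 11.5, "CD": 1.3}
    fc, fp = FLOOR_CODES[CONCOURSE], FLOOR_CODES[PLATFORM]

    # trains per side, extended past the window so late agents can board
    trains = {
        "CD": _train_times(60.0, demand.headway_s, duration + 2 * demand.headway_s),
        "AB": _train_times(240.0, demand.headway_s, duration + 2 * demand.headway_s),
    }

    exit_keys, exit_p = demand.exit_probs()

    # --- spawn boarding agents -------------------------------------------
    boarding = []
    pid = 0
    for side, rate in sorted(demand.boarding_per_hour.items()):
        n = int(round(rate * duration / 3600.0))
        if n == 0:
            continue
        exit_choice = r_choice.choice(exit_keys, size=n, p=exit_p)
        use_card = r_arrival.random(n) < demand.card_fraction
        speeds = np.atleast_1d(sample_speed(speed, r_speed, n))
        side_trains = trains[side]
        in_window = side_trains[side_trains <= duration + demand.headway_s]
        lo, hi = queues.arrival_margin_s
        margin = r_arrival.uniform(lo, hi, n)
        target_u = r_arrival.random(n)
        for k in range(n):
            e = exits[exit_choice[k]]
            v = float(speeds[k])
            walk_est = (
                (math.dist(e.center, security)
                 + math.dist(security, gates_in)
                 + math.dist(gates_in, esc_c)
                 + queues.platform_leg_est_m) / v
                + queues.escalator_ride_s
                + (queues.ticket[1] if not use_card[k] else 0.0)
                + queues.walk_estimate_pad_s)
            # target only trains the agent can plausibly reach
            reachable = in_window[in_window >= walk_est + margin[k]]
            if len(reachable) == 0:
                reachable = side_trains[-1:]
            target = reachable[int(target_u[k] * len(reachable))]
            spawn = max(0.0, target - margin[k] - walk_est)
            boarding.append({
                "pid": pid, "exit": exit_choice[k], "portal": e,
                "card": bool(use_card[k]), "speed": float(speeds[k]),
                "side": side, "spawn": spawn,
            })
            pid += 1

    # --- spawn alighting agents ------------------------------------------
    alighting = []
    for side, rate in sorted(demand.alighting_per_hour.items()):
        per_train = int(round(rate * demand.headway_s / 3600.0))
        for tt in trains[side]:
            if tt >= duration:
                continue
            speeds = np.atleast_1d(sample_speed(speed, r_speed, per_train))
            exit_choice = r_choice.choice(exit_keys, size=per_train, p=exit_p)
            door_x = r_choice.uniform(psd[side].rect[0], psd[side].rect[2],
                                      per_train)
            egress = r_arrival.uniform(0, queues.alight_egress_spread_s,
                                       per_train)
            for k in range(per_train):
                alighting.append({
                    "pid": pid, "exit": exit_choice[k],
                    "speed": float(speeds[k]), "side": side,
                    "spawn": tt + egress[k], "door_x": float(door_x[k]),
                })
                pid += 1

    dropped: list[dict] = []
    spawned = len(boarding) + len(alighting)

    # --- boarding itineraries: concourse legs + staged queues ------------
    for a in boarding:
        it = _Itinerary(a["spawn"], a["portal"].center, fc, a["speed"])
        a["it"] = it

    def _run_queue(agents, node_xy, servers, service, back_dir):
        if not agents:
            return
        arrivals = np.array([ag["it"].t + math.dist(ag["it"].pos, node_xy)
                             / ag["speed"] for ag in agents])
        start, depart, qlen = _fifo_multiserver(arrivals, servers, service)
        for ag, s, d, q in zip(agents, start, depart, qlen):
            it = ag["it"]
            back = min(queues.queue_spacing_m * q, 15.0)
            qpt = (node_xy[0] + back_dir[0] * back,
                   node_xy[1] + back_dir[1] * back)
            it.walk_to(qpt)
            walkin = math.dist(qpt, node_xy) / ag["speed"]
            it.wait_until(max(it.t, s - walkin))
            it.walk_to(node_xy)
            it.wait_until(max(it.t, d))

    ticket_users = [a for a in boarding if not a["card"]]
    for a in ticket_users:
        side = "north" if a["exit"] in ("A", "B") else "south"
        a["_ticket"] = tickets[side]
    # route ticket users past their side's machines first
    for side in ("north", "south"):
        grp = [a for a in ticket_users if a["_ticket"] == tickets[side]]
        _run_queue(grp, tickets[side], *queues.ticket, back_dir=(-1.0, 0.0))
    _run_queue(boarding, security, *queues.security, back_dir=(-1.0, 0.0))
    _run_queue(boarding, gates_in, *queues.gate_in, back_dir=(-1.0, 0.0))

    # --- stair vs escalator by route cost, then platform -----------------
    esc_free = 0.0
    for a in sorted(boarding, key=lambda ag: ag["it"].t):
        it = a["it"]
        v = a["speed"]
        d_esc = math.dist(it.pos, esc_c)
        d_st = math.dist(it.pos, stair_c)
        q_est = max(0.0, esc_free - (it.t + d_esc / v))
        c_esc = route_cost(d_esc, v, q_est,
                           weights.component_costs["escalator"], weights)
        c_st = route_cost(d_st, v, 0.0,
                          weights.component_costs["stairs"], weights)
        use_esc = c_esc <= c_st
        a["via"] = "escalator" if use_esc else "stairs"
        if use_esc:
            it.walk_to(esc_c)
            board_t = max(it.t, esc_free)
            esc_free = board_t + queues.escalator_board_s
            it.wait_until(board_t)
            it.transfer(esc_p, fp, queues.escalator_ride_s)
        else:
            it.walk_to(stair_c)
            it.transfer(stair_p, fp, queues.stair_length_m / v)
        # waiting position in front of a PSD on the agent's side
        door_x = float(r_choice.uniform(psd[a["side"]].rect[0],
                                        psd[a["side"]].rect[2]))
        it.walk_to((door_x, wait_y[a["side"]]))
        side_trains = trains[a["side"]]
        nxt = side_trains[np.searchsorted(side_trains, it.t)]
        it.wait_until(nxt)
        a["end_portal"] = psd[a["side"]].id

    # --- alighting itineraries -------------------------------------------
    for a in alighting:
        it = _Itinerary(a["spawn"], (a["door_x"], wait_y[a["side"]]), fp,
                        a["speed"])
        a["it"] = it
    esc_free_up = 0.0
    for a in sorted(alighting, key=lambda ag: ag["it"].t):
        it = a["it"]
        v = a["speed"]
        d_esc = math.dist(it.pos, esc_p)
        d_st = math.dist(it.pos, stair_p)
        q_est = max(0.0, esc_free_up - (it.t + d_esc / v))
        c_esc = route_cost(d_esc, v, q_est,
                           weights.component_costs["escalator"], weights)
        c_st = route_cost(d_st, v, 0.0,
                          weights.component_costs["stairs"], weights)
        if c_esc <= c_st:
            a["via"] = "escalator"
            it.walk_to(esc_p)
            board_t = max(it.t, esc_free_up)
            esc_free_up = board_t + queues.escalator_board_s
            it.wait_until(board_t)
            it.transfer(esc_c, fc, queues.escalator_ride_s)
        else:
            a["via"] = "stairs"
            it.walk_to(stair_p)
            it.transfer(stair_c, fc, queues.stair_length_m / v)
    _run_queue(alighting, gates_out, *queues.gate_out, back_dir=(1.0, 0.0))
    for a in alighting:
        a["it"].walk_to(exits[a["exit"]].center)
        a["end_portal"] = exits[a["exit"]].id

    # --- render per-second trajectories ----------------------------------
    out = []
    for a in boarding + alighting:
        it = a["it"]
        direction = BOARDING if "card" in a else ALIGHTING
        try:
            ts, x, y, fl = _sample_positions(it.legs)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"agent {a['pid']} dropped: {exc}")
            dropped.append(a)
            continue
        if len(ts) == 0:
            dropped.append(a)
            continue
        if direction == BOARDING:
            entry, endp = a["portal"].id, a["end_portal"]
        else:
            entry, endp = psd[a["side"]].id, a["end_portal"]
        out.append(Trajectory(a["pid"], direction, entry, endp, ts, x, y, fl))
    out.sort(key=lambda tr: tr.ped_id)
    return SimulationResult(out, dropped, spawned)


# ---------------------------------------------------------------------------
# densities, service levels, sources, residence stats

def density_map(trajectories, grid: Grid2D, window: tuple[float, float]) -> DensityField:
    """Time-averaged pedestrian density (person-seconds / window / cell area)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    counts = np.zeros(grid.shape)
    code = FLOOR_CODES[grid.floor]
    for tr in trajectories:
        sel = (tr.t >= t0) & (tr.t < t1) & (tr.floor == code)
        if not sel.any():
            continue
        i, j = grid.cell_of(tr.x[sel], tr.y[sel])
        np.add.at(counts, (i, j), 1.0)
    values = counts / ((t1 - t0) * grid.cell_area)
    return DensityField(grid=grid, values=values, window=(t0, t1))


def service_level(density):
    """IATA waiting level A-F for a density (person/m^2); vectorized."""
    d = np.asarray(density, float)
    if np.any(d < 0):
        raise ValueError("density must be >= 0")
    out = np.full(d.shape, "F", dtype="<U1")
    for letter, upper in reversed(_SERVICE_LEVELS):
        out[d <= upper] = letter
    return out if out.shape else str(out)


def _level_lower_bound(level: str) -> float:
    idx = _LEVEL_ORDER.index(level)
    return 0.0 if idx == 0 else _SERVICE_LEVELS[idx - 1][1]


def derive_sources(density: DensityField, bc: BoundaryConditions,
                   level_threshold: str = "C") -> list[ParticleSource]:
    """Pedestrian particulate sources at centroids of congested regions.

    Connected cell regions at or worse than ``level_threshold`` each become a
    point source; emission = mean persons present in the region x the
    per-person generation rate.
    """
    if not 6.5 <= bc.r_per <= 15.2:
        warnings.warn("per-person generation rate outside the reported "
                      "6.5-15.2 mg/h range")
    thr = _level_lower_bound(level_threshold)
    mask = density.values > thr
    labels, n = ndimage.label(mask)
    sources = []
    g = density.grid
    for k in range(1, n + 1):
        region = labels == k
        persons = float(density.values[region].sum() * g.cell_area)
        i, j = np.nonzero(region)
        w = density.values[region]
        cx = float(np.average((i + 0.5) * g.cell_size, weights=w))
        cy = float(np.average((j + 0.5) * g.cell_size, weights=w))
        area = float(region.sum() * g.cell_area)
        sources.append(ParticleSource(cx, cy, g.floor, persons,
                                      persons * bc.r_per,
                                      radius_m=math.sqrt(area / math.pi)))
    return sources


def residence_stats(trajectories) -> dict:
    """Per-direction (min, max, mean) residence time with a per-floor split."""
    by_dir: dict[str, list] = {}
    for tr in trajectories:
        by_dir.setdefault(tr.direction, []).append(tr)
    if not by_dir:
        raise ValueError("no trajectories")
    out = {}
    for d, trs in by_dir.items():
        res = np.array([tr.residence_s for tr in trs])
        out[d] = {
            "min": float(res.min()), "max": float(res.max()),
            "mean": float(res.mean()), "n": len(trs),
            "per_floor": {
                fname: float(np.mean([tr.seconds_on(fname) for tr in trs]))
                for fname in FLOOR_CODES
            },
        }
    return out
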