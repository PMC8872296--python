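"""Station geometry, grids, airflow-organization states and boundary conditions.

The default station is a two-floor underground island-platform station with
platform screen doors (PSDs): a 90.4 m x 20 m x 3.5 m concourse above a
110 m x 12.8 m x 3 m platform.  Four exits (A-D) with passageways sit at the
concourse corners; the island platform has PSD segments on both long sides
(the AB side and the CD side).  The ventilation regime is described by a small
set of discrete airflow-organization states: on the concourse the PSDs are
either closed (station air vents outward through the exits) or open (outdoor
air is drawn in through the exits and down to the platform); on the platform
the third state distinguishes which PSD side is open.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

CONCOURSE = "concourse"
PLATFORM = "platform"
FLOORS = (CONCOURSE, PLATFORM)
FLOOR_CODES = {CONCOURSE: 0, PLATFORM: 1}

# Airflow-organization states.
CLOSED = "CLOSED"
OPEN = "OPEN"
AB_OPEN = "AB_OPEN"
CD_OPEN = "CD_OPEN"
_STATES = {CONCOURSE: (CLOSED, OPEN), PLATFORM: (CLOSED, AB_OPEN, CD_OPEN)}

# Cell label codes for Grid2D; portal cells get codes >= PORTAL_BASE.
WALKABLE, WALL, SUPPLY, RETURN = 0, 1, 2, 3
PORTAL_BASE = 10


def airflow_states(floor: str) -> tuple[str, ...]:
    """Return the ordered airflow-organization states simulated for a floor."""
    try:
        return _STATES[floor]
    except KeyError:
        raise ValueError(f"unknown floor {floor!r}; expected one of {FLOORS}")


@dataclass(frozen=True)
class AirflowState:
    """One discrete ventilation regime of a floor."""

    floor: str
    label: str

    def __post_init__(self):
        if self.label not in airflow_states(self.floor):
            raise ValueError(
                f"state {self.label!r} not valid for floor {self.floor!r}"
            )


@dataclass
class Floor:
    name: str
    length_m: float
    width_m: float
    height_m: float

    @property
    def plan_area_m2(self) -> float:
        return self.length_m * self.width_m


@dataclass
class Portal:
    """A functional station element with an axis-aligned footprint.

    ``rect`` is (x0, y0, x1, y1) in the floor's metric frame (origin at the
    south-west corner, x along the floor length).
    """

    id: str
    floor: str
    role: str  # exit | passageway | stair | escalator | gate_in | gate_out
    #          | security | ticket | psd
    rect: tuple[float, float, float, float]
    meta: dict = field(default_factory=dict)

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.rect
        return (0.5 * (x0 + x1), 0.5 * (y0 + y1))


@dataclass
class BoundaryConditions:
    """Ventilation and particle boundary conditions.

    Units: velocities m/s, lighting W/m^2, particle density kg/m^3, diameter
    m, concentrations ug/m^3, per-person generation mg/(person.h), equipment
    generation kg/s.  ``rho_p``, ``d_p`` and ``w_l`` are carried for config
    fidelity; the depth-averaged solver does not use them.
    """

    v_c: float = 2.3
    v_p: float = 1.9
    w_l: float = 20.0
    rho_p: float = 1050.0
    d_p: float = 2.5e-6
    mu_out: float = 61.5
    mu_sup: float = 24.4
    r_per: float = 10.0
    r_eq: float = 3.78e-9
    filtration_efficiency: float = 0.40

    def __post_init__(self):
        for name, value in self.to_dict().items():
            if value < 0:
                raise ValueError(f"boundary condition {name} must be >= 0")

    def to_dict(self) -> dict:
        return {
            "v_c": self.v_c, "v_p": self.v_p, "w_l": self.w_l,
            "rho_p": self.rho_p, "d_p": self.d_p, "mu_out": self.mu_out,
            "mu_sup": self.mu_sup, "r_per": self.r_per, "r_eq": self.r_eq,
            "filtration_efficiency": self.filtration_efficiency,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoundaryConditions":
        return cls(**d)


@dataclass
class StationGeometry:
    floors: dict[str, Floor]
    portals: list[Portal]
    # per-floor arrays of outlet (x, y) positions and one outlet size (m, m)
    supply_outlets: dict[str, np.ndarray]
    return_outlets: dict[str, np.ndarray]
    outlet_size: dict[str, tuple[float, float]]
    bc: BoundaryConditions = field(default_factory=BoundaryConditions)

    def __post_init__(self):
        self.validate()

    # -- queries -----------------------------------------------------------
    def portals_on(self, floor: str, role: str | None = None) -> list[Portal]:
        out = [p for p in self.portals if p.floor == floor]
        if role is not None:
            out = [p for p in out if p.role == role]
        return out

    def portal(self, pid: str) -> Portal:
        for p in self.portals:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def contains(self, floor: str, x, y) -> np.ndarray:
        f = self.floors[floor]
        return (
            (np.asarray(x) >= 0) & (np.asarray(x) <= f.length_m)
            & (np.asarray(y) >= 0) & (np.asarray(y) <= f.width_m)
        )

    def validate(self) -> None:
        for p in self.portals:
            f = self.floors[p.floor]
            x0, y0, x1, y1 = p.rect
            if not (0 <= x0 < x1 <= f.length_m and 0 <= y0 < y1 <= f.width_m):
                raise ValueError(f"portal {p.id} footprint outside floor")
            if p.role == "exit" and p.floor != CONCOURSE:
                raise ValueError("exits exist only on the concourse")
            if p.role == "psd" and p.floor != PLATFORM:
                raise ValueError("PSDs exist only on the platform")

    # -- serialization -----------------------------------------------------
    def to_config(self) -> dict:
        return {
            "floors": {
                n: {"length_m": f.length_m, "width_m": f.width_m,
                    "height_m": f.height_m}
                for n, f in self.floors.items()
            },
            "portals": [
                {"id": p.id, "floor": p.floor, "role": p.role,
                 "rect": list(p.rect), "meta": p.meta}
                for p in self.portals
            ],
            "supply_outlets": {k: v.tolist() for k, v in self.supply_outlets.items()},
            "return_outlets": {k: v.tolist() for k, v in self.return_outlets.items()},
            "outlet_size": {k: list(v) for k, v in self.outlet_size.items()},
            "boundary_conditions": self.bc.to_dict(),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "StationGeometry":
        floors = {
            n: Floor(n, d["length_m"], d["width_m"], d["height_m"])
            for n, d in cfg["floors"].items()
        }
        portals = [
            Portal(d["id"], d["floor"], d["role"], tuple(d["rect"]),
                   dict(d.get("meta", {})))
            for d in cfg["portals"]
        ]
        return cls(
            floors=floors,
            portals=portals,
            supply_outlets={k: np.asarray(v, float)
                            for k, v in cfg["supply_outlets"].items()},
            return_outlets={k: np.asarray(v, float)
                            for k, v in cfg["return_outlets"].items()},
            outlet_size={k: tuple(v) for k, v in cfg["outlet_size"].items()},
            bc=BoundaryConditions.from_dict(cfg["boundary_conditions"]),
        )

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(self.to_config(), fh, indent=1)
            else:
                yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "StationGeometry":
        path = str(path)
        with open(path) as fh:
            cfg = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        return cls.from_config(cfg)


def _outlet_grid(xs, ys) -> np.ndarray:
    pts = [(x, y) for y in ys for x in xs]
    return np.asarray(pts, float)


def build_default_station(bc: BoundaryConditions | None = None) -> StationGeometry:
    """The built-in two-floor island-platform station.

    Concourse 90.4 x 20 x 3.5 m with four corner exits (A, B north side;
    C, D south side) behind short passageways, one security checkpoint, ticket
    machines, in/out fare-gate arrays and a stair + escalator pair down to the
    110 x 12.8 x 3 m platform, whose PSD segments run along both long sides.
    Supply/return outlets are uniformly spaced arrays at the printed outlet
    sizes (300x300 mm concourse, 600x500 mm platform).
    """
    floors = {
        CONCOURSE: Floor(CONCOURSE, 90.4, 20.0, 3.5),
        PLATFORM: Floor(PLATFORM, 110.0, 12.8, 3.0),
    }
    portals = [
        # corner passageways and exits (A/B north, C/D south)
        Portal("passageway_A", CONCOURSE, "passageway", (0.0, 15.0, 9.0, 20.0)),
        Portal("exit_A", CONCOURSE, "exit", (0.0, 16.0, 1.2, 20.0), {"label": "A"}),
        Portal("passageway_B", CONCOURSE, "passageway", (81.4, 15.0, 90.4, 20.0)),
        Portal("exit_B", CONCOURSE, "exit", (89.2, 16.0, 90.4, 20.0), {"label": "B"}),
        Portal("passageway_C", CONCOURSE, "passageway", (0.0, 0.0, 9.0, 5.0)),
        Portal("exit_C", CONCOURSE, "exit", (0.0, 0.0, 1.2, 4.0), {"label": "C"}),
        Portal("passageway_D", CONCOURSE, "passageway", (81.4, 0.0, 90.4, 5.0)),
        Portal("exit_D", CONCOURSE, "exit", (89.2, 0.0, 90.4, 4.0), {"label": "D"}),
        # concourse furniture
        Portal("ticket_north", CONCOURSE, "ticket", (18.0, 17.0, 22.0, 19.5)),
        Portal("ticket_south", CONCOURSE, "ticket", (18.0, 0.5, 22.0, 3.0)),
        Portal("security", CONCOURSE, "security", (27.0, 8.0, 31.0, 12.0)),
        Portal("gates_in", CONCOURSE, "gate_in", (38.0, 10.5, 40.0, 16.5)),
        Portal("gates_out", CONCOURSE, "gate_out", (38.0, 3.5, 40.0, 9.5)),
        Portal("stair_c", CONCOURSE, "stair", (52.0, 6.4, 56.0, 9.4)),
        Portal("escalator_c", CONCOURSE, "escalator", (52.0, 10.6, 56.0, 13.6)),
        # platform
        Portal("stair_p", PLATFORM, "stair", (49.0, 4.9, 53.0, 7.9)),
        Portal("escalator_p", PLATFORM, "escalator", (57.0, 4.9, 61.0, 7.9)),
        Portal("psd_AB", PLATFORM, "psd", (9.0, 12.3, 101.0, 12.8), {"side": "AB"}),
        Portal("psd_CD", PLATFORM, "psd", (9.0, 0.0, 101.0, 0.5), {"side": "CD"}),
    ]
    supply = {
        CONCOURSE: _outlet_grid(np.linspace(8.0, 82.4, 10), (4.0, 10.0, 16.0)),
        PLATFORM: _outlet_grid(np.linspace(12.0, 98.0, 6), (4.3, 8.5)),
    }
    ret = {
        CONCOURSE: _outlet_grid(np.linspace(14.0, 76.4, 6), (7.0, 13.0)),
        # platform return outlets sit toward the AB side
        PLATFORM: _outlet_grid(np.linspace(16.0, 94.0, 6), (9.6,)),
    }
    return StationGeometry(
        floors=floors,
        portals=portals,
        supply_outlets=supply,
        return_outlets=ret,
        outlet_size={CONCOURSE: (0.3, 0.3), PLATFORM: (0.6, 0.5)},
        bc=bc if bc is not None else BoundaryConditions(),
    )


@dataclass
class Grid2D:
    """Cell-indexed raster of one floor.

    Row i covers x in [i*h, (i+1)*h), column j covers y likewise (0-based,
    row-major, origin at the floor's south-west corner).  ``labels`` holds
    cell codes; ``legend`` maps codes to names including per-portal codes.
    """

    floor: str
    cell_size: float
    n_rows: int
    n_cols: int
    labels: np.ndarray
    legend: dict[int, str]
    portal_cells: dict[str, np.ndarray]  # portal id -> (k, 2) array of (i, j)
    supply_cells: np.ndarray
    return_cells: np.ndarray
    floor_height: float
    floor_length: float
    floor_width: float

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        i = np.clip((np.asarray(x) / self.cell_size).astype(int), 0, self.n_rows - 1)
        j = np.clip((np.asarray(y) / self.cell_size).astype(int), 0, self.n_cols - 1)
        return i, j

    def center_of(self, i, j) -> tuple[np.ndarray, np.ndarray]:
        h = self.cell_size
        return ((np.asarray(i) + 0.5) * h, (np.asarray(j) + 0.5) * h)

    def walkable_mask(self) -> np.ndarray:
        return self.labels != WALL

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        i, j = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols),
                           indexing="ij")
        return self.center_of(i, j)


def blank_grid(floor: str, n_rows: int, n_cols: int, cell_size: float = 1.0,
               height: float = 3.0) -> Grid2D:
    """A fully walkable grid with no portals/outlets (solver test harness)."""
    return Grid2D(
        floor=floor, cell_size=cell_size, n_rows=n_rows, n_cols=n_cols,
        labels=np.full((n_rows, n_cols), WALKABLE, dtype=np.int16),
        legend={WALKABLE: "walkable", WALL: "wall"},
        portal_cells={}, supply_cells=np.empty((0, 2), int),
        return_cells=np.empty((0, 2), int), floor_height=height,
        floor_length=n_rows * cell_size, floor_width=n_cols * cell_size,
    )


def rasterize(geometry: StationGeometry, cell_size: float) -> dict[str, Grid2D]:
    """Rasterize every floor onto a square-cell grid.

    Cells whose center falls outside the floor rectangle become walls; every
    portal maps to at least one cell (the cell nearest its center if its
    footprint is sub-cell).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    grids = {}
    for name, f in geometry.floors.items():
        if cell_size > min(f.length_m, f.width_m):
            raise ValueError("cell_size exceeds the smallest floor dimension")
        n_rows = math.ceil(f.length_m / cell_size)
        n_cols = math.ceil(f.width_m / cell_size)
        labels = np.full((n_rows, n_cols), WALKABLE, dtype=np.int16)
        cx, cy = np.meshgrid(
            (np.arange(n_rows) + 0.5) * cell_size,
            (np.arange(n_cols) + 0.5) * cell_size, indexing="ij")
        labels[(cx > f.length_m) | (cy > f.width_m)] = WALL
        legend = {WALKABLE: "walkable", WALL: "wall", SUPPLY: "supply",
                  RETURN: "return"}

        portal_cells: dict[str, np.ndarray] = {}
        for k, p in enumerate(geometry.portals_on(name)):
            x0, y0, x1, y1 = p.rect
            inside = (cx >= x0) & (cx < x1) & (cy >= y0) & (cy < y1)
            ij = np.argwhere(inside)
            if len(ij) == 0:  # sub-cell footprint: nearest cell to the center
                px, py = p.center
                ij = np.array([[min(int(px / cell_size), n_rows - 1),
                                min(int(py / cell_size), n_cols - 1)]])
            code = PORTAL_BASE + k
            legend[code] = f"portal:{p.id}"
            labels[tuple(ij.T)] = code
            portal_cells[p.id] = ij

        def _points_to_cells(pts):
            i = np.clip((pts[:, 0] / cell_size).astype(int), 0, n_rows - 1)
            j = np.clip((pts[:, 1] / cell_size).astype(int), 0, n_cols - 1)
            return np.column_stack([i, j])

        sup = _points_to_cells(geometry.supply_outlets[name])
        retc = _points_to_cells(geometry.return_outlets[name])
        labels[tuple(sup.T)] = SUPPLY
        labels[tuple(retc.T)] = RETURN
        grids[name] = Grid2D(
            floor=name, cell_size=cell_size, n_rows=n_rows, n_cols=n_cols,
            labels=labels, legend=legend, portal_cells=portal_cells,
            supply_cells=sup, return_cells=retc, floor_height=f.height_m,
            floor_length=f.length_m, floor_width=f.width_m,
        )
    return grids
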