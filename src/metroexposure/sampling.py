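"""Optimal Latin hypercube placement of measurement points.

A Latin hypercube design places one point per axis stratum; the "optimal"
variant here maximizes the minimum pairwise Euclidean distance (maximin) by
accept-if-better random stratum swaps, which makes the score non-decreasing
over iterations and the whole design deterministic per seed.  Points sit at
stratum centers, so ``n = 1`` yields the domain center.

The station plan divides each long floor into two lengthwise halves with 20
points each, adds three points per concourse passageway, and then drops the
candidates closest to obstructive furniture (gate arrays on the concourse,
the stair/escalator block on the platform) until the requested totals are
reached — 47 concourse and 29 platform points by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .station import CONCOURSE, PLATFORM, StationGeometry


def maximin_distance(points: np.ndarray) -> float:
    """Minimum pairwise Euclidean distance of a design (inf for n < 2)."""
    pts = np.asarray(points, float)
    if len(pts) < 2:
        return float("inf")
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return float(d[np.triu_indices(len(pts), 1)].min())


def olhs(n: int, bounds, iterations: int = 300,
         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Maximin-optimized centered Latin hypercube in a box.

    ``bounds`` is ((lo, hi), ...) per dimension.  Starts from random stratum
    permutations and applies ``iterations`` random within-dimension swaps,
    keeping a swap only if it improves the maximin distance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    bounds = np.asarray(bounds, float)
    if bounds.ndim != 2 or np.any(bounds[:, 1] <= bounds[:, 0]):
        raise ValueError("bounds must be non-degenerate (lo < hi) per axis")
    d = len(bounds)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    perms = np.stack([rng.permutation(n) for _ in range(d)], axis=1)

    def _unit(p):
        return (p + 0.5) / n

    best = perms.copy()
    best_score = maximin_distance(_unit(best))
    if n > 1:
        cur, cur_score = best.copy(), best_score
        stall, stall_limit = 0, max(20, 2 * n * d)
        for _ in range(iterations):
            dim = int(rng.integers(d))
            i, j = rng.choice(n, size=2, replace=False)
            cand = cur.copy()
            cand[[i, j], dim] = cand[[j, i], dim]
            score = maximin_distance(_unit(cand))
            if score > cur_score:
                cur, cur_score = cand, score
                stall = 0
                if score > best_score:
                    best, best_score = cand, score
            else:
                stall += 1
                if stall >= stall_limit:  # restart from a fresh design
                    cur = np.stack([rng.permutation(n) for _ in range(d)],
                                   axis=1)
                    cur_score = maximin_distance(_unit(cur))
                    if cur_score > best_score:
                        best, best_score = cur.copy(), cur_score
                    stall = 0
    return bounds[:, 0] + _unit(best) * (bounds[:, 1] - bounds[:, 0])


@dataclass
class SamplePlan:
    """Ordered sample points with their design metadata."""

    points: pd.DataFrame  # point_id, floor, zone, x_m, y_m
    metadata: dict = field(default_factory=dict)

    def on_floor(self, floor: str) -> pd.DataFrame:
        return self.points[self.points.floor == floor].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.points)


DEFAULT_PLAN_SPEC = {
    CONCOURSE: {"per_half": 20, "per_passageway": 3, "target": 47},
    PLATFORM: {"per_half": 20, "target": 29},
}


def design_station_samples(geometry: StationGeometry,
                           plan_spec: dict | None = None,
                           seed: int = 0,
                           iterations: int = 300) -> SamplePlan:
    """OLHS measurement plan for both floors of the station."""
    spec = plan_spec or DEFAULT_PLAN_SPEC
    rng = np.random.default_rng(seed)
    margin = 0.5  # keep points off the walls
    records = []

    def _zone_points(n, rect, floor, zone):
        (x0, x1), (y0, y1) = rect
        pts = olhs(n, ((x0, x1), (y0, y1)), iterations=iterations, seed=rng)
        for x, y in pts:
            records.append({"floor": floor, "zone": zone,
                            "x_m": float(x), "y_m": float(y)})

    for floor, fs in spec.items():
        f = geometry.floors[floor]
        half = f.length_m / 2
        _zone_points(fs["per_half"], ((margin, half), (margin, f.width_m - margin)),
                     floor, "half-1")
        _zone_points(fs["per_half"], ((half, f.length_m - margin),
                                      (margin, f.width_m - margin)),
                     floor, "half-2")
        if "per_passageway" in fs:
            for p in geometry.portals_on(floor, "passageway"):
                x0, y0, x1, y1 = p.rect
                label = p.id.split("_")[-1]
                _zone_points(fs["per_passageway"],
                             ((x0 + 0.3, x1 - 0.3), (y0 + 0.3, y1 - 0.3)),
                             floor, f"passageway-{label}")

    df = pd.DataFrame(records)

    # drop the candidates least convenient to measure until targets are met:
    # concourse points closest to the fare-gate arrays, platform points
    # closest to the cordoned platform ends beyond the PSD range
    kept = []
    for floor, fs in spec.items():
        sub = df[df.floor == floor].reset_index(drop=True)
        target = fs.get("target", len(sub))
        n_drop = len(sub) - target
        if n_drop < 0:
            raise ValueError(f"target exceeds candidates on {floor}")
        if n_drop > 0:
            pts = sub[["x_m", "y_m"]].to_numpy()
            if floor == CONCOURSE:
                anchors = np.array([
                    geometry.portal(p.id).center
                    for p in geometry.portals_on(floor)
                    if p.role in ("gate_in", "gate_out")
                ])
                dist = np.linalg.norm(pts[:, None, :] - anchors[None, :, :],
                                      axis=-1).min(axis=1)
            else:
                length = geometry.floors[floor].length_m
                dist = np.minimum(pts[:, 0], length - pts[:, 0])
            order = np.argsort(dist, kind="stable")
            sub = sub.drop(index=order[:n_drop]).reset_index(drop=True)
        kept.append(sub)
    out = pd.concat(kept, ignore_index=True)
    for floor in spec:
        sub = out[out.floor == floor]
        ok = geometry.contains(floor, sub.x_m.to_numpy(), sub.y_m.to_numpy())
        if not np.all(ok):
            raise RuntimeError("sample point outside walkable area")
    out.insert(0, "point_id", np.arange(len(out)))
    meta = {
        "seed": seed,
        "n_per_zone": out.groupby(["floor", "zone"]).size().to_dict(),
        "maximin_m": {
            floor: maximin_distance(
                out[out.floor == floor][["x_m", "y_m"]].to_numpy())
            for floor in spec
        },
    }
    return SamplePlan(points=out, metadata=meta)
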