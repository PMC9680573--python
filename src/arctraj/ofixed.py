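"""Exact optimal fixed-couch arc selection (OFIXED) on an overlap map.

The solver answers: partition the 360-degree gantry circle into at most
``max_arcs`` contiguous sub-arcs, each spanning at least ``min_span``
degrees, assign every sub-arc one fixed couch angle (repeats allowed), and
minimize the summed overlap-map value over the covered control points (one
control point per gantry bin, each delivered exactly once). Collision-flagged
bins carry infinite cost, so a feasible solution never covers one.

The formalization follows the delivery budget of a single pass through the
gantry circle at 1-degree control-point spacing (360 control points total):
arcs partition the circle rather than independently re-covering gantry
ranges. Global optimality is guaranteed: per-sector best-couch costs come
from prefix sums, and the circular partition is solved by dynamic
programming with the first breakpoint enumerated. An exhaustive enumeration
oracle (:func:`enumerate_optimal`) exists for small maps to verify this.

Tie-breaking is deterministic: fewest arcs after merging adjacent
same-couch sectors, then the lexicographically smallest sequence of
(couch angle, gantry start) pairs with arcs ordered by gantry start.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import ArctrajError, ValidationError
from .bev import OverlapMap

logger = logging.getLogger("arctraj")


class InfeasibleError(ArctrajError):
    """No arc partition avoids the collision-flagged bins."""


@dataclass(frozen=True)
class ArcConstraints:
    """Delivery constraints: at most ``max_arcs`` sub-arcs of >= ``min_span`` deg.

    Defaults mirror clinical VMAT restrictions: no arc shorter than 30
    degrees, at most four sub-arcs, and a total budget of one full gantry
    revolution (360 degrees of control points).
    """

    max_arcs: int = 4
    min_span_deg: float = 30.0
    total_span_deg: float = 360.0

    def __post_init__(self) -> None:
        if self.max_arcs < 1:
            raise ValidationError("max_arcs must be >= 1")
        if self.min_span_deg <= 0:
            raise ValidationError("min_span_deg must be > 0")
        if self.max_arcs * self.min_span_deg > self.total_span_deg:
            raise ValidationError("max_arcs * min_span exceeds the total span")

    def min_span_bins(self, resolution_deg: float) -> int:
        if self.min_span_deg < resolution_deg:
            raise ValidationError("min_span must be >= the map resolution")
        m = int(round(self.min_span_deg / resolution_deg))
        if not np.isclose(m * resolution_deg, self.min_span_deg):
            raise ValidationError("min_span must be a multiple of the resolution")
        return m


@dataclass(frozen=True)
class Arc:
    """One fixed-couch sub-arc: half-open gantry sector [start, start+span)."""

    couch_deg: float
    gantry_start_deg: float
    span_deg: float


@dataclass
class ArcSolution:
    """An ordered set of sub-arcs jointly covering the gantry circle once."""

    arcs: list[Arc]
    total_cost: float | None   # None for fixed geometries not scored on a map
    resolution_deg: float
    feasible: bool = True

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {"arcs": [{"couch_deg": a.couch_deg,
                         "gantry_start_deg": a.gantry_start_deg,
                         "span_deg": a.span_deg} for a in self.arcs],
               "total_cost": self.total_cost,
               "resolution_deg": self.resolution_deg}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "ArcSolution":
        doc = json.loads(Path(path).read_text())
        return cls(arcs=[Arc(**a) for a in doc["arcs"]],
                   total_cost=doc["total_cost"],
                   resolution_deg=doc["resolution_deg"])

    def control_points(self) -> pd.DataFrame:
        """One row per control point: index, couch, gantry (total span / res rows)."""
        rows = []
        for arc in sorted(self.arcs, key=lambda a: a.gantry_start_deg):
            n = int(round(arc.span_deg / self.resolution_deg))
            for i in range(n):
                rows.append({"couch_deg": arc.couch_deg,
                             "gantry_deg": (arc.gantry_start_deg
                                            + i * self.resolution_deg) % 360.0})
        df = pd.DataFrame(rows)
        df.insert(0, "index", np.arange(len(df)))
        return df


# ---------------------------------------------------------------------------
# Sector cost tables
# ---------------------------------------------------------------------------

def _sector_tables(omap: OverlapMap, min_bins: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Best couch cost/index for every circular gantry sector [s, s+L).

    Returns ``(bestcost, bestcouch)`` of shape (G, G+1) indexed by start bin
    and length; entries are +inf / -1 for L < min_bins, L = 0, or sectors
    whose best couch row is collision-flagged everywhere cheaper rows fail.
    Ties in couch go to the lowest couch index (iteration order).
    """
    vals = omap.values
    col = omap.collision
    C, G = vals.shape
    starts = np.arange(G)
    lens = np.arange(G + 1)
    idx = starts[:, None] + lens[None, :]

    bestcost = np.full((G, G + 1), np.inf)
    bestcouch = np.full((G, G + 1), -1, dtype=int)
    for c in range(C):
        p = np.concatenate([[0.0], np.cumsum(np.concatenate([vals[c], vals[c]]))])
        pc = np.concatenate([[0], np.cumsum(np.concatenate([col[c], col[c]]).astype(int))])
        cost = p[idx] - p[starts[:, None]]
        blocked = (pc[idx] - pc[starts[:, None]]) > 0
        cost[blocked] = np.inf
        better = cost < bestcost
        bestcost[better] = cost[better]
        bestcouch[better] = c
    bestcost[:, :min_bins] = np.inf
    bestcouch[:, :min_bins] = -1
    return bestcost, bestcouch


def _canonical(sectors: list[tuple[int, int, int]], omap: OverlapMap,
               bestcost: np.ndarray) -> tuple[ArcSolution, tuple]:
    """Merge adjacent same-couch sectors, order by gantry start, build key.

    ``sectors`` are (start_bin, length_bins, couch_index) in circular order.
    Returns the solution and its tie-break key
    (total_cost, n_arcs, ((couch_deg, gantry_start_deg), ...)).
    """
    res = omap.resolution_deg
    G = omap.values.shape[1]

    merged = [list(sectors[0])]
    for s, length, c in sectors[1:]:
        if c == merged[-1][2] and (merged[-1][0] + merged[-1][1]) % G == s % G:
            merged[-1][1] += length
        else:
            merged.append([s, length, c])
    # wrap-around merge
    if len(merged) > 1 and merged[0][2] == merged[-1][2] \
            and (merged[-1][0] + merged[-1][1]) % G == merged[0][0] % G:
        merged[-1][1] += merged[0][1]
        merged.pop(0)

    cost = float(sum(bestcost[s % G, length] if length <= G else 0.0
                     for s, length, c in sectors))
    # recompute on original sectors; merged spans may exceed table range
    arcs = []
    for s, length, c in merged:
        if length >= G:
            start_deg = 0.0  # a full-circle arc has an arbitrary start
            length = G
        else:
            start_deg = float(omap.gantry_deg[s % G])
        arcs.append(Arc(couch_deg=float(omap.couch_deg[c]),
                        gantry_start_deg=start_deg,
                        span_deg=length * res))
    arcs.sort(key=lambda a: a.gantry_start_deg)
    key = (cost, len(arcs), tuple((a.couch_deg, a.gantry_start_deg) for a in arcs))
    return ArcSolution(arcs=arcs, total_cost=cost, resolution_deg=res), key


def _blocked_couches(omap: OverlapMap) -> list[float]:
    fully = omap.collision.all(axis=1)
    return [float(c) for c in omap.couch_deg[fully]]


# ---------------------------------------------------------------------------
# Exact DP solver
# ---------------------------------------------------------------------------

def solve(omap: OverlapMap, constraints: ArcConstraints | None = None) -> ArcSolution:
    """Globally optimal fixed-couch arc partition of the gantry circle.

    Dynamic programming over contiguous gantry sectors with the first
    breakpoint enumerated; per-sector costs are best-couch prefix-sum
    differences, so the optimum over all partitions into <= max_arcs sectors
    (each >= min_span) is exact.
    """
    constraints = constraints or ArcConstraints()
    C, G = omap.values.shape
    m = constraints.min_span_bins(omap.resolution_deg)
    kmax = min(constraints.max_arcs, G // m)
    if kmax < 1:
        raise ValidationError("min_span exceeds the full gantry circle")

    bestcost, bestcouch = _sector_tables(omap, m)

    # CL2[i, j]: best-couch cost of sector from absolute bin i to j (doubled circle)
    CL2 = np.full((2 * G + 1, 2 * G + 1), np.inf)
    for L in range(m, G + 1):
        i = np.arange(2 * G + 1 - L)
        CL2[i, i + L] = bestcost[i % G, L]

    def dp_for_start(s: int) -> list[np.ndarray]:
        """f[j][e]: min cost of j sectors covering absolute bins [s, e)."""
        fs = [CL2[s, :].copy()]
        for _ in range(2, kmax + 1):
            prev = fs[-1]
            window = slice(s, s + G + 1)
            f = np.full(2 * G + 1, np.inf)
            f[window] = (prev[window, None] + CL2[window, window]).min(axis=0)
            fs.append(f)
        return fs

    per_start_cost = np.full((kmax, G), np.inf)
    for s in range(G):
        fs = dp_for_start(s)
        for k in range(1, kmax + 1):
            per_start_cost[k - 1, s] = fs[k - 1][s + G]
    best = per_start_cost.min()
    if not np.isfinite(best):
        raise InfeasibleError(
            "no collision-free arc partition exists; fully blocked couch "
            f"angles: {_blocked_couches(omap)}")

    kstar = int(np.argmax(per_start_cost.min(axis=1) == best)) + 1
    starts = np.flatnonzero(per_start_cost[kstar - 1] == best)

    best_sol, best_key = None, None
    for s in starts:
        s = int(s)
        if kstar == 1:
            sectors = [(s, G, int(bestcouch[s % G, G]))]
        else:
            fs = dp_for_start(s)
            sectors = []
            pos = s + G
            for j in range(kstar, 1, -1):
                prev = fs[j - 2]
                mids = np.arange(s, pos)
                vals = prev[mids] + CL2[mids, pos]
                target_val = fs[j - 1][pos]
                mid = int(mids[np.flatnonzero(vals == target_val)[0]])
                sectors.append((mid, pos - mid, int(bestcouch[mid % G, pos - mid])))
                pos = mid
            sectors.append((s, pos - s, int(bestcouch[s % G, pos - s])))
            sectors.reverse()
        sol, key = _canonical(sectors, omap, bestcost)
        if best_key is None or key < best_key:
            best_sol, best_key = sol, key
    return best_sol


# ---------------------------------------------------------------------------
# Cost evaluation and brute-force oracle
# ---------------------------------------------------------------------------

def cost(omap: OverlapMap, solution: ArcSolution) -> float:
    """Summed map value over the solution's control points; inf if any is flagged.

    Validates that the arcs tile the gantry circle exactly once.
    """
    res = omap.resolution_deg
    G = omap.values.shape[1]
    covered = np.zeros(G, dtype=int)
    total = 0.0
    flagged = False
    for arc in solution.arcs:
        ci = int(np.argmin(np.abs(omap.couch_deg - arc.couch_deg)))
        if not np.isclose(omap.couch_deg[ci], arc.couch_deg):
            raise ValidationError(f"couch {arc.couch_deg} is not on the map grid")
        start = int(round((arc.gantry_start_deg % 360.0) / res))
        n = int(round(arc.span_deg / res))
        for i in range(n):
            g = (start + i) % G
            covered[g] += 1
            total += omap.values[ci, g]
            flagged |= bool(omap.collision[ci, g])
    if covered.max() > 1:
        raise ValidationError("arc sectors overlap in gantry angle")
    if covered.min() < 1:
        raise ValidationError("arc sectors do not cover the full gantry circle")
    return np.inf if flagged else total


def enumerate_optimal(omap: OverlapMap,
                      constraints: ArcConstraints | None = None) -> ArcSolution:
    """Brute-force exhaustive search over all partitions; test oracle.

    Enumerates every breakpoint set (all combinations of arc starts with
    circular gaps >= min_span) and every per-sector best couch, with the
    same tie-break as :func:`solve`. Refuses maps with more than 36 gantry
    bins.
    """
    constraints = constraints or ArcConstraints()
    C, G = omap.values.shape
    if G > 36:
        raise ValidationError(
            f"enumerate_optimal is a small-map oracle (<= 36 gantry bins), got {G}")
    m = constraints.min_span_bins(omap.resolution_deg)
    kmax = min(constraints.max_arcs, G // m)
    bestcost, bestcouch = _sector_tables(omap, m)

    best_sol, best_key = None, None

    def consider(sectors: list[tuple[int, int, int]]) -> None:
        nonlocal best_sol, best_key
        sol, key = _canonical(sectors, omap, bestcost)
        if best_key is None or key < best_key:
            best_sol, best_key = sol, key

    # k = 1: the single full-circle arc (identical cost for every start)
    if np.isfinite(bestcost[0, G]):
        consider([(0, G, int(bestcouch[0, G]))])

    for k in range(2, kmax + 1):
        combos = np.array(list(itertools.combinations(range(G), k)), dtype=int)
        if len(combos) == 0:
            continue
        lens = np.diff(np.concatenate([combos, combos[:, :1] + G], axis=1), axis=1)
        valid = (lens >= m).all(axis=1)
        combos, lens = combos[valid], lens[valid]
        if len(combos) == 0:
            continue
        costs = bestcost[combos % G, lens].sum(axis=1)
        finite = np.isfinite(costs)
        if not finite.any():
            continue
        cmin = costs[finite].min()
        current = best_key[0] if best_key is not None else np.inf
        if cmin > current:
            continue
        for row in np.flatnonzero(finite & (costs <= min(cmin, current))):
            sectors = [(int(combos[row, i]), int(lens[row, i]),
                        int(bestcouch[combos[row, i] % G, lens[row, i]]))
                       for i in range(k)]
            consider(sectors)

    if best_sol is None:
        raise InfeasibleError(
            "no collision-free arc partition exists; fully blocked couch "
            f"angles: {_blocked_couches(omap)}")
    return best_sol
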