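"""Curved column centerlines ("pins"), their regularization, and synapse
assignment to columns and depths.

A pin is an ordered list of ``n_samp`` 3D points through the center of one
column's synapse cloud, from the region's top boundary surface to its
bottom.  Construction follows an eight-step procedure: a global PCA fixes
the columnar axis, lateral outliers are dropped, endpoint sub-PCAs anchor
the pin on the boundary surfaces, a rank-ordered moving average smooths the
cloud into a line, a shortest sublist with bounded gaps straightens it, and
a monotone cubic (PCHIP) interpolation over cumulative chord length
resamples it uniformly.

Depth is the index of a pin point normalized to [0, 1]; every synapse gets
the depth of its globally nearest pin point.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.spatial import cKDTree

from .data_model import Dataset, HexCoord, RegionBounds


@dataclass(frozen=True)
class PinParams:
    """Region-specific pin construction parameters.

    f_lat
        Lateral outlier factor: points with lateral distance ≥ f_lat·σ_lat
        from the column axis are dropped (σ_lat is the RMS lateral distance).
    n_pc
        Minimum point count for the endpoint sub-PCAs (split mode).
    n_avg
        Moving-average neighborhood: each smoothed point averages a centered
        window of 2·n_avg+1 rank-ordered points, truncated at the ends.
    n_tang
        Divisor of the top-bottom distance defining the maximum gap d_max
        between consecutive points of the straightened sublist.
    n_samp
        Number of resampled pin points.
    endpoint_mode
        "split": separate top/bottom sub-PCAs (medulla); "single": one PCA
        over all points, endpoints from its axis (lobula, lobula plate).
    top_extrapolate_n
        If set (lobula), the top endpoint is the projection onto the column
        axis of the median position of the points with that many smallest
        axial coordinates, instead of a surface intersection.
    pca_on_neuron_means
        Run the axis PCA on per-neuron mean positions instead of raw
        synapses (lobula plate, where the region is thin).
    apply_criteria
        Enforce the three validity criteria; on violation the result is a
        typed no-pin value, not an exception.
    """

    f_lat: float = 2.0
    n_pc: int = 800
    n_avg: int = 260
    n_tang: int = 7
    n_samp: int = 121
    region: str = "ME"
    endpoint_mode: str = "split"
    top_extrapolate_n: int | None = None
    pca_on_neuron_means: bool = False
    apply_criteria: bool = False

    def __post_init__(self):
        for name in ("f_lat", "n_pc", "n_avg", "n_tang", "n_samp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def medulla(cls, **overrides) -> "PinParams":
        return replace(cls(f_lat=2.0, n_pc=800, n_avg=260, n_tang=7, n_samp=121,
                           region="ME", endpoint_mode="split"), **overrides)

    @classmethod
    def lobula(cls, **overrides) -> "PinParams":
        return replace(cls(f_lat=1.5, n_avg=37, n_tang=2, n_samp=76, region="LO",
                           endpoint_mode="single", top_extrapolate_n=37,
                           apply_criteria=True), **overrides)

    @classmethod
    def lobula_plate(cls, **overrides) -> "PinParams":
        return replace(cls(f_lat=1.0, n_avg=56, n_tang=2, n_samp=51, region="LOP",
                           endpoint_mode="single", pca_on_neuron_means=True,
                           apply_criteria=True), **overrides)


@dataclass
class Pin:
    """Ordered centerline of one column; first point on the region's top
    surface, last on the bottom."""

    coord: HexCoord
    points: np.ndarray  # (n_samp, 3)
    region: str = ""


@dataclass
class PinFailure:
    """Typed no-pin result (a validity criterion was violated)."""

    coord: HexCoord | None
    reason: str


@dataclass
class DepthAssignment:
    """synapse_id -> (column coordinate, depth index, normalized depth)."""

    assignments: dict[str, tuple[HexCoord, int, float]]
    unassigned: list[str]
    n_samp: int
    region: str = ""

    def __getitem__(self, sid: str):
        return self.assignments[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)

    def items(self):
        return self.assignments.items()

    def to_frame(self) -> pd.DataFrame:
        rows = [{"synapse_id": sid, "coord_p": c.p, "coord_q": c.q,
                 "depth_index": k, "depth": d}
                for sid, (c, k, d) in self.assignments.items()]
        return pd.DataFrame(rows, columns=["synapse_id", "coord_p", "coord_q",
                                           "depth_index", "depth"])


def _pca(points: np.ndarray):
    mu = points.mean(axis=0)
    centered = points - mu
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axes = np.zeros((3, 3))
    axes[: vt.shape[0]] = vt
    return mu, axes


def _moving_average(arr: np.ndarray, n_avg: int) -> np.ndarray:
    """Centered window of 2·n_avg+1 points, truncated at the ends."""
    n = len(arr)
    csum = np.vstack([np.zeros(3), np.cumsum(arr, axis=0)])
    idx = np.arange(n)
    lo = np.maximum(idx - n_avg, 0)
    hi = np.minimum(idx + n_avg, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)[:, None]


def _shortest_sublist(L: np.ndarray, d_max: float) -> np.ndarray | None:
    """Shortest sublist from L[0] to L[-1] with consecutive gaps <= d_max.

    BFS over indices; among equally short paths the lexicographically first
    (by index) is returned, so the result is deterministic.
    """
    n = len(L)
    pred = np.full(n, -1, dtype=int)
    visited = np.zeros(n, dtype=bool)
    visited[0] = True
    queue = deque([0])
    d2max = d_max * d_max
    while queue:
        i = queue.popleft()
        if i == n - 1:
            break
        later = np.arange(i + 1, n)
        later = later[~visited[i + 1:]]
        if later.size == 0:
            continue
        d2 = ((L[later] - L[i]) ** 2).sum(axis=1)
        reach = later[d2 <= d2max]
        for j in reach:
            visited[j] = True
            pred[j] = i
            queue.append(int(j))
        if visited[n - 1]:
            break
    if not visited[n - 1]:
        return None
    path = [n - 1]
    while path[-1] != 0:
        path.append(int(pred[path[-1]]))
    return L[np.array(path[::-1])]


def build_pin(positions: np.ndarray, bounds: RegionBounds, params: PinParams,
              neuron_ids: np.ndarray | None = None,
              coord: HexCoord | None = None) -> Pin | PinFailure:
    """Construct the pin of one column from its synapse positions.

    Positions should be ordered by synapse id: ties in the axial ranking are
    broken by input order, which keeps the construction deterministic.
    Returns :class:`PinFailure` (never raises) when a validity criterion or
    a geometric precondition fails.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need at least two 3D positions")

    # Step 2: principal axes; PC1 oriented top -> bottom.
    if params.pca_on_neuron_means:
        if neuron_ids is None:
            raise ValueError("pca_on_neuron_means requires neuron_ids")
        df = pd.DataFrame(pts, columns=["x", "y", "z"])
        df["nid"] = np.asarray(neuron_ids)
        pca_pts = df.groupby("nid", sort=True)[["x", "y", "z"]].mean().to_numpy()
        if len(pca_pts) < 2:
            return PinFailure(coord, "fewer than two neurons for axis PCA")
        mu, axes = _pca(pca_pts)
    else:
        mu, axes = _pca(pts)
    pc1 = axes[0]

    hit_top = bounds.top.intersect(mu, pc1)
    hit_bot = bounds.bottom.intersect(mu, pc1)
    if hit_top is None or hit_bot is None:
        return PinFailure(coord, "column axis does not intersect a boundary surface")
    s_top = float(np.dot(hit_top - mu, pc1))
    s_bot = float(np.dot(hit_bot - mu, pc1))
    if s_top > s_bot:
        pc1 = -pc1
        s_top, s_bot = -s_top, -s_bot
        hit_top, hit_bot = bounds.top.intersect(mu, pc1), bounds.bottom.intersect(mu, pc1)

    # Step 3: drop lateral outliers at f_lat * RMS lateral distance.
    rel = pts - mu
    axial = rel @ pc1
    lateral = rel - axial[:, None] * pc1
    l_dist = np.linalg.norm(lateral, axis=1)
    sigma_lat = float(np.sqrt(np.mean(l_dist**2)))
    keep = l_dist < params.f_lat * sigma_lat if sigma_lat > 0 else np.ones(len(pts), bool)
    kept = pts[keep]
    if len(kept) < 2:
        return PinFailure(coord, "fewer than two points after outlier removal")

    # Step 4: normalized axial coordinate, -1 at the top surface, +1 at the bottom.
    span = s_bot - s_top
    t = -1.0 + 2.0 * ((kept - mu) @ pc1 - s_top) / span

    if params.apply_criteria and len(kept) < params.n_avg:
        return PinFailure(coord, f"only {len(kept)} points after outlier removal (< n_avg)")

    # Step 5: endpoints.
    order = np.argsort(t, kind="stable")
    if params.endpoint_mode == "split":
        sel_top = t < 0.1
        if sel_top.sum() < params.n_pc:
            sel_top = np.zeros(len(kept), bool)
            sel_top[order[: min(params.n_pc, len(kept))]] = True
        m_top, axes_top = _pca(kept[sel_top]) if sel_top.sum() >= 2 else (kept[sel_top][0], np.eye(3))
        r_top = bounds.top.intersect(m_top, axes_top[0])
        sel_bot = t > 0.2
        if sel_bot.sum() < params.n_pc:
            sel_bot = np.zeros(len(kept), bool)
            sel_bot[order[-min(params.n_pc, len(kept)):]] = True
        m_bot, axes_bot = _pca(kept[sel_bot]) if sel_bot.sum() >= 2 else (kept[sel_bot][0], np.eye(3))
        r_bottom = bounds.bottom.intersect(m_bot, axes_bot[0])
        if r_top is None or r_bottom is None:
            return PinFailure(coord, "endpoint axis does not intersect a boundary surface")
    else:
        r_top, r_bottom = hit_top, hit_bot
        if params.top_extrapolate_n is not None:
            k = min(params.top_extrapolate_n, len(kept))
            med = np.median(kept[order[:k]], axis=0)
            r_top = mu + float(np.dot(med - mu, pc1)) * pc1

    d_max = float(np.linalg.norm(np.asarray(r_top) - np.asarray(r_bottom))) / params.n_tang
    if d_max <= 0:
        return PinFailure(coord, "degenerate top-bottom distance")

    if params.apply_criteria:
        k5 = max(1, int(np.ceil(0.05 * len(kept))))
        top_mean = kept[order[:k5]].mean(axis=0)
        bot_mean = kept[order[-k5:]].mean(axis=0)
        if np.linalg.norm(top_mean - r_top) > d_max:
            return PinFailure(coord, "top endpoint too far from the extreme synapses")
        if np.linalg.norm(bot_mean - r_bottom) > d_max:
            return PinFailure(coord, "bottom endpoint too far from the extreme synapses")

    # Step 6: rank by t, moving-average smoothing.
    Lp = np.vstack([r_top, kept[order], r_bottom])
    L = np.vstack([r_top, _moving_average(Lp, params.n_avg)[1:-1], r_bottom])

    # Step 7: shortest sublist with gaps <= d_max.
    O = _shortest_sublist(L, d_max)
    if O is None:
        return PinFailure(coord, "no gap-bounded path from top to bottom")

    # Step 8: PCHIP over cumulative chord length, resampled uniformly.
    gaps = np.linalg.norm(np.diff(O, axis=0), axis=1)
    keep_rows = np.concatenate([[True], gaps > 1e-9])
    O = O[keep_rows]
    if len(O) < 2:
        return PinFailure(coord, "degenerate straightened path")
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(O, axis=0), axis=1))])
    s /= s[-1]
    u = np.linspace(0.0, 1.0, params.n_samp)
    points = np.column_stack([PchipInterpolator(s, O[:, d])(u) for d in range(3)])
    return Pin(coord=coord, points=points, region=params.region)


_AXIS_STEPS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def refine_pins(pins: dict[HexCoord, Pin | PinFailure | None],
                max_iter: int = 10) -> dict[HexCoord, Pin]:
    """Regularize pins from their neighbors and fill in missing coordinates.

    Each iteration (a) replaces every existing pin by its own first point
    plus the coordinate-wise median of the first-point-anchored offsets of
    all pins within hex distance 2, and (b) fills each missing coordinate
    from the coordinate-wise median of its 4 axis neighbors (±1 along one
    axial coordinate) or, failing that, of the 2 neighbors along a single
    axis.  Iteration stops when no pin is filled in; coordinates that never
    acquire donors remain missing.
    """
    current: dict[HexCoord, Pin] = {c: p for c, p in pins.items() if isinstance(p, Pin)}
    missing = {c for c, p in pins.items() if not isinstance(p, Pin)}
    if not current:
        raise ValueError("at least one pin is required")
    region = next(iter(current.values())).region

    for _ in range(max_iter):
        coords = sorted(current)
        regular: dict[HexCoord, Pin] = {}
        for a in coords:
            donors = [current[b].points - current[b].points[0]
                      for b in coords if a.distance(b) <= 2]
            med = np.median(np.stack(donors), axis=0)
            regular[a] = Pin(coord=a, points=current[a].points[0] + med, region=region)
        current = regular

        filled = []
        for a in sorted(missing):
            axis_nb = [HexCoord(a.p + dp, a.q + dq) for dp, dq in _AXIS_STEPS]
            donors = [current[b].points for b in axis_nb if b in current]
            if len(donors) < 4:
                pair_p = [b for b in axis_nb[:2] if b in current]
                pair_q = [b for b in axis_nb[2:] if b in current]
                if len(pair_p) == 2:
                    donors = [current[b].points for b in pair_p]
                elif len(pair_q) == 2:
                    donors = [current[b].points for b in pair_q]
                else:
                    continue
            current[a] = Pin(coord=a, points=np.median(np.stack(donors), axis=0), region=region)
            filled.append(a)
        missing -= set(filled)
        if not filled:
            break
    return current


def assign_to_columns(synapses: pd.DataFrame | Dataset,
                      pins: dict[HexCoord, Pin]) -> DepthAssignment:
    """Assign every synapse to the pin holding its globally nearest pin point.

    The depth index is that point's order along the pin; exact distance ties
    go to the lexicographically smaller (p, q, index).  Synapses outside the
    pins' region are reported as unassigned.
    """
    if not pins:
        raise ValueError("pins must be non-empty")
    syn = synapses.synapses if isinstance(synapses, Dataset) else synapses
    some = next(iter(pins.values()))
    region, n_samp = some.region, len(some.points)

    coords = sorted(pins)
    stack, labels = [], []
    for c in coords:
        stack.append(pins[c].points)
        labels.extend((c, k) for k in range(len(pins[c].points)))
    tree = cKDTree(np.vstack(stack))

    in_region = syn["region"] == region if region else np.ones(len(syn), bool)
    sids = syn.loc[in_region, "synapse_id"].to_numpy()
    pos = syn.loc[in_region, ["x", "y", "z"]].to_numpy(dtype=float)
    unassigned = syn.loc[~in_region, "synapse_id"].tolist()
    assignments: dict[str, tuple[HexCoord, int, float]] = {}
    if len(pos):
        k = min(2, tree.n)
        dist, idx = tree.query(pos, k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        for row in range(len(pos)):
            best = idx[row, 0]
            if k == 2 and abs(dist[row, 0] - dist[row, 1]) <= 1e-9:
                best = min(idx[row, 0], idx[row, 1])
            c, depth_idx = labels[best]
            assignments[sids[row]] = (c, depth_idx, depth_idx / (n_samp - 1))
    return DepthAssignment(assignments=assignments, unassigned=unassigned,
                           n_samp=n_samp, region=region)


def build_region_pins(ds: Dataset, columns: dict[str, HexCoord], params: PinParams,
                      refine: bool | None = None) -> dict[HexCoord, Pin]:
    """Group synapses by their neurons' column and build one pin per column.

    Neighbor regularization and fill-in run when the parameter set enforces
    the validity criteria (lobula / lobula plate mode), where failures are
    expected; with medulla parameters every column normally yields a pin and
    refinement is skipped unless requested.
    """
    region = params.region
    syn = ds.synapses[ds.synapses["region"] == region].sort_values("synapse_id")
    syn = syn[syn["neuron_id"].isin(columns)]
    bounds = ds.region_bounds[region]
    raw: dict[HexCoord, Pin | PinFailure | None] = {}
    for coord in sorted(set(columns.values())):
        nids = {n for n, c in columns.items() if c == coord}
        sub = syn[syn["neuron_id"].isin(nids)]
        pts = sub[["x", "y", "z"]].to_numpy(float)
        if len(pts) < 2:
            raw[coord] = None
            continue
        raw[coord] = build_pin(pts, bounds, params,
                               neuron_ids=sub["neuron_id"].to_numpy(), coord=coord)
    if refine is None:
        refine = params.apply_criteria
    if refine:
        return refine_pins(raw)
    return {c: p for c, p in raw.items() if isinstance(p, Pin)}


def pin_geometry(pin: Pin) -> tuple[float, float]:
    """(length in nm, straightness = end-to-end distance / length)."""
    pts = pin.points
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    if length <= 0:
        raise ValueError("degenerate zero-length pin")
    return length, float(np.linalg.norm(pts[-1] - pts[0]) / length)
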