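"""Trimming and spatial-coverage statistics.

Columnar neurons have a clear home column but sprinkle a few synapses into
neighboring columns, so raw column counts overestimate cell size.  The trim
rank is found on the median cumulative-fraction curve of per-column synapse
counts with an internal kneedle knee detector (concave increasing branch,
sensitivity S), with a cumulative-mass fallback when the knee captures too
little mass.  Coverage statistics per type and region: trimmed median cell
size, mean cells per occupied column (coverage factor), untrimmed columnar
completeness, and convex-hull area in column units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial._qhull import QhullError

from .data_model import Dataset, HexCoord
from .pins import DepthAssignment


@dataclass(frozen=True)
class TrimSpec:
    """Knee sensitivity and cumulative-mass fallback fractions."""

    S: float = 1.0
    fallback_low: float = 0.775
    fallback_high: float = 0.995

    def __post_init__(self):
        if not 0 < self.fallback_low < self.fallback_high <= 1:
            raise ValueError("need 0 < fallback_low < fallback_high <= 1")


@dataclass
class CumfracCurves:
    """Per-neuron cumulative synapse fractions by column rank, plus the
    across-neuron median curve with the point (0, 0) prepended."""

    per_neuron: dict[str, np.ndarray]
    median_ranks: np.ndarray
    median_values: np.ndarray


@dataclass
class ConvexAreaResult:
    area: float
    fallback: bool  # True when the hull degenerated and columns were counted


@dataclass
class CoverageSummary:
    type_label: str
    region: str
    cell_size: float
    coverage_factor: float
    columnar_completeness: float
    convex_area: float
    convex_area_fallback: bool
    n_cells: int


def cumfrac_curves(counts: dict[str, "dict[HexCoord, int] | pd.Series"]) -> CumfracCurves:
    """Cumulative fraction of each neuron's synapses by descending column rank.

    The median curve pads ragged neurons with 1.0 beyond their last rank
    (their cumulative fraction is 1 from there on by definition).
    """
    per_neuron = {}
    for nid, c in counts.items():
        vals = np.sort(np.asarray(list(c.values()) if isinstance(c, dict) else c, dtype=float))[::-1]
        if vals.sum() <= 0:
            raise ValueError(f"neuron {nid!r} has no synapses")
        per_neuron[nid] = np.cumsum(vals) / vals.sum()
    max_len = max(len(v) for v in per_neuron.values())
    padded = np.ones((len(per_neuron), max_len))
    for i, v in enumerate(per_neuron.values()):
        padded[i, : len(v)] = v
    median = np.median(padded, axis=0)
    return CumfracCurves(
        per_neuron=per_neuron,
        median_ranks=np.arange(0, max_len + 1, dtype=float),
        median_values=np.concatenate([[0.0], median]),
    )


def detect_knee(values: np.ndarray, x: np.ndarray | None = None,
                S: float = 1.0) -> float | None:
    """Kneedle knee of a concave, increasing curve; None if there is none.

    Both axes are min-max normalized, the difference curve d = y - x is
    formed, and a local maximum of d is a knee if d falls below its
    sensitivity threshold d_max - S/(n-1) before the next local maximum.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 3:
        return None
    x = np.arange(n, dtype=float) if x is None else np.asarray(x, dtype=float)
    xs = (x - x.min()) / (x.max() - x.min())
    ys = (y - y.min()) / (y.max() - y.min()) if y.max() > y.min() else np.zeros(n)
    d = ys - xs

    lmx = [i for i in range(1, n - 1) if d[i] > d[i - 1] and d[i] >= d[i + 1]]
    lmx_set = set(lmx)
    for i in lmx:
        threshold = d[i] - S * float(np.mean(np.diff(xs)))
        for j in range(i + 1, n):
            if j in lmx_set:
                break
            if d[j] < threshold:
                return float(x[i])
    return None


def trim_rank(curves: CumfracCurves, spec: TrimSpec = TrimSpec()) -> int:
    """Trim rank from the knee of the median curve, with mass fallback.

    If no knee exists, or the median cumulative fraction at the knee is
    below ``fallback_low``, the rank becomes the first one reaching
    ``fallback_high`` (or the last rank if never reached).
    """
    ranks, values = curves.median_ranks, curves.median_values
    knee = detect_knee(values, x=ranks, S=spec.S)
    if knee is not None:
        rank_star = int(round(knee))
        if rank_star >= 1 and values[rank_star] >= spec.fallback_low:
            return rank_star
    reached = np.nonzero(values >= spec.fallback_high)[0]
    return int(ranks[reached[0]]) if len(reached) else int(ranks[-1])


def trim_neuron(counts: "dict[HexCoord, int] | pd.Series", rank_star: int) -> set:
    """Columns retained after trimming at rank ``rank_star``.

    The threshold is the synapse count of the neuron's rank-``rank_star``
    column; columns with a count >= that threshold are retained, so ties at
    the threshold survive even beyond the rank.  A rank beyond the column
    count retains everything.
    """
    if rank_star < 1:
        raise ValueError("rank_star must be >= 1")
    items = list(counts.items())
    if rank_star >= len(items):
        return {c for c, _ in items}
    sorted_counts = sorted((v for _, v in items), reverse=True)
    threshold = sorted_counts[rank_star - 1]
    return {c for c, v in items if v >= threshold}


def per_neuron_column_counts(assign: DepthAssignment, ds: Dataset,
                             neuron_ids: list[str]) -> dict[str, dict[HexCoord, int]]:
    """Per-neuron synapse counts by column (summed over depth)."""
    frame = assign.to_frame()
    syn = ds.synapses[ds.synapses["neuron_id"].isin(set(neuron_ids))]
    merged = syn.merge(frame, on="synapse_id", how="inner")
    out: dict[str, dict[HexCoord, int]] = {}
    for (nid, p, q), grp in merged.groupby(["neuron_id", "coord_p", "coord_q"]):
        out.setdefault(nid, {})[HexCoord(int(p), int(q))] = len(grp)
    return out


def convex_area(coords: "set[HexCoord] | list[HexCoord]") -> ConvexAreaResult:
    """Convex-hull area of hexagonal coordinates, in column units.

    Axial coordinates map to Cartesian at unit lattice pitch; the hull area
    is divided by the per-column footprint (sqrt(3)/2).  Degenerate sets
    (<= 2 coordinates or collinear) fall back to the column count, flagged.
    """
    coords = sorted(set(coords))
    if not coords:
        raise ValueError("empty coordinate set")
    if len(coords) <= 2:
        return ConvexAreaResult(area=float(len(coords)), fallback=True)
    pts = np.array([c.to_xy() for c in coords])
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return ConvexAreaResult(area=float(len(coords)), fallback=True)
    return ConvexAreaResult(area=float(hull.volume / (np.sqrt(3.0) / 2.0)), fallback=False)


def coverage_summary(trimmed: dict[str, set], untrimmed: dict[str, set],
                     region_columns: "set[HexCoord] | list[HexCoord]",
                     type_label: str = "", region: str = "") -> CoverageSummary:
    """Coverage statistics of one type in one region.

    cell_size: median trimmed column count per cell; coverage_factor: mean
    number of cells contributing (trimmed) synapses to an occupied column;
    columnar_completeness: fraction of region columns occupied before
    trimming; convex_area: hull area of the untrimmed occupied coordinates.
    """
    if not trimmed:
        raise ValueError("zero cells")
    region_columns = set(region_columns)
    cell_size = float(np.median([len(s) for s in trimmed.values()]))
    occupied: dict[HexCoord, int] = {}
    for s in trimmed.values():
        for c in s:
            occupied[c] = occupied.get(c, 0) + 1
    coverage_factor = float(np.mean(list(occupied.values()))) if occupied else 0.0
    union_raw = set().union(*untrimmed.values()) if untrimmed else set()
    completeness = len(union_raw & region_columns) / len(region_columns)
    hull = convex_area(union_raw) if union_raw else ConvexAreaResult(0.0, True)
    return CoverageSummary(
        type_label=type_label, region=region,
        cell_size=cell_size, coverage_factor=coverage_factor,
        columnar_completeness=completeness,
        convex_area=hull.area, convex_area_fallback=hull.fallback,
        n_cells=len(trimmed),
    )


def type_coverage(assign: DepthAssignment, ds: Dataset, type_label: str,
                  region_columns: "set[HexCoord] | list[HexCoord]",
                  spec: TrimSpec = TrimSpec(), region: str = "") -> CoverageSummary:
    """End-to-end coverage summary for one type: per-neuron column counts,
    median cumulative-fraction trim rank, per-neuron trimming, statistics."""
    cells = ds.neurons.loc[ds.neurons["type"] == type_label, "neuron_id"].tolist()
    counts = per_neuron_column_counts(assign, ds, cells)
    if not counts:
        raise ValueError(f"type {type_label!r} has no assigned synapses")
    curves = cumfrac_curves(counts)
    rank_star = trim_rank(curves, spec)
    trimmed = {nid: trim_neuron(c, rank_star) for nid, c in counts.items()}
    untrimmed = {nid: set(c) for nid, c in counts.items()}
    return coverage_summary(trimmed, untrimmed, region_columns,
                            type_label=type_label, region=region or assign.region)
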