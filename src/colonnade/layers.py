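"""Depth distributions and layer boundaries.

Layers are depth intervals shared across all pins of a region.  Each
boundary is the cutoff of a peak in the 1D synapse-depth distribution of a
marker cell type; peaks are delimited by the threshold at which a chosen
fraction of the distribution's mass lies above (``frac_peaks``), with
cutoffs at least 3 depth bins apart.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Dataset
from .pins import DepthAssignment

#: Per-region peak-mass fraction defaults.
FRAC_PEAKS_DEFAULTS = {"ME": 0.85, "LO": 0.80, "LOP": 0.75}


@dataclass
class DepthProfile:
    """Mean per-depth-bin synapse counts of a cell type, pre/post separately.

    Depth bins are the pin's sample points subsampled by a factor of 2
    (even indices kept), so the bin count is ceil(n_samp / 2).
    """

    type_label: str
    region: str
    bins: int
    pre_counts: np.ndarray
    post_counts: np.ndarray
    pre_smoothed: np.ndarray
    post_smoothed: np.ndarray


@dataclass(frozen=True)
class MarkerSpec:
    """One layer-boundary marker: a type's pre/post peak and cutoff side."""

    type_label: str
    direction: str  # "pre" | "post"
    peak_index: int  # 0-based
    side: str  # "lower" | "upper"


@dataclass
class LayerBoundaries:
    region: str
    thresholds: list[float]
    provenance: list = field(default_factory=list)


def smooth_boxcar5(values: np.ndarray) -> np.ndarray:
    """Order-1, window-5 Savitzky-Golay smoothing (a centered 5-point mean)
    with symmetric end reflection, which conserves total mass exactly."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return v.copy()
    pad = min(2, len(v) - 1)
    padded = np.pad(v, pad, mode="symmetric")
    kernel = np.ones(2 * pad + 1) / (2 * pad + 1)
    return np.convolve(padded, kernel, mode="valid")


def _binned_counts(depth_indices: np.ndarray, nbins: int, pool: bool) -> np.ndarray:
    """Subsample depth indices by a factor of 2.

    Decimation (default) keeps synapses at even depth indices; pooling sums
    adjacent index pairs instead.
    """
    counts = np.zeros(nbins)
    if pool:
        binned = np.minimum(depth_indices // 2, nbins - 1)
        np.add.at(counts, binned, 1)
    else:
        even = depth_indices[depth_indices % 2 == 0]
        np.add.at(counts, even // 2, 1)
    return counts


def depth_profile(assign: DepthAssignment, ds: Dataset, type_label: str,
                  region: str, pool: bool = False) -> DepthProfile:
    """Per-depth-bin mean pre/post synapse counts across a type's cells."""
    cells = ds.neurons.loc[ds.neurons["type"] == type_label, "neuron_id"]
    if cells.empty:
        raise ValueError(f"unknown type {type_label!r}")
    nbins = math.ceil(assign.n_samp / 2)
    frame = assign.to_frame()
    syn = ds.synapses[ds.synapses["neuron_id"].isin(set(cells))]
    syn = syn[syn["region"] == region]
    merged = syn.merge(frame[["synapse_id", "depth_index"]], on="synapse_id", how="inner")

    n_cells = len(cells)
    pre = np.zeros(nbins)
    post = np.zeros(nbins)
    for kind, acc in (("pre", pre), ("post", post)):
        idx = merged.loc[merged["kind"] == kind, "depth_index"].to_numpy(dtype=int)
        acc += _binned_counts(idx, nbins, pool)
    pre /= n_cells
    post /= n_cells
    return DepthProfile(type_label=type_label, region=region, bins=nbins,
                        pre_counts=pre, post_counts=post,
                        pre_smoothed=smooth_boxcar5(pre),
                        post_smoothed=smooth_boxcar5(post))


def peak_cutoffs(profile: np.ndarray, frac_peaks: float) -> list[tuple[int, int]]:
    """Peak (lower, upper) cutoff bins of a 1D depth distribution.

    The threshold syn_thre is the largest value t such that the summed mass
    of bins with value > t is at least ``frac_peaks`` of the total mass; a
    peak's lower cutoff is the first bin surpassing syn_thre and its upper
    cutoff the next crossing below, each at least 3 bins from the previous
    cutoff.  A peak still above threshold at the last bin is closed there.
    """
    v = np.asarray(profile, dtype=float)
    if np.any(v < 0):
        raise ValueError("profile must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero profile")
    candidates = np.unique(np.concatenate([[0.0], v]))
    syn_thre = 0.0
    for t in candidates:
        if v[v > t].sum() >= frac_peaks * total:
            syn_thre = float(t)
    above = v > syn_thre

    cutoffs: list[tuple[int, int]] = []
    i = 0
    prev_cut = -3  # allows a cutoff at bin 0
    n = len(v)
    while i < n:
        # lower cutoff: first crossing above, >= 3 bins from the previous cutoff
        while i < n and not (above[i] and i >= prev_cut + 3):
            i += 1
        if i == n:
            break
        lower = i
        j = lower + 3
        while j < n and above[j]:
            j += 1
        upper = min(j, n - 1)
        cutoffs.append((lower, upper))
        prev_cut = upper
        i = upper + 1
    return cutoffs


def layer_boundaries(profiles: dict, markers: list, region: str = "",
                     frac_peaks: float | None = None) -> LayerBoundaries:
    """Derive ordered layer boundaries from marker peak cutoffs.

    ``profiles`` maps (type_label, direction) -> 1D depth distribution.
    Each element of ``markers`` is a :class:`MarkerSpec` or a list of them;
    a list yields the mean of its members' thresholds (the two-marker
    averaging rule used where marker peaks leave gaps in depth).
    """
    if frac_peaks is None:
        frac_peaks = FRAC_PEAKS_DEFAULTS.get(region, 0.85)
    thresholds: list[float] = []
    provenance: list = []
    for spec_group in markers:
        group = spec_group if isinstance(spec_group, (list, tuple)) else [spec_group]
        values = []
        for m in group:
            prof = np.asarray(profiles[(m.type_label, m.direction)], dtype=float)
            peaks = peak_cutoffs(prof, frac_peaks)
            if not 0 <= m.peak_index < len(peaks):
                raise ValueError(
                    f"marker {m.type_label}/{m.direction}: peak index {m.peak_index} "
                    f"out of range ({len(peaks)} peaks found)")
            lower, upper = peaks[m.peak_index]
            bin_idx = lower if m.side == "lower" else upper
            values.append(bin_idx / (len(prof) - 1))
        thresholds.append(float(np.mean(values)))
        provenance.append(spec_group)
    order = np.argsort(thresholds, kind="stable")
    thresholds = [thresholds[i] for i in order]
    provenance = [provenance[i] for i in order]
    if any(b >= c for b, c in zip(thresholds, thresholds[1:])):
        raise ValueError("layer boundaries must be strictly increasing")
    return LayerBoundaries(region=region, thresholds=thresholds, provenance=provenance)


def depth_to_layer(depth: float, bounds: LayerBoundaries) -> int:
    """1-based index of the half-open layer interval [b_i, b_{i+1}) holding
    ``depth``; depth 1.0 maps to the last layer."""
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must be in [0, 1]")
    return bisect_right(bounds.thresholds, depth) + 1
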