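"""Inter-region connectivity weighting.

A neuron receiving inputs in several regions and sending outputs to several
regions contributes to each (source, target) pair the product of its output
count in the target and its input *fraction* in the source, so its
contributions to a fixed target sum to its downstream count there.
Contributions are summed over a neuron group into a region x region flow
matrix, whose entries are binned by their share of the ascending cumulative
sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Dataset

#: Cumulative-percentage bin edges: binary subdivision of the upper half.
DEFAULT_EDGES = (50.0, 75.0, 87.5, 93.75, 100.0)


@dataclass
class RegionFlowMatrix:
    values: pd.DataFrame  # sources x targets, non-negative weighted sums
    skipped_neurons: list[str] = field(default_factory=list)

    @property
    def sources(self):
        return list(self.values.index)

    @property
    def targets(self):
        return list(self.values.columns)


def neuron_contributions(upstream: dict[str, float],
                         downstream: dict[str, float]) -> dict[tuple[str, str], float]:
    """Per-neuron inter-region contributions by the product rule.

    contribution(A -> C) = downstream[C] * upstream[A] / sum(upstream); a
    neuron with no upstream connections contributes nothing.
    """
    total_up = sum(upstream.values())
    if total_up <= 0:
        return {}
    out = {}
    for src, u in upstream.items():
        frac = u / total_up
        for tgt, d in downstream.items():
            out[(src, tgt)] = d * frac
    return out


def _neuron_region_tallies(ds: Dataset, region_of=None):
    """Per-neuron upstream/downstream connection counts by region."""
    con = ds.connections.copy()
    if region_of is not None:
        con["region"] = [region_of(row) for row in con.itertuples(index=False)]
    up = con.groupby(["post", "region"])["weight"].sum()
    down = con.groupby(["pre", "region"])["weight"].sum()
    return up, down


def aggregate_flow(ds: Dataset, group_ids: list[str], sources: list[str],
                   targets: list[str], region_of=None,
                   denominator: str = "sources") -> RegionFlowMatrix:
    """Sum of the group's neuron contributions, restricted to the listed
    source and target regions.

    ``region_of`` optionally remaps each connection row to a finer region
    label (e.g. a layer).  ``denominator`` selects whether input fractions
    are taken over the listed source regions only ("sources") or over all
    regions with upstream connections ("all").  Neurons with no upstream
    connections in scope contribute nothing and are reported.
    """
    if denominator not in ("sources", "all"):
        raise ValueError("denominator must be 'sources' or 'all'")
    up, down = _neuron_region_tallies(ds, region_of)
    M = pd.DataFrame(0.0, index=list(sources), columns=list(targets))
    skipped = []
    for nid in sorted(group_ids):
        upstream = up.loc[nid].to_dict() if nid in up.index.get_level_values(0) else {}
        downstream = down.loc[nid].to_dict() if nid in down.index.get_level_values(0) else {}
        if denominator == "sources":
            upstream = {r: v for r, v in upstream.items() if r in set(sources)}
        downstream = {r: v for r, v in downstream.items() if r in set(targets)}
        contrib = neuron_contributions(upstream, downstream)
        if not contrib:
            skipped.append(nid)
            continue
        for (src, tgt), v in contrib.items():
            if src in M.index and tgt in M.columns:
                M.loc[src, tgt] += v
    return RegionFlowMatrix(values=M, skipped_neurons=skipped)


def cumulative_bins(M: "RegionFlowMatrix | pd.DataFrame",
                    edges: tuple[float, ...] = DEFAULT_EDGES) -> pd.DataFrame:
    """Label every matrix entry by its share of the ascending cumulative sum.

    Entries are ranked ascending (ties by row-major position), the running
    cumulative percentage of the total is computed, and each entry gets the
    first edge its cumulative share does not exceed.  Labels are invariant
    to global scaling; an all-zero matrix lands entirely in the lowest bin.
    """
    edges = tuple(float(e) for e in edges)
    if not all(b > a for a, b in zip(edges, edges[1:])) or not (0 < edges[0] and edges[-1] <= 100):
        raise ValueError("edges must be increasing within (0, 100]")
    values = M.values if isinstance(M, RegionFlowMatrix) else M
    flat = values.to_numpy(dtype=float).ravel()
    total = flat.sum()
    labels = np.full(flat.shape, edges[0])
    if total > 0:
        order = np.argsort(flat, kind="stable")
        cum = np.cumsum(flat[order]) / total * 100.0
        for pos, share in zip(order, cum):
            for e in edges:
                if share <= e + 1e-9:
                    labels[pos] = e
                    break
    return pd.DataFrame(labels.reshape(values.shape),
                        index=values.index, columns=values.columns)
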