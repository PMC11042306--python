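"""Connectivity-based cell typing.

Per-neuron feature vectors are the summed connection weights to every named
cell type, split by direction (input/output) and by side instance, within a
set of scope regions.  Cells are grouped by hierarchical clustering with
Ward linkage on L2-normalized rows — the Euclidean formulation of cosine
distance, which is the normalization that matters here — and scored against
annotations with confusion matrices, entropy-based completeness and
homogeneity, and top-k partner distinguishability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import completeness_score, homogeneity_score

from .data_model import Dataset

CONFUSION_CATEGORIES = ("one_to_one", "many_to_one", "one_to_many", "mixed", "outlier")


@dataclass
class ClusterResult:
    labels: dict[str, int]
    linkage: np.ndarray
    k: int
    excluded: list[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster")


@dataclass
class ConfusionMatrix:
    """Type x cluster neuron counts with the five-way cell categorization."""

    counts: pd.DataFrame  # rows: types (lexicographic); cols: picked cluster order
    categories: pd.DataFrame  # same shape; category name per non-zero cell, else ""


def _partner_label(type_label: str, instance: str) -> str:
    side = instance[-2:] if instance.endswith(("_R", "_L")) else ""
    return f"{type_label}{side}"


def connectivity_features(ds: Dataset, scope_regions: list[str],
                          neuron_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-neuron summed connection weights to each named type-instance.

    Partners with types ending in "_unclear" (or untyped) contribute
    nothing; "fragment" cells are summed into their parent type; only
    connections inside ``scope_regions`` count.  Columns are
    "<type><_side>:in" and "<type><_side>:out".
    """
    neu = ds.neurons
    rows = list(neuron_ids) if neuron_ids is not None else sorted(neu["neuron_id"])
    named = neu[(neu["type"] != "") & ~neu["type"].str.endswith("_unclear")]
    partner_label = {nid: _partner_label(t, inst) for nid, t, inst in
                     zip(named["neuron_id"], named["type"], named["instance"])}
    if not partner_label:
        raise ValueError("no named partner types in the dataset")

    con = ds.connections
    con = con[con["region"].isin(set(scope_regions))]
    entries: dict[tuple[str, str], float] = {}
    row_set = set(rows)
    for pre, post, w in zip(con["pre"], con["post"], con["weight"]):
        if post in row_set and pre in partner_label:
            key = (post, f"{partner_label[pre]}:in")
            entries[key] = entries.get(key, 0.0) + w
        if pre in row_set and post in partner_label:
            key = (pre, f"{partner_label[post]}:out")
            entries[key] = entries.get(key, 0.0) + w

    cols = sorted({c for _, c in entries})
    F = pd.DataFrame(0.0, index=rows, columns=cols)
    for (nid, col), w in entries.items():
        F.loc[nid, col] = w
    F.index.name = "neuron_id"
    return F


def type_connectivity(ds: Dataset, scope_regions: list[str]) -> pd.DataFrame:
    """Type-level aggregate of :func:`connectivity_features` (summed over cells)."""
    F = connectivity_features(ds, scope_regions)
    types = ds.neuron_types().reindex(F.index).fillna("")
    named = types[(types != "") & ~types.str.endswith("_unclear")]
    return F.loc[named.index].groupby(named).sum()


def cluster_cells(F: pd.DataFrame, k: int) -> ClusterResult:
    """Agglomerative clustering, cosine distance with Ward linkage, cut at k.

    Implemented as Ward on L2-normalized rows (the equivalent Euclidean
    formulation); rows with zero norm are excluded and reported.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = F.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    keep = norms > 0
    excluded = sorted(F.index[~keep])
    X = X[keep] / norms[keep][:, None]
    ids = list(F.index[keep])
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} clusterable rows")
    if len(ids) == 1:
        return ClusterResult(labels={ids[0]: 1}, linkage=np.empty((0, 4)), k=1,
                             excluded=excluded)
    Z = linkage(X, method="ward")
    flat = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(labels=dict(zip(ids, flat.tolist())), linkage=Z, k=k,
                         excluded=excluded)


def cluster_scores(types: dict[str, str], clusters: ClusterResult | dict[str, int]) -> tuple[float, float]:
    """(completeness, homogeneity) of a clustering against type annotations.

    Standard conditional-entropy definitions: completeness is 1 when each
    type sits inside a single cluster, homogeneity 1 when each cluster
    contains a single type.
    """
    labels = clusters.labels if isinstance(clusters, ClusterResult) else clusters
    ids = sorted(set(types) & set(labels))
    if not ids:
        raise ValueError("no common neurons between annotations and clustering")
    truth = [types[i] for i in ids]
    pred = [labels[i] for i in ids]
    return float(completeness_score(truth, pred)), float(homogeneity_score(truth, pred))


def _pick_cluster_order(counts: pd.DataFrame) -> list:
    """Greedy column ordering: per type (row order), pick clusters by
    descending count until each remaining cluster holds <= 5% of the type."""
    remaining = list(counts.columns)
    picked: list = []
    for t in counts.index:
        size = counts.loc[t].sum()
        if size == 0:
            continue
        while remaining:
            row = counts.loc[t, remaining]
            best = row.idxmax()
            if row[best] <= 0.05 * size:
                break
            picked.append(best)
            remaining.remove(best)
    picked.extend(remaining)
    return picked


def confusion(types: dict[str, str], clusters: ClusterResult | dict[str, int]) -> ConfusionMatrix:
    """Type x cluster confusion matrix with the five-way categorization.

    Each non-zero cell is categorized from the fraction of the type in the
    cluster (f_t) and the fraction of the cluster that is the type (f_c):
    one_to_one (f_t>=0.8 and f_c>=0.8), many_to_one (f_t>=0.8, f_c<0.8),
    one_to_many (0.1<=f_t<0.8, f_c>=0.8), mixed (0.1<=f_t<0.8 and
    0.1<=f_c<0.8), outlier (the rest).
    """
    labels = clusters.labels if isinstance(clusters, ClusterResult) else clusters
    ids = sorted(set(types) & set(labels))
    df = pd.DataFrame({"type": [types[i] for i in ids], "cluster": [labels[i] for i in ids]})
    counts = df.pivot_table(index="type", columns="cluster", aggfunc="size", fill_value=0)
    counts = counts.sort_index()
    counts = counts[_pick_cluster_order(counts)]

    type_sizes = counts.sum(axis=1)
    cluster_sizes = counts.sum(axis=0)
    cats = pd.DataFrame("", index=counts.index, columns=counts.columns, dtype=object)
    for t in counts.index:
        for c in counts.columns:
            n = counts.loc[t, c]
            if n == 0:
                continue
            f_t = n / type_sizes[t]
            f_c = n / cluster_sizes[c]
            if f_t >= 0.8 and f_c >= 0.8:
                cat = "one_to_one"
            elif f_t >= 0.8:
                cat = "many_to_one"
            elif f_t >= 0.1 and f_c >= 0.8:
                cat = "one_to_many"
            elif f_t >= 0.1 and f_c >= 0.1:
                cat = "mixed"
            else:
                cat = "outlier"
            cats.loc[t, c] = cat
    return ConfusionMatrix(counts=counts, categories=cats)


def topk_uniqueness(type_connectivity_table: pd.DataFrame, k: int = 5) -> float:
    """Fraction of types whose top-k strongest partner connections are unique.

    Partners are (partner label, direction) columns ranked by weight, ties
    broken by column label; only positive weights qualify.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tops = {}
    for t, row in type_connectivity_table.iterrows():
        pos = row[row > 0]
        ranked = sorted(pos.items(), key=lambda kv: (-kv[1], kv[0]))
        tops[t] = frozenset(label for label, _ in ranked[:k])
    values = list(tops.values())
    unique = sum(1 for s in values if values.count(s) == 1)
    return unique / len(values) if values else 0.0


def classify_group(tallies: dict[str, dict[str, float]],
                   optic_lobe_regions: tuple[str, ...] = ("LA", "ME", "LO", "LOP", "AME"),
                   ) -> tuple[str, list[str]]:
    """Classify a cell (or type) into OLIN/OLCN/VPN/VCN/other by the
    quantitative synapse-location rules.

    ``tallies`` maps direction ("in"/"out") to per-region connection counts.
    OLIN: >98% of both input and output connections in the optic lobe,
    single region; OLCN: the same across multiple regions; VPN: >10% of
    inputs in the optic lobe (outputs mostly central); VCN: the converse;
    otherwise "other".  Returns the group and the rules that fired.
    """
    ol = set(optic_lobe_regions)
    fracs, regions_used = {}, set()
    for direction in ("in", "out"):
        counts = tallies.get(direction, {})
        total = sum(counts.values())
        in_ol = sum(v for r, v in counts.items() if r in ol)
        fracs[direction] = in_ol / total if total > 0 else None
        regions_used |= {r for r, v in counts.items() if r in ol and v > 0}
    if fracs["in"] is None and fracs["out"] is None:
        return "unassigned", ["zero connections"]
    f_in = fracs["in"] if fracs["in"] is not None else 0.0
    f_out = fracs["out"] if fracs["out"] is not None else 0.0

    if f_in > 0.98 and f_out > 0.98:
        if len(regions_used) <= 1:
            return "OLIN", [">98% both directions in optic lobe", "single region"]
        return "OLCN", [">98% both directions in optic lobe", "multiple regions"]
    rules = []
    if f_in > 0.10:
        rules.append(">10% of inputs in optic lobe")
    if f_out > 0.10:
        rules.append(">10% of outputs in optic lobe")
    if f_in > 0.10 and f_out <= 0.10:
        return "VPN", rules
    if f_out > 0.10 and f_in <= 0.10:
        return "VCN", rules
    return "other", rules or ["below both 10% rules"]


def mosaic_projection(ds: Dataset, neuron_ids: list[str], region: str,
                      reference_synapses: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cell synapse centers of mass projected on a fixed 2D view.

    The view is the first two principal axes of a reference synapse set for
    the region (all of the region's synapses by default), so projections are
    comparable across candidate types.
    """
    syn = ds.synapses[ds.synapses["region"] == region]
    ref = (np.asarray(reference_synapses, float) if reference_synapses is not None
           else syn[["x", "y", "z"]].to_numpy(float))
    mu = ref.mean(axis=0)
    _, _, vt = np.linalg.svd(ref - mu, full_matrices=False)
    rows = []
    for nid in neuron_ids:
        pts = syn.loc[syn["neuron_id"] == nid, ["x", "y", "z"]].to_numpy(float)
        if len(pts) == 0:
            raise ValueError(f"neuron {nid!r} has no synapses in {region!r}")
        com = pts.mean(axis=0) - mu
        rows.append({"neuron_id": nid, "pc1": float(com @ vt[0]), "pc2": float(com @ vt[1])})
    return pd.DataFrame(rows).set_index("neuron_id")
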