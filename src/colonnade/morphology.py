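"""Morphology feature vectors from depth-resolved synapse and column counts.

Each neuron is described by four concatenated blocks over the depth bins of
one region (pin samples subsampled by a factor of 2): presynapse counts,
postsynapse counts, presynapse-innervated column counts and
postsynapse-innervated column counts.  The synapse blocks are rescaled by
one common factor per direction, N_size / N_syn (total innervated-column
count over total synapse count), which brings the two kinds of block to a
comparable scale without changing the ratio between depth bins; the column
blocks stay raw.  With the 121-sample pins of the medulla this yields
4 x 61 = 244 features.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .data_model import Dataset
from .pins import DepthAssignment

BLOCKS = ("pre_syn", "post_syn", "pre_col", "post_col")


def _block_columns(nbins: int) -> list[str]:
    return [f"{block}_{b:03d}" for block in BLOCKS for b in range(nbins)]


def morphology_features(assign: DepthAssignment, ds: Dataset,
                        neuron_ids: list[str], region: str,
                        pool: bool = False) -> pd.DataFrame:
    """Per-neuron morphology vectors of length 4 * ceil(n_samp / 2).

    Depth subsampling decimates to even depth indices by default; ``pool``
    sums adjacent index pairs instead.  Neurons without synapses in the
    region get a zero vector (their rescaling factor is undefined).
    """
    nbins = math.ceil(assign.n_samp / 2)
    frame = assign.to_frame()
    syn = ds.synapses[ds.synapses["neuron_id"].isin(set(neuron_ids))]
    if region:
        syn = syn[syn["region"] == region]
    merged = syn.merge(frame, on="synapse_id", how="inner")
    if pool:
        merged["bin"] = np.minimum(merged["depth_index"] // 2, nbins - 1)
    else:
        merged = merged[merged["depth_index"] % 2 == 0]
        merged["bin"] = merged["depth_index"] // 2

    out = pd.DataFrame(0.0, index=list(neuron_ids), columns=_block_columns(nbins))
    out.index.name = "neuron_id"
    for nid, grp in merged.groupby("neuron_id"):
        vec = {}
        for kind, syn_block, col_block in (("pre", "pre_syn", "pre_col"),
                                           ("post", "post_syn", "post_col")):
            g = grp[grp["kind"] == kind]
            syn_counts = np.zeros(nbins)
            col_counts = np.zeros(nbins)
            if len(g):
                np.add.at(syn_counts, g["bin"].to_numpy(int), 1)
                per_bin_cols = g.groupby("bin").apply(
                    lambda d: d[["coord_p", "coord_q"]].drop_duplicates().shape[0],
                    include_groups=False)
                col_counts[per_bin_cols.index.to_numpy(int)] = per_bin_cols.to_numpy()
            n_syn, n_size = syn_counts.sum(), col_counts.sum()
            factor = n_size / n_syn if n_syn > 0 else 0.0
            vec[syn_block] = syn_counts * factor
            vec[col_block] = col_counts
        out.loc[nid] = np.concatenate([vec[b] for b in BLOCKS])
    return out


def cluster_morphology(F: pd.DataFrame, k: int):
    """Ward-linkage hierarchical clustering of raw morphology vectors under
    the Euclidean metric, flat cut at k clusters."""
    from scipy.cluster.hierarchy import fcluster, linkage

    from .celltyping import ClusterResult

    if k < 1:
        raise ValueError("k must be >= 1")
    X = F.to_numpy(dtype=float)
    ids = list(F.index)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} rows")
    Z = linkage(X, method="ward")
    flat = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(labels=dict(zip(ids, flat.tolist())), linkage=Z, k=k)
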