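"""Connectivity features, clustering, scores against a direct entropy
oracle, confusion taxonomy, top-k distinguishability and group rules."""

import numpy as np
import pandas as pd
import pytest

from colonnade.celltyping import (
    classify_group,
    cluster_cells,
    cluster_scores,
    confusion,
    connectivity_features,
    mosaic_projection,
    topk_uniqueness,
    type_connectivity,
)
from colonnade.synthetic import SyntheticConfig, simulate_dataset

from conftest import tiny_dataset, probs_for


def _feature_fixture():
    neu = [
        {"neuron_id": "n1", "type": "A", "instance": "A_R", "group": "OLIN", "status": "traced"},
        {"neuron_id": "x1", "type": "X", "instance": "X_R", "group": "OLIN", "status": "traced"},
        {"neuron_id": "u1", "type": "Tm1_unclear", "instance": "Tm1_unclear_R",
         "group": "OLIN", "status": "unclear"},
        {"neuron_id": "f1", "type": "X", "instance": "X_fragment_R", "group": "OLIN",
         "status": "fragment"},
    ]
    con = [
        {"pre": "x1", "post": "n1", "weight": 5, "region": "ME"},
        {"pre": "u1", "post": "n1", "weight": 7, "region": "ME"},   # unclear: excluded
        {"pre": "f1", "post": "n1", "weight": 2, "region": "ME"},   # fragment: merged
        {"pre": "x1", "post": "n1", "weight": 9, "region": "LO"},   # out of scope
    ]
    return tiny_dataset([], neu, con, regions=("ME", "LO"))


def test_features_sum_named_partners_within_scope():
    F = connectivity_features(_feature_fixture(), scope_regions=["ME"], neuron_ids=["n1"])
    assert F.loc["n1", "X_R:in"] == 7  # 5 from x1 + 2 from the fragment
    assert not any(c.startswith("Tm1_unclear") for c in F.columns)
    nonzero = F.loc["n1"][F.loc["n1"] > 0]
    assert list(nonzero.index) == ["X_R:in"]


def test_block_features_match_poisson_expectation():
    names = ["A", "B", "C", "D"]
    B = pd.DataFrame(0.0, index=names, columns=names)
    B.loc["A", "C"] = 8.0
    cfg = SyntheticConfig(lattice_radius=2, type_names=names, type_block_matrix=B,
                          seed=21, stray_rate=0.0)
    ds, truth = simulate_dataset(cfg)
    a_cells = [n for n, t in truth.true_type.items() if t == "A"]
    F = connectivity_features(ds, scope_regions=["ME"], neuron_ids=a_cells)
    out = F["C_R:out"].to_numpy()
    se = np.sqrt(8.0 / len(out))
    assert abs(out.mean() - 8.0) < 3 * se


def test_orthogonal_blocks_split_perfectly_and_duplicates_cocluster():
    F = pd.DataFrame(
        [[10, 0], [11, 0], [10, 0], [0, 9], [0, 8], [0, 9]],
        index=[f"n{i}" for i in range(6)], columns=["X:in", "Y:in"], dtype=float)
    res = cluster_cells(F, k=2)
    left = {res.labels[f"n{i}"] for i in range(3)}
    right = {res.labels[f"n{i}"] for i in range(3, 6)}
    assert len(left) == 1 and len(right) == 1 and left != right
    assert res.labels["n0"] == res.labels["n2"]  # duplicated rows


def test_clustering_invariant_to_per_row_scaling():
    rng = np.random.default_rng(3)
    F = pd.DataFrame(rng.gamma(2, 1, (12, 5)), index=[f"n{i}" for i in range(12)])
    scaled = F.mul(rng.uniform(0.1, 30, 12), axis=0)
    assert cluster_cells(F, 3).labels == cluster_cells(scaled, 3).labels


def test_zero_rows_excluded_and_reported():
    F = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["a", "b"])
    res = cluster_cells(F, k=1)
    assert res.excluded == ["b"]


def _entropy(labels):
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return -np.sum(p * np.log(p))


def _scores_oracle(truth, pred):
    """Direct conditional-entropy computation of completeness/homogeneity."""
    truth, pred = np.asarray(truth), np.asarray(pred)
    n = len(truth)
    h_t, h_p = _entropy(truth), _entropy(pred)
    joint = {}
    for t, p in zip(truth, pred):
        joint[(t, p)] = joint.get((t, p), 0) + 1
    h_t_given_p = h_p_given_t = 0.0
    for (t, p), c in joint.items():
        pj = c / n
        pt = np.sum(truth == t) / n
        pp = np.sum(pred == p) / n
        h_t_given_p -= pj * np.log(pj / pp)
        h_p_given_t -= pj * np.log(pj / pt)
    homogeneity = 1.0 if h_t == 0 else 1.0 - h_t_given_p / h_t
    completeness = 1.0 if h_p == 0 else 1.0 - h_p_given_t / h_p
    return completeness, homogeneity


def test_scores_extremes_and_entropy_oracle():
    perfect = {f"n{i}": i % 3 for i in range(9)}
    types = {f"n{i}": f"T{i % 3}" for i in range(9)}
    assert cluster_scores(types, perfect) == (pytest.approx(1.0), pytest.approx(1.0))
    one_cluster = {f"n{i}": 0 for i in range(8)}
    two_types = {f"n{i}": f"T{i % 2}" for i in range(8)}
    c, h = cluster_scores(two_types, one_cluster)
    assert c == pytest.approx(1.0) and h == pytest.approx(0.0)
    rng = np.random.default_rng(5)
    for _ in range(10):
        ids = [f"n{i}" for i in range(60)]
        t = {i: f"T{v}" for i, v in zip(ids, rng.integers(0, 4, 60))}
        p = {i: int(v) for i, v in zip(ids, rng.integers(0, 6, 60))}
        got = cluster_scores(t, p)
        want = _scores_oracle([t[i] for i in ids], [p[i] for i in ids])
        assert got == (pytest.approx(want[0]), pytest.approx(want[1]))


def test_confusion_categories_match_threshold_rules():
    # pure 1-to-1: 10 cells of A alone in cluster 1
    types = {f"a{i}": "A" for i in range(10)}
    clusters = {f"a{i}": 1 for i in range(10)}
    cm = confusion(types, clusters)
    assert cm.counts.loc["A"].iloc[0] == 10
    assert cm.categories.loc["A"].iloc[0] == "one_to_one"

    # type split 6/4 into two pure clusters -> both one_to_many
    types = {f"a{i}": "A" for i in range(10)}
    clusters = {f"a{i}": (1 if i < 6 else 2) for i in range(10)}
    cm = confusion(types, clusters)
    assert set(cm.categories.loc["A"][cm.counts.loc["A"] > 0]) == {"one_to_many"}

    # cluster containing 5 A + 5 B, each type fully inside -> both many_to_one
    types = {**{f"a{i}": "A" for i in range(5)}, **{f"b{i}": "B" for i in range(5)}}
    clusters = {n: 1 for n in types}
    cm = confusion(types, clusters)
    assert cm.categories.loc["A"].iloc[0] == "many_to_one"
    assert cm.categories.loc["B"].iloc[0] == "many_to_one"


def test_confusion_partition_and_row_sums():
    rng = np.random.default_rng(8)
    ids = [f"n{i}" for i in range(100)]
    types = {i: f"T{v}" for i, v in zip(ids, rng.integers(0, 5, 100))}
    clusters = {i: int(v) for i, v in zip(ids, rng.integers(0, 7, 100))}
    cm = confusion(types, clusters)
    nonzero = cm.counts.to_numpy() > 0
    labeled = cm.categories.to_numpy() != ""
    assert np.array_equal(nonzero, labeled)  # categories partition non-zero cells
    sizes = pd.Series(types).value_counts()
    for t in cm.counts.index:
        assert cm.counts.loc[t].sum() == sizes[t]


def test_confusion_ordering_stable_under_input_permutation():
    rng = np.random.default_rng(9)
    ids = [f"n{i}" for i in range(60)]
    types = {i: f"T{v}" for i, v in zip(ids, rng.integers(0, 4, 60))}
    clusters = {i: int(v) for i, v in zip(ids, rng.integers(0, 5, 60))}
    cm1 = confusion(types, clusters)
    perm = list(reversed(ids))
    cm2 = confusion({i: types[i] for i in perm}, {i: clusters[i] for i in perm})
    pd.testing.assert_frame_equal(cm1.counts, cm2.counts)


def test_topk_uniqueness_cases():
    T = pd.DataFrame(0.0, index=["A", "B"], columns=["x:in", "y:in"])
    T.loc["A", "x:in"] = 5
    T.loc["B", "y:in"] = 5
    assert topk_uniqueness(T, k=1) == 1.0
    T.loc["B"] = T.loc["A"]
    assert topk_uniqueness(T, k=1) == 0.0
    assert topk_uniqueness(T, k=5) == 0.0

    # 10 types, one duplicated block pair -> 0.8 at k=5
    cols = [f"p{i}:out" for i in range(10)]
    M = pd.DataFrame(0.0, index=[f"T{i}" for i in range(10)], columns=cols)
    for i in range(10):
        for j in range(5):
            M.iloc[i, (i + j) % 10] = 10 - j
    M.loc["T9"] = M.loc["T0"]  # duplicate one pair
    assert topk_uniqueness(M, k=5) == pytest.approx(0.8)


def test_type_connectivity_aggregates_cells(small_sim):
    _, ds, truth = small_sim
    T = type_connectivity(ds, scope_regions=ds.regions)
    assert set(T.index) == set(truth.true_nt)
    # every planted type has a distinct top-5 partner set at high contrast
    assert topk_uniqueness(T, k=5) == 1.0


@pytest.mark.parametrize("tallies,expected", [
    ({"in": {"ME": 50}, "out": {"ME": 40}}, "OLIN"),
    ({"in": {"ME": 60, "LO": 39, "PLP": 1}, "out": {"ME": 99, "PLP": 1}}, "OLCN"),
    ({"in": {"ME": 60, "PLP": 40}, "out": {"PLP": 95, "ME": 5}}, "VPN"),
    ({"in": {"PLP": 95, "ME": 5}, "out": {"ME": 60, "PLP": 40}}, "VCN"),
    ({"in": {"PLP": 95, "ME": 5}, "out": {"PLP": 95, "ME": 5}}, "other"),
    ({}, "unassigned"),
])
def test_group_classification_rules(tallies, expected):
    group, rules = classify_group(tallies)
    assert group == expected
    assert rules


def test_mosaic_projection_line_collapses_to_first_axis():
    syn, neu = [], []
    for i in range(12):
        nid = f"n{i}"
        neu.append({"neuron_id": nid, "type": "A", "instance": "A_R", "group": "OLIN",
                    "status": "traced"})
        syn.append({"synapse_id": f"s{i}", "neuron_id": nid, "kind": "pre",
                    "x": 1000.0 * i, "y": 2000.0 * i, "z": 500.0 * i, "region": "ME",
                    "partner_synapse_id": "", **probs_for("p_ach")})
    ds = tiny_dataset(syn, neu, [])
    proj = mosaic_projection(ds, [f"n{i}" for i in range(12)], region="ME")
    assert np.all(np.abs(proj["pc2"]) < 1e-6)
    single = mosaic_projection(ds, ["n3"], region="ME")
    assert len(single) == 1


def test_interleaved_mosaics_both_span_the_lattice(small_sim):
    """With a lateral reference view, each planted mosaic covers the lattice
    extent, and within-type neighbor spacing exceeds the pooled spacing."""
    _, ds, truth = small_sim
    cells = [n for n, t in truth.true_type.items() if t in ("Pt00", "Pt01")]
    # reference set in the lattice plane: region synapses with depth flattened
    ref = ds.synapses.loc[ds.synapses["region"] == "ME", ["x", "y", "z"]].to_numpy(float)
    ref = ref * np.array([1.0, 1.0, 0.0])
    proj = mosaic_projection(ds, cells, region="ME", reference_synapses=ref)
    pooled = proj[["pc1", "pc2"]].to_numpy()

    def min_nn(P):
        d = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)

    for t in ("Pt00", "Pt01"):
        sub = proj.loc[[n for n in cells if truth.true_type[n] == t]]
        span = sub["pc1"].max() - sub["pc1"].min()
        assert span > 0.8 * (proj["pc1"].max() - proj["pc1"].min())
        within = min_nn(sub[["pc1", "pc2"]].to_numpy())
        assert np.median(within) > np.median(min_nn(pooled))
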