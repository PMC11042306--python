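"""Paired-connection coordinate voting, bipartite matching against a
brute-force oracle, distance pruning and column groups."""

import itertools

import numpy as np
import pandas as pd
import pytest

from colonnade.assignment import (
    assign_by_paired_connections,
    build_column_groups,
    match_bipartite,
    prune_by_distance,
    MatchResult,
)
from colonnade.data_model import HexCoord
from colonnade.pins import build_region_pins, PinParams
from colonnade.synthetic import (
    SyntheticConfig,
    neuron_assignment_accuracy,
    simulate_dataset,
)

from conftest import tiny_dataset, probs_for


def _voting_dataset(votes_a, votes_b):
    """Cell 'target' with votes_a paired synapses near axis (0,0) and
    votes_b near axis (0,1)."""
    syn, con = [], []
    sid = 0
    for n, x in ((votes_a, 0.0), (votes_b, 5000.0)):
        for _ in range(n):
            sid += 1
            syn.append({"synapse_id": f"p{sid}", "neuron_id": "target", "kind": "pre",
                        "x": x, "y": 0, "z": 100.0 * sid, "region": "ME",
                        "partner_synapse_id": f"q{sid}", **probs_for("p_ach")})
            syn.append({"synapse_id": f"q{sid}", "neuron_id": "partner", "kind": "post",
                        "x": x, "y": 0, "z": 100.0 * sid, "region": "ME",
                        "partner_synapse_id": f"p{sid}",
                        **{c: np.nan for c in probs_for("p_ach")}})
    con.append({"pre": "target", "post": "partner", "weight": sid, "region": "ME"})
    neu = [{"neuron_id": "target", "type": "A", "instance": "A_R", "group": "OLIN",
            "status": "traced"},
           {"neuron_id": "partner", "type": "B", "instance": "B_R", "group": "OLIN",
            "status": "traced"}]
    return tiny_dataset(syn, neu, con)


AXES = {HexCoord(0, 0): np.array([[0.0, 0.0, z] for z in np.linspace(0, 30000, 11)]),
        HexCoord(0, 1): np.array([[5000.0, 0.0, z] for z in np.linspace(0, 30000, 11)])}


def test_mode_rule_assigns_majority_coordinate():
    ds = _voting_dataset(10, 2)
    res = assign_by_paired_connections(ds, AXES, [("A", "B")])
    assert res.assigned["target"] == HexCoord(0, 0)
    assert not res.flagged


def test_exact_vote_tie_is_flagged_not_assigned():
    ds = _voting_dataset(5, 5)
    res = assign_by_paired_connections(ds, AXES, [("A", "B")])
    assert "target" not in res.assigned
    assert res.flagged["target"] == "vote tie"


def test_cell_with_no_qualifying_synapses_reported_unassigned():
    ds = _voting_dataset(3, 0)
    res = assign_by_paired_connections(ds, AXES, [("A", "C")])
    assert res.unassigned == ["target"]


def test_zero_jitter_dataset_recovers_all_home_columns():
    cfg = SyntheticConfig(lattice_radius=2, n_types=6, seed=13,
                          lateral_jitter_sd=0.0, stray_rate=0.0)
    ds, truth = simulate_dataset(cfg)
    axes = {c: pts for c, pts in truth.true_pins.items()}
    pairs = [(f"Pt{i:02d}", f"Pt{(i + 1) % 6:02d}") for i in range(6)] + \
            [(f"Pt{i:02d}", f"Pt{(i + 2) % 6:02d}") for i in range(6)]
    res = assign_by_paired_connections(ds, axes, pairs)
    assert not res.unassigned
    assert neuron_assignment_accuracy(res.assigned, truth) == 1.0


def _brute_force_best(C: np.ndarray):
    """All optimal assignments of the row-normalized matrix, by enumeration."""
    N = C / C.sum(axis=1, keepdims=True)
    n = N.shape[0]
    best, best_perms = -1.0, []
    for perm in itertools.permutations(range(n)):
        w = sum(N[i, perm[i]] for i in range(n))
        if w > best + 1e-12:
            best, best_perms = w, [perm]
        elif abs(w - best) <= 1e-12:
            best_perms.append(perm)
    return best, best_perms


def test_two_by_two_worked_example():
    res = match_bipartite(np.array([[9.0, 1.0], [2.0, 8.0]]))
    assert res.pairs == {"a0": "c0", "a1": "c1"}
    assert res.total_weight == pytest.approx(0.9 + 0.8)


def test_diagonal_matrix_matches_identity():
    res = match_bipartite(np.diag([3.0, 5.0, 2.0]))
    assert res.pairs == {"a0": "c0", "a1": "c1", "a2": "c2"}


def test_matching_equals_exhaustive_search_on_random_matrices():
    rng = np.random.default_rng(17)
    for _ in range(25):
        C = rng.integers(1, 10, size=(6, 6)).astype(float)
        best, best_perms = _brute_force_best(C)
        res = match_bipartite(C)
        assert res.total_weight == pytest.approx(best)
        # lexicographically smallest optimal pairing
        lex = min(best_perms)
        expected = {f"a{i}": f"c{j}" for i, j in enumerate(lex)}
        assert res.pairs == expected


def test_row_scaling_leaves_matching_unchanged():
    rng = np.random.default_rng(23)
    C = rng.integers(1, 10, size=(5, 5)).astype(float)
    scaled = C * rng.uniform(0.5, 20.0, size=(5, 1))
    assert match_bipartite(C).pairs == match_bipartite(scaled).pairs


def test_rectangular_matrix_leaves_surplus_unmatched():
    C = pd.DataFrame([[5.0, 1.0], [1.0, 5.0], [3.0, 3.0]],
                     index=["a0", "a1", "a2"], columns=["c0", "c1"])
    res = match_bipartite(C)
    assert len(res.pairs) == 2
    assert len([u for u in res.unmatched if u.startswith("a")]) == 1


def test_zero_rows_excluded_and_reported():
    C = pd.DataFrame([[0.0, 0.0], [1.0, 3.0]], index=["a0", "a1"], columns=["c0", "c1"])
    res = match_bipartite(C)
    assert res.zero_rows == ["a0"]
    assert "a0" not in res.pairs


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        match_bipartite(np.zeros((0, 0)))


def _pruning_dataset(offset_nm):
    """Anchor 'm' connects to candidate 't' whose postsynapses sit offset_nm away."""
    syn = [
        {"synapse_id": "p1", "neuron_id": "m", "kind": "pre", "x": 0, "y": 0, "z": 0,
         "region": "ME", "partner_synapse_id": "q1", **probs_for("p_ach")},
        {"synapse_id": "q1", "neuron_id": "t", "kind": "post", "x": offset_nm, "y": 0,
         "z": 0, "region": "ME", "partner_synapse_id": "p1",
         **{c: np.nan for c in probs_for("p_ach")}},
    ]
    neu = [{"neuron_id": "m", "type": "Anchor", "instance": "Anchor_R", "group": "OLIN",
            "status": "traced"},
           {"neuron_id": "t", "type": "Role", "instance": "Role_R", "group": "OLIN",
            "status": "traced"}]
    con = [{"pre": "m", "post": "t", "weight": 1, "region": "ME"}]
    return tiny_dataset(syn, neu, con)


def test_prune_keeps_close_pairs_and_rejects_distant_ones():
    match = MatchResult(pairs={"m": "t"})
    near = prune_by_distance(match, _pruning_dataset(0.0), threshold_nm=8000)
    assert near.pairs == {"m": "t"}
    far = prune_by_distance(match, _pruning_dataset(9000.0), threshold_nm=8000)
    assert far.pairs == {}
    assert far.rejected[0][0] == ("m", "t")
    assert far.rejected[0][1] == pytest.approx(9000.0)


def test_infinite_threshold_is_identity_and_pruning_never_adds_pairs():
    match = MatchResult(pairs={"m": "t"})
    ds = _pruning_dataset(9000.0)
    same = prune_by_distance(match, ds, threshold_nm=float("inf"))
    assert same.pairs == match.pairs
    pruned = prune_by_distance(match, ds, threshold_nm=100.0)
    assert set(pruned.pairs) <= set(match.pairs)


def test_column_groups_complete_flag():
    matches = {f"role{r}": MatchResult(pairs={"m1": f"t{r}"}) for r in range(4)}
    matches["role3"] = MatchResult(pairs={})  # m1 missing one role
    groups = build_column_groups(matches, min_types=3)
    assert len(groups) == 1
    assert groups[0].complete and len(groups[0].members) == 3
    two = {r: (MatchResult(pairs={"m1": "x"}) if r in ("role0", "role1")
               else MatchResult(pairs={})) for r in ("role0", "role1", "role2", "role3")}
    assert not build_column_groups(two, min_types=3)[0].complete
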