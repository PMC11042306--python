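"""Cell-to-column assignment and cross-region coordinate extension.

Two mechanisms: (1) the paired-connection mode rule, where each synapse
participating in a listed type-pair connection votes for its nearest column
axis and a cell takes the modal coordinate; (2) normalized maximum-weight
bipartite matching between an anchor type and a candidate type, with
distance-based rejection of implausible pairs, used to carry a coordinate
system from one region into another.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .data_model import Dataset, HexCoord
from .pins import Pin


@dataclass
class PairedAssignment:
    assigned: dict[str, HexCoord]
    flagged: dict[str, str]  # neuron_id -> reason (vote tie / conflicting modes)
    unassigned: list[str]


@dataclass
class MatchResult:
    """An injective anchor -> candidate matching with diagnostics."""

    pairs: dict[str, str]
    rejected: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)
    zero_rows: list[str] = field(default_factory=list)
    total_weight: float = 0.0


@dataclass
class ColumnGroup:
    anchor: str
    coord: HexCoord | None
    members: dict[str, str]  # role type -> cell id
    complete: bool


def _axis_tree(axes: dict[HexCoord, "Pin | np.ndarray"]):
    coords = sorted(axes)
    stack, labels = [], []
    for c in coords:
        pts = axes[c].points if isinstance(axes[c], Pin) else np.atleast_2d(np.asarray(axes[c], float))
        stack.append(pts)
        labels.extend([c] * len(pts))
    return cKDTree(np.vstack(stack)), labels


def assign_by_paired_connections(ds: Dataset, axes: dict[HexCoord, "Pin | np.ndarray"],
                                 pair_specs: list[tuple[str, str]]) -> PairedAssignment:
    """Assign cells to coordinates by the mode of paired-connection votes.

    For every cell whose type appears in a pair spec, each of its synapses
    whose partner belongs to the paired type votes for the nearest axis.
    Exact vote ties and conflicting per-pair modes are flagged for review,
    never silently resolved; cells with no qualifying synapse are reported
    as unassigned.
    """
    if not axes:
        raise ValueError("axes must be non-empty")
    tree, labels = _axis_tree(axes)
    pairs = {frozenset(p) for p in pair_specs}
    types = ds.neuron_types()
    syn = ds.synapses
    partner_neuron = syn.set_index("synapse_id")["neuron_id"]

    target_types = set().union(*pairs) if pairs else set()
    votes: dict[str, dict[frozenset, Counter]] = {}
    cells = types[types.isin(target_types)].index

    sub = syn[syn["neuron_id"].isin(set(cells))].copy()
    sub["partner_neuron"] = sub["partner_synapse_id"].map(partner_neuron)
    sub = sub.dropna(subset=["partner_neuron"])
    sub["partner_type"] = sub["partner_neuron"].map(types)
    sub["own_type"] = sub["neuron_id"].map(types)
    mask = [frozenset((a, b)) in pairs and a != b
            for a, b in zip(sub["own_type"], sub["partner_type"])]
    sub = sub[np.asarray(mask, bool)] if len(sub) else sub

    if len(sub):
        _, idx = tree.query(sub[["x", "y", "z"]].to_numpy(float), k=1)
        nearest = [labels[i] for i in idx]
        for (nid, own, partner), coord in zip(
                sub[["neuron_id", "own_type", "partner_type"]].itertuples(index=False), nearest):
            votes.setdefault(nid, {}).setdefault(frozenset((own, partner)), Counter())[coord] += 1

    assigned, flagged, unassigned = {}, {}, []
    for nid in sorted(cells):
        per_pair = votes.get(nid)
        if not per_pair:
            unassigned.append(nid)
            continue
        overall = Counter()
        for c in per_pair.values():
            overall.update(c)
        ranked = overall.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            flagged[nid] = "vote tie"
            continue
        modes = {min(c.most_common(), key=lambda kv: (-kv[1], kv[0]))[0] for c in per_pair.values()}
        if len(modes) > 1:
            flagged[nid] = "conflicting modes across pair specs"
            continue
        assigned[nid] = ranked[0][0]
    return PairedAssignment(assigned=assigned, flagged=flagged, unassigned=unassigned)


def _normalize_rows(C: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    sums = C.sum(axis=1)
    zero = sorted(C.index[sums <= 0])
    kept = C.loc[sums > 0]
    return kept.div(kept.sum(axis=1), axis=0), zero


def match_bipartite(C: "pd.DataFrame | np.ndarray") -> MatchResult:
    """Maximum-weight matching on the row-normalized connectivity matrix.

    Rows (anchors) are normalized by their row sums so that each anchor
    distributes one unit of weight over the candidates; zero rows are
    excluded and reported.  Among equal-weight optima the lexicographically
    smallest pairing by anchor id is returned (resolved by fixing each
    anchor's smallest feasible candidate and re-solving the remainder).
    """
    if not isinstance(C, pd.DataFrame):
        arr = np.asarray(C, dtype=float)
        if arr.size == 0:
            raise ValueError("empty matrix")
        C = pd.DataFrame(arr,
                         index=[f"a{i}" for i in range(arr.shape[0])],
                         columns=[f"c{j}" for j in range(arr.shape[1])])
    if C.size == 0:
        raise ValueError("empty matrix")
    if (C.to_numpy() < 0).any():
        raise ValueError("connectivity counts must be non-negative")
    N, zero_rows = _normalize_rows(C.sort_index().sort_index(axis=1))
    if N.empty:
        raise ValueError("no positive row in the matrix")

    def opt(mat: np.ndarray) -> float:
        if mat.size == 0 or min(mat.shape) == 0:
            return 0.0
        r, c = linear_sum_assignment(mat, maximize=True)
        return float(mat[r, c].sum())

    anchors = list(N.index)
    cands = list(N.columns)
    M = N.to_numpy()
    total = opt(M)
    remaining_rows = list(range(len(anchors)))
    remaining_cols = list(range(len(cands)))
    current = total
    pairs: dict[str, str] = {}
    tol = 1e-9
    for i in list(remaining_rows):
        rest_rows = [r for r in remaining_rows if r != i]
        fixed = None
        for j in remaining_cols:
            rest_cols = [c for c in remaining_cols if c != j]
            if M[i, j] + opt(M[np.ix_(rest_rows, rest_cols)]) >= current - tol:
                fixed = j
                break
        if fixed is None:
            # anchor unmatched in every optimum (surplus side)
            if opt(M[np.ix_(rest_rows, remaining_cols)]) >= current - tol:
                remaining_rows = rest_rows
                continue
            raise RuntimeError("inconsistent optimum during tie resolution")
        pairs[anchors[i]] = cands[fixed]
        current -= M[i, fixed]
        remaining_rows = rest_rows
        remaining_cols = [c for c in remaining_cols if c != fixed]

    matched_cands = set(pairs.values())
    unmatched = sorted(set(anchors) - set(pairs)) + sorted(set(cands) - matched_cands)
    return MatchResult(pairs=pairs, unmatched=unmatched, zero_rows=zero_rows,
                       total_weight=total)


def pair_distance(ds: Dataset, anchor: str, candidate: str, role_type: str) -> float:
    """Distance between an anchor and a matched candidate.

    The anchor side is the mean position of the anchor's presynapses onto
    any cell of the candidate's type; the candidate side is the mean
    position of the candidate's postsynapses.
    """
    types = ds.neuron_types()
    syn = ds.synapses
    role_cells = set(types[types == role_type].index)
    partner_neuron = syn.set_index("synapse_id")["neuron_id"]
    pre = syn[(syn["neuron_id"] == anchor) & (syn["kind"] == "pre")].copy()
    pre["partner_neuron"] = pre["partner_synapse_id"].map(partner_neuron)
    pre = pre[pre["partner_neuron"].isin(role_cells)]
    post = syn[(syn["neuron_id"] == candidate) & (syn["kind"] == "post")]
    if pre.empty or post.empty:
        return float("inf")
    r_pre = pre[["x", "y", "z"]].to_numpy(float).mean(axis=0)
    r_post = post[["x", "y", "z"]].to_numpy(float).mean(axis=0)
    return float(np.linalg.norm(r_pre - r_post))


def prune_by_distance(match: MatchResult, ds: Dataset,
                      threshold_nm: float = 8000.0) -> MatchResult:
    """Move matched pairs farther apart than ``threshold_nm`` to rejected."""
    types = ds.neuron_types()
    pairs: dict[str, str] = {}
    rejected = list(match.rejected)
    for anchor, cand in match.pairs.items():
        d = pair_distance(ds, anchor, cand, types.get(cand, ""))
        if d > threshold_nm:
            rejected.append(((anchor, cand), d))
        else:
            pairs[anchor] = cand
    unmatched = sorted(set(match.unmatched) | {a for (a, _), _ in rejected if a not in pairs})
    return MatchResult(pairs=pairs, rejected=rejected, unmatched=unmatched,
                       zero_rows=match.zero_rows, total_weight=match.total_weight)


def build_column_groups(matches: dict[str, MatchResult], min_types: int = 3,
                        coords: dict[str, HexCoord] | None = None) -> list[ColumnGroup]:
    """Group per-role matches by anchor; a group is complete at >= min_types
    filled roles (complete groups seed downstream pin construction)."""
    anchors = sorted({a for m in matches.values() for a in m.pairs})
    groups = []
    for a in anchors:
        members = {role: m.pairs[a] for role, m in sorted(matches.items()) if a in m.pairs}
        groups.append(ColumnGroup(
            anchor=a,
            coord=coords.get(a) if coords else None,
            members=members,
            complete=len(members) >= min_types,
        ))
    return groups
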