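"""Synthetic retinotopic connectome generator with planted ground truth.

Emulates the statistical structure the analysis stages assume: a hexagonal
column lattice with gently curved centerlines, planted columnar cell types
with per-type depth profiles of pre/post synapses, overlapping spatial
mosaics, block-structured type-level connectivity with Poisson counts, and
per-presynapse transmitter probability vectors with a planted dominant
transmitter.

Every source of randomness flows from one :class:`numpy.random.Generator`
seeded by ``SyntheticConfig.seed``; identical configs produce byte-identical
datasets.  The planted :class:`GroundTruth` suffices to score every
downstream stage (pin error, column-assignment accuracy, clustering
completeness, transmitter-consensus accuracy).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    COLUMN_BY_NT,
    NT_COLUMNS,
    TRANSMITTERS,
    Dataset,
    HexCoord,
    RegionBounds,
)


class ConfigError(ValueError):
    """The synthetic configuration is inconsistent."""


def make_lattice(radius: int) -> list[HexCoord]:
    """All axial coordinates within hex distance ``radius`` of the origin.

    The patch size is the centered hexagonal number 3·r·(r+1)+1.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    coords = []
    for p in range(-radius, radius + 1):
        for q in range(max(-radius, -radius - p), min(radius, radius - p) + 1):
            coords.append(HexCoord(p, q))
    return sorted(coords)


# A mixture-of-Gaussians depth profile: list of (mean, sd, weight) over [0,1],
# truncated to [0,1] and renormalized.
Profile = list[tuple[float, float, float]]


def _default_profiles(type_names: list[str]) -> dict[str, dict[str, Profile]]:
    """Spread unimodal pre/post profiles across depth, one band per type.

    The bands jointly span nearly the full depth, as the layered arbors of
    real columns do, so column synapse clouds reach both region surfaces.
    """
    n = len(type_names)
    out = {}
    for i, t in enumerate(type_names):
        mu_pre = 0.08 + 0.84 * (i / max(n - 1, 1))
        mu_post = 0.08 + 0.84 * (((i + n // 2) % n) / max(n - 1, 1))
        out[t] = {"pre": [(mu_pre, 0.06, 1.0)], "post": [(mu_post, 0.06, 1.0)]}
    return out


def _default_blocks(type_names: list[str], w1: float = 10.0, w2: float = 5.0) -> pd.DataFrame:
    """Ring-structured type x type expected connection counts.

    Each type outputs to its two lattice successors with distinct weights,
    so both input and output feature blocks separate the types.
    """
    n = len(type_names)
    B = pd.DataFrame(0.0, index=type_names, columns=type_names)
    for i, t in enumerate(type_names):
        B.loc[t, type_names[(i + 1) % n]] = w1
        B.loc[t, type_names[(i + 2) % n]] = w2
    return B


@dataclass
class SyntheticConfig:
    """Parameters of the planted connectome.

    Scales follow the real tissue: ~5 µm column pitch, ~30 µm region depth,
    synapse placement jitter well below the pitch, and a quadratic bend far
    smaller than the pitch so columns are "slightly bent".
    """

    lattice_radius: int = 3
    n_types: int = 6
    cells_per_type: int | dict[str, int] | None = None  # default: one cell per column
    type_names: list[str] | None = None
    depth_profiles: dict[str, dict[str, Profile]] | None = None
    type_block_matrix: pd.DataFrame | None = None
    region: str = "ME"
    pitch_nm: float = 5000.0
    depth_nm: float = 30000.0
    lateral_jitter_sd: float = 200.0
    column_curvature: float = 1500.0
    neighbor_overlap: float = 0.0
    stray_rate: float = 0.05
    nt_dominant: dict[str, str] | None = None
    nt_dominant_prob: float = 0.75
    nt_concentration: float = 50.0
    seed: int = 0

    def resolve(self) -> "_Resolved":
        names = self.type_names or [f"Pt{i:02d}" for i in range(self.n_types)]
        if len(names) != len(set(names)):
            raise ConfigError("type names must be unique")
        columns = make_lattice(self.lattice_radius)
        if isinstance(self.cells_per_type, dict):
            cells = {t: int(self.cells_per_type.get(t, len(columns))) for t in names}
        elif self.cells_per_type is None:
            cells = {t: len(columns) for t in names}
        else:
            cells = {t: int(self.cells_per_type) for t in names}
        profiles = self.depth_profiles or _default_profiles(names)
        for t in names:
            if t not in profiles:
                raise ConfigError(f"no depth profile for type {t!r}")
            for direction in ("pre", "post"):
                for comp in profiles[t][direction]:
                    if len(comp) != 3:
                        raise ConfigError(f"profile component of {t!r}/{direction} must be (mean, sd, weight)")
                    if comp[1] <= 0 or comp[2] < 0:
                        raise ConfigError(f"profile of {t!r}/{direction} has a non-positive sd or negative weight")
        B = self.type_block_matrix if self.type_block_matrix is not None else _default_blocks(names)
        B = B.reindex(index=names, columns=names, fill_value=0.0).astype(float)
        if (B.to_numpy() < 0).any():
            raise ConfigError("type_block_matrix must be non-negative")
        nt = self.nt_dominant or {t: TRANSMITTERS[i % len(TRANSMITTERS)] for i, t in enumerate(names)}
        for t, name in nt.items():
            if name not in TRANSMITTERS:
                raise ConfigError(f"unknown transmitter {name!r} for type {t!r}")
        for value, label in [(self.lateral_jitter_sd, "lateral_jitter_sd"),
                             (self.column_curvature, "column_curvature"),
                             (self.stray_rate, "stray_rate"),
                             (self.neighbor_overlap, "neighbor_overlap")]:
            if value < 0:
                raise ConfigError(f"{label} must be >= 0")
        return _Resolved(names, columns, cells, profiles, B, nt)


@dataclass
class _Resolved:
    type_names: list[str]
    columns: list[HexCoord]
    cells_per_type: dict[str, int]
    profiles: dict[str, dict[str, Profile]]
    blocks: pd.DataFrame
    nt_dominant: dict[str, str]


@dataclass
class GroundTruth:
    """Planted truth covering every generated neuron and synapse."""

    true_pins: dict[HexCoord, np.ndarray]
    true_type: dict[str, str]
    true_column: dict[str, HexCoord]
    true_nt: dict[str, str]
    true_synapse_column: dict[str, HexCoord]


class _Centerline:
    """Quadratic Bezier between top and bottom anchors of one column."""

    def __init__(self, coord: HexCoord, pitch: float, depth: float,
                 bend: float, bend_angle: float):
        x, y = coord.to_xy(pitch)
        self.p0 = np.array([x, y, 0.0])
        self.p2 = np.array([x, y, depth])
        offset = bend * np.array([np.cos(bend_angle), np.sin(bend_angle), 0.0])
        self.p1 = 0.5 * (self.p0 + self.p2) + offset

    def at(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
        return (1 - t) ** 2 * self.p0 + 2 * (1 - t) * t * self.p1 + t**2 * self.p2


def _draw_depths(rng: np.random.Generator, profile: Profile, n: int) -> np.ndarray:
    """Sample from a truncated-renormalized Gaussian mixture on [0,1]."""
    weights = np.array([w for _, _, w in profile], dtype=float)
    weights = weights / weights.sum()
    out = np.empty(n)
    comp = rng.choice(len(profile), size=n, p=weights)
    for i in range(n):
        mu, sd, _ = profile[comp[i]]
        d = rng.normal(mu, sd)
        while not (0.0 <= d <= 1.0):
            d = rng.normal(mu, sd)
        out[i] = d
    return out


def _nt_probs(rng: np.random.Generator, dominant: str, p_dom: float, conc: float) -> np.ndarray:
    target = np.full(len(TRANSMITTERS), (1.0 - p_dom) / (len(TRANSMITTERS) - 1))
    target[TRANSMITTERS.index(dominant)] = p_dom
    probs = rng.dirichlet(conc * target)
    r = np.round(probs, 6)
    k = int(np.argmax(r))
    r[k] = 1.0 - (r.sum() - r[k])  # keep the rounded vector summing to 1
    return r


def simulate_dataset(cfg: SyntheticConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a dataset and its planted ground truth.

    Connection weights are Poisson with mean from the type block matrix
    scaled by the spatial overlap of the incident cells' home columns
    (1 for the same column, ``neighbor_overlap`` for hex-distance 1, else 0).
    Each unit of connection weight instantiates one pre and one post synapse
    on the placement column's centerline, at depths drawn from the pre
    type's presynaptic and the post type's postsynaptic profile, plus
    isotropic lateral jitter; so the number of post records of a neuron
    equals its summed input connection weight by construction.
    """
    res = cfg.resolve()
    rng = np.random.default_rng(cfg.seed)

    centerlines: dict[HexCoord, _Centerline] = {}
    true_pins: dict[HexCoord, np.ndarray] = {}
    ts = np.linspace(0.0, 1.0, 121)
    # Columns bend coherently (one global direction, small per-column wobble),
    # as in curved neuropil; amplitude is the per-column config knob.
    global_angle = rng.uniform(0.0, 2.0 * np.pi)
    for coord in res.columns:
        angle = global_angle + rng.normal(0.0, 0.2)
        cl = _Centerline(coord, cfg.pitch_nm, cfg.depth_nm, cfg.column_curvature, angle)
        centerlines[coord] = cl
        true_pins[coord] = cl.at(ts)

    # Cells: round-robin over sorted columns, so equal-count types interleave
    # into overlapping full-coverage mosaics.
    neurons = []
    home: dict[str, HexCoord] = {}
    true_type: dict[str, str] = {}
    cells_of: dict[str, list[str]] = {}
    cells_in: dict[tuple[str, HexCoord], list[str]] = {}
    n_cols = len(res.columns)
    for t in res.type_names:
        cells_of[t] = []
        for j in range(res.cells_per_type[t]):
            nid = f"{t}.{j:04d}"
            col = res.columns[j % n_cols]
            home[nid] = col
            true_type[nid] = t
            cells_of[t].append(nid)
            cells_in.setdefault((t, col), []).append(nid)
            neurons.append({"neuron_id": nid, "type": t, "instance": f"{t}_R",
                            "group": "OLIN", "status": "traced"})

    # Connections: Poisson block counts between cells whose home columns overlap.
    neighbor_pairs: list[tuple[HexCoord, HexCoord]] = []
    if cfg.neighbor_overlap > 0:
        col_set = set(res.columns)
        for c in res.columns:
            for dp, dq in ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)):
                nb = HexCoord(c.p + dp, c.q + dq)
                if nb in col_set:
                    neighbor_pairs.append((c, nb))

    connections = []
    conn_events: list[tuple[str, str, str, str, HexCoord, int]] = []
    for t1 in res.type_names:
        for t2 in res.type_names:
            mean = float(res.blocks.loc[t1, t2])
            if mean <= 0:
                continue
            for col in res.columns:
                pre_cells = cells_in.get((t1, col), [])
                post_cells = cells_in.get((t2, col), [])
                for a in pre_cells:
                    for b in post_cells:
                        if a == b:
                            continue
                        w = int(rng.poisson(mean))
                        if w > 0:
                            conn_events.append((a, b, t1, t2, col, w))
            if cfg.neighbor_overlap > 0:
                for ca, cb in neighbor_pairs:
                    for a in cells_in.get((t1, ca), []):
                        for b in cells_in.get((t2, cb), []):
                            w = int(rng.poisson(mean * cfg.neighbor_overlap))
                            if w > 0:
                                col = ca if rng.random() < 0.5 else cb
                                conn_events.append((a, b, t1, t2, col, w))

    # Synapses: one pre/post pair per unit weight, on the placement column.
    col_set = set(res.columns)
    neighbors_of: dict[HexCoord, list[HexCoord]] = {}
    for c in res.columns:
        neighbors_of[c] = [HexCoord(c.p + dp, c.q + dq)
                           for dp, dq in ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))
                           if HexCoord(c.p + dp, c.q + dq) in col_set]

    synapses = []
    true_syn_col: dict[str, HexCoord] = {}
    sid = 0

    def _new_id() -> str:
        nonlocal sid
        sid += 1
        return f"s{sid:07d}"

    for a, b, t1, t2, col, w in conn_events:
        connections.append({"pre": a, "post": b, "weight": w, "region": cfg.region})
        d_pre = _draw_depths(rng, res.profiles[t1]["pre"], w)
        d_post = _draw_depths(rng, res.profiles[t2]["post"], w)
        for i in range(w):
            place = col
            if cfg.stray_rate > 0 and neighbors_of[col] and rng.random() < cfg.stray_rate:
                place = neighbors_of[col][rng.integers(len(neighbors_of[col]))]
            cl = centerlines[place]
            pre_pos = cl.at(d_pre[i])[0] + np.array([*rng.normal(0, cfg.lateral_jitter_sd, 2), 0.0]) \
                if cfg.lateral_jitter_sd > 0 else cl.at(d_pre[i])[0]
            post_pos = cl.at(d_post[i])[0] + np.array([*rng.normal(0, cfg.lateral_jitter_sd, 2), 0.0]) \
                if cfg.lateral_jitter_sd > 0 else cl.at(d_post[i])[0]
            pre_id, post_id = _new_id(), _new_id()
            probs = _nt_probs(rng, res.nt_dominant[t1], cfg.nt_dominant_prob, cfg.nt_concentration)
            pre_row = {"synapse_id": pre_id, "neuron_id": a, "kind": "pre",
                       "x": round(pre_pos[0], 3), "y": round(pre_pos[1], 3), "z": round(pre_pos[2], 3),
                       "region": cfg.region, "partner_synapse_id": post_id}
            pre_row.update({c: p for c, p in zip(NT_COLUMNS, probs)})
            post_row = {"synapse_id": post_id, "neuron_id": b, "kind": "post",
                        "x": round(post_pos[0], 3), "y": round(post_pos[1], 3), "z": round(post_pos[2], 3),
                        "region": cfg.region, "partner_synapse_id": pre_id}
            post_row.update({c: np.nan for c in NT_COLUMNS})
            synapses.append(pre_row)
            synapses.append(post_row)
            true_syn_col[pre_id] = place
            true_syn_col[post_id] = place

    syn_df = pd.DataFrame(synapses, columns=["synapse_id", "neuron_id", "kind", "x", "y", "z",
                                             "region", "partner_synapse_id", *NT_COLUMNS])
    neu_df = pd.DataFrame(neurons, columns=["neuron_id", "type", "instance", "group", "status"])
    con_df = pd.DataFrame(connections, columns=["pre", "post", "weight", "region"])
    ds = Dataset(
        synapses=syn_df,
        neurons=neu_df,
        connections=con_df,
        regions=[cfg.region],
        region_bounds={cfg.region: RegionBounds.from_z(0.0, cfg.depth_nm)},
    )
    truth = GroundTruth(
        true_pins=true_pins,
        true_type=true_type,
        true_column=home,
        true_nt={t: res.nt_dominant[t] for t in res.type_names},
        true_synapse_column=true_syn_col,
    )
    return ds, truth


def plant_mosaic_pair(cfg: SyntheticConfig, type_a: str, type_b: str,
                      contrast: float = 1.0, base_weight: float = 8.0,
                      contrast_weight: float = 12.0) -> SyntheticConfig:
    """Configure two types as interleaved full-coverage mosaics.

    Both types get one cell per lattice column (so each covers every
    coordinate) and identical connectivity except for a contrast-scaled
    weight to a distinct partner type each; at ``contrast=0`` their block
    rows are identical and clustering cannot separate them.
    """
    res = cfg.resolve()
    names = res.type_names
    for t in (type_a, type_b):
        if t not in names:
            raise ConfigError(f"unknown type {t!r}")
    partners = [t for t in names if t not in (type_a, type_b)]
    if len(partners) < 3:
        raise ConfigError("need at least three other types for distinct mosaic partners")
    out = copy.deepcopy(cfg)
    out.type_names = names
    cells = dict(res.cells_per_type)
    cells[type_a] = len(res.columns)
    cells[type_b] = len(res.columns)
    out.cells_per_type = cells
    B = res.blocks.copy()
    # outputs: a shared partner plus one contrast-scaled distinct partner each;
    # inputs: a single shared upstream partner, so at zero contrast the two
    # types are exchangeable in every feature.
    B.loc[type_a, :] = 0.0
    B.loc[type_b, :] = 0.0
    B.loc[:, type_a] = 0.0
    B.loc[:, type_b] = 0.0
    B.loc[type_a, partners[0]] = base_weight
    B.loc[type_b, partners[0]] = base_weight
    B.loc[type_a, partners[1]] = contrast * contrast_weight
    B.loc[type_b, partners[2]] = contrast * contrast_weight
    B.loc[partners[0], type_a] = base_weight
    B.loc[partners[0], type_b] = base_weight
    out.type_block_matrix = B
    out.depth_profiles = res.profiles
    return out


# ---------------------------------------------------------------------------
# Ground-truth scoring hooks


def pin_rms_error(pins, truth: GroundTruth) -> float:
    """RMS distance of built pin points to the nearest true-centerline point."""
    sq = []
    for coord, pin in pins.items():
        pts = pin.points if hasattr(pin, "points") else np.asarray(pin)
        ref = truth.true_pins[coord]
        d2 = ((pts[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2).min(axis=1)
        sq.extend(d2.tolist())
    return float(np.sqrt(np.mean(sq)))


def synapse_assignment_accuracy(assignment, truth: GroundTruth) -> float:
    """Fraction of assigned synapses mapped to their planted column."""
    hits = total = 0
    for sid, (coord, _, _) in assignment.items():
        if sid not in truth.true_synapse_column:
            continue
        total += 1
        hits += int(coord == truth.true_synapse_column[sid])
    if total == 0:
        raise ValueError("no scored synapses")
    return hits / total


def neuron_assignment_accuracy(coords: dict[str, HexCoord], truth: GroundTruth) -> float:
    """Fraction of neurons assigned to their planted home column."""
    hits = total = 0
    for nid, coord in coords.items():
        if nid not in truth.true_column:
            continue
        total += 1
        hits += int(coord == truth.true_column[nid])
    if total == 0:
        raise ValueError("no scored neurons")
    return hits / total
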