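"""Shared domain types and tabular I/O for connectome exports.

A dataset is the triplet of a synapse table, a neuron table and a directed
connection table, plus per-region boundary surfaces.  All tables are plain
CSV (UTF-8, header row) with the schemas documented on :func:`read_dataset`.
Synapse positions are in nanometres in the EM voxel frame; identifiers are
opaque strings.

Downstream results never depend on row order: every module sorts or
aggregates before computing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical transmitter names, in the column order used on disk.
TRANSMITTERS = (
    "acetylcholine",
    "glutamate",
    "gaba",
    "histamine",
    "dopamine",
    "octopamine",
    "serotonin",
)

#: CSV column per transmitter probability.
NT_COLUMNS = ("p_ach", "p_glu", "p_gaba", "p_his", "p_dop", "p_oa", "p_ser")

NT_BY_COLUMN = dict(zip(NT_COLUMNS, TRANSMITTERS))
COLUMN_BY_NT = dict(zip(TRANSMITTERS, NT_COLUMNS))

SYNAPSE_COLUMNS = (
    "synapse_id", "neuron_id", "kind", "x", "y", "z",
    "region", "partner_synapse_id", *NT_COLUMNS,
)
NEURON_COLUMNS = ("neuron_id", "type", "instance", "group", "status")
CONNECTION_COLUMNS = ("pre", "post", "weight", "region")
REGION_COLUMNS = ("region", "top_z", "bottom_z")

NEURON_GROUPS = ("OLIN", "OLCN", "VPN", "VCN", "other", "unassigned")
NEURON_STATUSES = ("traced", "fragment", "unclear")


class SchemaError(ValueError):
    """A table is missing a required column."""


class IntegrityError(ValueError):
    """A table references a neuron_id absent from the neuron table."""


class ValidationError(ValueError):
    """A record violates a dataset invariant."""


@dataclass(frozen=True, order=True)
class HexCoord:
    """Axial hexagonal lattice coordinate (p, q)."""

    p: int
    q: int

    def distance(self, other: "HexCoord") -> int:
        """Hex-grid distance: max absolute cube-coordinate difference."""
        dp = self.p - other.p
        dq = self.q - other.q
        return max(abs(dp), abs(dq), abs(dp + dq))

    def to_xy(self, pitch: float = 1.0) -> tuple[float, float]:
        """Cartesian center of the column for a given lattice pitch."""
        x = pitch * (self.p + 0.5 * self.q)
        y = pitch * (np.sqrt(3.0) / 2.0) * self.q
        return (x, y)


@dataclass(frozen=True)
class PlaneSurface:
    """A planar region boundary supporting ray intersection and side queries."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def intersect(self, origin: np.ndarray, direction: np.ndarray) -> np.ndarray | None:
        """Intersection of the line origin + t*direction with the plane, or None."""
        n = np.asarray(self.normal, dtype=float)
        p0 = np.asarray(self.point, dtype=float)
        denom = float(np.dot(n, direction))
        if abs(denom) < 1e-12:
            return None
        t = float(np.dot(n, p0 - origin)) / denom
        return np.asarray(origin, dtype=float) + t * np.asarray(direction, dtype=float)

    def signed_side(self, point: np.ndarray) -> float:
        """Signed distance of a point from the plane, along the normal."""
        n = np.asarray(self.normal, dtype=float)
        return float(np.dot(n, np.asarray(point, dtype=float) - np.asarray(self.point, dtype=float)))


@dataclass(frozen=True)
class RegionBounds:
    """Top and bottom boundary surfaces of one region."""

    top: PlaneSurface
    bottom: PlaneSurface

    @classmethod
    def from_z(cls, top_z: float, bottom_z: float) -> "RegionBounds":
        return cls(
            top=PlaneSurface((0.0, 0.0, top_z), (0.0, 0.0, 1.0)),
            bottom=PlaneSurface((0.0, 0.0, bottom_z), (0.0, 0.0, 1.0)),
        )


@dataclass
class Dataset:
    """In-memory connectome export.

    Attributes
    ----------
    synapses, neurons, connections
        DataFrames with the documented column schemas.
    regions
        Ordered list of region labels.
    region_bounds
        Per region, the two boundary surfaces.
    """

    synapses: pd.DataFrame
    neurons: pd.DataFrame
    connections: pd.DataFrame
    regions: list[str] = field(default_factory=list)
    region_bounds: dict[str, RegionBounds] = field(default_factory=dict)

    def neuron_types(self) -> pd.Series:
        """neuron_id -> type label (may contain empty strings)."""
        return self.neurons.set_index("neuron_id")["type"]


@dataclass(frozen=True)
class Violation:
    record: str
    rule: str
    message: str


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"table {table!r} is missing column {col!r}")


_STR_SYN = ["synapse_id", "neuron_id", "kind", "region", "partner_synapse_id"]


def _normalize_tables(synapses, neurons, connections):
    synapses = synapses.copy()
    neurons = neurons.copy()
    connections = connections.copy()
    for col in _STR_SYN:
        synapses[col] = synapses[col].fillna("").astype(str)
    for col in ["x", "y", "z", *NT_COLUMNS]:
        synapses[col] = pd.to_numeric(synapses[col], errors="coerce")
    for col in NEURON_COLUMNS:
        neurons[col] = neurons[col].fillna("").astype(str)
    for col in ["pre", "post", "region"]:
        connections[col] = connections[col].fillna("").astype(str)
    connections["weight"] = pd.to_numeric(connections["weight"], errors="coerce").astype(int)
    return synapses, neurons, connections


def validate_dataset(ds: Dataset) -> list[Violation]:
    """Check every dataset invariant; return violations, never raise.

    Rules checked: transmitter probabilities in [0,1] summing to 1 (±1e-6);
    post synapses carry a partner; finite positions; instance side suffix;
    "unclear" status consistency; connection weights ≥ 1; no autapses;
    referential integrity; conservation of post-synapse counts against
    summed input connection weights.
    """
    out: list[Violation] = []
    syn, neu, con = ds.synapses, ds.neurons, ds.connections

    known = set(neu["neuron_id"])
    for nid in sorted(set(syn["neuron_id"]) - known):
        out.append(Violation(nid, "referential-integrity", f"synapse references unknown neuron {nid!r}"))
    for nid in sorted((set(con["pre"]) | set(con["post"])) - known):
        out.append(Violation(nid, "referential-integrity", f"connection references unknown neuron {nid!r}"))

    probs = syn[list(NT_COLUMNS)].to_numpy(dtype=float)
    has_probs = ~np.all(np.isnan(probs), axis=1)
    bad_range = has_probs & (np.nan_to_num(probs, nan=0.0).min(axis=1) < -1e-12)
    bad_range |= has_probs & (np.nan_to_num(probs, nan=0.0).max(axis=1) > 1 + 1e-12)
    sums = np.nansum(probs, axis=1)
    bad_sum = has_probs & (np.abs(sums - 1.0) > 1e-6)
    for sid in syn.loc[bad_range | bad_sum, "synapse_id"]:
        out.append(Violation(sid, "nt-probability", f"transmitter probabilities of synapse {sid!r} invalid"))

    pos = syn[["x", "y", "z"]].to_numpy(dtype=float)
    for sid in syn.loc[~np.all(np.isfinite(pos), axis=1), "synapse_id"]:
        out.append(Violation(sid, "finite-position", f"synapse {sid!r} has a non-finite position"))

    post_missing = (syn["kind"] == "post") & (syn["partner_synapse_id"] == "")
    for sid in syn.loc[post_missing, "synapse_id"]:
        out.append(Violation(sid, "post-partner", f"post synapse {sid!r} lacks a partner"))

    bad_kind = ~syn["kind"].isin(["pre", "post"])
    for sid in syn.loc[bad_kind, "synapse_id"]:
        out.append(Violation(sid, "kind", f"synapse {sid!r} has kind outside {{pre, post}}"))

    has_instance = neu["instance"] != ""
    bad_suffix = has_instance & ~(neu["instance"].str.endswith("_R") | neu["instance"].str.endswith("_L"))
    for nid in neu.loc[bad_suffix, "neuron_id"]:
        out.append(Violation(nid, "instance-suffix", f"instance of neuron {nid!r} lacks _R/_L suffix"))

    unclear_type = neu["type"].str.endswith("_unclear")
    inconsistent = (neu["status"] == "unclear") != unclear_type
    for nid in neu.loc[inconsistent & (neu["type"] != ""), "neuron_id"]:
        out.append(Violation(nid, "unclear-status", f"neuron {nid!r}: 'unclear' status must match a *_unclear type"))

    for _, row in con[con["weight"] < 1].iterrows():
        out.append(Violation(f"{row['pre']}->{row['post']}", "weight", "connection weight must be >= 1"))
    for _, row in con[con["pre"] == con["post"]].iterrows():
        out.append(Violation(f"{row['pre']}->{row['post']}", "no-autapse", f"autapse on neuron {row['pre']!r}"))

    # Conservation: per-neuron post-synapse count == summed input connection weight.
    post_counts = syn.loc[syn["kind"] == "post", "neuron_id"].value_counts()
    in_weights = con.groupby("post")["weight"].sum()
    universe = sorted(set(post_counts.index) | set(in_weights.index))
    for nid in universe:
        if nid not in known:
            continue
        n_post = int(post_counts.get(nid, 0))
        w_in = int(in_weights.get(nid, 0))
        if n_post != w_in:
            out.append(Violation(nid, "conservation",
                                 f"neuron {nid!r} has {n_post} post synapses but {w_in} summed input weight"))
    return out


def read_dataset(paths: dict[str, str] | str) -> Dataset:
    """Read and validate a dataset.

    Parameters
    ----------
    paths
        Either a directory containing ``synapses.csv``, ``neurons.csv``,
        ``connections.csv`` and ``regions.csv``, or a mapping from those
        table names (sans extension) to file paths.

    Raises
    ------
    SchemaError, IntegrityError, ValidationError
        On a missing column, dangling neuron reference, or any other
        invariant violation, respectively.
    """
    if isinstance(paths, (str, os.PathLike)):
        base = str(paths)
        paths = {name: os.path.join(base, f"{name}.csv")
                 for name in ("synapses", "neurons", "connections", "regions")}
    syn = pd.read_csv(paths["synapses"], dtype=str, keep_default_na=False)
    neu = pd.read_csv(paths["neurons"], dtype=str, keep_default_na=False)
    con = pd.read_csv(paths["connections"], dtype=str, keep_default_na=False)
    reg = pd.read_csv(paths["regions"], dtype=str, keep_default_na=False)

    _require_columns(syn, SYNAPSE_COLUMNS, "synapses")
    _require_columns(neu, NEURON_COLUMNS, "neurons")
    _require_columns(con, CONNECTION_COLUMNS, "connections")
    _require_columns(reg, REGION_COLUMNS, "regions")

    syn = syn.replace({c: {"": np.nan} for c in ["x", "y", "z", *NT_COLUMNS]})
    syn, neu, con = _normalize_tables(syn, neu, con)

    regions = list(reg["region"])
    bounds = {row["region"]: RegionBounds.from_z(float(row["top_z"]), float(row["bottom_z"]))
              for _, row in reg.iterrows()}
    ds = Dataset(synapses=syn, neurons=neu, connections=con, regions=regions, region_bounds=bounds)

    violations = validate_dataset(ds)
    dangling = [v for v in violations if v.rule == "referential-integrity"]
    if dangling:
        offenders = ", ".join(v.record for v in dangling)
        raise IntegrityError(f"dangling neuron references: {offenders}")
    if violations:
        raise ValidationError("; ".join(v.message for v in violations[:20]))
    return ds


def _fmt_float(x, decimals: int) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return f"{x:.{decimals}f}"


def write_dataset(ds: Dataset, out_dir: str) -> None:
    """Write a dataset as four CSV files with fixed decimal formatting.

    Positions are written with 3 decimals and probabilities with 6, so
    write -> read -> write is byte-identical.
    """
    os.makedirs(out_dir, exist_ok=True)
    syn = ds.synapses.copy()
    for col in ("x", "y", "z"):
        syn[col] = syn[col].map(lambda v: _fmt_float(v, 3))
    for col in NT_COLUMNS:
        syn[col] = syn[col].map(lambda v: _fmt_float(v, 6))
    syn[list(SYNAPSE_COLUMNS)].to_csv(os.path.join(out_dir, "synapses.csv"), index=False)
    ds.neurons[list(NEURON_COLUMNS)].to_csv(os.path.join(out_dir, "neurons.csv"), index=False)
    ds.connections[list(CONNECTION_COLUMNS)].to_csv(os.path.join(out_dir, "connections.csv"), index=False)
    rows = []
    for r in ds.regions:
        b = ds.region_bounds[r]
        rows.append({"region": r, "top_z": _fmt_float(b.top.point[2], 3),
                     "bottom_z": _fmt_float(b.bottom.point[2], 3)})
    pd.DataFrame(rows, columns=list(REGION_COLUMNS)).to_csv(os.path.join(out_dir, "regions.csv"), index=False)
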