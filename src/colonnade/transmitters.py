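"""Neurotransmitter consensus from per-presynapse probability vectors.

Each presynapse carries a probability over seven transmitters
(acetylcholine, glutamate, GABA, histamine, dopamine, octopamine,
serotonin).  The per-synapse call is the argmax; a neuron's (or type's)
consensus is the modal call, accepted only with enough presynapses and
enough modal agreement, otherwise "unclear".  Aminergic type-level calls
without independent experimental support are overridden to "unclear", since
those transmitters are underrepresented in classifier training data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import NT_COLUMNS, NT_BY_COLUMN, Dataset

#: Aminergic calls subject to the experimental-support override.
AMINERGIC = frozenset({"dopamine", "octopamine", "serotonin"})

UNCLEAR = "unclear"


@dataclass
class ConsensusResult:
    subject: str
    n_presynapses: int
    modal_transmitter: str | None
    confidence: float
    call: str
    override_applied: bool = False
    tie_flagged: bool = False


def synapse_calls(presynapses: pd.DataFrame) -> tuple[list[str], bool]:
    """Argmax transmitter per presynapse; exact probability ties go to the
    lexicographically first transmitter name and are flagged."""
    # columns reordered so argmax ties resolve to the lexicographically first name
    cols_sorted = sorted(NT_COLUMNS, key=lambda c: NT_BY_COLUMN[c])
    names = [NT_BY_COLUMN[c] for c in cols_sorted]
    probs = presynapses[cols_sorted].to_numpy(dtype=float)
    best = np.argmax(probs, axis=1)
    tie = bool(np.any(np.sum(probs == probs.max(axis=1, keepdims=True), axis=1) > 1))
    return [names[i] for i in best], tie


def _consensus(presynapses: pd.DataFrame, subject: str, min_syn: int,
               min_conf: float) -> ConsensusResult:
    has_probs = ~presynapses[list(NT_COLUMNS)].isna().all(axis=1)
    pre = presynapses[has_probs]
    n = len(pre)
    if n == 0:
        return ConsensusResult(subject=subject, n_presynapses=0, modal_transmitter=None,
                               confidence=0.0, call=UNCLEAR)
    calls, tie = synapse_calls(pre)
    counts = Counter(calls)
    top = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    modal, modal_n = top
    modal_tie = sum(1 for v in counts.values() if v == modal_n) > 1
    confidence = modal_n / n
    accepted = n >= min_syn and confidence >= min_conf
    return ConsensusResult(subject=subject, n_presynapses=n, modal_transmitter=modal,
                           confidence=confidence, call=modal if accepted else UNCLEAR,
                           tie_flagged=tie or modal_tie)


def neuron_consensus(ds: Dataset, neuron_id: str, min_syn: int = 50,
                     min_conf: float = 0.5) -> ConsensusResult:
    """Modal per-synapse transmitter of one neuron; accepted with >= min_syn
    presynapses and modal fraction >= min_conf, else "unclear"."""
    syn = ds.synapses
    pre = syn[(syn["neuron_id"] == neuron_id) & (syn["kind"] == "pre")]
    return _consensus(pre, neuron_id, min_syn, min_conf)


def type_consensus(ds: Dataset, type_label: str, min_syn: int = 100,
                   min_conf: float = 0.5) -> ConsensusResult:
    """Consensus pooled over all presynapses of a type's cells (the pooled
    call can differ from every individual cell's when cells are small)."""
    cells = ds.neurons.loc[ds.neurons["type"] == type_label, "neuron_id"]
    if cells.empty:
        raise ValueError(f"unknown type {type_label!r}")
    syn = ds.synapses
    pre = syn[(syn["neuron_id"].isin(set(cells))) & (syn["kind"] == "pre")]
    return _consensus(pre, type_label, min_syn, min_conf)


def apply_override(result: ConsensusResult,
                   supported_aminergic: "set[str] | frozenset[str]") -> ConsensusResult:
    """Set aminergic type-level calls to "unclear" unless the type is in the
    experimentally supported set; non-aminergic calls are never touched."""
    if result.call in AMINERGIC and result.subject not in supported_aminergic:
        return ConsensusResult(subject=result.subject, n_presynapses=result.n_presynapses,
                               modal_transmitter=result.modal_transmitter,
                               confidence=result.confidence, call=UNCLEAR,
                               override_applied=True, tie_flagged=result.tie_flagged)
    return result


def fanout(ds: Dataset, type_label: str) -> float:
    """Average ratio of output connections to presynapses over a type's cells.

    Per cell: summed output connection weight / presynapse count; cells with
    presynapses but no matched outputs contribute 0.  Types without any
    presynaptic cell have no defined fanout.
    """
    cells = ds.neurons.loc[ds.neurons["type"] == type_label, "neuron_id"]
    if cells.empty:
        raise ValueError(f"unknown type {type_label!r}")
    syn = ds.synapses
    pre_counts = syn[(syn["kind"] == "pre") & syn["neuron_id"].isin(set(cells))] \
        .groupby("neuron_id").size()
    out_weights = ds.connections[ds.connections["pre"].isin(set(cells))] \
        .groupby("pre")["weight"].sum()
    ratios = [float(out_weights.get(nid, 0)) / int(n_pre)
              for nid, n_pre in pre_counts.items() if n_pre > 0]
    if not ratios:
        raise ValueError(f"type {type_label!r} has no presynapses; fanout undefined")
    return float(np.mean(ratios))
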