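"""Per-neuron substructure mining.

For each first-hidden-layer neuron: select the training compounds whose
activation exceeds mean + ThreshCompound standard deviations, select the
top-ThreshBits fraction of input bits by learned weight, run formal concept
analysis on the resulting compound x bit context, and convert concepts — in
order of decreasing support — into connected molecular fragments scored by the
summed input weight of the bits they contain.  Fragments are pruned (a more
generic accepted fragment with identical summed weight supersedes a specific
one), capped, deduplicated by canonical form and organized into a DAG by
subgraph containment (generic above specific).

Only first-layer neurons are mined; for deeper layers the neurons tend to
aggregate rather than detect chemistry, and the evaluation module provides
diagnostics instead.

Bit ranking defaults to signed weights (most positive first): with rectified
activations only positively weighted bits can drive a neuron above threshold.
Ranking by magnitude is available behind a flag.  The bias term plays no role
when comparing summed bit weights to the activation threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem

from .chem import (
    Fingerprint,
    Fragment,
    Molecule,
    fragment_from_atoms,
    is_strict_subfragment,
)
from .fca import build_context, enumerate_concepts, order_by_support, FormalConcept
from .network import TrainedModel, hidden_activations, input_weights

__all__ = [
    "ExtractionConfig",
    "SubstructureRecord",
    "SubstructureNetwork",
    "select_activating_compounds",
    "select_top_bits",
    "extract_neuron_substructures",
    "extract_all_neurons",
    "build_hierarchy",
]


@dataclass
class ExtractionConfig:
    """Mining thresholds.

    thresh_compound: activation cut in standard deviations above the mean (2).
    thresh_bits: top fraction of bits by weight to keep (0.1, i.e. the 90th
        percentile and above).
    thresh_weight: fraction of the compound activation threshold that a
        concept's (and a fragment's) summed bit weight must reach (1).
    max_substructures: per-neuron cap on accepted substructures (200).
    rank_by_magnitude: rank bits by absolute instead of signed weight.
    """

    thresh_compound: float = 2.0
    thresh_bits: float = 0.1
    thresh_weight: float = 1.0
    max_substructures: int = 200
    rank_by_magnitude: bool = False

    def __post_init__(self):
        if not 0 < self.thresh_bits <= 1:
            raise ValueError("thresh_bits must be in (0, 1]")
        if self.max_substructures < 1:
            raise ValueError("max_substructures must be >= 1")


@dataclass
class SubstructureRecord:
    """A mined fragment with the bits (and weights) that make it relevant.

    ``bit_env_atoms`` records, per contributing bit, the atom sets of the
    environments that lie fully inside the fragment (in source-molecule atom
    indices); the weighted atom-sharing scheme of the hidden-layer explanation
    is built from these.
    """

    fragment: Fragment
    contributing_bits: dict[int, float]
    bit_env_atoms: dict[int, list[frozenset[int]]]
    neuron: tuple[int, int]  # (layer, index)
    source_concept: FormalConcept | None = None

    @property
    def summed_weight(self) -> float:
        return float(sum(self.contributing_bits.values()))


@dataclass
class SubstructureNetwork:
    """Per-neuron hierarchy of mined substructures.

    Nodes are deduplicated by fragment canonical form; edges run from generic
    (subgraph) to specific (supergraph) with transitive edges removed, so the
    structure is a DAG whose roots are the most generic fragments.
    """

    neuron: tuple[int, int]
    records: list[SubstructureRecord] = field(default_factory=list)
    children: dict[int, list[int]] = field(default_factory=dict)  # node idx -> child idxs
    parents: dict[int, list[int]] = field(default_factory=dict)
    activation_threshold: float = 0.0

    @property
    def roots(self) -> list[int]:
        return [i for i in range(len(self.records)) if not self.parents.get(i)]

    def __len__(self) -> int:
        return len(self.records)

    # -- serialization ------------------------------------------------------

    def to_json_dict(self, config: ExtractionConfig | None = None) -> dict:
        nodes = []
        for rec in self.records:
            frag = rec.fragment
            mol = frag.source_mol
            smiles = Chem.MolToSmiles(mol)
            order = json.loads(mol.GetProp("_smilesAtomOutputOrder").replace(",]", "]"))
            remap = {old: new for new, old in enumerate(order)}
            nodes.append(
                {
                    "canonical_form": frag.canonical_form,
                    "source_id": frag.source_id,
                    "source_smiles": smiles,
                    "atom_indices": sorted(remap[a] for a in frag.atom_indices),
                    "contributing_bits": {
                        str(b): w for b, w in sorted(rec.contributing_bits.items())
                    },
                    "bit_env_atoms": {
                        str(b): [sorted(remap[a] for a in env) for env in envs]
                        for b, envs in sorted(rec.bit_env_atoms.items())
                    },
                    "summed_weight": rec.summed_weight,
                }
            )
        out = {
            "neuron": list(self.neuron),
            "activation_threshold": self.activation_threshold,
            "nodes": nodes,
            "edges": sorted(
                (p, c) for p, cs in self.children.items() for c in cs
            ),
        }
        if config is not None:
            out["config"] = {
                "thresh_compound": config.thresh_compound,
                "thresh_bits": config.thresh_bits,
                "thresh_weight": config.thresh_weight,
                "max_substructures": config.max_substructures,
                "rank_by_magnitude": config.rank_by_magnitude,
            }
        return out

    @classmethod
    def from_json_dict(cls, data: dict) -> "SubstructureNetwork":
        records = []
        for node in data["nodes"]:
            mol = Chem.MolFromSmiles(node["source_smiles"])
            atoms = frozenset(node["atom_indices"])
            frag = Fragment(
                source_id=node["source_id"],
                atom_indices=atoms,
                canonical_form=node["canonical_form"],
                source_mol=mol,
            )
            records.append(
                SubstructureRecord(
                    fragment=frag,
                    contributing_bits={int(b): w for b, w in node["contributing_bits"].items()},
                    bit_env_atoms={
                        int(b): [frozenset(env) for env in envs]
                        for b, envs in node["bit_env_atoms"].items()
                    },
                    neuron=tuple(data["neuron"]),
                )
            )
        net = cls(
            neuron=tuple(data["neuron"]),
            records=records,
            activation_threshold=data.get("activation_threshold", 0.0),
        )
        net.children = {i: [] for i in range(len(records))}
        net.parents = {i: [] for i in range(len(records))}
        for p, c in data.get("edges", []):
            net.children[p].append(c)
            net.parents[c].append(p)
        return net


# ---------------------------------------------------------------------------
# Selection steps
# ---------------------------------------------------------------------------


def select_activating_compounds(
    activations: Sequence[float] | np.ndarray,
    cfg: ExtractionConfig,
    ids: Sequence | None = None,
) -> tuple[set, float]:
    """Compounds whose activation strictly exceeds mean + k * population SD.

    Returns the selected id set (positional indices when ``ids`` is None) and
    the threshold itself.  A zero-variance neuron yields an empty selection.
    """
    acts = np.asarray(activations, dtype=float)
    if acts.size < 2:
        raise ValueError("need at least two training compounds")
    threshold = float(acts.mean() + cfg.thresh_compound * acts.std(ddof=0))
    keys = list(range(acts.size)) if ids is None else list(ids)
    selected = {keys[i] for i in np.flatnonzero(acts > threshold)}
    return selected, threshold


def select_top_bits(weights: Sequence[float] | np.ndarray, cfg: ExtractionConfig) -> set[int]:
    """Bits at or above the (1 - thresh_bits) quantile of the weights.

    The cut value is the weight at descending rank ceil(f * n); everything
    >= the cut is kept, so ties at the cut are all included and with distinct
    weights exactly ceil(f * n) bits survive (205 for f=0.1, n=2048).
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight vector")
    if cfg.rank_by_magnitude:
        w = np.abs(w)
    n_keep = min(math.ceil(cfg.thresh_bits * w.size), w.size)
    rank = w.size - n_keep + 1  # ascending, 1-based
    cut = np.sort(w)[rank - 1]
    return {int(b) for b in np.flatnonzero(w >= cut)}


# ---------------------------------------------------------------------------
# Concept -> fragments
# ---------------------------------------------------------------------------


def _fragments_for_compound(
    mol: Molecule,
    fp: Fingerprint,
    intent: frozenset[int],
    weights: np.ndarray,
) -> list[tuple[Fragment, dict[int, float], dict[int, list[frozenset[int]]]]]:
    """Mark every atom in any environment of any intent bit, split into
    connected fragments and attach each fragment's contained bits.

    A bit contributes to a fragment only if at least one of its environments
    lies fully inside the fragment; a bit's weight counts once per fragment
    regardless of how many of its environments are contained.
    """
    marked: set[int] = set()
    present = [b for b in intent if b in fp.env_map]
    for b in present:
        for env in fp.env_map[b]:
            marked |= env.atom_indices
    out = []
    for frag in fragment_from_atoms(mol, marked):
        contributing: dict[int, float] = {}
        env_atoms: dict[int, list[frozenset[int]]] = {}
        for b in present:
            inside = [
                env.atom_indices
                for env in fp.env_map[b]
                if env.atom_indices <= frag.atom_indices
            ]
            if inside:
                contributing[b] = float(weights[b])
                env_atoms[b] = inside
        out.append((frag, contributing, env_atoms))
    return out


def extract_neuron_substructures(
    model: TrainedModel,
    layer: int,
    neuron: int,
    training: Sequence[tuple[Molecule, Fingerprint]],
    cfg: ExtractionConfig | None = None,
) -> SubstructureNetwork:
    """Mine the substructure hierarchy of one first-hidden-layer neuron.

    ``training`` pairs each training molecule with its fingerprint (the
    environment map is required).  An empty compound selection gives an empty
    network.
    """
    cfg = cfg or ExtractionConfig()
    if layer != 1:
        raise ValueError("substructure extraction is defined for the first hidden layer only")
    by_id = {mol.id: (mol, fp) for mol, fp in training}
    X = np.stack([fp.as_input() for _, fp in training])
    acts = hidden_activations(model, X, layer)[:, neuron]
    ids = [mol.id for mol, _ in training]
    selected_ids, act_threshold = select_activating_compounds(acts, cfg, ids=ids)
    empty = SubstructureNetwork(neuron=(layer, neuron), activation_threshold=act_threshold)
    if not selected_ids:
        return empty
    weights = input_weights(model, layer, neuron)
    bits = select_top_bits(weights, cfg)
    ordered_sel = [cid for cid in ids if cid in selected_ids]  # stable order
    ctx = build_context([(cid, by_id[cid][1]) for cid in ordered_sel], bits)
    concepts = order_by_support(enumerate_concepts(ctx))
    weight_floor = cfg.thresh_weight * act_threshold
    covered_bits: set[int] = set()
    accepted: list[SubstructureRecord] = []
    for concept in concepts:
        if len(accepted) >= cfg.max_substructures:
            break
        if not concept.extent or not concept.intent:
            continue
        intent_weight = float(sum(weights[b] for b in concept.intent))
        if intent_weight < weight_floor:
            continue
        if set(concept.intent) <= covered_bits:
            continue  # every bit already represented: skip the concept
        covered_bits |= set(concept.intent)
        for cid in sorted(concept.extent, key=ordered_sel.index):
            if len(accepted) >= cfg.max_substructures:
                break
            mol, fp = by_id[cid]
            candidates = _fragments_for_compound(mol, fp, concept.intent, weights)
            if not candidates:
                continue
            # most relevant substructure for the compound: highest summed
            # weight; ties resolved toward the more generic (smaller) fragment
            frag, contributing, env_atoms = max(
                candidates,
                key=lambda t: (
                    sum(t[1].values()),
                    -t[0].num_atoms,
                    t[0].canonical_form,
                ),
            )
            score = float(sum(contributing.values()))
            if score < weight_floor:
                continue
            # generic-duplicate pruning against the neuron's accepted set
            if any(
                abs(rec.summed_weight - score) < 1e-12
                and is_strict_subfragment(rec.fragment, frag)
                for rec in accepted
            ):
                continue
            accepted.append(
                SubstructureRecord(
                    fragment=frag,
                    contributing_bits=contributing,
                    bit_env_atoms=env_atoms,
                    neuron=(layer, neuron),
                    source_concept=concept,
                )
            )
    if not accepted:
        return empty
    deduped: dict[str, SubstructureRecord] = {}
    for rec in accepted:
        deduped.setdefault(rec.fragment.canonical_form, rec)
    network = build_hierarchy(list(deduped.values()))
    network.neuron = (layer, neuron)
    network.activation_threshold = act_threshold
    return network


def extract_all_neurons(
    model: TrainedModel,
    training: Sequence[tuple[Molecule, Fingerprint]],
    cfg: ExtractionConfig | None = None,
    layer: int = 1,
    neurons: Iterable[int] | None = None,
) -> dict[int, SubstructureNetwork]:
    """Mine every neuron of the first hidden layer (or a subset)."""
    cfg = cfg or ExtractionConfig()
    n_neurons = model.weights[layer - 1].shape[1]
    idx = range(n_neurons) if neurons is None else neurons
    return {
        n: extract_neuron_substructures(model, layer, n, training, cfg) for n in idx
    }


def build_hierarchy(records: Sequence[SubstructureRecord]) -> SubstructureNetwork:
    """Arrange deduplicated records into a DAG by strict subgraph containment,
    keeping only cover edges (transitive reduction)."""
    records = list(records)
    g = nx.DiGraph()
    g.add_nodes_from(range(len(records)))
    for i, a in enumerate(records):
        for j, b in enumerate(records):
            if i != j and is_strict_subfragment(a.fragment, b.fragment):
                g.add_edge(i, j)
    reduced = nx.transitive_reduction(g)
    network = SubstructureNetwork(
        neuron=records[0].neuron if records else (1, -1), records=records
    )
    network.children = {i: sorted(reduced.successors(i)) for i in reduced.nodes}
    network.parents = {i: sorted(reduced.predecessors(i)) for i in reduced.nodes}
    return network


def save_networks(
    networks: dict[int, SubstructureNetwork],
    path: str | Path,
    config: ExtractionConfig | None = None,
) -> None:
    data = {str(n): net.to_json_dict(config) for n, net in networks.items()}
    Path(path).write_text(json.dumps(data, indent=1))


def load_networks(path: str | Path) -> dict[int, SubstructureNetwork]:
    data = json.loads(Path(path).read_text())
    return {int(n): SubstructureNetwork.from_json_dict(d) for n, d in data.items()}
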