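"""Turn integrated-gradients outputs into per-atom explanations.

Input-level route (``explain_ig_input``): per-bit attributions are filtered
(bits under 1% of the strongest bit, by magnitude, are dropped), then each
surviving bit's attribution is shared equally between its distinct atom
environments (collisions), each environment's share is divided equally over
its atoms across all occurrences, and atoms sum what they receive.

Hidden-neuron route (``explain_ig_hidden``): each first-layer neuron gets a
layer-IG attribution; the neuron's mined substructure hierarchy is matched
against the compound from the generic roots downward (a node is only tried
once all its parents matched), the matched set is reduced to its most specific
members, and the neuron's attribution is split equally between them, then
equally between the embeddings of each, then onto atoms — either uniformly or
weighted by the summed input-bit weight covering each atom (the default).
Neurons without any match contribute nothing; the fraction of positive neuron
attribution that survives this filter is reported as
``accounted_positive_fraction``.

Both sharing schemes conserve attribution: atom totals equal the summed bit
attributions of surviving bits (input route) or the summed attributions of
matched neurons (hidden route).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem import Fingerprint, Molecule, make_fragment, match_fragment
from .extraction import SubstructureNetwork, SubstructureRecord
from .ig import IGConfig, ig_input, ig_layer
from .network import TrainedModel, predict

logger = logging.getLogger(__name__)

__all__ = ["Explanation", "explain_ig_input", "explain_ig_hidden", "atom_weights"]


@dataclass
class Explanation:
    """Per-atom attribution for one compound.

    Positive values push toward the toxic class, negative toward nontoxic.
    ``per_neuron`` (hidden route only) lists, per contributing neuron, its
    attribution and the canonical forms of the most specific matched
    fragments; ``accounted_positive_fraction`` is the share of positive neuron
    attribution carried by neurons with at least one match.
    """

    compound_id: str
    atom_values: np.ndarray
    method: str  # "ig_input" | "ig_hidden"
    predicted_proba: float
    accounted_positive_fraction: float | None = None
    per_neuron: list[dict] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        out = {
            "compound_id": self.compound_id,
            "method": self.method,
            "predicted_proba": self.predicted_proba,
            "atom_values": [float(v) for v in self.atom_values],
        }
        if self.method == "ig_hidden":
            out["accounted_positive_fraction"] = self.accounted_positive_fraction
            out["per_neuron"] = self.per_neuron
        return out

    @classmethod
    def from_json_dict(cls, d: dict) -> "Explanation":
        return cls(
            compound_id=d["compound_id"],
            atom_values=np.asarray(d["atom_values"], dtype=float),
            method=d["method"],
            predicted_proba=d["predicted_proba"],
            accounted_positive_fraction=d.get("accounted_positive_fraction"),
            per_neuron=d.get("per_neuron", []),
        )


# ---------------------------------------------------------------------------
# IG_input
# ---------------------------------------------------------------------------


def share_bit_attributions(
    bit_attr: Mapping[int, float],
    mol: Molecule,
    fp: Fingerprint,
    rel_filter: float = 0.01,
) -> np.ndarray:
    """Distribute per-bit attributions onto atoms.

    Bits whose attribution magnitude falls below ``rel_filter`` times the strongest bit are
    dropped.  Each surviving bit's attribution is split equally across its
    distinct environments (bit collisions); within a distinct environment the
    share is split equally across the atoms of all its occurrences.
    """
    atom_values = np.zeros(mol.num_atoms)
    if not bit_attr:
        return atom_values
    max_mag = max(abs(v) for v in bit_attr.values())
    if max_mag == 0:
        return atom_values
    for bit, value in bit_attr.items():
        if abs(value) < rel_filter * max_mag:
            continue
        envs = fp.env_map.get(bit)
        if not envs:
            continue
        # distinct environments = same induced subgraph form and radius;
        # multiple occurrences of one form are a single group
        groups: dict[tuple[int, str], list[frozenset[int]]] = {}
        for env in envs:
            form = make_fragment(mol, env.atom_indices).canonical_form
            groups.setdefault((env.radius, form), []).append(env.atom_indices)
        env_share = value / len(groups)
        for occurrences in groups.values():
            slots = [a for occ in occurrences for a in occ]
            for a in slots:
                atom_values[a] += env_share / len(slots)
    return atom_values


def explain_ig_input(
    model: TrainedModel,
    mol: Molecule,
    fp: Fingerprint,
    cfg: IGConfig | None = None,
) -> Explanation:
    """Atom-level explanation from input-bit integrated gradients."""
    cfg = cfg or IGConfig()
    attr = ig_input(model, fp, cfg)
    bit_attr = {b: float(attr.values[b]) for b in fp.env_map}
    atom_values = share_bit_attributions(bit_attr, mol, fp)
    return Explanation(
        compound_id=mol.id,
        atom_values=atom_values,
        method="ig_input",
        predicted_proba=predict(model, fp),
    )


# ---------------------------------------------------------------------------
# IG_hidden
# ---------------------------------------------------------------------------


def atom_weights(record: SubstructureRecord) -> dict[int, float]:
    """Relative importance of each fragment atom, from the bit weights.

    An atom's raw score is the summed weight of the contributing bits having
    at least one (fragment-contained) environment that covers the atom; scores
    are normalized to sum to 1.  When no atom is covered by any bit — possible
    after cross-compound deduplication — the fallback is uniform.
    """
    atoms = sorted(record.fragment.atom_indices)
    if not atoms:
        raise ValueError("empty fragment")
    raw = {a: 0.0 for a in atoms}
    for bit, weight in record.contributing_bits.items():
        covered: set[int] = set()
        for env in record.bit_env_atoms.get(bit, []):
            covered |= env
        for a in covered & set(atoms):
            raw[a] += weight
    total = sum(raw.values())
    if total <= 0:
        logger.debug(
            "fragment %s: no positive bit coverage; uniform atom weights",
            record.fragment.canonical_form,
        )
        return {a: 1.0 / len(atoms) for a in atoms}
    return {a: v / total for a, v in raw.items()}


def _matched_most_specific(
    network: SubstructureNetwork, mol: Molecule
) -> list[tuple[int, list[dict[int, int]]]]:
    """Match the hierarchy root-down; return the most specific matched nodes.

    A node is tested only when all its parents matched; the matched set is
    reduced to nodes with no matched child.
    """
    matched: dict[int, list[dict[int, int]]] = {}
    order = list(range(len(network.records)))
    # process in topological order: parents before children (parent lists are
    # indices into records; a simple Kahn pass)
    indeg = {i: len(network.parents.get(i, [])) for i in order}
    queue = [i for i in order if indeg[i] == 0]
    topo: list[int] = []
    while queue:
        i = queue.pop()
        topo.append(i)
        for c in network.children.get(i, []):
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    for i in topo:
        parents = network.parents.get(i, [])
        if any(p not in matched for p in parents):
            continue
        embeddings = match_fragment(network.records[i].fragment, mol)
        if embeddings:
            matched[i] = embeddings
    most_specific = [
        (i, embs)
        for i, embs in matched.items()
        if not any(c in matched for c in network.children.get(i, []))
    ]
    return sorted(most_specific)


def distribute_neuron_attributions(
    attributions: Sequence[float] | np.ndarray,
    networks: Mapping[int, SubstructureNetwork],
    mol: Molecule,
    weighted: bool = True,
) -> tuple[np.ndarray, float, list[dict]]:
    """Share neuron attributions over matched substructures onto atoms.

    Returns (atom values, accounted positive fraction, per-neuron breakdown).
    The neuron attribution is split equally between its most specific matched
    fragments, then equally between the embeddings of each fragment, then onto
    atoms — uniformly, or in proportion to the covering bit weights.
    """
    attributions = np.asarray(attributions, dtype=float)
    atom_values = np.zeros(mol.num_atoms)
    per_neuron: list[dict] = []
    pos_total = float(attributions[attributions > 0].sum())
    pos_matched = 0.0
    for n, a in enumerate(attributions):
        network = networks.get(n)
        if network is None or len(network) == 0:
            continue
        hits = _matched_most_specific(network, mol)
        if not hits:
            continue
        if a > 0:
            pos_matched += float(a)
        frag_share = float(a) / len(hits)
        for i, embeddings in hits:
            record = network.records[i]
            emb_share = frag_share / len(embeddings)
            if weighted:
                w = atom_weights(record)
            else:
                w = {
                    at: 1.0 / record.fragment.num_atoms
                    for at in record.fragment.atom_indices
                }
            for emb in embeddings:
                for frag_atom, target_atom in emb.items():
                    atom_values[target_atom] += emb_share * w[frag_atom]
        per_neuron.append(
            {
                "neuron": n,
                "attribution": float(a),
                "matched_fragments": [
                    network.records[i].fragment.canonical_form for i, _ in hits
                ],
            }
        )
    accounted = pos_matched / pos_total if pos_total > 0 else 0.0
    return atom_values, accounted, per_neuron


def explain_ig_hidden(
    model: TrainedModel,
    mol: Molecule,
    fp: Fingerprint,
    networks: Mapping[int, SubstructureNetwork],
    cfg: IGConfig | None = None,
    weighted: bool = True,
    layer: int = 1,
) -> Explanation:
    """Atom-level explanation from hidden-neuron integrated gradients."""
    cfg = cfg or IGConfig()
    for net in networks.values():
        if len(net) and net.neuron[0] != layer:
            raise ValueError(
                f"substructure networks were mined for layer {net.neuron[0]}, "
                f"explanation requested for layer {layer}"
            )
    attr = ig_layer(model, fp, layer, cfg)
    atom_values, accounted, per_neuron = distribute_neuron_attributions(
        attr.values, networks, mol, weighted=weighted
    )
    return Explanation(
        compound_id=mol.id,
        atom_values=atom_values,
        method="ig_hidden",
        predicted_proba=predict(model, fp),
        accounted_positive_fraction=accounted,
        per_neuron=per_neuron,
    )
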