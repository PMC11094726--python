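"""Atom-level attribution sharing: the bit->environment->atom route, the
neuron->substructure->atom route, weighting and conservation."""

import numpy as np
import pytest

from molscope.attribution import (
    atom_weights,
    distribute_neuron_attributions,
    explain_ig_hidden,
    explain_ig_input,
    share_bit_attributions,
)
from molscope.chem import (
    AtomEnvironment,
    Fingerprint,
    Molecule,
    make_fragment,
    morgan_fingerprint,
)
from molscope.extraction import SubstructureRecord, build_hierarchy
from molscope.ig import IGConfig, ig_input, ig_layer
from molscope.network import NetConfig, TrainedModel


def fp_with_envs(env_map, n_bits=64):
    bits = np.zeros(n_bits, dtype=np.uint8)
    for b in env_map:
        bits[b] = 1
    return Fingerprint(bits=bits, env_map=env_map, radius=1, n_bits=n_bits)


# ---------------------------------------------------------------------------
# IG_input sharing
# ---------------------------------------------------------------------------


def test_single_environment_shares_equally():
    # one bit with attribution 0.16 over a single 4-atom environment:
    # each atom receives 0.04
    mol = Molecule.from_smiles("CCCCCCCCCC", "decane")
    env_map = {7: [AtomEnvironment(1, 1, frozenset({0, 1, 2, 3}), frozenset())]}
    out = share_bit_attributions({7: 0.16}, mol, fp_with_envs(env_map))
    assert out[:4] == pytest.approx([0.04] * 4)
    assert out[4:].sum() == 0.0


def test_one_percent_filter_drops_weak_bits():
    mol = Molecule.from_smiles("CCCC", "butane")
    env_map = {
        1: [AtomEnvironment(0, 0, frozenset({0}), frozenset())],
        2: [AtomEnvironment(1, 0, frozenset({1}), frozenset())],
    }
    out = share_bit_attributions({1: 1.0, 2: 0.0001}, mol, fp_with_envs(env_map))
    assert out[0] == pytest.approx(1.0)
    assert out[1] == 0.0


def test_collision_and_occurrences_share_hierarchically():
    """A bit with two distinct environments (one of 4 atoms, one single-atom
    with five occurrences): half the attribution per distinct environment,
    then equal split over that environment's atoms across occurrences."""
    mol = Molecule.from_smiles("CCCCCCCCCC", "decane")
    A = 0.8
    env_map = {
        3: [
            AtomEnvironment(1, 1, frozenset({0, 1, 2, 3}), frozenset()),
            AtomEnvironment(4, 0, frozenset({4}), frozenset()),
            AtomEnvironment(5, 0, frozenset({5}), frozenset()),
            AtomEnvironment(6, 0, frozenset({6}), frozenset()),
            AtomEnvironment(7, 0, frozenset({7}), frozenset()),
            AtomEnvironment(8, 0, frozenset({8}), frozenset()),
        ]
    }
    out = share_bit_attributions({3: A}, mol, fp_with_envs(env_map))
    assert out[:4] == pytest.approx([A / 8] * 4)  # A/2 over 4 atoms
    assert out[4:9] == pytest.approx([A / 10] * 5)  # A/2 over 5 occurrences
    assert out.sum() == pytest.approx(A)


def test_ig_input_conservation_on_real_model():
    """Atom totals equal the summed attributions of surviving bits."""
    rng = np.random.default_rng(4)
    mol = Molecule.from_smiles("O=[N+]([O-])c1ccc(CCl)cc1", "m")
    fp = morgan_fingerprint(mol, n_bits=256)
    cfg0 = NetConfig(n_bits=256, hidden_size=8, dropout=0.0, l2=0.0)
    model = TrainedModel.from_weights(
        [rng.normal(0, 0.2, (256, 8)), rng.normal(0, 0.5, (8, 1))],
        [rng.normal(0, 0.1, 8), np.zeros(1)],
        cfg0,
    )
    exp = explain_ig_input(model, mol, fp, IGConfig(m=100))
    attr = ig_input(model, fp, IGConfig(m=100))
    bit_attr = {b: attr.values[b] for b in fp.env_map}
    max_mag = max(abs(v) for v in bit_attr.values())
    surviving = sum(v for v in bit_attr.values() if abs(v) >= 0.01 * max_mag)
    assert exp.atom_values.sum() == pytest.approx(surviving, abs=1e-12)
    assert exp.method == "ig_input"


# ---------------------------------------------------------------------------
# atom weights
# ---------------------------------------------------------------------------


def _record(mol, atoms, contributing, env_atoms):
    return SubstructureRecord(
        fragment=make_fragment(mol, atoms),
        contributing_bits=contributing,
        bit_env_atoms=env_atoms,
        neuron=(1, 0),
    )


def test_atom_weights_single_covering_bit_is_uniform():
    mol = Molecule.from_smiles("CCCC", "m")
    rec = _record(mol, {0, 1, 2}, {5: 0.7}, {5: [frozenset({0, 1, 2})]})
    w = atom_weights(rec)
    assert w == {0: pytest.approx(1 / 3), 1: pytest.approx(1 / 3), 2: pytest.approx(1 / 3)}


def test_atom_weights_proportional_to_bit_coverage():
    # bits w=0.2 on atoms {1,2} and w=0.1 on atoms {2,3}:
    # raw (0.2, 0.3, 0.1) -> normalized (1/3, 1/2, 1/6)
    mol = Molecule.from_smiles("CCCC", "m")
    rec = _record(
        mol,
        {1, 2, 3},
        {5: 0.2, 6: 0.1},
        {5: [frozenset({1, 2})], 6: [frozenset({2, 3})]},
    )
    w = atom_weights(rec)
    assert w[1] == pytest.approx(1 / 3)
    assert w[2] == pytest.approx(1 / 2)
    assert w[3] == pytest.approx(1 / 6)
    assert sum(w.values()) == pytest.approx(1.0)


def test_atom_weights_fallback_uniform_when_uncovered():
    mol = Molecule.from_smiles("CCCC", "m")
    rec = _record(mol, {0, 1}, {5: 0.2}, {})
    assert atom_weights(rec) == {0: 0.5, 1: 0.5}


# ---------------------------------------------------------------------------
# IG_hidden sharing
# ---------------------------------------------------------------------------


def test_equal_sharing_worked_example(nitrobenzene):
    """A neuron attribution of 0.24 over one matched 4-atom substructure
    (nitro + attached aromatic carbon), unweighted: 0.06 per atom."""
    rec = _record(nitrobenzene, {0, 1, 2, 3}, {5: 1.0}, {5: [frozenset({0, 1, 2, 3})]})
    net = build_hierarchy([rec])
    out, accounted, per_neuron = distribute_neuron_attributions(
        [0.24], {0: net}, nitrobenzene, weighted=False
    )
    assert out[[0, 1, 2, 3]] == pytest.approx([0.06] * 4)
    assert out.sum() == pytest.approx(0.24)
    assert accounted == pytest.approx(1.0)


def test_two_neuron_sharing_with_multiple_embeddings():
    """+0.3 on a 3-atom fragment matched once gives +0.1 per atom; -0.1 on a
    2-atom fragment matched twice gives -0.05 per embedding, -0.025 per atom."""
    mol = Molecule.from_smiles("O=[N+]([O-])c1ccc(Cl)cc1Cl", "m")
    nitro = _record(mol, {0, 1, 2}, {1: 1.0}, {1: [frozenset({0, 1, 2})]})
    cl_pos = [a.GetIdx() for a in mol.rdmol.GetAtoms() if a.GetSymbol() == "Cl"]
    c_of = lambda cl: mol.rdmol.GetAtomWithIdx(cl).GetNeighbors()[0].GetIdx()
    clc = _record(mol, {cl_pos[0], c_of(cl_pos[0])}, {2: 1.0},
                  {2: [frozenset({cl_pos[0], c_of(cl_pos[0])})]})
    nets = {0: build_hierarchy([nitro]), 1: build_hierarchy([clc])}
    out, accounted, _ = distribute_neuron_attributions(
        [0.3, -0.1], nets, mol, weighted=False
    )
    assert out[[0, 1, 2]] == pytest.approx([0.1] * 3)
    touched = {cl_pos[0], c_of(cl_pos[0]), cl_pos[1], c_of(cl_pos[1])}
    for a in touched:
        assert out[a] == pytest.approx(-0.025)
    assert out.sum() == pytest.approx(0.3 - 0.1)
    assert accounted == pytest.approx(1.0)  # the negative neuron does not count


def test_most_specific_matched_fragment_wins(nitrobenzene):
    """When parent and child both match, only the child (most specific) is
    used; parents gate the traversal."""
    parent = _record(nitrobenzene, {0, 1, 2}, {1: 1.0}, {1: [frozenset({0, 1, 2})]})
    child = _record(nitrobenzene, {0, 1, 2, 3}, {1: 1.0}, {1: [frozenset({0, 1, 2, 3})]})
    net = build_hierarchy([parent, child])
    out, _, per_neuron = distribute_neuron_attributions(
        [0.4], {0: net}, nitrobenzene, weighted=False
    )
    assert per_neuron[0]["matched_fragments"] == [child.fragment.canonical_form]
    assert out[[0, 1, 2, 3]] == pytest.approx([0.1] * 4)


def test_no_match_means_zero_and_unaccounted(nitrobenzene):
    halide_src = Molecule.from_smiles("CCCl", "src")
    rec = _record(halide_src, {0, 1, 2}, {1: 1.0}, {1: [frozenset({0, 1, 2})]})
    net = build_hierarchy([rec])
    out, accounted, per_neuron = distribute_neuron_attributions(
        [0.7], {0: net}, nitrobenzene, weighted=False
    )
    assert not out.any()
    assert accounted == 0.0
    assert per_neuron == []


def test_weighted_sharing_uses_bit_coverage(nitrobenzene):
    # one bit covers only the N and O atoms: the aromatic C gets zero weight
    rec = _record(nitrobenzene, {0, 1, 2, 3}, {1: 0.9}, {1: [frozenset({0, 1, 2})]})
    net = build_hierarchy([rec])
    out, _, _ = distribute_neuron_attributions([0.3], {0: net}, nitrobenzene, weighted=True)
    assert out[[0, 1, 2]] == pytest.approx([0.1] * 3)
    assert out[3] == 0.0
    assert out.sum() == pytest.approx(0.3)


def test_explain_ig_hidden_conservation(nitrobenzene):
    """End to end on a real model: atom totals equal the summed layer
    attributions of the matched neurons, and the accounted fraction is a
    proper fraction."""
    rng = np.random.default_rng(8)
    fp = morgan_fingerprint(nitrobenzene, n_bits=128)
    model = TrainedModel.from_weights(
        [rng.normal(0, 0.3, (128, 4)), rng.normal(0, 0.8, (4, 1))],
        [np.abs(rng.normal(0, 0.2, 4)), np.zeros(1)],
        NetConfig(n_bits=128, hidden_size=4, dropout=0.0),
    )
    rec = _record(nitrobenzene, {0, 1, 2, 3}, {1: 1.0}, {1: [frozenset({0, 1, 2, 3})]})
    networks = {0: build_hierarchy([rec]), 2: build_hierarchy([rec])}
    exp = explain_ig_hidden(model, nitrobenzene, fp, networks, IGConfig(m=100))
    attr = ig_layer(model, fp, 1, IGConfig(m=100))
    matched = [p["neuron"] for p in exp.per_neuron]
    assert exp.atom_values.sum() == pytest.approx(
        sum(attr.values[n] for n in matched), abs=1e-10
    )
    assert 0.0 <= exp.accounted_positive_fraction <= 1.0
    d = exp.to_json_dict()
    assert d["method"] == "ig_hidden" and len(d["atom_values"]) == nitrobenzene.num_atoms
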