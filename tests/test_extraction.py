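"""Substructure mining: selection arithmetic, the engineered aromatic-nitro
fixture, pruning/capping and the fragment hierarchy."""

import json

import numpy as np
import pytest

from molscope.chem import (
    Molecule,
    canonical_subgraph_smiles,
    make_fragment,
    match_fragment,
    morgan_fingerprint,
)
from molscope.extraction import (
    ExtractionConfig,
    SubstructureNetwork,
    SubstructureRecord,
    build_hierarchy,
    extract_neuron_substructures,
    select_activating_compounds,
    select_top_bits,
)
from molscope.network import NetConfig, TrainedModel

N_BITS = 2048


# ---------------------------------------------------------------------------
# selection arithmetic
# ---------------------------------------------------------------------------


def test_equal_activations_select_nothing():
    sel, thr = select_activating_compounds([1.0] * 5, ExtractionConfig())
    assert sel == set() and thr == pytest.approx(1.0)  # strict inequality


def test_activation_threshold_arithmetic():
    # [0]*9 + [10]: mean 1, population SD 3, threshold 7
    sel, thr = select_activating_compounds([0.0] * 9 + [10.0], ExtractionConfig())
    assert thr == pytest.approx(7.0)
    assert sel == {9}


def test_zero_sd_multiplier_selects_above_mean():
    cfg = ExtractionConfig(thresh_compound=0.0)
    sel, thr = select_activating_compounds([0.0, 1.0, 2.0, 3.0], cfg)
    assert thr == pytest.approx(1.5)
    assert sel == {2, 3}


def test_top_bits_distinct_weights():
    rng = np.random.default_rng(0)
    w = rng.permutation(N_BITS).astype(float)  # all distinct
    sel = select_top_bits(w, ExtractionConfig())
    assert len(sel) == 205  # ceil(0.1 * 2048)
    assert min(w[list(sel)]) > max(w[b] for b in range(N_BITS) if b not in sel)


def test_top_bits_all_equal_keeps_everything():
    sel = select_top_bits(np.ones(100), ExtractionConfig())
    assert len(sel) == 100


def test_top_bits_small_vector():
    sel = select_top_bits(np.arange(1.0, 11.0), ExtractionConfig())
    assert sel == {9}


def test_selection_monotonicity():
    rng = np.random.default_rng(1)
    acts = rng.random(50)
    w = rng.normal(size=200)
    prev_c = None
    for tc in (0.0, 1.0, 2.0, 3.0):
        sel, _ = select_activating_compounds(acts, ExtractionConfig(thresh_compound=tc))
        if prev_c is not None:
            assert sel <= prev_c  # raising the cut never enlarges the set
        prev_c = sel
    prev_b = None
    for tb in (0.05, 0.1, 0.5, 1.0):
        sel = select_top_bits(w, ExtractionConfig(thresh_bits=tb))
        if prev_b is not None:
            assert prev_b <= sel  # a larger fraction never shrinks the set
        prev_b = sel


# ---------------------------------------------------------------------------
# engineered aromatic-nitro fixture
# ---------------------------------------------------------------------------


def nitro_fixture():
    """Three aromatic-nitro compounds among 97 inert ones, and a model whose
    neuron 0 puts high weight on exactly two nitro-group bits (the N-centered
    and the =O-centered radius-1 environments)."""
    nitro_smiles = [
        "O=[N+]([O-])c1ccccc1",
        "Cc1ccc(cc1)[N+](=O)[O-]",
        "O=[N+]([O-])c1cccc2ccccc12",
    ]
    mols = [Molecule.from_smiles(s, f"nitro{i}") for i, s in enumerate(nitro_smiles)]
    mols += [Molecule.from_smiles("c1ccccc1", f"bg{i}") for i in range(97)]
    fps = [morgan_fingerprint(m) for m in mols]
    ref = fps[0]
    rd = mols[0].rdmol
    b_nitro = b_oxo = None
    for bit, envs in ref.env_map.items():
        for env in envs:
            sym = rd.GetAtomWithIdx(env.center).GetSymbol()
            if env.radius == 1 and sym == "N":
                b_nitro = bit
            if env.radius == 1 and sym == "O" and env.atom_indices == frozenset({0, 1}):
                b_oxo = bit
    assert b_nitro is not None and b_oxo is not None
    for fp in fps[1:3]:  # both bits present in every nitro compound
        assert b_nitro in fp.env_map and b_oxo in fp.env_map
    on_anywhere = set().union(*(fp.env_map.keys() for fp in fps))
    fillers = [b for b in range(N_BITS) if b not in on_anywhere][:203]
    w = np.full(N_BITS, -0.001)
    w[fillers] = 0.001 + 0.000001 * np.arange(203)
    w[b_nitro] = 1.0
    w[b_oxo] = 0.8
    weights0 = np.zeros((N_BITS, 2))
    weights0[:, 0] = w
    model = TrainedModel.from_weights(
        [weights0, np.array([[1.0], [1.0]])],
        [np.zeros(2), np.zeros(1)],
        NetConfig(n_bits=N_BITS, hidden_size=2, dropout=0.0),
    )
    return model, list(zip(mols, fps))


def test_nitro_fixture_yields_single_nitro_fragment(nitrobenzene):
    model, training = nitro_fixture()
    net = extract_neuron_substructures(model, 1, 0, training)
    assert len(net) == 1
    rec = net.records[0]
    expected = canonical_subgraph_smiles(nitrobenzene.rdmol, {0, 1, 2, 3})
    assert rec.fragment.canonical_form == expected  # nitro + attached aromatic C
    assert rec.fragment.num_atoms == 4
    assert set(rec.contributing_bits.values()) == {1.0, 0.8}
    assert rec.summed_weight == pytest.approx(1.8)
    assert rec.summed_weight >= net.activation_threshold  # thresh_weight = 1


def test_constant_neuron_gives_empty_network():
    model, training = nitro_fixture()
    net = extract_neuron_substructures(model, 1, 1, training)  # all-zero weights
    assert len(net) == 0


def test_extraction_restricted_to_first_layer():
    model, training = nitro_fixture()
    with pytest.raises(ValueError):
        extract_neuron_substructures(model, 2, 0, training)


def test_cap_stops_acceptance(monkeypatch, nitrobenzene):
    import molscope.extraction as ex

    model, training = nitro_fixture()
    pieces = [
        frozenset({0, 1, 2}),
        frozenset({3, 4, 5, 6, 7, 8}),
        frozenset({1, 2}),
    ]
    counter = {"i": 0}

    def fake_fragments(mol, fp, intent, weights):
        frag = make_fragment(nitrobenzene, pieces[counter["i"] % 3])
        counter["i"] += 1
        bits = dict(enumerate([1.0 + 0.1 * counter["i"]]))
        return [(frag, bits, {0: [frag.atom_indices]})]

    monkeypatch.setattr(ex, "_fragments_for_compound", fake_fragments)
    cfg = ExtractionConfig(max_substructures=2)
    net = extract_neuron_substructures(model, 1, 0, training, cfg)
    assert len(net) <= 2


def test_generic_duplicate_pruning():
    """A fragment is dropped when a smaller accepted fragment has the same
    summed weight."""
    mol = Molecule.from_smiles("O=[N+]([O-])c1ccccc1", "m")
    small = SubstructureRecord(
        fragment=make_fragment(mol, {0, 1, 2}),
        contributing_bits={5: 1.8},
        bit_env_atoms={5: [frozenset({0, 1, 2})]},
        neuron=(1, 0),
    )
    # the pruning rule itself lives in the extraction loop; exercised via the
    # fixture by replaying the same concept twice would be identical anyway,
    # so check the primitive it rests on:
    big = make_fragment(mol, {0, 1, 2, 3})
    from molscope.chem import is_strict_subfragment

    assert is_strict_subfragment(small.fragment, big)
    assert small.summed_weight == pytest.approx(1.8)


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------


def _rec(mol, atoms, weight=1.0):
    frag = make_fragment(mol, atoms)
    return SubstructureRecord(
        fragment=frag,
        contributing_bits={0: weight},
        bit_env_atoms={0: [frag.atom_indices]},
        neuron=(1, 0),
    )


def test_hierarchy_single_node():
    mol = Molecule.from_smiles("O=[N+]([O-])c1ccccc1", "m")
    net = build_hierarchy([_rec(mol, {0, 1, 2})])
    assert len(net) == 1 and net.roots == [0]
    assert net.children.get(0, []) == []


def test_hierarchy_generic_above_specific():
    mol = Molecule.from_smiles("O=[N+]([O-])c1ccccc1", "m")
    nitro = _rec(mol, {0, 1, 2, 3})
    whole = _rec(mol, set(range(9)))
    net = build_hierarchy([nitro, whole])
    assert net.children[0] == [1] and net.parents[1] == [0]
    assert net.roots == [0]


def test_hierarchy_disjoint_chemistries_make_two_roots():
    mol = Molecule.from_smiles("O=[N+]([O-])c1ccccc1CCl", "m")
    nitro = _rec(mol, {0, 1, 2})
    halide = _rec(mol, {9, 10})
    net = build_hierarchy([nitro, halide])
    assert sorted(net.roots) == [0, 1]
    assert not any(net.children.get(i) for i in (0, 1))


def test_hierarchy_transitive_reduction():
    mol = Molecule.from_smiles("O=[N+]([O-])c1ccccc1", "m")
    chain = [_rec(mol, {1, 2}), _rec(mol, {0, 1, 2}), _rec(mol, {0, 1, 2, 3})]
    net = build_hierarchy(chain)
    assert net.children[0] == [1] and net.children[1] == [2]
    assert net.children.get(2, []) == []  # no 0 -> 2 shortcut


def test_network_serialization_round_trip(nitrobenzene):
    model, training = nitro_fixture()
    net = extract_neuron_substructures(model, 1, 0, training)
    data = json.loads(json.dumps(net.to_json_dict(ExtractionConfig())))
    back = SubstructureNetwork.from_json_dict(data)
    assert [r.fragment.canonical_form for r in back.records] == [
        r.fragment.canonical_form for r in net.records
    ]
    assert back.children == net.children
    assert back.records[0].contributing_bits == net.records[0].contributing_bits
    # reloaded fragments still match compounds
    assert len(match_fragment(back.records[0].fragment, nitrobenzene)) == 1
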