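"""Synthetic alert-labeled molecular libraries.

Compounds are assembled by attaching decoration fragments to scaffolds; a
configurable set of SMARTS-defined structural alerts (a small vocabulary of
well-known mutagenicity toxicophores: aromatic nitro, epoxide, aziridine,
nitrosamine, primary aromatic amine, alkyl/acyl halide, nitrogen mustard)
determines the binary label: a compound is positive iff at least one alert
matches.  The matched atoms are recorded per alert as ground truth, which
makes every downstream stage — training, substructure mining, atom-level
attribution and its ROC-AUC evaluation — testable without proprietary data.

Labels are a deterministic function of structure, so the classification task
is exactly learnable; optional label noise flips labels after assignment.
Alert rules may carry exception patterns (a match of the exception silences
the rule), which creates deactivated analogues for exercising explanations of
negative predictions.

The generator emulates the shape of an assay-style SAR library (one scaffold,
a few substituents, ~50% prevalence); it does not attempt realistic property
distributions, ring-system diversity or activity cliffs, and molecules are
small (roughly 6-30 heavy atoms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem import Molecule

__all__ = ["AlertRule", "LibraryConfig", "generate_library", "DEFAULT_ALERTS"]


@dataclass(frozen=True)
class AlertRule:
    """A structural alert: SMARTS pattern plus optional deactivating exceptions."""

    alert_id: str
    pattern: str
    description: str = ""
    exceptions: tuple[str, ...] = ()

    def compiled(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.pattern)
        if q is None:
            raise ValueError(f"alert {self.alert_id}: invalid SMARTS {self.pattern!r}")
        return q

    def match_atoms(self, rdmol: Chem.Mol) -> frozenset[int]:
        """Union of atoms over all matches; empty when the rule does not fire
        (or an exception pattern silences it)."""
        for exc in self.exceptions:
            eq = Chem.MolFromSmarts(exc)
            if eq is not None and rdmol.HasSubstructMatch(eq):
                return frozenset()
        atoms: set[int] = set()
        for m in rdmol.GetSubstructMatches(self.compiled()):
            atoms |= set(m)
        return frozenset(atoms)


DEFAULT_ALERTS: list[AlertRule] = [
    AlertRule("aromatic_nitro", "[c][N+](=O)[O-]", "nitro group on an aromatic ring"),
    AlertRule("epoxide", "[C;r3]1[C;r3][O;r3]1", "three-membered cyclic ether"),
    AlertRule("aziridine", "[C;r3]1[C;r3][N;r3]1", "three-membered cyclic amine"),
    AlertRule("nitrosamine", "[NX3][NX2]=O", "N-nitroso group"),
    AlertRule("aromatic_amine", "[NX3;H2][c]", "primary aromatic amine"),
    AlertRule("alkyl_halide", "[CX4][Cl,Br,I]", "sp3 carbon bearing a halogen"),
    AlertRule("acyl_halide", "[CX3](=O)[Cl,Br]", "acid halide"),
    AlertRule(
        "n_mustard",
        "[NX3]([CH2][CH2][Cl,Br])[CH2][CH2][Cl,Br]",
        "bis(2-haloethyl)amine",
    ),
]

# scaffold SMILES; decorations are (smiles, attachment atom index, needs_aromatic)
DEFAULT_SCAFFOLDS: list[str] = [
    "c1ccccc1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "c1ccoc1",
    "c1ccsc1",
    "C1CCCCC1",
    "C1CCOCC1",
    "CCCCCC",
]

# alert-bearing decorations: attaching atom 0 to the scaffold plants the motif
ALERT_DECORATIONS: list[tuple[str, int, bool]] = [
    ("[N+](=O)[O-]", 0, True),  # aromatic nitro (only on aromatic scaffolds)
    ("C1CO1", 0, False),        # epoxide
    ("C1CN1", 0, False),        # aziridine
    ("N(C)N=O", 0, False),      # nitrosamine
    ("N", 0, True),             # primary aromatic amine
    ("CCl", 0, False),          # alkyl halide
    ("C(=O)Cl", 0, False),      # acyl halide
    ("N(CCCl)CCCl", 0, False),  # nitrogen mustard
]

BENIGN_DECORATIONS: list[tuple[str, int, bool]] = [
    ("C", 0, False),
    ("CC", 0, False),
    ("C(C)C", 0, False),
    ("O", 0, False),
    ("OC", 0, False),
    ("F", 0, False),
    ("C(F)(F)F", 0, False),
    ("C#N", 0, False),
    ("C(=O)OC", 0, False),
    ("S(C)(=O)=O", 0, False),
    ("C(=O)C", 0, False),
]


@dataclass
class LibraryConfig:
    """Study conditions of a generated library.

    Defaults: 2000 compounds, the first four default alerts planted
    (aromatic nitro, epoxide, aziridine, nitrosamine), a 50% positive target
    and no label noise.
    """

    n_compounds: int = 2000
    alert_rules: Sequence[AlertRule] = field(
        default_factory=lambda: list(DEFAULT_ALERTS[:4])
    )
    positive_fraction: float = 0.5
    scaffolds: Sequence[str] = field(default_factory=lambda: list(DEFAULT_SCAFFOLDS))
    decorations: Sequence[tuple[str, int, bool]] = field(
        default_factory=lambda: list(BENIGN_DECORATIONS)
    )
    alert_decorations: Sequence[tuple[str, int, bool]] = field(
        default_factory=lambda: list(ALERT_DECORATIONS[:4])
    )
    label_noise: float = 0.0
    seed: int = 0
    max_retries: int = 30

    def __post_init__(self):
        if not self.alert_rules:
            raise ValueError("need at least one alert rule")
        if not self.scaffolds or not self.decorations:
            raise ValueError("scaffold and decoration sets must be non-empty")
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must be in [0, 1)")


def _open_positions(rdmol: Chem.Mol, aromatic_only: bool = False) -> list[int]:
    """Carbon atoms with at least one hydrogen to replace."""
    out = []
    for atom in rdmol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetTotalNumHs() < 1:
            continue
        if aromatic_only and not atom.GetIsAromatic():
            continue
        out.append(atom.GetIdx())
    return out


def _attach(scaffold: Chem.Mol, decorations: list[tuple[Chem.Mol, int, int]]) -> Chem.Mol | None:
    """Bond each decoration's attachment atom to a chosen scaffold position."""
    combined = Chem.RWMol(scaffold)
    for deco, attach_idx, scaffold_pos in decorations:
        offset = combined.GetNumAtoms()
        combined.InsertMol(deco)
        combined.AddBond(scaffold_pos, offset + attach_idx, Chem.BondType.SINGLE)
    mol = combined.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _assemble(
    rng: np.random.Generator, cfg: LibraryConfig, want_positive: bool
) -> Chem.Mol | None:
    scaffold_smi = cfg.scaffolds[rng.integers(len(cfg.scaffolds))]
    scaffold = Chem.MolFromSmiles(scaffold_smi)
    n_deco = int(rng.integers(1, 4))
    chosen: list[tuple[Chem.Mol, int, int]] = []
    pool = list(cfg.decorations)
    alert_pool = list(cfg.alert_decorations)
    used_positions: set[int] = set()
    for k in range(n_deco):
        # positives carry one alert motif; a second one is rare (as in real
        # alert-labeled data, where most positives match a single alert)
        plant_alert = want_positive and (k == 0 or rng.random() < 0.05)
        src = alert_pool if plant_alert else pool
        smi, attach_idx, needs_aromatic = src[rng.integers(len(src))]
        positions = [
            p
            for p in _open_positions(scaffold, aromatic_only=needs_aromatic)
            if p not in used_positions
        ]
        if not positions:
            if plant_alert:
                return None  # e.g. aromatic-nitro decoration on an aliphatic scaffold
            continue
        pos = int(positions[rng.integers(len(positions))])
        used_positions.add(pos)
        chosen.append((Chem.MolFromSmiles(smi), attach_idx, pos))
    if not chosen:
        return None
    return _attach(scaffold, chosen)


def generate_library(cfg: LibraryConfig) -> list[Molecule]:
    """Generate a labeled library; the same seed reproduces it exactly.

    Each compound's label is 1 iff at least one configured alert rule matches
    (before optional label noise); ``alert_hits`` stores, per fired rule, the
    union of its matched atoms.
    """
    rng = np.random.default_rng(cfg.seed)
    # separate stream for label noise, so noise does not perturb the structures
    noise_rng = np.random.default_rng([cfg.seed, 1])
    molecules: list[Molecule] = []
    shortfall = 0
    for i in range(cfg.n_compounds):
        want_positive = bool(rng.random() < cfg.positive_fraction)
        accepted: Chem.Mol | None = None
        hits: list[tuple[str, frozenset[int]]] = []
        for _ in range(cfg.max_retries):
            rdmol = _assemble(rng, cfg, want_positive)
            if rdmol is None:
                continue
            hits = [
                (rule.alert_id, atoms)
                for rule in cfg.alert_rules
                if (atoms := rule.match_atoms(rdmol))
            ]
            if bool(hits) == want_positive:
                accepted = rdmol
                break
            accepted = accepted or rdmol  # keep something as best effort
        if accepted is None:
            continue
        final_hits = [
            (rule.alert_id, atoms)
            for rule in cfg.alert_rules
            if (atoms := rule.match_atoms(accepted))
        ]
        if bool(final_hits) != want_positive:
            shortfall += 1
        label = int(bool(final_hits))
        if cfg.label_noise > 0 and noise_rng.random() < cfg.label_noise:
            label = 1 - label
        molecules.append(
            Molecule(
                id=f"C{i:05d}",
                rdmol=accepted,
                label=label,
                alert_hits=final_hits,
            )
        )
    if shortfall:
        warnings.warn(
            f"{shortfall} compounds could not be assembled with the requested "
            "label; realized positive fraction may drift from the target"
        )
    return molecules
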