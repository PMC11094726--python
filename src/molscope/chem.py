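"""Molecular I/O, circular fingerprints with bit->atom-environment provenance,
fragments and subgraph matching.

The central bridge between the feature space of the network (hashed Morgan
fingerprint bits) and chemistry is the environment map: for every on-bit the
set of atom environments (center atom + bonds within a radius) that hashed to
it.  Fragments are connected induced subgraphs of a source molecule; they are
compared by a canonical SMILES of the induced subgraph and matched into other
molecules respecting element, aromaticity, formal charge and bond order.

Inputs are expected to be pre-standardized: SMILES are taken as given and only
RDKit sanitization / aromaticity perception is applied (no salt stripping,
tautomer canonicalization or charge neutralization).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "AtomEnvironment",
    "Fingerprint",
    "Fragment",
    "ParseResult",
    "parse_dataset",
    "write_dataset",
    "morgan_fingerprint",
    "canonical_subgraph_smiles",
    "make_fragment",
    "fragment_from_atoms",
    "match_fragment",
    "is_subfragment",
    "is_strict_subfragment",
]


class DatasetError(ValueError):
    """Fatal problem with an input dataset (unreadable, empty, no valid records)."""


# ---------------------------------------------------------------------------
# Molecule
# ---------------------------------------------------------------------------


@dataclass
class Molecule:
    """A parsed structure with optional binary label and ground-truth alert atoms.

    ``alert_hits`` holds ``(alert_id, atom_indices)`` pairs: the atoms (0-based)
    responsible for each structural alert that fires on the compound.
    """

    id: str
    rdmol: Chem.Mol
    label: int | None = None
    alert_hits: list[tuple[str, frozenset[int]]] = field(default_factory=list)

    @classmethod
    def from_smiles(
        cls,
        smiles: str,
        mol_id: str = "",
        label: int | None = None,
        alert_hits: Sequence[tuple[str, Iterable[int]]] = (),
    ) -> "Molecule":
        rdmol = Chem.MolFromSmiles(smiles)
        if rdmol is None:
            raise ValueError(f"invalid SMILES: {smiles!r}")
        hits = [(str(a), frozenset(int(i) for i in idx)) for a, idx in alert_hits]
        mol = cls(id=mol_id or smiles, rdmol=rdmol, label=label, alert_hits=hits)
        mol._check_alert_indices()
        return mol

    def _check_alert_indices(self) -> None:
        n = self.num_atoms
        for alert_id, idx in self.alert_hits:
            if idx and (min(idx) < 0 or max(idx) >= n):
                raise ValueError(
                    f"alert {alert_id!r}: atom index out of range for {self.id!r}"
                )

    @property
    def num_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def atoms(self) -> list[tuple[str, bool, int]]:
        """(element symbol, aromatic flag, formal charge) per atom, in index order."""
        return [
            (a.GetSymbol(), a.GetIsAromatic(), a.GetFormalCharge())
            for a in self.rdmol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[tuple[int, int], float, bool]]:
        """((i, j), bond order, aromatic flag) per bond."""
        return [
            (
                (b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                b.GetBondTypeAsDouble(),
                b.GetIsAromatic(),
            )
            for b in self.rdmol.GetBonds()
        ]

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)

    def alert_atom_union(self) -> frozenset[int]:
        """Union of atoms over all fired alerts (the ground truth for evaluation)."""
        out: set[int] = set()
        for _, idx in self.alert_hits:
            out |= idx
        return frozenset(out)


# ---------------------------------------------------------------------------
# Dataset parsing
# ---------------------------------------------------------------------------


@dataclass
class ParseResult:
    molecules: list[Molecule]
    n_skipped: int

    def __iter__(self):
        return iter(self.molecules)

    def __len__(self) -> int:
        return len(self.molecules)


def _parse_alert_columns(alert_ids: str, alert_atoms: str) -> list[tuple[str, frozenset[int]]]:
    ids = [a for a in alert_ids.split(";") if a] if alert_ids else []
    atom_groups = [g for g in alert_atoms.split(";")] if alert_atoms else []
    if ids and len(atom_groups) != len(ids):
        raise ValueError("alert_ids and alert_atoms are not aligned")
    hits = []
    for aid, grp in zip(ids, atom_groups):
        idx = frozenset(int(t) for t in grp.split("|") if t != "")
        hits.append((aid, idx))
    return hits


def parse_dataset(path: str | Path, format: str = "smiles-csv") -> ParseResult:
    """Read a compound table into :class:`Molecule` records, preserving order.

    ``smiles-csv`` columns: ``id,smiles,label[,alert_ids,alert_atoms]`` where
    ``alert_atoms`` is a ``;``-separated list of ``|``-joined 0-based atom
    indices aligned with ``alert_ids``.  ``sdf`` reads structures only.
    Invalid records are skipped and counted; zero valid records is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    molecules: list[Molecule] = []
    n_skipped = 0
    if format == "smiles-csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise DatasetError(f"{path}: missing 'smiles' column")
            for i, row in enumerate(reader):
                smiles = (row.get("smiles") or "").strip()
                rdmol = Chem.MolFromSmiles(smiles) if smiles else None
                if rdmol is None:
                    n_skipped += 1
                    continue
                label_s = (row.get("label") or "").strip()
                label = int(float(label_s)) if label_s else None
                try:
                    hits = _parse_alert_columns(
                        (row.get("alert_ids") or "").strip(),
                        (row.get("alert_atoms") or "").strip(),
                    )
                except ValueError:
                    n_skipped += 1
                    continue
                mol = Molecule(
                    id=(row.get("id") or "").strip() or f"record{i}",
                    rdmol=rdmol,
                    label=label,
                    alert_hits=hits,
                )
                try:
                    mol._check_alert_indices()
                except ValueError:
                    n_skipped += 1
                    continue
                molecules.append(mol)
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, rdmol in enumerate(supplier):
            if rdmol is None:
                n_skipped += 1
                continue
            mol_id = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
            molecules.append(Molecule(id=mol_id or f"record{i}", rdmol=rdmol))
    else:
        raise DatasetError(f"unknown format: {format!r}")
    if not molecules:
        raise DatasetError(f"{path}: no valid records")
    return ParseResult(molecules, n_skipped)


def write_dataset(molecules: Iterable[Molecule], path: str | Path) -> None:
    """Write the smiles-csv dialect, including alert annotation columns.

    The canonical SMILES is emitted, so alert atom indices are remapped to the
    atom order a fresh parse of that SMILES produces; a round trip through the
    file preserves which atoms carry each alert.
    """
    import json as _json

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "label", "alert_ids", "alert_atoms"])
        for mol in molecules:
            smiles = Chem.MolToSmiles(mol.rdmol)
            order = _json.loads(
                mol.rdmol.GetProp("_smilesAtomOutputOrder").replace(",]", "]")
            )
            remap = {old: new for new, old in enumerate(order)}
            ids = ";".join(a for a, _ in mol.alert_hits)
            atoms = ";".join(
                "|".join(str(remap[i]) for i in sorted(idx))
                for _, idx in mol.alert_hits
            )
            label = "" if mol.label is None else str(int(mol.label))
            writer.writerow([mol.id, smiles, label, ids, atoms])


# ---------------------------------------------------------------------------
# Morgan fingerprints with environment provenance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomEnvironment:
    """Atoms/bonds within ``radius`` bonds of a center atom."""

    center: int
    radius: int
    atom_indices: frozenset[int]
    bond_indices: frozenset[int]


@dataclass
class Fingerprint:
    """Hashed circular fingerprint plus the bit -> environment multimap.

    ``env_map`` may hold several environments per bit: repeated occurrences of
    the same environment in the molecule, or genuinely different environments
    colliding on the same hash slot.
    """

    bits: np.ndarray  # uint8 vector of length n_bits
    env_map: dict[int, list[AtomEnvironment]]
    radius: int
    n_bits: int

    @property
    def on_bits(self) -> list[int]:
        return sorted(self.env_map)

    def as_input(self) -> np.ndarray:
        return self.bits.astype(np.float64)


def _environment(mol: Chem.Mol, center: int, radius: int) -> AtomEnvironment:
    if radius == 0:
        return AtomEnvironment(center, 0, frozenset({center}), frozenset())
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
    atoms = {center}
    for b in bond_ids:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return AtomEnvironment(center, radius, frozenset(atoms), frozenset(int(b) for b in bond_ids))


def morgan_fingerprint(mol: Molecule, radius: int = 1, n_bits: int = 2048) -> Fingerprint:
    """Morgan/circular fingerprint hashed to ``n_bits``, with provenance.

    Every on-bit is mapped to the full list of atom environments (center,
    radius, atom and bond index sets) that set it.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    bv = gen.GetFingerprint(mol.rdmol, additionalOutput=ao)
    info = ao.GetBitInfoMap()
    bits = np.zeros(n_bits, dtype=np.uint8)
    env_map: dict[int, list[AtomEnvironment]] = {}
    for bit, occurrences in info.items():
        bits[bit] = 1
        env_map[int(bit)] = [
            _environment(mol.rdmol, int(center), int(rad)) for center, rad in occurrences
        ]
    assert bv.GetNumOnBits() == len(env_map)
    return Fingerprint(bits=bits, env_map=env_map, radius=radius, n_bits=n_bits)


def fingerprint_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Stack fingerprints into a float design matrix (n_compounds x n_bits)."""
    return np.stack([fp.as_input() for fp in fps])


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

_BOND_SMARTS = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


@dataclass
class Fragment:
    """Connected induced subgraph of a source molecule.

    Equality / deduplication is by ``canonical_form`` (canonical SMILES of the
    induced subgraph, aromaticity preserved, hydrogens implicit).  The source
    molecule is retained so the fragment can be matched and so subgraph
    relations between fragments can be decided without re-parsing partial
    aromatic SMILES.
    """

    source_id: str
    atom_indices: frozenset[int]
    canonical_form: str
    source_mol: Chem.Mol

    def __post_init__(self):
        self._query: Chem.Mol | None = None

    def __eq__(self, other) -> bool:
        return isinstance(other, Fragment) and self.canonical_form == other.canonical_form

    def __hash__(self) -> int:
        return hash(self.canonical_form)

    @property
    def num_atoms(self) -> int:
        return len(self.atom_indices)

    @property
    def query_atom_order(self) -> list[int]:
        """Source atom indices in the order used to build the query molecule."""
        return sorted(self.atom_indices)

    def query(self) -> Chem.Mol:
        """Query molecule matching on element, aromaticity, charge and bond type."""
        if self._query is None:
            self._query = _build_query(self.source_mol, self.query_atom_order)
        return self._query


def _build_query(mol: Chem.Mol, atom_indices: Sequence[int]) -> Chem.Mol:
    pos = {a: i for i, a in enumerate(atom_indices)}
    rw = Chem.RWMol()
    for a in atom_indices:
        atom = mol.GetAtomWithIdx(a)
        chg = atom.GetFormalCharge()
        chg_s = f"{chg:+d}" if chg else "+0"
        arom = "a" if atom.GetIsAromatic() else "A"
        rw.AddAtom(Chem.AtomFromSmarts(f"[{arom};#{atom.GetAtomicNum()};{chg_s}]"))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in pos and j in pos:
            bidx = rw.AddBond(pos[i], pos[j], bond.GetBondType()) - 1
            rw.ReplaceBond(bidx, Chem.BondFromSmarts(_BOND_SMARTS[bond.GetBondType()]))
    return rw.GetMol()


def _bonds_within(mol: Chem.Mol, atoms: frozenset[int]) -> list[int]:
    return [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms
    ]


def fragment_from_atoms(mol: Molecule, atom_indices: Iterable[int]) -> list[Fragment]:
    """Split an atom set into the connected fragments it induces.

    Returns one :class:`Fragment` per connected component of the induced
    subgraph (neighbouring marked atoms are connected); the union of fragment
    atoms equals the input set.  An empty set yields an empty list.
    """
    atoms = set(int(a) for a in atom_indices)
    if not atoms:
        return []
    n = mol.num_atoms
    if atoms and (min(atoms) < 0 or max(atoms) >= n):
        raise ValueError("atom index out of range")
    adj: dict[int, list[int]] = {a: [] for a in atoms}
    for bond in mol.rdmol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in atoms and j in atoms:
            adj[i].append(j)
            adj[j].append(i)
    seen: set[int] = set()
    fragments: list[Fragment] = []
    for start in sorted(atoms):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        fragments.append(make_fragment(mol, comp))
    return fragments


def canonical_subgraph_smiles(rdmol: Chem.Mol, atoms: Iterable[int]) -> str:
    """Canonical SMILES of the induced subgraph as a standalone graph.

    The subgraph is copied out (element, aromatic flag, formal charge on
    atoms; bond type on bonds; no hydrogens), so isomorphic fragments from
    different source molecules canonicalize to the same string — which is the
    same equivalence the fragment matcher uses.
    """
    atoms = sorted(atoms)
    pos = {a: i for i, a in enumerate(atoms)}
    rw = Chem.RWMol()
    for a in atoms:
        src = rdmol.GetAtomWithIdx(a)
        atom = Chem.Atom(src.GetAtomicNum())
        atom.SetIsAromatic(src.GetIsAromatic())
        atom.SetFormalCharge(src.GetFormalCharge())
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for bond in rdmol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in pos and j in pos:
            rw.AddBond(pos[i], pos[j], bond.GetBondType())
    frag = rw.GetMol()
    frag.UpdatePropertyCache(strict=False)
    return Chem.MolToSmiles(frag)


def make_fragment(mol: Molecule, atoms: Iterable[int]) -> Fragment:
    """Build a fragment from an atom set that is known to be connected."""
    atoms = frozenset(int(a) for a in atoms)
    smi = canonical_subgraph_smiles(mol.rdmol, atoms)
    return Fragment(
        source_id=mol.id, atom_indices=atoms, canonical_form=smi, source_mol=mol.rdmol
    )


def match_fragment(query: Fragment, target: Molecule | Chem.Mol) -> list[dict[int, int]]:
    """All embeddings of a fragment into a target molecule.

    Each embedding maps source-fragment atom index -> target atom index and
    respects element, aromatic flag, formal charge and bond order/aromaticity
    (hydrogens implicit).  Embeddings touching the same target atom set in a
    different order (automorphisms) are reported once.
    """
    rdtarget = target.rdmol if isinstance(target, Molecule) else target
    order = query.query_atom_order
    matches = rdtarget.GetSubstructMatches(query.query(), uniquify=True, maxMatches=10000)
    return [dict(zip(order, m)) for m in matches]


def is_subfragment(query: Fragment, target: Fragment) -> bool:
    """True when ``query`` embeds into ``target`` (as a subgraph of the target
    fragment, matching within the target's source molecule)."""
    allowed = target.atom_indices
    rdmol = target.source_mol
    for m in rdmol.GetSubstructMatches(query.query(), uniquify=True, maxMatches=10000):
        if set(m) <= allowed:
            return True
    return False


def is_strict_subfragment(query: Fragment, target: Fragment) -> bool:
    """Strict subgraph: embeds into the target fragment and is not equal to it."""
    if query.canonical_form == target.canonical_form:
        return False
    if query.num_atoms > target.num_atoms:
        return False
    return is_subfragment(query, target)
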