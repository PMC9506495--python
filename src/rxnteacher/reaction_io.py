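"""Atom-mapped reaction SMILES parsing, featurization, and bond-change extraction.

Reactions are given in the USPTO dialect ``reactants>reagents>products``, one
per line, with atom-map numbers (``:n``) linking reactant atoms to product
atoms.  A *reaction center* is a pair of mapped atoms whose bond changes
between the reactant and product sides, together with the product-side bond
type (``none`` when the bond is broken).  Because the mapping is given, the
full center set ``TR(p)`` is recovered exactly by diffing the bond tables of
the two sides through the mapping.

Reagents (the middle field) are merged into the reactant graph: they take part
in message passing but, being unmapped, are excluded from center candidacy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger("rxnteacher")

__all__ = [
    "BOND_VOCAB",
    "BOND_VOCAB_WITH_TRIPLE",
    "ATOM_FDIM",
    "BOND_FDIM",
    "AtomFeatures",
    "BondFeatures",
    "MolGraph",
    "ReactionCenter",
    "ReactionRecord",
    "ReactionParseError",
    "ReactionValidationError",
    "parse_reaction",
    "parse_reaction_file",
    "extract_true_centers",
    "featurize",
    "mol_from_smiles",
    "write_reaction",
    "write_reaction_file",
]


class ReactionParseError(ValueError):
    """A reaction line could not be parsed."""


class ReactionValidationError(ValueError):
    """A parsed reaction violates a structural invariant (maps, valence)."""


# ---------------------------------------------------------------------------
# feature encoding
# ---------------------------------------------------------------------------

#: Element vocabulary: the common organic/organometallic elements; anything
#: else lands in a trailing "other" bucket.
ELEMENTS: Tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B",
    "Si", "Se", "H", "Li", "Na", "K", "Mg", "Ca", "Zn", "Cu",
    "Fe", "Mn", "Ni", "Co", "Cr", "Pd", "Pt", "Sn", "Al", "Ti",
    "Hg", "As", "Sb", "Bi", "Te", "Ge", "Zr", "Ag", "Au", "Cd",
)
_ELEMENT_INDEX = {el: i for i, el in enumerate(ELEMENTS)}

_MAX_DEGREE = 5
_MAX_VALENCE = 6

#: New-bond vocabulary for reaction centers.  The default follows the
#: four-outcome convention (no bond / single / double / aromatic); pass
#: :data:`BOND_VOCAB_WITH_TRIPLE` to models working on corpora with triple-bond
#: changes.
BOND_VOCAB: Tuple[str, ...] = ("none", "single", "double", "aromatic")
BOND_VOCAB_WITH_TRIPLE: Tuple[str, ...] = ("none", "single", "double", "aromatic", "triple")

_BOND_TYPES = ("single", "double", "triple", "aromatic")

_RDKIT_BOND = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}

# one-hot element + other | mass/100 | aromatic | one-hot degree | one-hot valence
ATOM_FDIM = len(ELEMENTS) + 1 + 1 + 1 + (_MAX_DEGREE + 1) + (_MAX_VALENCE + 1)
# one-hot bond type | conjugated | in-ring
BOND_FDIM = len(_BOND_TYPES) + 2


@dataclass(frozen=True)
class AtomFeatures:
    """Chemically interpretable per-atom descriptors.

    ``connectivity`` counts all bonded neighbors including hydrogens;
    ``valence`` is the total valence (bond-order sum, hydrogens included).
    """

    atomic_number: int
    symbol: str
    mass: float
    is_aromatic: bool
    connectivity: int
    valence: int

    def encode(self) -> np.ndarray:
        v = np.zeros(ATOM_FDIM)
        idx = _ELEMENT_INDEX.get(self.symbol)
        if idx is None:
            idx = len(ELEMENTS)  # "other" bucket
            logger.warning("element %r outside vocabulary, using 'other' bucket", self.symbol)
        v[idx] = 1.0
        off = len(ELEMENTS) + 1
        v[off] = self.mass / 100.0  # scaled for numeric conditioning
        v[off + 1] = float(self.is_aromatic)
        v[off + 2 + min(self.connectivity, _MAX_DEGREE)] = 1.0
        v[off + 2 + (_MAX_DEGREE + 1) + min(self.valence, _MAX_VALENCE)] = 1.0
        return v


@dataclass(frozen=True)
class BondFeatures:
    bond_type: str  # single | double | triple | aromatic
    is_conjugated: bool
    is_in_ring: bool

    def encode(self) -> np.ndarray:
        v = np.zeros(BOND_FDIM)
        v[_BOND_TYPES.index(self.bond_type)] = 1.0
        v[len(_BOND_TYPES)] = float(self.is_conjugated)
        v[len(_BOND_TYPES) + 1] = float(self.is_in_ring)
        return v


class ReactionCenter(NamedTuple):
    """A changed bond: the two atom-map numbers (a1 < a2) and the new bond type."""

    a1: int
    a2: int
    new_bond: str

    @staticmethod
    def make(m1: int, m2: int, new_bond: str) -> "ReactionCenter":
        if m1 == m2:
            raise ReactionValidationError(f"reaction center with identical atoms: {m1}")
        a1, a2 = (m1, m2) if m1 < m2 else (m2, m1)
        return ReactionCenter(a1, a2, new_bond)


@dataclass
class MolGraph:
    """Featurized graph of one or more molecules (e.g. all reactants).

    ``features`` is the encoded atom-feature matrix the models consume; the
    per-atom :class:`AtomFeatures` records are kept for introspection.
    Adjacency and bond incidence are index-based; reaction centers are always
    keyed by atom-map number so they survive canonicalization.
    """

    mol: Chem.Mol
    atoms: List[AtomFeatures]
    atom_map_nums: np.ndarray  # (n,) int; 0 = unmapped
    features: np.ndarray  # (n, ATOM_FDIM)
    bonds: List[Tuple[int, int, BondFeatures]]  # i < j
    bond_features: np.ndarray  # (n_bonds, BOND_FDIM)
    adjacency: List[List[int]]
    bond_incidence: List[List[int]]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def index_of_map(self, map_num: int) -> int:
        hits = np.nonzero(self.atom_map_nums == map_num)[0]
        if len(hits) != 1:
            raise ReactionValidationError(f"atom map {map_num} not uniquely present")
        return int(hits[0])

    def mapped_bond_table(self) -> Dict[Tuple[int, int], str]:
        """Bond type per mapped-atom pair, keyed by sorted map numbers."""
        table: Dict[Tuple[int, int], str] = {}
        for i, j, bf in self.bonds:
            mi, mj = int(self.atom_map_nums[i]), int(self.atom_map_nums[j])
            if mi > 0 and mj > 0:
                table[(min(mi, mj), max(mi, mj))] = bf.bond_type
        return table


@dataclass
class ReactionRecord:
    """One reaction: reactant graph, optional product graph, true centers."""

    reactants: MolGraph
    product: Optional[MolGraph]
    true_centers: FrozenSet[ReactionCenter]
    id: str = ""
    reagent_smiles: str = ""

    @property
    def is_labeled(self) -> bool:
        return self.product is not None


# ---------------------------------------------------------------------------
# parsing / featurization
# ---------------------------------------------------------------------------

_PARSER_PARAMS = Chem.SmilesParserParams()
_PARSER_PARAMS.removeHs = False  # keep explicitly written (possibly mapped) hydrogens


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles, _PARSER_PARAMS)
    if mol is None:
        raise ReactionParseError(f"unparsable SMILES: {smiles!r}")
    return mol


def _bond_type_name(bond: Chem.Bond) -> str:
    if bond.GetIsAromatic() or bond.GetBondType() == Chem.BondType.AROMATIC:
        return "aromatic"
    bt = bond.GetBondType()
    if bt == Chem.BondType.SINGLE:
        return "single"
    if bt == Chem.BondType.DOUBLE:
        return "double"
    if bt == Chem.BondType.TRIPLE:
        return "triple"
    raise ReactionValidationError(f"unsupported bond type {bt}")


def featurize(mol: Chem.Mol) -> MolGraph:
    """Build the featurized graph for a sanitized (multi-fragment) molecule."""
    atoms: List[AtomFeatures] = []
    maps = np.zeros(mol.GetNumAtoms(), dtype=np.int64)
    for a in mol.GetAtoms():
        atoms.append(
            AtomFeatures(
                atomic_number=a.GetAtomicNum(),
                symbol=a.GetSymbol(),
                mass=a.GetMass(),
                is_aromatic=a.GetIsAromatic(),
                connectivity=a.GetTotalDegree(),
                valence=a.GetTotalValence(),
            )
        )
        maps[a.GetIdx()] = a.GetAtomMapNum()

    features = (
        np.stack([af.encode() for af in atoms])
        if atoms
        else np.zeros((0, ATOM_FDIM))
    )

    bonds: List[Tuple[int, int, BondFeatures]] = []
    adjacency: List[List[int]] = [[] for _ in atoms]
    bond_incidence: List[List[int]] = [[] for _ in atoms]
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        bf = BondFeatures(
            bond_type=_bond_type_name(b),
            is_conjugated=b.GetIsConjugated(),
            is_in_ring=b.IsInRing(),
        )
        idx = len(bonds)
        bonds.append((i, j, bf))
        adjacency[i].append(j)
        adjacency[j].append(i)
        bond_incidence[i].append(idx)
        bond_incidence[j].append(idx)

    bond_features = (
        np.stack([bf.encode() for (_, _, bf) in bonds])
        if bonds
        else np.zeros((0, BOND_FDIM))
    )
    return MolGraph(
        mol=mol,
        atoms=atoms,
        atom_map_nums=maps,
        features=features,
        bonds=bonds,
        bond_features=bond_features,
        adjacency=adjacency,
        bond_incidence=bond_incidence,
    )


def _check_unique_maps(graph: MolGraph, where: str) -> None:
    mapped = graph.atom_map_nums[graph.atom_map_nums > 0]
    if len(mapped) != len(set(mapped.tolist())):
        dupes = sorted({int(m) for m in mapped if (mapped == m).sum() > 1})
        raise ReactionValidationError(f"duplicate atom map number(s) {dupes} in {where}")


def parse_reaction(line: str, id: str = "") -> ReactionRecord:
    """Parse one ``reactants>reagents>products`` line into a :class:`ReactionRecord`.

    Reagent molecules are merged into the reactant graph.  When the products
    field is empty the record is unlabeled (``true_centers`` empty).
    """
    line = line.strip()
    parts = line.split(">")
    if len(parts) != 3:
        raise ReactionParseError(f"expected 'reactants>reagents>products' in line: {line!r}")
    reactant_smi, reagent_smi, product_smi = parts
    if not reactant_smi:
        raise ReactionParseError(f"empty reactant field in line: {line!r}")

    try:
        combined = reactant_smi if not reagent_smi else f"{reactant_smi}.{reagent_smi}"
        reactants = featurize(mol_from_smiles(combined))
    except ReactionParseError as e:
        raise ReactionParseError(f"{e} (line: {line!r})") from None
    _check_unique_maps(reactants, f"reactants of {line!r}")

    product: Optional[MolGraph] = None
    centers: FrozenSet[ReactionCenter] = frozenset()
    if product_smi:
        try:
            product = featurize(mol_from_smiles(product_smi))
        except ReactionParseError as e:
            raise ReactionParseError(f"{e} (line: {line!r})") from None
        _check_unique_maps(product, f"products of {line!r}")

    record = ReactionRecord(
        reactants=reactants,
        product=product,
        true_centers=centers,
        id=id,
        reagent_smiles=reagent_smi,
    )
    if product is not None:
        record.true_centers = extract_true_centers(record)
        if not record.true_centers:
            raise ReactionValidationError(
                f"labeled reaction with no changed bonds: {line!r}"
            )
    return record


def extract_true_centers(record: ReactionRecord) -> FrozenSet[ReactionCenter]:
    """Diff reactant and product bonds through the atom mapping.

    Returns every mapped atom pair whose bond differs between the two sides,
    with the product-side bond type (``none`` when the pair is not bonded in
    the product — including pairs where an atom leaves the product entirely).
    """
    if record.product is None:
        raise ReactionValidationError("cannot extract centers from an unlabeled record")

    reac_maps = set(record.reactants.atom_map_nums[record.reactants.atom_map_nums > 0].tolist())
    prod_maps = set(record.product.atom_map_nums[record.product.atom_map_nums > 0].tolist())
    missing = prod_maps - reac_maps
    if missing:
        raise ReactionValidationError(
            f"product atom map(s) {sorted(missing)} absent from reactants (record {record.id!r})"
        )

    r_table = record.reactants.mapped_bond_table()
    p_table = record.product.mapped_bond_table()
    centers = set()
    for pair in set(r_table) | set(p_table):
        r_type = r_table.get(pair)
        p_type = p_table.get(pair)
        if r_type != p_type:
            centers.add(ReactionCenter.make(pair[0], pair[1], p_type or "none"))
    return frozenset(centers)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_reaction(record: ReactionRecord) -> str:
    """Serialize a record back to the ``reactants>reagents>products`` dialect.

    Reagents stay merged in the reactant field (they were merged at parse
    time), so the middle field is empty.  ``parse(write(r))`` preserves atom
    maps, bond orders and the extracted center set.
    """
    reac = Chem.MolToSmiles(record.reactants.mol, canonical=True)
    prod = Chem.MolToSmiles(record.product.mol, canonical=True) if record.product else ""
    return f"{reac}>>{prod}"


def parse_reaction_file(path) -> List[ReactionRecord]:
    """Read one reaction per line; TSV lines ``id<TAB>reaction`` are accepted."""
    records = []
    with open(path) as fh:
        for n, raw in enumerate(fh):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                rid, line = line.split("\t", 1)
            else:
                rid = f"line{n + 1}"
            try:
                records.append(parse_reaction(line, id=rid))
            except (ReactionParseError, ReactionValidationError) as e:
                raise type(e)(f"{path}:{n + 1}: {e}") from None
    return records


def write_reaction_file(records: Sequence[ReactionRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.id}\t{write_reaction(r)}\n" if r.id else write_reaction(r) + "\n")
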