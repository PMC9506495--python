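"""Candidate-product construction from predicted reaction centers.

Given the top-k predicted centers, every non-empty subset of them is applied
to the reactant graph as a set of bond edits, yielding 2^k - 1 candidate
products (31 for the default k = 5).  Hydrogen counts on edited atoms are
rebalanced by the default valence tables; candidates that fail valence or
sanitization are kept but flagged invalid (and excluded from ranking by
default).  The true product, when known, is located in the candidate list by
canonical-structure comparison with atom maps stripped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from rdkit import Chem

from .reaction_io import (
    MolGraph,
    ReactionCenter,
    _RDKIT_BOND,
    featurize,
)

__all__ = [
    "Candidate",
    "EditError",
    "apply_edits",
    "enumerate_candidates",
    "label_true_candidate",
    "canonical_product_form",
    "write_candidates_tsv",
]


class EditError(ValueError):
    """A bond edit could not be applied to the graph."""


@dataclass
class Candidate:
    """One enumerated product: the edit subset and the resulting graph."""

    applied: FrozenSet[ReactionCenter]
    graph: Optional[MolGraph]  # None when sanitization failed
    smiles: Optional[str]  # canonical, maps stripped; None when invalid
    valid: bool
    is_duplicate: bool = False
    score: Optional[float] = None


def _strip_maps_smiles(mol: Chem.Mol) -> str:
    copy = Chem.Mol(mol)
    for a in copy.GetAtoms():
        a.SetAtomMapNum(0)
    return Chem.MolToSmiles(copy, canonical=True)


def canonical_product_form(g: MolGraph, mapped_fragments_only: bool = False) -> str:
    """Canonical SMILES of a product graph with atom maps removed.

    With ``mapped_fragments_only``, fragments made entirely of unmapped atoms
    (merged-in reagents and spectators, which cannot appear in the product
    field) are dropped before canonicalization; mapped spectator molecules
    are retained.
    """
    mol = g.mol
    if mapped_fragments_only:
        frags = Chem.GetMolFrags(mol)
        drop = [
            idx
            for frag in frags
            if all(mol.GetAtomWithIdx(i).GetAtomMapNum() == 0 for i in frag)
            for idx in frag
        ]
        if drop:
            rw = Chem.RWMol(mol)
            for idx in sorted(drop, reverse=True):
                rw.RemoveAtom(idx)
            mol = rw.GetMol()
    return _strip_maps_smiles(mol)


def apply_edits(g: MolGraph, edits: Iterable[ReactionCenter]) -> MolGraph:
    """Apply a set of bond edits to a reactant graph, returning a new graph.

    ``new_bond='none'`` removes the bond; other types set (or create) it.
    Hydrogen counts on every edited atom are recomputed from the element's
    default valence during sanitization.  The input graph is not modified.

    Raises :class:`EditError` when an edit references a map number missing
    from the graph or the edited molecule fails sanitization.
    """
    edits = list(edits)
    rw = Chem.RWMol(g.mol)
    map_to_idx = {}
    for a in rw.GetAtoms():
        if a.GetAtomMapNum() > 0:
            map_to_idx[a.GetAtomMapNum()] = a.GetIdx()

    touched: Set[int] = set()
    for c in edits:
        if c.a1 not in map_to_idx or c.a2 not in map_to_idx:
            raise EditError(f"edit {c} references a map number missing from the graph")
        i, j = map_to_idx[c.a1], map_to_idx[c.a2]
        touched.update((i, j))
        bond = rw.GetBondBetweenAtoms(i, j)
        if c.new_bond == "none":
            if bond is not None:
                rw.RemoveBond(i, j)
        else:
            bt = _RDKIT_BOND[c.new_bond]
            if bond is None:
                rw.AddBond(i, j, bt)
            else:
                bond.SetBondType(bt)
                bond.SetIsAromatic(c.new_bond == "aromatic")
            if c.new_bond == "aromatic":
                rw.GetAtomWithIdx(i).SetIsAromatic(True)
                rw.GetAtomWithIdx(j).SetIsAromatic(True)

    # rebalance hydrogens on edited atoms via implicit-valence rules
    for idx in touched:
        a = rw.GetAtomWithIdx(idx)
        a.SetNumExplicitHs(0)
        a.SetNoImplicit(False)

    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as e:  # rdkit raises several exception types here
        raise EditError(f"edited molecule failed sanitization: {e}") from None
    return featurize(mol)


def _subset_order(centers: Sequence[ReactionCenter]) -> List[Tuple[int, ...]]:
    """All non-empty index subsets, by size then lexicographic order."""
    idx = range(len(centers))
    out: List[Tuple[int, ...]] = []
    for size in range(1, len(centers) + 1):
        out.extend(itertools.combinations(idx, size))
    return out


def enumerate_candidates(g: MolGraph, centers: Sequence[ReactionCenter]) -> List[Candidate]:
    """Enumerate all 2^k - 1 non-empty edit subsets of the k given centers.

    Candidates are produced in a deterministic order (subset size, then
    lexicographic center order).  Each candidate is marked valid/invalid by
    sanitization; later candidates whose canonical product form repeats an
    earlier one are flagged ``is_duplicate``.
    """
    if len(centers) == 0:
        raise ValueError("need at least one center to enumerate candidates")
    seen_forms: Set[str] = set()
    out: List[Candidate] = []
    for subset in _subset_order(centers):
        applied = frozenset(centers[i] for i in subset)
        try:
            graph = apply_edits(g, applied)
            smiles = canonical_product_form(graph, mapped_fragments_only=True)
            dup = smiles in seen_forms
            seen_forms.add(smiles)
            out.append(Candidate(applied=applied, graph=graph, smiles=smiles,
                                 valid=True, is_duplicate=dup))
        except EditError:
            out.append(Candidate(applied=applied, graph=None, smiles=None, valid=False))
    return out


def label_true_candidate(
    cands: Sequence[Candidate],
    true_product: MolGraph,
    compare: str = "full",
) -> Optional[int]:
    """Index of the first candidate matching the true product, or None.

    ``compare='full'`` requires the candidate's whole fragment set (including
    spectators and leaving groups) to equal the product form; ``'fragments'``
    requires every fragment of the recorded product to occur among the
    candidate's fragments, for corpora whose product field omits leaving
    groups.
    """
    true_form = canonical_product_form(true_product)
    if compare == "full":
        for i, c in enumerate(cands):
            if c.valid and c.smiles == true_form:
                return i
        return None
    if compare == "fragments":
        want = sorted(true_form.split("."))
        for i, c in enumerate(cands):
            if not c.valid:
                continue
            have = c.smiles.split(".")
            ok = True
            pool = list(have)
            for f in want:
                if f in pool:
                    pool.remove(f)
                else:
                    ok = False
                    break
            if ok:
                return i
        return None
    raise ValueError(f"unknown compare mode {compare!r}")


def write_candidates_tsv(
    fh,
    reaction_id: str,
    centers: Sequence[ReactionCenter],
    cands: Sequence[Candidate],
    true_index: Optional[int] = None,
    header: bool = False,
) -> None:
    """Dump one reaction's candidate set: id, subset bitmask, SMILES, flags.

    Bit i of the mask is set when centers[i] is part of the candidate's edit
    subset; ``true_index`` marks the candidate matching the real product.
    """
    if header:
        fh.write("reaction_id\tsubset_bitmask\tcandidate_smiles\tvalid\tis_true\n")
    for pos, c in enumerate(cands):
        mask = sum(1 << i for i, ctr in enumerate(centers) if ctr in c.applied)
        fh.write(
            f"{reaction_id}\t{mask}\t{c.smiles or ''}\t{int(c.valid)}\t"
            f"{int(true_index == pos)}\n"
        )
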