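"""Rule-grammar generator of atom-mapped synthetic reaction corpora.

Every stage of the pipeline (center finding, candidate enumeration, ranking)
is trainable on corpora produced here, with exact ground truth: each sampled
reaction is built by applying a known set of 1-5 bond edits to a random small
organic scaffold, so the true center set TR(p) is the rule's instantiated
edits by construction, and the generator asserts that bond-diff extraction
recovers it.

The default grammar spans the full new-bond vocabulary with mass concentrated
on 1-2 edits per reaction, mirroring how real patent corpora distribute
center counts:

* ``alkene_reduction``    (1 edit)  C=C -> C-C
* ``halide_substitution`` (2 edits) break C-Cl, make C-N to an amine
* ``elimination``         (2 edits) C-C -> C=C, break C-Br
* ``substitute_reduce``   (3 edits) independent substitution + reduction
* ``substitute_eliminate``(4 edits) independent substitution + elimination
* ``aromatization``       (5 edits) 2,5-dihydrofuran ring -> furan (all five
  ring bonds become aromatic)

Unlabeled pools are the same reactions with the product field stripped; the
hidden truth is kept in a sidecar so oracle evaluation remains possible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Dict, FrozenSet, List, Optional, Tuple

import numpy as np
from rdkit import Chem

from .candidate_enum import apply_edits, canonical_product_form
from .reaction_io import (
    ReactionCenter,
    ReactionRecord,
    featurize,
    parse_reaction,
)

__all__ = [
    "GrammarRule",
    "CorpusSpec",
    "Corpus",
    "DEFAULT_RULES",
    "sample_reaction",
    "generate_corpus",
    "make_corpus",
    "format_centers",
    "parse_centers",
]

# edits at build time are (atom_i, atom_j, new_bond) in RWMol indices
_IdxEdit = Tuple[int, int, str]


@dataclass(frozen=True)
class GrammarRule:
    """A reaction template: a scaffold builder plus its bond-edit set."""

    name: str
    n_edits: int
    builder: Callable[[np.random.Generator, int], Tuple[Chem.RWMol, List[_IdxEdit]]]


@dataclass
class CorpusSpec:
    """Generation parameters for one synthetic corpus."""

    n_labeled: int = 800
    n_unlabeled: int = 2000
    #: probability of each center count 1..5
    center_count_dist: Tuple[float, ...] = (0.35, 0.35, 0.12, 0.12, 0.06)
    scaffold_size: Tuple[int, int] = (6, 16)
    spectator_prob: float = 0.2
    hetero_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_labeled < 0 or self.n_unlabeled < 0:
            raise ValueError("corpus sizes must be non-negative")
        if abs(sum(self.center_count_dist) - 1.0) > 1e-9:
            raise ValueError("center_count_dist must sum to 1")


@dataclass
class Corpus:
    labeled: List[ReactionRecord]
    unlabeled: List[ReactionRecord]  # product stripped
    #: hidden full records for the unlabeled pool (oracle evaluation)
    unlabeled_truth: List[ReactionRecord]


# ---------------------------------------------------------------------------
# scaffold construction helpers
# ---------------------------------------------------------------------------


def _grow_tree(rw: Chem.RWMol, rng: np.random.Generator, n_new: int,
               attach_to: Optional[List[int]] = None) -> List[int]:
    """Grow `n_new` carbons as a random tree; returns the new atom indices."""
    added: List[int] = []
    for _ in range(n_new):
        pool = [
            a.GetIdx()
            for a in rw.GetAtoms()
            if a.GetDegree() < 3 and (attach_to is None or a.GetIdx() in attach_to or a.GetIdx() in added)
        ]
        new = rw.AddAtom(Chem.Atom(6))
        if pool:
            rw.AddBond(int(rng.choice(pool)), new, Chem.BondType.SINGLE)
        added.append(new)
    return added


def _free_sites(rw: Chem.RWMol, used: set, max_degree: int = 2) -> List[int]:
    return [
        a.GetIdx()
        for a in rw.GetAtoms()
        if a.GetIdx() not in used and a.GetAtomicNum() == 6
        and not a.GetIsAromatic() and a.GetDegree() <= max_degree
        and all(b.GetBondType() == Chem.BondType.SINGLE for b in a.GetBonds())
    ]


def _free_edges(rw: Chem.RWMol, used: set) -> List[Tuple[int, int]]:
    """Single C-C bonds whose endpoints are unused, single-bonded, degree <= 2."""
    sites = set(_free_sites(rw, used))
    edges = []
    for b in rw.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in sites and j in sites:
            edges.append((min(i, j), max(i, j)))
    return edges


class _BuildFailed(Exception):
    pass


def _motif_reduce(rw: Chem.RWMol, rng: np.random.Generator, used: set) -> List[_IdxEdit]:
    edges = _free_edges(rw, used)
    if not edges:
        raise _BuildFailed("no free edge for double bond")
    u, v = edges[int(rng.integers(len(edges)))]
    rw.GetBondBetweenAtoms(u, v).SetBondType(Chem.BondType.DOUBLE)
    used.update((u, v))
    return [(u, v, "single")]


def _motif_substitute(rw: Chem.RWMol, rng: np.random.Generator, used: set,
                      amine_carbons: int) -> List[_IdxEdit]:
    sites = _free_sites(rw, used)
    if not sites:
        raise _BuildFailed("no free substitution site")
    u = int(rng.choice(sites))
    cl = rw.AddAtom(Chem.Atom(17))
    rw.AddBond(u, cl, Chem.BondType.SINGLE)
    # amine nucleophile as a separate fragment: N with 0-2 carbons
    n_idx = rw.AddAtom(Chem.Atom(7))
    prev = n_idx
    for _ in range(amine_carbons):
        c = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(prev, c, Chem.BondType.SINGLE)
        prev = c
    used.update((u, cl, n_idx))
    return [(u, cl, "none"), (u, n_idx, "single")]


def _motif_eliminate(rw: Chem.RWMol, rng: np.random.Generator, used: set) -> List[_IdxEdit]:
    edges = _free_edges(rw, used)
    if not edges:
        raise _BuildFailed("no free edge for elimination")
    u, v = edges[int(rng.integers(len(edges)))]
    # Br, not Cl: the two halides mark which elementary step applies where
    br = rw.AddAtom(Chem.Atom(35))
    rw.AddBond(v, br, Chem.BondType.SINGLE)
    used.update((u, v, br))
    return [(u, v, "double"), (v, br, "none")]


def _build_alkene_reduction(rng: np.random.Generator, n: int):
    rw = Chem.RWMol()
    _grow_tree(rw, rng, max(n, 3))
    used: set = set()
    return rw, _motif_reduce(rw, rng, used)


def _build_halide_substitution(rng: np.random.Generator, n: int):
    amine_c = int(rng.integers(0, 3))
    rw = Chem.RWMol()
    _grow_tree(rw, rng, max(n - 2 - amine_c, 2))
    used: set = set()
    return rw, _motif_substitute(rw, rng, used, amine_c)


def _build_elimination(rng: np.random.Generator, n: int):
    rw = Chem.RWMol()
    _grow_tree(rw, rng, max(n - 1, 3))
    used: set = set()
    return rw, _motif_eliminate(rw, rng, used)


def _build_substitute_reduce(rng: np.random.Generator, n: int):
    amine_c = int(rng.integers(0, 2))
    rw = Chem.RWMol()
    _grow_tree(rw, rng, max(n - 2 - amine_c, 5))
    used: set = set()
    edits = _motif_substitute(rw, rng, used, amine_c)
    edits += _motif_reduce(rw, rng, used)
    return rw, edits


def _build_substitute_eliminate(rng: np.random.Generator, n: int):
    amine_c = int(rng.integers(0, 2))
    rw = Chem.RWMol()
    _grow_tree(rw, rng, max(n - 3 - amine_c, 6))
    used: set = set()
    edits = _motif_substitute(rw, rng, used, amine_c)
    edits += _motif_eliminate(rw, rng, used)
    return rw, edits


def _build_aromatization(rng: np.random.Generator, n: int):
    """2,5-dihydrofuran core; all five ring bonds turn aromatic (furan)."""
    rw = Chem.RWMol()
    o = rw.AddAtom(Chem.Atom(8))
    c = [rw.AddAtom(Chem.Atom(6)) for _ in range(4)]
    ring = [o] + c
    rw.AddBond(o, c[0], Chem.BondType.SINGLE)
    rw.AddBond(c[0], c[1], Chem.BondType.SINGLE)
    rw.AddBond(c[1], c[2], Chem.BondType.DOUBLE)
    rw.AddBond(c[2], c[3], Chem.BondType.SINGLE)
    rw.AddBond(c[3], o, Chem.BondType.SINGLE)
    # substituents: each ring carbon takes at most one branch
    extra = max(n - 5, 0)
    if extra:
        _grow_tree(rw, rng, extra, attach_to=c)
    edits = [
        (o, c[0], "aromatic"),
        (c[0], c[1], "aromatic"),
        (c[1], c[2], "aromatic"),
        (c[2], c[3], "aromatic"),
        (c[3], o, "aromatic"),
    ]
    return rw, edits


DEFAULT_RULES: Tuple[GrammarRule, ...] = (
    GrammarRule("alkene_reduction", 1, _build_alkene_reduction),
    GrammarRule("halide_substitution", 2, _build_halide_substitution),
    GrammarRule("elimination", 2, _build_elimination),
    GrammarRule("substitute_reduce", 3, _build_substitute_reduce),
    GrammarRule("substitute_eliminate", 4, _build_substitute_eliminate),
    GrammarRule("aromatization", 5, _build_aromatization),
)

_RULES_BY_COUNT: Dict[int, List[GrammarRule]] = {}
for _r in DEFAULT_RULES:
    _RULES_BY_COUNT.setdefault(_r.n_edits, []).append(_r)

_SPECTATORS = ("O", "CO", "CCO", "CC(C)=O")


def _sprinkle_heteroatoms(rw: Chem.RWMol, rng: np.random.Generator,
                          edit_atoms: set, prob: float) -> None:
    """Convert some uninvolved low-degree carbons to ethers/alcohols.

    Oxygen only: sprinkling amine nitrogens would make the nucleophile in
    substitution reactions ambiguous from the reactant side alone.
    """
    for a in rw.GetAtoms():
        if a.GetIdx() in edit_atoms or a.GetAtomicNum() != 6 or a.GetIsAromatic():
            continue
        if a.GetDegree() > 2:
            continue
        if any(b.GetBondType() != Chem.BondType.SINGLE for b in a.GetBonds()):
            continue
        if any(nb.GetAtomicNum() != 6 for nb in a.GetNeighbors()):
            continue
        if rng.random() < prob:
            a.SetAtomicNum(8)


def sample_reaction(spec: CorpusSpec, rng: np.random.Generator,
                    id: str = "") -> ReactionRecord:
    """Sample one labeled reaction; TR(p) equals the rule's edits exactly."""
    for _ in range(200):
        count = int(rng.choice(np.arange(1, 6), p=np.asarray(spec.center_count_dist)))
        rules = _RULES_BY_COUNT[count]
        rule = rules[int(rng.integers(len(rules)))]
        n = int(rng.integers(spec.scaffold_size[0], spec.scaffold_size[1] + 1))
        try:
            rw, idx_edits = rule.builder(rng, n)
        except _BuildFailed:
            continue
        edit_atoms = {i for e in idx_edits for i in e[:2]}
        _sprinkle_heteroatoms(rw, rng, edit_atoms, spec.hetero_prob)

        perm = rng.permutation(rw.GetNumAtoms()) + 1
        for a in rw.GetAtoms():
            a.SetAtomMapNum(int(perm[a.GetIdx()]))
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        centers = frozenset(
            ReactionCenter.make(int(perm[i]), int(perm[j]), t) for i, j, t in idx_edits
        )
        reactants = featurize(mol)
        try:
            product = apply_edits(reactants, centers)
        except Exception:
            continue

        reagent = ""
        if rng.random() < spec.spectator_prob:
            reagent = _SPECTATORS[int(rng.integers(len(_SPECTATORS)))]
        line = f"{Chem.MolToSmiles(mol)}>{reagent}>{Chem.MolToSmiles(product.mol)}"
        record = parse_reaction(line, id=id)
        # generator/extractor agreement is a hard guarantee, not a hope
        if record.true_centers != centers:
            raise AssertionError(
                f"bond-diff extraction disagrees with generating edits: "
                f"{sorted(record.true_centers)} vs {sorted(centers)}"
            )
        return record
    raise RuntimeError("failed to sample a valid reaction after 200 attempts")


def _reaction_key(record: ReactionRecord) -> str:
    """Map-stripped canonical reaction, for cross-pool overlap checks."""
    reac = canonical_product_form(record.reactants)
    prod = canonical_product_form(record.product) if record.product else ""
    return f"{reac}>>{prod}"


def _strip_product(record: ReactionRecord) -> ReactionRecord:
    return ReactionRecord(
        reactants=record.reactants,
        product=None,
        true_centers=frozenset(),
        id=record.id,
        reagent_smiles=record.reagent_smiles,
    )


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Generate labeled and unlabeled pools sharing no canonical reaction."""
    rng = np.random.default_rng(spec.seed)
    seen: set = set()
    labeled: List[ReactionRecord] = []
    truth: List[ReactionRecord] = []
    while len(labeled) < spec.n_labeled:
        r = sample_reaction(spec, rng, id=f"lab-{len(labeled):06d}")
        key = _reaction_key(r)
        if key in seen:
            continue
        seen.add(key)
        labeled.append(r)
    while len(truth) < spec.n_unlabeled:
        r = sample_reaction(spec, rng, id=f"unl-{len(truth):06d}")
        key = _reaction_key(r)
        if key in seen:
            continue
        seen.add(key)
        truth.append(r)
    return Corpus(
        labeled=labeled,
        unlabeled=[_strip_product(r) for r in truth],
        unlabeled_truth=truth,
    )


def format_centers(centers: FrozenSet[ReactionCenter]) -> str:
    return ";".join(f"{c.a1}-{c.a2}:{c.new_bond}" for c in sorted(centers))


def parse_centers(text: str) -> FrozenSet[ReactionCenter]:
    out = set()
    for tok in text.split(";"):
        if not tok:
            continue
        pair, bond = tok.split(":")
        a1, a2 = pair.split("-")
        out.add(ReactionCenter.make(int(a1), int(a2), bond))
    return frozenset(out)


def make_corpus(spec: CorpusSpec, outdir) -> Dict[str, str]:
    """Write labeled/unlabeled reaction files plus the truth sidecar.

    Returns the three paths.  Unlabeled lines end in ``>`` (products
    stripped); the sidecar records the hidden centers of every reaction.
    """
    from .reaction_io import write_reaction

    os.makedirs(outdir, exist_ok=True)
    corpus = generate_corpus(spec)
    paths = {
        "labeled": os.path.join(outdir, "labeled.txt"),
        "unlabeled": os.path.join(outdir, "unlabeled.txt"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    with open(paths["labeled"], "w") as fh:
        for r in corpus.labeled:
            fh.write(f"{r.id}\t{write_reaction(r)}\n")
    with open(paths["unlabeled"], "w") as fh:
        for r in corpus.unlabeled:
            fh.write(f"{r.id}\t{write_reaction(r)}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("id\tcenters\n")
        for r in corpus.labeled + corpus.unlabeled_truth:
            fh.write(f"{r.id}\t{format_centers(r.true_centers)}\n")
    return paths
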