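"""Weisfeiler-Lehman network with global attention for reaction-center scoring.

The model embeds every atom of the (multi-molecule) reactant graph by
``depth`` rounds of neighbor aggregation — each round updates an atom's state
from its own state plus a learned function of (neighbor state, bond features)
summed over neighbors, the graph-network analogue of Weisfeiler-Lehman label
refinement.  A bilinear attention over atom embeddings then builds a global
context vector per atom, so that atoms far from a bond can still influence
its predicted reactivity (a distant nucleophile, a directing group).  Every
unordered pair of *mapped* atoms is scored per new-bond type and squashed to
(0, 1) with a logistic; the top-k pairs (one bond type per pair, the argmax)
form the predicted center set R(p).

A prediction is counted correct when R(p) contains every true center,
``R(p) ⊇ TR(p)``, matching on both the atom pair and the new bond type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor, gather, relu, segment_sum, sigmoid
from .reaction_io import (
    ATOM_FDIM,
    BOND_FDIM,
    BOND_VOCAB,
    MolGraph,
    ReactionCenter,
    ReactionRecord,
)

__all__ = [
    "WLNConfig",
    "WLNParams",
    "PairScores",
    "CenterPrediction",
    "GraphBatch",
    "init_wln_params",
    "wln_embed",
    "attend_and_score",
    "pair_scores",
    "predict_centers",
    "covers_true_centers",
    "center_coverage",
    "save_params",
    "load_params",
    "write_attention_tsv",
]


@dataclass(frozen=True)
class WLNConfig:
    """Architecture hyperparameters of the center-scoring network."""

    depth: int = 3
    hidden_dim: int = 300
    bond_vocab: Tuple[str, ...] = BOND_VOCAB

    def __post_init__(self) -> None:
        # depth 0 (pure input projection) is allowed for diagnostics
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass
class WLNParams:
    """Named weight tensors plus the architecture config.

    Also used for the difference-network tower, which adds a pooling radius.
    """

    config: WLNConfig
    tensors: Dict[str, Tensor]
    pool_radius: int = 1

    def copy(self) -> "WLNParams":
        return WLNParams(
            config=self.config,
            tensors={k: Tensor(t.data.copy(), requires_grad=t.requires_grad)
                     for k, t in self.tensors.items()},
            pool_radius=self.pool_radius,
        )

    def trainable(self) -> Dict[str, Tensor]:
        return self.tensors


def _glorot(rng: np.random.Generator, shape: Tuple[int, ...]) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


def init_wln_params(config: WLNConfig, rng: np.random.Generator) -> WLNParams:
    H = config.hidden_dim
    T = len(config.bond_vocab)
    shapes: Dict[str, Tuple[int, ...]] = {"W_in": (ATOM_FDIM, H)}
    for layer in range(config.depth):
        shapes[f"W_nei_{layer}"] = (H, H)
        shapes[f"W_bondm_{layer}"] = (BOND_FDIM, H)
        shapes[f"W_self_{layer}"] = (H, H)
        shapes[f"W_msg_{layer}"] = (H, H)
    shapes.update(
        W_att=(H, H),
        U_loc=(H, H),
        U_ctx=(H, H),
        U_bf=(BOND_FDIM, H),
        b_h=(H,),
        W_out=(H, T),
        b_out=(T,),
    )
    tensors = {
        name: Tensor(np.zeros(shape) if name.startswith("b_") else _glorot(rng, shape),
                     requires_grad=True)
        for name, shape in shapes.items()
    }
    return WLNParams(config=config, tensors=tensors)


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------


class GraphBatch:
    """Several molecular graphs flattened into one disconnected graph.

    Atom indices are offset per graph; a same-graph mask confines attention,
    and per-graph pair slices recover individual reactions.  Pairs are all
    unordered (i < j by map number) mapped-atom pairs of each graph.
    """

    def __init__(self, graphs: Sequence[MolGraph]):
        feats, srcs, dsts, efeats, gids = [], [], [], [], []
        pair_i, pair_j, pair_bf, pair_maps, pair_graph = [], [], [], [], []
        self.pair_slices: List[Tuple[int, int]] = []
        offset = 0
        for gi, g in enumerate(graphs):
            n = g.n_atoms
            feats.append(g.features)
            gids.append(np.full(n, gi))
            for (i, j, _), bf in zip(g.bonds, g.bond_features):
                srcs.extend((i + offset, j + offset))
                dsts.extend((j + offset, i + offset))
                efeats.extend((bf, bf))
            start = len(pair_i)
            mapped = [(int(m), idx) for idx, m in enumerate(g.atom_map_nums) if m > 0]
            mapped.sort()
            bond_lookup = {}
            for (i, j, _), bf in zip(g.bonds, g.bond_features):
                bond_lookup[(i, j)] = bf
                bond_lookup[(j, i)] = bf
            for a in range(len(mapped)):
                for b in range(a + 1, len(mapped)):
                    (ma, ia), (mb, ib) = mapped[a], mapped[b]
                    pair_i.append(ia + offset)
                    pair_j.append(ib + offset)
                    pair_bf.append(bond_lookup.get((ia, ib), np.zeros(BOND_FDIM)))
                    pair_maps.append((ma, mb))
                    pair_graph.append(gi)
            self.pair_slices.append((start, len(pair_i)))
            offset += n

        self.graphs = list(graphs)
        self.n_atoms = offset
        self.features = np.concatenate(feats) if feats else np.zeros((0, ATOM_FDIM))
        self.graph_ids = np.concatenate(gids) if gids else np.zeros(0, dtype=int)
        self.edge_src = np.asarray(srcs, dtype=np.intp)
        self.edge_dst = np.asarray(dsts, dtype=np.intp)
        self.edge_feat = (
            np.stack(efeats) if efeats else np.zeros((0, BOND_FDIM))
        )
        self.pair_i = np.asarray(pair_i, dtype=np.intp)
        self.pair_j = np.asarray(pair_j, dtype=np.intp)
        self.pair_bf = np.stack(pair_bf) if pair_bf else np.zeros((0, BOND_FDIM))
        self.pair_maps = pair_maps
        self.pair_graph = np.asarray(pair_graph, dtype=np.intp)
        self.same_graph = (self.graph_ids[:, None] == self.graph_ids[None, :]).astype(float)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_i)


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------


def wln_embed(
    batch: GraphBatch,
    params: WLNParams,
    features: Optional[np.ndarray] = None,
) -> Tensor:
    """Depth-round Weisfeiler-Lehman embedding; returns an (N, H) tensor.

    ``features`` overrides the batch's atom-feature matrix (used for the
    perturbed student input); topology and bond features are never perturbed.
    """
    t = params.tensors
    x = Tensor(batch.features if features is None else features)
    h = relu(x @ t["W_in"])
    for layer in range(params.config.depth):
        nei = gather(h, batch.edge_src)
        msg = relu(nei @ t[f"W_nei_{layer}"] + Tensor(batch.edge_feat) @ t[f"W_bondm_{layer}"])
        agg = segment_sum(msg, batch.edge_dst, batch.n_atoms)
        h = relu(h @ t[f"W_self_{layer}"] + agg @ t[f"W_msg_{layer}"])
    return h


def attend_and_score(
    h: Tensor,
    batch: GraphBatch,
    params: WLNParams,
    zero_attention: bool = False,
) -> Tuple[Tensor, np.ndarray]:
    """Pairwise reactivity scores from embeddings plus global attention.

    Returns a (P, T) tensor of logistic-squashed scores over the batch's
    mapped-atom pairs and bond-type vocabulary, and the (P,) symmetrized
    attention weights for inspection.  ``zero_attention=True`` forces every
    attention weight to zero (the local-only ablation).
    """
    t = params.tensors
    if zero_attention:
        ctx = Tensor(np.zeros_like(h.data))
        att_mat = np.zeros((batch.n_atoms, batch.n_atoms))
    else:
        att = sigmoid((h @ t["W_att"]) @ h.T)
        att = att * Tensor(batch.same_graph)
        ctx = att @ h
        att_mat = att.data

    hi = gather(h, batch.pair_i)
    hj = gather(h, batch.pair_j)
    ci = gather(ctx, batch.pair_i)
    cj = gather(ctx, batch.pair_j)
    z = relu(
        hi @ t["U_loc"] + hj @ t["U_loc"]
        + ci @ t["U_ctx"] + cj @ t["U_ctx"]
        + Tensor(batch.pair_bf) @ t["U_bf"] + t["b_h"]
    )
    scores = sigmoid(z @ t["W_out"] + t["b_out"])
    pair_att = 0.5 * (att_mat[batch.pair_i, batch.pair_j] + att_mat[batch.pair_j, batch.pair_i])
    return scores, pair_att


@dataclass
class PairScores:
    """Reactivity scores of one reaction's mapped-atom pairs.

    ``scores[p, t]`` is the squashed score of pair ``pairs[p]`` taking bond
    type ``bond_vocab[t]`` in the product; ``attention[p]`` the symmetrized
    attention weight between the two atoms.
    """

    pairs: List[Tuple[int, int]]  # (map1, map2), map1 < map2
    scores: np.ndarray  # (P, T)
    attention: np.ndarray  # (P,)
    bond_vocab: Tuple[str, ...]

    def as_dict(self) -> Dict[Tuple[int, int, str], float]:
        return {
            (a1, a2, bond): float(self.scores[p, t])
            for p, (a1, a2) in enumerate(self.pairs)
            for t, bond in enumerate(self.bond_vocab)
        }


@dataclass
class CenterPrediction:
    centers: List[ReactionCenter]  # descending score
    k: int


def pair_scores(g: MolGraph, params: WLNParams, zero_attention: bool = False) -> PairScores:
    """Score one reactant graph.  Graphs with <2 mapped atoms give an empty map."""
    batch = GraphBatch([g])
    if batch.n_pairs == 0:
        import logging

        logging.getLogger("rxnteacher").warning(
            "graph has fewer than 2 mapped atoms; no scorable pairs"
        )
        return PairScores([], np.zeros((0, len(params.config.bond_vocab))),
                          np.zeros(0), params.config.bond_vocab)
    h = wln_embed(batch, params)
    scores, att = attend_and_score(h, batch, params, zero_attention=zero_attention)
    return PairScores(
        pairs=list(batch.pair_maps),
        scores=scores.data,
        attention=att,
        bond_vocab=params.config.bond_vocab,
    )


def predict_centers(ps: PairScores, k: int) -> CenterPrediction:
    """Top-k centers: per-pair argmax bond type, then the k best pairs.

    Ties are broken deterministically by ascending (a1, a2, bond-type index),
    so a fixed score map always yields the same selection.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    entries = []
    for p, (a1, a2) in enumerate(ps.pairs):
        t = int(np.argmax(ps.scores[p]))
        entries.append((-float(ps.scores[p, t]), a1, a2, t))
    entries.sort()
    centers = [
        ReactionCenter(a1, a2, ps.bond_vocab[t]) for (_, a1, a2, t) in entries[:k]
    ]
    return CenterPrediction(centers=centers, k=k)


def covers_true_centers(pred: CenterPrediction, tr: FrozenSet[ReactionCenter]) -> bool:
    """The correctness criterion: R(p) ⊇ TR(p), bond types included."""
    return set(pred.centers) >= set(tr)


def center_coverage(
    records: Sequence[ReactionRecord],
    params: WLNParams,
    k: int = 5,
    batch_size: int = 32,
) -> float:
    """Fraction of labeled records whose top-k prediction covers TR(p)."""
    if not records:
        return float("nan")
    hits = 0
    for lo in range(0, len(records), batch_size):
        chunk = records[lo : lo + batch_size]
        batch = GraphBatch([r.reactants for r in chunk])
        h = wln_embed(batch, params)
        scores, att = attend_and_score(h, batch, params)
        for r, (s, e) in zip(chunk, batch.pair_slices):
            ps = PairScores(
                pairs=batch.pair_maps[s:e],
                scores=scores.data[s:e],
                attention=att[s:e],
                bond_vocab=params.config.bond_vocab,
            )
            if covers_true_centers(predict_centers(ps, k), r.true_centers):
                hits += 1
    return hits / len(records)


# ---------------------------------------------------------------------------
# persistence / inspection
# ---------------------------------------------------------------------------


def save_params(params: WLNParams, path) -> None:
    """Single-file checkpoint: named tensors plus a JSON config header."""
    header = json.dumps(
        {
            "depth": params.config.depth,
            "hidden_dim": params.config.hidden_dim,
            "bond_vocab": list(params.config.bond_vocab),
            "pool_radius": params.pool_radius,
        }
    )
    np.savez_compressed(
        path, __config__=np.frombuffer(header.encode(), dtype=np.uint8),
        **{k: t.data for k, t in params.tensors.items()},
    )


def load_params(path) -> WLNParams:
    with np.load(path) as z:
        cfg = json.loads(bytes(z["__config__"]).decode())
        tensors = {
            k: Tensor(z[k].copy(), requires_grad=True)
            for k in z.files
            if k != "__config__"
        }
    config = WLNConfig(
        depth=cfg["depth"], hidden_dim=cfg["hidden_dim"], bond_vocab=tuple(cfg["bond_vocab"])
    )
    return WLNParams(config=config, tensors=tensors, pool_radius=cfg.get("pool_radius", 1))


def write_attention_tsv(g: MolGraph, params: WLNParams, path) -> None:
    """Dump per-atom-pair attention weights (map numbers) for visualization."""
    ps = pair_scores(g, params)
    with open(path, "w") as fh:
        fh.write("atom_i\tatom_j\tattention\n")
        for (a1, a2), w in zip(ps.pairs, ps.attention):
            fh.write(f"{a1}\t{a2}\t{w:.6f}\n")
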