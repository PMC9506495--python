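"""Weisfeiler-Lehman difference network: rank candidate products.

Each candidate product is embedded by a WLN tower of the same form as the
center model's; the *difference vectors* — candidate-atom embedding minus
reactant-atom embedding, matched through the atom mapping — are pooled over
the atoms within one bond of the edited pairs and fed to a small scoring
head, giving a scalar s(p_i) per candidate.  Training minimizes the softmax
log-likelihood so the true product's score ranks first; evaluation reports
top-k accuracy (true product among the k best-scored valid candidates).

Restricting the pooling to the edited neighborhood is what makes this a
*difference* network: atoms far from every edit have identical embeddings in
candidate and reactants and contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor, clip_grad_norm, gather, logsumexp, relu, segment_sum
from .candidate_enum import Candidate, enumerate_candidates, label_true_candidate
from .reaction_io import ATOM_FDIM, BOND_FDIM, MolGraph, ReactionCenter, ReactionRecord
from .wln_center import (
    GraphBatch,
    WLNConfig,
    WLNParams,
    _glorot,
    pair_scores,
    predict_centers,
    wln_embed,
)

__all__ = [
    "WLDNConfig",
    "RankedSet",
    "RankTrainConfig",
    "RankTrainResult",
    "init_wldn_params",
    "wldn_score",
    "score_candidates",
    "rank_candidates",
    "rank_loss",
    "train_ranker",
    "evaluate_topk",
    "oracle_centers",
    "model_center_fn",
]


@dataclass(frozen=True)
class WLDNConfig:
    depth: int = 3
    hidden_dim: int = 300
    #: pooling neighborhood radius around edited atoms, in bonds
    pool_radius: int = 1
    bond_vocab: Tuple[str, ...] = ("none", "single", "double", "aromatic")


def init_wldn_params(config: WLDNConfig, rng: np.random.Generator) -> WLNParams:
    """Tower weights (same layer form as the center WLN) plus the scoring head."""
    H = config.hidden_dim
    shapes: Dict[str, Tuple[int, ...]] = {"W_in": (ATOM_FDIM, H)}
    for layer in range(config.depth):
        shapes[f"W_nei_{layer}"] = (H, H)
        shapes[f"W_bondm_{layer}"] = (BOND_FDIM, H)
        shapes[f"W_self_{layer}"] = (H, H)
        shapes[f"W_msg_{layer}"] = (H, H)
    shapes.update(M_pool=(H, H), b_pool=(H,), w_score=(H, 1), b_score=(1,))
    tensors = {
        name: Tensor(np.zeros(shape) if name.startswith("b_") else _glorot(rng, shape),
                     requires_grad=True)
        for name, shape in shapes.items()
    }
    wrapped = WLNConfig(depth=config.depth, hidden_dim=config.hidden_dim,
                        bond_vocab=config.bond_vocab)
    return WLNParams(config=wrapped, tensors=tensors, pool_radius=config.pool_radius)


def _pool_atoms(reactants: MolGraph, cand: Candidate, radius: int) -> List[int]:
    """Reactant atom indices within `radius` bonds of any edited atom."""
    edit_maps = {m for c in cand.applied for m in (c.a1, c.a2)}
    seeds = [reactants.index_of_map(m) for m in edit_maps]
    selected = set(seeds)
    frontier = list(seeds)
    for _ in range(radius):
        nxt = []
        for i in frontier:
            for j in reactants.adjacency[i]:
                if j not in selected:
                    selected.add(j)
                    nxt.append(j)
        frontier = nxt
    return sorted(selected)


def score_candidates(
    reactants: MolGraph,
    cands: Sequence[Candidate],
    params: WLNParams,
) -> Tensor:
    """Score a reaction's valid candidates in one batched forward; (m,) tensor."""
    if any(not c.valid for c in cands):
        raise ValueError("score_candidates expects valid candidates only")
    radius = getattr(params, "pool_radius", 1)
    batch = GraphBatch([reactants] + [c.graph for c in cands])
    h = wln_embed(batch, params)

    n0 = reactants.n_atoms
    reac_row_of_map = {
        int(m): i for i, m in enumerate(reactants.atom_map_nums) if m > 0
    }
    cand_rows, reac_rows, seg = [], [], []
    offset = n0
    for ci, c in enumerate(cands):
        g = c.graph
        cand_row_of_map = {int(m): i for i, m in enumerate(g.atom_map_nums) if m > 0}
        for i in _pool_atoms(reactants, c, radius):
            m = int(reactants.atom_map_nums[i])
            if m <= 0 or m not in cand_row_of_map:
                continue
            reac_rows.append(reac_row_of_map[m])
            cand_rows.append(offset + cand_row_of_map[m])
            seg.append(ci)
        offset += g.n_atoms

    diff = gather(h, np.asarray(cand_rows, dtype=np.intp)) - gather(
        h, np.asarray(reac_rows, dtype=np.intp)
    )
    pooled = segment_sum(diff, np.asarray(seg, dtype=np.intp), len(cands))
    t = params.tensors
    z = relu(pooled @ t["M_pool"] + t["b_pool"])
    return (z @ t["w_score"] + t["b_score"]).reshape(len(cands))


def wldn_score(reactants: MolGraph, cand: Candidate, params: WLNParams) -> float:
    """Scalar score of one valid candidate product."""
    if not cand.valid:
        raise ValueError("cannot score an invalid candidate")
    return float(score_candidates(reactants, [cand], params).data[0])


@dataclass
class RankedSet:
    """Candidates in descending score order; ties keep subset-enumeration order."""

    candidates: List[Candidate]
    scores: List[float]
    true_index: Optional[int]  # position of the true product in this order


def rank_candidates(
    reactants: MolGraph,
    cands: Sequence[Candidate],
    params: WLNParams,
    true_product: Optional[MolGraph] = None,
) -> RankedSet:
    valid = [c for c in cands if c.valid]
    if not valid:
        return RankedSet([], [], None)
    scores = score_candidates(reactants, valid, params).data
    order = sorted(range(len(valid)), key=lambda i: (-scores[i], i))
    ranked = [valid[i] for i in order]
    for c, i in zip(ranked, order):
        c.score = float(scores[i])
    true_index = None
    if true_product is not None:
        unranked_idx = label_true_candidate(valid, true_product)
        if unranked_idx is not None:
            true_index = order.index(unranked_idx)
    return RankedSet(ranked, [float(scores[i]) for i in order], true_index)


def rank_loss(rs: RankedSet) -> float:
    """-log softmax probability of the true product, max-subtracted."""
    if rs.true_index is None:
        raise ValueError("rank_loss requires the true product's position")
    s = np.asarray(rs.scores)
    m = s.max()
    return float(np.log(np.exp(s - m).sum()) - (s[rs.true_index] - m))


# ---------------------------------------------------------------------------
# center sources
# ---------------------------------------------------------------------------


def oracle_centers(record: ReactionRecord, k: int = 5) -> List[ReactionCenter]:
    """TR(p) padded to k with deterministic decoy pairs (single-bond edits)."""
    centers = sorted(record.true_centers)
    have = {(c.a1, c.a2) for c in centers}
    maps = sorted(int(m) for m in record.reactants.atom_map_nums if m > 0)
    for i in range(len(maps)):
        for j in range(i + 1, len(maps)):
            if len(centers) >= k:
                return centers[:k]
            if (maps[i], maps[j]) not in have:
                centers.append(ReactionCenter(maps[i], maps[j], "single"))
                have.add((maps[i], maps[j]))
    return centers[:k]


def model_center_fn(center_params, k: int = 5) -> Callable[[ReactionRecord], List[ReactionCenter]]:
    """Center source backed by a trained center model."""

    def fn(record: ReactionRecord) -> List[ReactionCenter]:
        ps = pair_scores(record.reactants, center_params)
        return predict_centers(ps, k).centers

    return fn


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankTrainConfig:
    depth: int = 3
    hidden_dim: int = 300
    pool_radius: int = 1
    k: int = 5
    lr0: float = 0.001
    epochs: int = 3
    seed: int = 0
    #: global gradient-norm cap; single-reaction steps occasionally produce
    #: spiky gradients that otherwise derail a converged model
    max_grad_norm: float = 5.0


@dataclass
class RankTrainResult:
    params: WLNParams
    history: pd.DataFrame
    n_skipped: int  # records whose true product was not among valid candidates


def _prepared(records, center_fn, k):
    """Candidates + true index per record; None where the true product is lost."""
    out = []
    for r in records:
        centers = center_fn(r)[:k]
        if not centers:
            out.append(None)
            continue
        cands = enumerate_candidates(r.reactants, centers)
        valid = [c for c in cands if c.valid]
        idx = label_true_candidate(valid, r.product) if r.product is not None else None
        out.append((r, valid, idx))
    return out


def train_ranker(
    records: Sequence[ReactionRecord],
    center_fn: Callable[[ReactionRecord], List[ReactionCenter]],
    config: RankTrainConfig,
    val_records: Sequence[ReactionRecord] = (),
) -> RankTrainResult:
    """Fit the difference network by per-reaction softmax log-likelihood.

    ``center_fn`` supplies the candidate centers (a trained center model, or
    :func:`oracle_centers` for controlled experiments).  Records whose true
    product does not survive into the valid candidate set are skipped in the
    loss and counted; if none survive the center source is broken and an
    error is raised.
    """
    ss = np.random.SeedSequence(config.seed)
    init_rng, order_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    params = init_wldn_params(
        WLDNConfig(depth=config.depth, hidden_dim=config.hidden_dim,
                   pool_radius=config.pool_radius),
        init_rng,
    )
    prepared = [p for p in _prepared(records, center_fn, config.k) if p is not None]
    usable = [(r, valid, idx) for (r, valid, idx) in prepared if idx is not None and valid]
    n_skipped = len(records) - len(usable)
    if not usable:
        raise ValueError(
            "no training record retains its true product among valid candidates; "
            "the center source is broken"
        )

    opt = Adam(params.trainable(), lr=config.lr0)
    rows = []
    for epoch in range(config.epochs):
        order = order_rng.permutation(len(usable))
        losses = []
        for i in order:
            r, valid, idx = usable[i]
            scores = score_candidates(r.reactants, valid, params)
            loss = logsumexp(scores) - scores[np.asarray([idx])].sum()
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"non-finite ranking loss on record {r.id!r}")
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(params.trainable(), config.max_grad_norm)
            opt.step()
            losses.append(loss.item())
        row = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val_records:
            report = evaluate_topk(val_records, None, params, ks=(1,),
                                   center_fn=center_fn, k_centers=config.k)
            row["val_top1"] = report["topk"][1]
        rows.append(row)
    return RankTrainResult(params=params, history=pd.DataFrame(rows), n_skipped=n_skipped)


def evaluate_topk(
    records: Sequence[ReactionRecord],
    center_params,
    ranker_params: WLNParams,
    ks: Sequence[int] = (1, 2, 3, 5),
    center_fn: Optional[Callable[[ReactionRecord], List[ReactionCenter]]] = None,
    k_centers: int = 5,
) -> Dict:
    """Top-k product accuracy of the two-stage pipeline on labeled records.

    A record counts correct at k when its true product is among the k
    highest-scored valid candidates; records losing their true product at the
    center or enumeration stage count as failures at every k.  Also reports
    center coverage (R(p) ⊇ TR(p)) and the candidate validity rate.
    """
    if center_fn is None:
        if center_params is None:
            raise ValueError("need either center_params or center_fn")
        center_fn = model_center_fn(center_params, k=k_centers)
    ks = sorted(ks)
    hits = {k: 0 for k in ks}
    covered = 0
    n_valid = 0
    n_cands = 0
    for r in records:
        centers = center_fn(r)[:k_centers]
        if set(centers) >= set(r.true_centers):
            covered += 1
        cands = enumerate_candidates(r.reactants, centers) if centers else []
        n_cands += len(cands)
        valid = [c for c in cands if c.valid]
        n_valid += len(valid)
        rs = rank_candidates(r.reactants, valid, ranker_params, true_product=r.product)
        if rs.true_index is None:
            continue
        for k in ks:
            if rs.true_index < k:
                hits[k] += 1
    n = len(records)
    return {
        "topk": {k: hits[k] / n for k in ks},
        "center_coverage": covered / n,
        "candidate_validity_rate": n_valid / n_cands if n_cands else float("nan"),
        "n_records": n,
    }
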