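"""Semi-supervised mean-teacher training of the center-scoring network.

Two copies of the WLN are kept: the *student*, trained by gradient descent,
and the *teacher*, an exponential moving average of the student that never
receives gradients.  Each step the student sees a perturbed reactant graph
(every atom's feature vector is independently zeroed with probability
``lambda``) while the teacher sees the clean graph; the student minimizes

    L_stu = L_CEL + omega * L_MSE

where L_CEL is the binary cross-entropy of the student's pair scores against
the true center labels (labeled data only) and L_MSE is the mean squared
difference between student and teacher score vectors (labeled and unlabeled
data) — the teacher's scores acting as soft pseudo-labels.  After each
student update the teacher parameters are refreshed by EMA.

Two EMA conventions are shipped: ``standard`` blends the previous *teacher*
with the current student (theta_t <- alpha*theta_t + (1-alpha)*theta_s), the
usual mean-teacher rule; ``literal`` blends the two most recent *student*
iterates (theta_t <- alpha*theta_s^(i-1) + (1-alpha)*theta_s^i).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .reaction_io import BOND_VOCAB, MolGraph, ReactionCenter, ReactionRecord
from .wln_center import (
    GraphBatch,
    PairScores,
    WLNConfig,
    WLNParams,
    attend_and_score,
    center_coverage,
    init_wln_params,
    wln_embed,
)

logger = logging.getLogger("rxnteacher")

__all__ = [
    "PerturbConfig",
    "EMAConfig",
    "LossReport",
    "CenterTrainConfig",
    "TrainResult",
    "TrainingDiverged",
    "perturb",
    "perturb_features",
    "loss_cel",
    "loss_mse",
    "combined_loss",
    "ema_update",
    "train_center_model",
    "learning_rate",
    "consistency_weight",
]

_CLAMP = 1e-7


class TrainingDiverged(RuntimeError):
    """Loss became non-finite; carries the step diagnostics."""


@dataclass(frozen=True)
class PerturbConfig:
    """Atom-feature dropout: each atom loses its features with prob lambda."""

    lam: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")


@dataclass(frozen=True)
class EMAConfig:
    alpha: float = 0.99
    mode: str = "standard"  # or "literal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.mode not in ("standard", "literal"):
            raise ValueError("mode must be 'standard' or 'literal'")


@dataclass(frozen=True)
class LossReport:
    l_cel: float
    l_mse: float
    omega: float

    @property
    def l_total(self) -> float:
        return self.l_cel + self.omega * self.l_mse


def perturb_features(features: np.ndarray, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Zero whole atom rows independently with probability lam."""
    if lam <= 0.0:
        return features
    keep = (rng.random(features.shape[0]) >= lam)[:, None]
    return features * keep


def perturb(g: MolGraph, cfg: PerturbConfig, rng: np.random.Generator) -> MolGraph:
    """Perturbed copy of a graph: features dropped, topology/bonds/maps intact."""
    return dataclasses.replace(g, features=perturb_features(g.features, cfg.lam, rng))


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _labels_for(pairs, bond_vocab, tr: FrozenSet[ReactionCenter]) -> np.ndarray:
    y = np.zeros((len(pairs), len(bond_vocab)))
    index = {(c.a1, c.a2, c.new_bond) for c in tr}
    for p, (a1, a2) in enumerate(pairs):
        for t, bond in enumerate(bond_vocab):
            if (a1, a2, bond) in index:
                y[p, t] = 1.0
    return y


def _cel_tensor(scores: Tensor, y: np.ndarray) -> Tensor:
    s = scores.clip(_CLAMP, 1.0 - _CLAMP)
    return -(Tensor(y) * s.log() + Tensor(1.0 - y) * (1.0 - s).log()).sum()


def loss_cel(student_scores: PairScores, tr: FrozenSet[ReactionCenter]) -> float:
    """Binary cross-entropy, summed over every (pair, bond-type) slot."""
    if len(student_scores.pairs) == 0:
        raise ValueError("empty score map: no scorable pairs")
    y = _labels_for(student_scores.pairs, student_scores.bond_vocab, tr)
    s = np.clip(student_scores.scores, _CLAMP, 1.0 - _CLAMP)
    return float(-(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)).sum())


def loss_mse(student_scores: PairScores, teacher_scores: PairScores) -> float:
    """Mean squared student-teacher score difference over identical slots."""
    if (
        student_scores.pairs != teacher_scores.pairs
        or student_scores.bond_vocab != teacher_scores.bond_vocab
    ):
        raise ValueError("student and teacher score maps have mismatched slots")
    d = teacher_scores.scores - student_scores.scores
    return float(np.mean(d * d))


def combined_loss(l_cel: Optional[float], l_mse: float, omega: float) -> LossReport:
    """L_stu = L_CEL + omega * L_MSE; absent CEL (unlabeled batch) counts as 0."""
    if omega < 0:
        raise ValueError("omega must be >= 0")
    return LossReport(l_cel=l_cel if l_cel is not None else 0.0, l_mse=l_mse, omega=omega)


# ---------------------------------------------------------------------------
# EMA
# ---------------------------------------------------------------------------


def ema_update(
    teacher: WLNParams,
    student_prev: Optional[WLNParams],
    student_now: WLNParams,
    cfg: EMAConfig,
) -> WLNParams:
    """Refresh teacher weights; gradients never reach the teacher.

    standard: theta_t <- alpha*theta_t      + (1-alpha)*theta_s^i
    literal:  theta_t <- alpha*theta_s^(i-1) + (1-alpha)*theta_s^i
    """
    a = cfg.alpha
    for name, t_tea in teacher.tensors.items():
        s_now = student_now.tensors[name].data
        if t_tea.data.shape != s_now.shape:
            raise ValueError(f"shape mismatch for parameter {name!r}")
        if cfg.mode == "standard":
            t_tea.data = a * t_tea.data + (1.0 - a) * s_now
        else:
            if student_prev is None:
                raise ValueError("literal EMA mode requires the previous student iterate")
            t_tea.data = a * student_prev.tensors[name].data + (1.0 - a) * s_now
    return teacher


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def learning_rate(step: int, lr0: float = 0.01, decay: float = 0.95, every: int = 10000) -> float:
    """lr(step) = lr0 * decay^floor(step/every)."""
    return lr0 * decay ** (step // every)


def consistency_weight(step: int, steps: int, omega_max: float, ramp_fraction: float) -> float:
    """Sigmoid ramp of omega from 0 to omega_max over the first ramp fraction."""
    if omega_max <= 0.0:
        return 0.0
    ramp = max(1, int(round(ramp_fraction * steps)))
    p = min(1.0, (step + 1) / ramp)
    return float(omega_max * np.exp(-5.0 * (1.0 - p) ** 2))


@dataclass(frozen=True)
class CenterTrainConfig:
    """Everything that determines a center-model training run."""

    depth: int = 3
    hidden_dim: int = 300
    bond_vocab: Tuple[str, ...] = BOND_VOCAB
    lam: float = 0.1
    omega_max: float = 1.0
    ramp_fraction: float = 0.1
    alpha: float = 0.99
    ema_mode: str = "standard"
    lr0: float = 0.01
    lr_decay: float = 0.95
    decay_every: int = 10000
    batch_size: int = 16
    unlabeled_batch_size: int = 16
    steps: int = 2000
    seed: int = 0
    k: int = 5
    eval_every: int = 0  # 0: only at the end
    supervised_only: bool = False

    def wln_config(self) -> WLNConfig:
        return WLNConfig(depth=self.depth, hidden_dim=self.hidden_dim,
                         bond_vocab=self.bond_vocab)


@dataclass
class TrainResult:
    student: WLNParams
    teacher: Optional[WLNParams]
    history: pd.DataFrame


def _sample(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    if n >= size:
        return rng.choice(n, size=size, replace=False)
    return rng.choice(n, size=size, replace=True)


def train_center_model(
    labeled: Sequence[ReactionRecord],
    unlabeled: Sequence[ReactionRecord],
    config: CenterTrainConfig,
    val_records: Sequence[ReactionRecord] = (),
) -> TrainResult:
    """Run the mean-teacher loop (or plain supervised training).

    Per step: the student scores a perturbed batch, the teacher the clean
    batch; L_CEL comes from the labeled half, L_MSE from all graphs; the
    combined loss is backpropagated into the student only and the teacher is
    EMA-updated.  With ``supervised_only=True`` (or omega_max = 0, lambda = 0
    and no unlabeled pool) the loop degenerates to supervised WLN training
    with an identical random stream, so the loss trajectories coincide.
    """
    if not labeled:
        raise ValueError("at least one labeled record is required")

    ss = np.random.SeedSequence(config.seed)
    init_rng, order_rng, perturb_rng, unl_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    student = init_wln_params(config.wln_config(), init_rng)
    teacher = None if config.supervised_only else student.copy()
    ema_cfg = EMAConfig(alpha=config.alpha, mode=config.ema_mode)
    opt = Adam(student.trainable(), lr=config.lr0)

    rows: List[Dict[str, float]] = []
    for step in range(config.steps):
        lr = learning_rate(step, config.lr0, config.lr_decay, config.decay_every)
        opt.lr = lr
        omega = (
            0.0
            if config.supervised_only
            else consistency_weight(step, config.steps, config.omega_max, config.ramp_fraction)
        )

        lab_idx = _sample(order_rng, len(labeled), min(config.batch_size, len(labeled)))
        lab_records = [labeled[i] for i in lab_idx]
        use_consistency = omega > 0.0 and not config.supervised_only
        unl_records: List[ReactionRecord] = []
        if use_consistency and unlabeled:
            unl_idx = _sample(unl_rng, len(unlabeled),
                              min(config.unlabeled_batch_size, len(unlabeled)))
            unl_records = [unlabeled[i] for i in unl_idx]

        batch = GraphBatch([r.reactants for r in lab_records + unl_records])
        stu_feats = (
            perturb_features(batch.features, config.lam, perturb_rng)
            if config.lam > 0.0 and not config.supervised_only
            else None
        )
        h_stu = wln_embed(batch, student, features=stu_feats)
        s_stu, _ = attend_and_score(h_stu, batch, student)

        y = np.zeros_like(s_stu.data)
        n_lab_pairs = batch.pair_slices[len(lab_records) - 1][1]
        for r, (lo, hi) in zip(lab_records, batch.pair_slices):
            y[lo:hi] = _labels_for(batch.pair_maps[lo:hi], config.bond_vocab, r.true_centers)

        cel = _cel_tensor(s_stu[np.arange(n_lab_pairs)], y[:n_lab_pairs]) * (
            1.0 / len(lab_records)
        )
        if use_consistency:
            h_tea = wln_embed(batch, teacher)
            s_tea, _ = attend_and_score(h_tea, batch, teacher)
            diff = Tensor(s_tea.data) - s_stu  # teacher treated as constant
            mse = (diff * diff).mean()
            total = cel + omega * mse
            l_mse = mse.item()
        else:
            total = cel
            l_mse = 0.0

        if not np.isfinite(total.item()):
            raise TrainingDiverged(
                f"non-finite loss at step {step}: cel={cel.item()}, mse={l_mse}, lr={lr}"
            )

        opt.zero_grad()
        total.backward()
        student_prev = (
            student.copy() if (teacher is not None and ema_cfg.mode == "literal") else None
        )
        opt.step()
        if teacher is not None:
            ema_update(teacher, student_prev, student, ema_cfg)

        row = {
            "step": step,
            "lr": lr,
            "omega": omega,
            "l_cel": cel.item(),
            "l_mse": l_mse,
            "l_total": total.item(),
        }
        if val_records and config.eval_every and (step + 1) % config.eval_every == 0:
            row["val_center_acc_student"] = center_coverage(val_records, student, k=config.k)
            row["val_center_acc_teacher"] = (
                center_coverage(val_records, teacher, k=config.k)
                if teacher is not None
                else np.nan
            )
        rows.append(row)

    history = pd.DataFrame(rows)
    if val_records:
        final = {
            "val_center_acc_student": center_coverage(val_records, student, k=config.k),
            "val_center_acc_teacher": (
                center_coverage(val_records, teacher, k=config.k)
                if teacher is not None
                else np.nan
            ),
        }
        for key, v in final.items():
            history.loc[history.index[-1], key] = v
    return TrainResult(student=student, teacher=teacher, history=history)
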