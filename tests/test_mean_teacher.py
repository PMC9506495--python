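"""Perturbation, loss algebra, EMA, and the training loop's contracts."""

import numpy as np
import pytest

from rxnteacher.mean_teacher import (
    CenterTrainConfig,
    EMAConfig,
    PerturbConfig,
    combined_loss,
    consistency_weight,
    ema_update,
    learning_rate,
    loss_cel,
    loss_mse,
    perturb,
    perturb_features,
    train_center_model,
)
from rxnteacher.reaction_io import ReactionCenter, featurize, mol_from_smiles
from rxnteacher.wln_center import (
    PairScores,
    WLNConfig,
    init_wln_params,
)

VOCAB = ("none", "single", "double", "aromatic")


def _random_ps(rng, n_pairs=20):
    pairs = [(i, i + 1) for i in range(1, n_pairs + 1)]
    return PairScores(pairs=pairs, scores=rng.uniform(0.01, 0.99, size=(n_pairs, 4)),
                      attention=np.zeros(n_pairs), bond_vocab=VOCAB)


class TestPerturb:
    def test_lambda_zero_is_identity(self):
        g = featurize(mol_from_smiles("[CH3:1][CH2:2][OH:3]"))
        out = perturb(g, PerturbConfig(lam=0.0), np.random.default_rng(0))
        assert np.array_equal(out.features, g.features)

    def test_lambda_one_zeroes_every_atom_but_not_bonds(self):
        g = featurize(mol_from_smiles("[CH3:1][CH2:2][OH:3]"))
        out = perturb(g, PerturbConfig(lam=1.0), np.random.default_rng(0))
        assert np.all(out.features == 0.0)
        assert np.array_equal(out.bond_features, g.bond_features)
        assert out.bonds == g.bonds
        assert np.array_equal(g.features, featurize(g.mol).features)  # input untouched

    def test_drop_fraction_concentrates_at_lambda(self):
        feats = np.ones((10_000, 4))
        out = perturb_features(feats, 0.3, np.random.default_rng(7))
        dropped = float((out.sum(axis=1) == 0).mean())
        assert dropped == pytest.approx(0.3, abs=0.02)


class TestLossAlgebra:
    def test_cel_zero_when_scores_equal_labels(self):
        ps = PairScores([(1, 2)], np.array([[1.0, 0.0, 0.0, 0.0]]), np.zeros(1), VOCAB)
        assert loss_cel(ps, frozenset({ReactionCenter(1, 2, "none")})) == pytest.approx(
            0.0, abs=1e-5
        )

    def test_cel_single_slot_half_score_is_ln2(self):
        # one positive slot at s=0.5 contributes ln 2; the three negative
        # slots at s=0 contribute 0 after clamping
        ps = PairScores([(1, 2)], np.array([[0.5, 0.0, 0.0, 0.0]]), np.zeros(1), VOCAB)
        got = loss_cel(ps, frozenset({ReactionCenter(1, 2, "none")}))
        assert got == pytest.approx(np.log(2), abs=1e-5)

    def test_cel_matches_bruteforce_sum(self):
        rng = np.random.default_rng(1)
        ps = _random_ps(rng)
        tr = frozenset({ReactionCenter(1, 2, "single"), ReactionCenter(5, 6, "none")})
        y = np.zeros((20, 4))
        y[0, 1] = 1.0
        y[4, 0] = 1.0
        expected = -np.sum(y * np.log(ps.scores) + (1 - y) * np.log(1 - ps.scores))
        assert loss_cel(ps, tr) == pytest.approx(expected, abs=1e-6)

    def test_cel_empty_score_map_raises(self):
        empty = PairScores([], np.zeros((0, 4)), np.zeros(0), VOCAB)
        with pytest.raises(ValueError):
            loss_cel(empty, frozenset())

    def test_mse_identical_maps_is_zero_and_example_value(self):
        rng = np.random.default_rng(2)
        ps = _random_ps(rng)
        assert loss_mse(ps, ps) == 0.0
        a = PairScores([(1, 2)], np.array([[0.5, 0.5, 0.0, 0.0]]), np.zeros(1), VOCAB)
        b = PairScores([(1, 2)], np.array([[0.6, 0.8, 0.0, 0.0]]), np.zeros(1), VOCAB)
        # squared diffs 0.01 and 0.09 over 4 slots -> mean 0.025
        assert loss_mse(a, b) == pytest.approx(0.1 / 4, abs=1e-12)

    def test_mse_mismatched_slots_raise(self):
        rng = np.random.default_rng(3)
        a, b = _random_ps(rng), _random_ps(rng, n_pairs=19)
        with pytest.raises(ValueError):
            loss_mse(a, b)

    @pytest.mark.parametrize(
        "l_cel,l_mse,omega,total",
        [(1.0, 0.5, 2.0, 2.0), (3.0, 9.9, 0.0, 3.0), (None, 0.5, 2.0, 1.0)],
    )
    def test_combined_loss_arithmetic(self, l_cel, l_mse, omega, total):
        rep = combined_loss(l_cel, l_mse, omega)
        assert rep.l_total == pytest.approx(total)
        assert rep.l_total == pytest.approx(rep.l_cel + rep.omega * rep.l_mse)


class TestEMA:
    def _params(self, seed):
        return init_wln_params(WLNConfig(depth=1, hidden_dim=4), np.random.default_rng(seed))

    def test_alpha_zero_copies_current_student_in_both_modes(self):
        for mode in ("standard", "literal"):
            tea, prev, now = self._params(0), self._params(1), self._params(2)
            ema_update(tea, prev, now, EMAConfig(alpha=0.0, mode=mode))
            for k in tea.tensors:
                assert np.array_equal(tea.tensors[k].data, now.tensors[k].data)

    def test_standard_mode_converges_geometrically_to_constant_student(self):
        tea, stu = self._params(0), self._params(1)
        gap0 = {k: stu.tensors[k].data - tea.tensors[k].data for k in tea.tensors}
        for step in range(1, 4):
            ema_update(tea, None, stu, EMAConfig(alpha=0.5, mode="standard"))
            for k in tea.tensors:
                gap = stu.tensors[k].data - tea.tensors[k].data
                assert np.allclose(gap, gap0[k] * 0.5**step, atol=1e-12)

    def test_literal_mode_with_frozen_student_equals_student_after_one_step(self):
        tea, stu = self._params(0), self._params(1)
        ema_update(tea, stu, stu, EMAConfig(alpha=0.7, mode="literal"))
        for k in tea.tensors:
            assert np.allclose(tea.tensors[k].data, stu.tensors[k].data)

    def test_two_step_hand_trace_both_modes(self):
        """Teacher follows the hand-computed recursion on a 2-step trajectory."""
        s0, s1, s2 = self._params(0), self._params(1), self._params(2)
        a = 0.9
        tea = s0.copy()
        ema_update(tea, s0, s1, EMAConfig(alpha=a, mode="standard"))
        ema_update(tea, s1, s2, EMAConfig(alpha=a, mode="standard"))
        for k in tea.tensors:
            hand = a * (a * s0.tensors[k].data + (1 - a) * s1.tensors[k].data) + (
                1 - a
            ) * s2.tensors[k].data
            assert np.allclose(tea.tensors[k].data, hand, atol=1e-12)
        tea = s0.copy()
        ema_update(tea, s0, s1, EMAConfig(alpha=a, mode="literal"))
        ema_update(tea, s1, s2, EMAConfig(alpha=a, mode="literal"))
        for k in tea.tensors:
            hand = a * s1.tensors[k].data + (1 - a) * s2.tensors[k].data
            assert np.allclose(tea.tensors[k].data, hand, atol=1e-12)

    def test_shape_mismatch_raises(self):
        tea = self._params(0)
        other = init_wln_params(WLNConfig(depth=1, hidden_dim=5), np.random.default_rng(1))
        with pytest.raises((ValueError, KeyError)):
            ema_update(tea, None, other, EMAConfig(alpha=0.5))


class TestSchedules:
    def test_learning_rate_decays_five_percent_every_10k_steps(self):
        assert learning_rate(0) == 0.01
        assert learning_rate(9_999) == 0.01
        assert learning_rate(10_000) == pytest.approx(0.0095)
        assert learning_rate(25_000) == pytest.approx(0.01 * 0.95**2)

    def test_consistency_weight_ramps_to_omega_max(self):
        assert consistency_weight(0, 100, 0.0, 0.1) == 0.0
        w_early = consistency_weight(0, 1000, 1.0, 0.1)
        w_late = consistency_weight(99, 1000, 1.0, 0.1)
        assert 0 < w_early < w_late <= 1.0
        assert w_late == pytest.approx(1.0)


class TestTrainingLoop:
    def test_teacher_receives_no_gradients(self, small_corpus):
        cfg = CenterTrainConfig(hidden_dim=12, steps=5, batch_size=4, seed=0,
                                lr0=0.002, lam=0.1, omega_max=1.0, ramp_fraction=0.01,
                                alpha=0.0)
        res = train_center_model(small_corpus.labeled[:8], small_corpus.unlabeled[:8], cfg)
        # alpha=0 forces teacher == student after every EMA step; if gradients
        # leaked into the teacher the two would drift apart
        for k in res.teacher.tensors:
            assert np.array_equal(res.teacher.tensors[k].data, res.student.tensors[k].data)
            assert res.teacher.tensors[k].grad is None

    def test_seeded_rerun_reproduces_history_exactly(self, small_corpus):
        cfg = CenterTrainConfig(hidden_dim=12, steps=8, batch_size=4, seed=3, lr0=0.002)
        h1 = train_center_model(small_corpus.labeled[:8], small_corpus.unlabeled[:8], cfg).history
        h2 = train_center_model(small_corpus.labeled[:8], small_corpus.unlabeled[:8], cfg).history
        assert np.allclose(h1["l_total"], h2["l_total"], atol=1e-6)

    def test_lambda_zero_teacher_equals_student_gives_zero_mse(self, small_corpus):
        """With unperturbed input and teacher==student, consistency loss is 0."""
        cfg = CenterTrainConfig(hidden_dim=12, steps=1, batch_size=4, seed=0,
                                lam=0.0, omega_max=1.0, ramp_fraction=1e-9)
        res = train_center_model(small_corpus.labeled[:4], [], cfg)
        assert res.history["l_mse"].iloc[0] == 0.0

    def test_no_labeled_data_is_an_error(self):
        with pytest.raises(ValueError):
            train_center_model([], [], CenterTrainConfig(steps=1))
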