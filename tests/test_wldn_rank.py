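"""Difference-network scoring, ranking loss, and top-k evaluation."""

import dataclasses

import numpy as np
import pytest
from rdkit import Chem

from rxnteacher.candidate_enum import Candidate, enumerate_candidates
from rxnteacher.reaction_io import featurize
from rxnteacher.wldn_rank import (
    RankedSet,
    RankTrainConfig,
    WLDNConfig,
    evaluate_topk,
    init_wldn_params,
    oracle_centers,
    rank_candidates,
    rank_loss,
    score_candidates,
    train_ranker,
    wldn_score,
)


@pytest.fixture(scope="module")
def wldn_params():
    return init_wldn_params(WLDNConfig(depth=2, hidden_dim=16), np.random.default_rng(9))


class TestWldnScore:
    def test_identical_candidate_scores_head_zero_output(self, small_corpus, wldn_params):
        """No edits -> all difference vectors vanish -> head sees zeros."""
        r = small_corpus.labeled[0]
        cand = Candidate(
            applied=frozenset(list(r.true_centers)[:1]),
            graph=r.reactants, smiles="", valid=True,
        )
        t = {k: v.data for k, v in wldn_params.tensors.items()}
        zero_out = float(
            (np.maximum(np.zeros(16) @ t["M_pool"] + t["b_pool"], 0) @ t["w_score"]
             + t["b_score"])[0]
        )
        assert wldn_score(r.reactants, cand, wldn_params) == pytest.approx(zero_out, abs=1e-10)

    def test_score_invariant_under_candidate_atom_relabeling(self, small_corpus, wldn_params):
        rng = np.random.default_rng(3)
        for r in small_corpus.labeled[:5]:
            cands = enumerate_candidates(r.reactants, sorted(r.true_centers))
            cand = next(c for c in cands if c.valid)
            s1 = wldn_score(r.reactants, cand, wldn_params)
            perm = rng.permutation(cand.graph.n_atoms).tolist()
            permuted = dataclasses.replace(
                cand, graph=featurize(Chem.RenumberAtoms(cand.graph.mol, perm))
            )
            s2 = wldn_score(r.reactants, permuted, wldn_params)
            assert s1 == pytest.approx(s2, abs=1e-5)

    def test_score_unchanged_when_spectators_are_permuted(self, wldn_params):
        """Fragment order in the reaction SMILES must not matter."""
        from rxnteacher.reaction_io import parse_reaction

        a = parse_reaction("[CH3:1][Cl:2].[NH3:3]>CCO>[ClH:2].[CH3:1][NH2:3]")
        b = parse_reaction("[NH3:3].[CH3:1][Cl:2]>CCO>[CH3:1][NH2:3].[ClH:2]")
        for r1, r2 in [(a, b)]:
            c1 = enumerate_candidates(r1.reactants, sorted(r1.true_centers))[-1]
            c2 = enumerate_candidates(r2.reactants, sorted(r2.true_centers))[-1]
            s1 = wldn_score(r1.reactants, c1, wldn_params)
            s2 = wldn_score(r2.reactants, c2, wldn_params)
            assert s1 == pytest.approx(s2, abs=1e-5)

    def test_invalid_candidate_rejected(self, small_corpus, wldn_params):
        bad = Candidate(applied=frozenset(), graph=None, smiles=None, valid=False)
        with pytest.raises(ValueError):
            wldn_score(small_corpus.labeled[0].reactants, bad, wldn_params)


class TestRankLoss:
    def _rs(self, scores, true_index):
        return RankedSet(candidates=[None] * len(scores), scores=list(scores),
                         true_index=true_index)

    def test_single_true_candidate_has_zero_loss(self):
        assert rank_loss(self._rs([3.7], 0)) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_scores_give_ln2(self):
        assert rank_loss(self._rs([1.1, 1.1], 0)) == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_softmax_oracle_on_random_scores(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = rng.normal(size=5)
            i = int(rng.integers(5))
            expected = -np.log(np.exp(s[i]) / np.exp(s).sum())
            assert rank_loss(self._rs(s, i)) == pytest.approx(expected, abs=1e-6)

    def test_shift_invariance(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=4)
        assert rank_loss(self._rs(s, 2)) == pytest.approx(
            rank_loss(self._rs(s + 123.0, 2)), abs=1e-9
        )

    def test_missing_true_index_raises(self):
        with pytest.raises(ValueError):
            rank_loss(self._rs([1.0, 2.0], None))


class TestRankLossProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        scores=st.lists(st.floats(-50, 50), min_size=1, max_size=12),
        shift=st.floats(-100, 100),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_softmax_loss_properties(self, scores, shift, data):
        """Non-negative, equals the softmax oracle, invariant to score shifts."""
        i = data.draw(self.st.integers(0, len(scores) - 1))
        rs = RankedSet([None] * len(scores), scores, i)
        loss = rank_loss(rs)
        s = np.asarray(scores)
        m = s.max()
        oracle = -np.log(np.exp(s[i] - m) / np.exp(s - m).sum())
        assert loss >= -1e-12
        assert loss == pytest.approx(oracle, abs=1e-9)
        shifted = RankedSet([None] * len(scores), (s + shift).tolist(), i)
        assert rank_loss(shifted) == pytest.approx(loss, abs=1e-6)


class TestEvaluation:
    def test_topk_monotone_and_k_covering_counts_correct(self, small_corpus, wldn_params):
        rep = evaluate_topk(
            small_corpus.labeled[:25], None, wldn_params,
            ks=(1, 2, 3, 5, 31), center_fn=lambda r: oracle_centers(r, 5),
        )
        accs = [rep["topk"][k] for k in (1, 2, 3, 5, 31)]
        assert accs == sorted(accs)
        # with oracle centers the true product always survives enumeration,
        # so k >= candidate count recovers every record
        assert rep["topk"][31] == 1.0
        assert rep["center_coverage"] == 1.0

    def test_ranked_order_is_descending_and_tie_stable(self, small_corpus, wldn_params):
        r = small_corpus.labeled[2]
        cands = enumerate_candidates(r.reactants, oracle_centers(r, 4))
        rs = rank_candidates(r.reactants, [c for c in cands if c.valid], wldn_params,
                             true_product=r.product)
        assert rs.scores == sorted(rs.scores, reverse=True)
        assert rs.true_index is not None

    def test_broken_center_source_raises_in_training(self, small_corpus):
        def disjoint_centers(r):
            return [c for c in oracle_centers(r, 5) if c not in r.true_centers][:2]

        with pytest.raises(ValueError):
            train_ranker(small_corpus.labeled[:5], disjoint_centers,
                         RankTrainConfig(hidden_dim=8, epochs=1))

    def test_seeded_rerun_gives_identical_history(self, small_corpus):
        cfg = RankTrainConfig(hidden_dim=8, epochs=1, seed=4)
        fn = lambda r: oracle_centers(r, 3)  # noqa: E731
        h1 = train_ranker(small_corpus.labeled[:10], fn, cfg).history
        h2 = train_ranker(small_corpus.labeled[:10], fn, cfg).history
        assert np.array_equal(h1["loss"].values, h2["loss"].values)
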