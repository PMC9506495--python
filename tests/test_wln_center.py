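"""Structural properties of the center-scoring network."""

import numpy as np
import pytest
from rdkit import Chem

from rxnteacher.reaction_io import featurize, mol_from_smiles
from rxnteacher.wln_center import (
    GraphBatch,
    PairScores,
    WLNConfig,
    attend_and_score,
    covers_true_centers,
    init_wln_params,
    pair_scores,
    predict_centers,
    wln_embed,
)
from rxnteacher.reaction_io import ReactionCenter


def _permuted(graph, rng):
    perm = rng.permutation(graph.n_atoms).tolist()
    return featurize(Chem.RenumberAtoms(graph.mol, perm))


class TestEmbedding:
    def test_permutation_equivariance_of_embeddings(self, small_corpus, tiny_params):
        """Relabeling atoms permutes embeddings; the multiset is invariant."""
        rng = np.random.default_rng(0)
        for r in small_corpus.labeled[:5]:
            g = r.reactants
            h1 = wln_embed(GraphBatch([g]), tiny_params).data
            g2 = _permuted(g, rng)
            h2 = wln_embed(GraphBatch([g2]), tiny_params).data
            by_map1 = {int(m): h1[i] for i, m in enumerate(g.atom_map_nums) if m > 0}
            by_map2 = {int(m): h2[i] for i, m in enumerate(g2.atom_map_nums) if m > 0}
            for m in by_map1:
                assert np.allclose(by_map1[m], by_map2[m], atol=1e-5)

    def test_single_atom_graph_embedding_depends_only_on_its_features(self, tiny_params):
        h_alone = wln_embed(GraphBatch([featurize(mol_from_smiles("[CH4:1]"))]), tiny_params).data
        h_with_other = wln_embed(
            GraphBatch([featurize(mol_from_smiles("[CH4:1]")),
                        featurize(mol_from_smiles("[NH3:1]"))]),
            tiny_params,
        ).data
        assert np.allclose(h_alone[0], h_with_other[0], atol=1e-12)

    def test_depth_zero_equals_input_projection(self):
        """With no message-passing rounds the embedding is relu(x W_in)."""
        rng = np.random.default_rng(1)
        params = init_wln_params(WLNConfig(depth=0, hidden_dim=8), rng)
        g = featurize(mol_from_smiles("[CH3:1][OH:2]"))
        h = wln_embed(GraphBatch([g]), params).data
        expected = np.maximum(g.features @ params.tensors["W_in"].data, 0.0)
        assert np.allclose(h, expected, atol=1e-12)

    def test_embeddings_are_deterministic_across_calls(self, small_corpus, tiny_params):
        g = small_corpus.labeled[0].reactants
        a = wln_embed(GraphBatch([g]), tiny_params).data
        b = wln_embed(GraphBatch([g]), tiny_params).data
        assert np.array_equal(a, b)


class TestAttendAndScore:
    def test_scores_invariant_under_atom_permutation(self, small_corpus, tiny_params):
        rng = np.random.default_rng(2)
        for r in small_corpus.labeled[:5]:
            d1 = pair_scores(r.reactants, tiny_params).as_dict()
            d2 = pair_scores(_permuted(r.reactants, rng), tiny_params).as_dict()
            assert d1.keys() == d2.keys()
            for k in d1:
                assert d1[k] == pytest.approx(d2[k], abs=1e-5)

    def test_zeroed_attention_equals_local_only_path(self, small_corpus, tiny_params):
        """With every attention weight forced to 0 the context term vanishes."""
        g = small_corpus.labeled[0].reactants
        batch = GraphBatch([g])
        h = wln_embed(batch, tiny_params)
        scores, att = attend_and_score(h, batch, tiny_params, zero_attention=True)
        assert np.all(att == 0.0)
        t = {k: v.data for k, v in tiny_params.tensors.items()}
        hi, hj = h.data[batch.pair_i], h.data[batch.pair_j]
        z = np.maximum(hi @ t["U_loc"] + hj @ t["U_loc"] + batch.pair_bf @ t["U_bf"] + t["b_h"], 0)
        expected = 1.0 / (1.0 + np.exp(-(z @ t["W_out"] + t["b_out"])))
        assert np.allclose(scores.data, expected, atol=1e-10)

    def test_attention_weights_lie_in_unit_interval(self, small_corpus, tiny_params):
        ps = pair_scores(small_corpus.labeled[1].reactants, tiny_params)
        assert np.all((ps.attention >= 0) & (ps.attention <= 1))
        assert np.all((ps.scores > 0) & (ps.scores < 1))

    def test_graph_with_fewer_than_two_mapped_atoms_gives_empty_map(self, tiny_params):
        ps = pair_scores(featurize(mol_from_smiles("[CH4:1]")), tiny_params)
        assert ps.pairs == [] and ps.scores.shape[0] == 0


class TestPredictCenters:
    def _ps(self, scores):
        pairs = [(1, 2), (1, 3), (2, 3)]
        return PairScores(pairs=pairs, scores=np.asarray(scores),
                          attention=np.zeros(3), bond_vocab=("none", "single", "double", "aromatic"))

    def test_k1_returns_global_argmax_pair(self):
        ps = self._ps([[0.1, 0.9, 0.2, 0.1], [0.3, 0.2, 0.1, 0.0], [0.5, 0.4, 0.3, 0.2]])
        pred = predict_centers(ps, 1)
        assert pred.centers == [ReactionCenter(1, 2, "single")]

    def test_equal_scores_break_ties_deterministically(self):
        ps = self._ps(np.full((3, 4), 0.5))
        a = predict_centers(ps, 2).centers
        b = predict_centers(ps, 2).centers
        assert a == b == [ReactionCenter(1, 2, "none"), ReactionCenter(1, 3, "none")]

    def test_k_larger_than_pair_count_returns_all_pairs(self):
        ps = self._ps(np.random.default_rng(0).random((3, 4)))
        assert len(predict_centers(ps, 10).centers) == 3

    def test_one_bond_type_per_pair(self):
        ps = self._ps([[0.9, 0.8, 0.1, 0.0], [0.2, 0.1, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]])
        pred = predict_centers(ps, 3)
        assert len({(c.a1, c.a2) for c in pred.centers}) == len(pred.centers)


def test_coverage_criterion_requires_matching_bond_types():
    pred_ok = predict_centers(
        PairScores([(1, 2)], np.array([[0.9, 0.1, 0.1, 0.1]]), np.zeros(1),
                   ("none", "single", "double", "aromatic")), 1)
    tr = frozenset({ReactionCenter(1, 2, "none")})
    assert covers_true_centers(pred_ok, tr)
    assert not covers_true_centers(pred_ok, frozenset({ReactionCenter(1, 2, "single")}))
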