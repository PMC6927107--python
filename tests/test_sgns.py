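"""Skip-gram with negative sampling: model init, losses, gradients, training."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from multipath2vec import (
    PCG32,
    SyntheticConfig,
    TrainConfig,
    WalkConfig,
    WalkStrategy,
    context_pairs,
    generate_corpus,
    generate_planted_network,
    init_model,
    mean_pair_loss,
    negative_sample,
    pair_loss_and_gradients,
    sgd_step,
    softmax_probability,
    train,
)
from multipath2vec.ranking import cosine_similarity
from multipath2vec.sgns import EmbeddingModel, _noise_cum
from multipath2vec.walks import WalkCorpus


@pytest.fixture
def tiny_corpus(small_planted):
    return generate_corpus(
        small_planted, WalkConfig(5, 12, WalkStrategy.MULTIPATH, seed=2)
    )


@pytest.fixture
def tiny_config():
    return TrainConfig(dimension=8, window=3, negatives=4, epochs=2, seed=2)


class TestInitModel:
    def test_shapes_and_zero_psi(self):
        m = init_model(["a", "b", "c"], 4, seed=1)
        assert m.phi.shape == (3, 4) and m.psi.shape == (3, 4)
        assert not m.psi.any()

    def test_reproducible(self):
        m1 = init_model(["a", "b"], 6, seed=5)
        m2 = init_model(["a", "b"], 6, seed=5)
        assert np.array_equal(m1.phi, m2.phi)

    def test_entries_strictly_inside_bounds(self):
        m = init_model([f"v{i}" for i in range(20)], 16, seed=0)
        assert np.all(np.abs(m.phi) < 0.5 / 16)

    def test_bad_dimension(self):
        with pytest.raises(ValueError):
            init_model(["a"], 0, seed=0)


@pytest.mark.parametrize(
    "walk,k,expected",
    [
        (("a", "b", "c"), 1, [("a", "b"), ("b", "a"), ("b", "c"), ("c", "b")]),
        (
            ("a", "b", "c"), 7,
            [("a", "b"), ("a", "c"), ("b", "a"), ("b", "c"), ("c", "a"), ("c", "b")],
        ),
        (("a",), 3, []),
    ],
)
def test_context_pairs(walk, k, expected):
    assert context_pairs(walk, k) == expected


class TestNegativeSample:
    def test_count_and_exclusion(self):
        freqs = {"a": 5, "b": 3, "c": 2}
        negs = negative_sample(freqs, 5, "a", PCG32(1))
        assert len(negs) == 5 and "a" not in negs

    def test_two_id_vocabulary(self):
        negs = negative_sample({"a": 1, "b": 9}, 4, "b", PCG32(2))
        assert negs == ["a"] * 4

    def test_vocab_only_exclude_is_error(self):
        with pytest.raises(ValueError):
            negative_sample({"a": 3}, 2, "a", PCG32(0))

    def test_draws_follow_power_distribution(self):
        """1e5 draws match unigram^0.75 by chi-square at the 1% level."""
        freqs = {"a": 100, "b": 40, "c": 10, "d": 1}
        vocab = sorted(freqs)
        n = 100_000
        rng = PCG32(7)
        counts = {v: 0 for v in vocab}
        # exclude a dummy never-matching id so the raw distribution is tested
        for v in negative_sample({**freqs, "zz": 1}, n, "zz", rng):
            counts[v] = counts.get(v, 0) + 1
        p = np.array([freqs[v] for v in vocab], dtype=float) ** 0.75
        # account for the tiny excluded mass
        p_full = np.append(p, 1.0**0.75)
        p_full /= p_full.sum()
        expected = p_full[:-1] / p_full[:-1].sum() * n
        observed = np.array([counts[v] for v in vocab], dtype=float)
        chi = stats.chisquare(observed, expected * observed.sum() / expected.sum())
        assert chi.pvalue > 0.01


class TestPairLoss:
    def test_zero_vectors_give_analytic_loss(self):
        m = EmbeddingModel(["a", "b", "c"], np.zeros((3, 4)), np.zeros((3, 4)))
        pl = pair_loss_and_gradients(m, "a", "b", ["c", "c", "b"])
        assert pl.loss == pytest.approx(4 * math.log(2))

    def test_saturated_scores_drive_loss_to_zero(self):
        phi = np.array([[50.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        psi = np.array([[0.0, 0.0], [50.0, 0.0], [-50.0, 0.0]])
        m = EmbeddingModel(["a", "b", "c"], phi, psi)
        pl = pair_loss_and_gradients(m, "a", "b", ["c"])
        assert pl.loss == pytest.approx(0.0, abs=1e-12)

    def test_unknown_id_is_error(self):
        m = init_model(["a", "b"], 2, 0)
        with pytest.raises(KeyError):
            pair_loss_and_gradients(m, "a", "zz", [])

    @pytest.mark.parametrize("seed", range(20))
    def test_gradients_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"v{i}" for i in range(6)]
        m = EmbeddingModel(
            ids, rng.normal(0, 1, (6, 5)), rng.normal(0, 1, (6, 5))
        )
        center, context = rng.choice(ids, 2)
        negs = list(rng.choice([v for v in ids], 3))
        pl = pair_loss_and_gradients(m, center, context, negs)
        h = 1e-6
        for table, grads in (("phi", pl.grad_phi), ("psi", pl.grad_psi)):
            mat = getattr(m, table)
            for vid, g in grads.items():
                row = m.index[vid]
                for j in range(5):
                    orig = mat[row, j]
                    mat[row, j] = orig + h
                    up = pair_loss_and_gradients(m, center, context, negs).loss
                    mat[row, j] = orig - h
                    dn = pair_loss_and_gradients(m, center, context, negs).loss
                    mat[row, j] = orig
                    fd = (up - dn) / (2 * h)
                    assert abs(g[j] - fd) <= 1e-5 * max(1.0, abs(fd))


class TestSgdStep:
    def test_zero_alpha_leaves_model_unchanged(self):
        m = init_model(["a", "b"], 3, 1)
        phi0, psi0 = m.phi.copy(), m.psi.copy()
        pl = pair_loss_and_gradients(m, "a", "b", ["b"])
        sgd_step(m, pl, 0.0)
        assert np.array_equal(m.phi, phi0) and np.array_equal(m.psi, psi0)

    def test_update_is_v_minus_alpha_grad(self):
        rng = np.random.default_rng(0)
        m = EmbeddingModel(["a", "b"], rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        pl = pair_loss_and_gradients(m, "a", "b", [])
        before = m.phi[m.index["a"]].copy()
        sgd_step(m, pl, 0.1)
        assert m.phi[m.index["a"]] == pytest.approx(before - 0.1 * pl.grad_phi["a"])

    def test_small_step_does_not_increase_loss(self):
        rng = np.random.default_rng(3)
        m = EmbeddingModel(["a", "b", "c"], rng.normal(size=(3, 4)), rng.normal(size=(3, 4)))
        negs = ["c"]
        before = pair_loss_and_gradients(m, "a", "b", negs)
        sgd_step(m, before, 1e-4)
        after = pair_loss_and_gradients(m, "a", "b", negs)
        assert after.loss <= before.loss + 1e-12


class TestTrain:
    def test_deterministic_given_seed(self, tiny_corpus, tiny_config):
        m1 = train(tiny_corpus, tiny_config)
        m2 = train(tiny_corpus, tiny_config)
        assert np.array_equal(m1.phi, m2.phi) and np.array_equal(m1.psi, m2.psi)

    def test_fast_and_reference_trainers_agree_exactly(self, tiny_corpus, tiny_config):
        small = WalkCorpus(tiny_corpus.walks[:40])
        m_fast = train(small, tiny_config, fast=True)
        m_ref = train(small, tiny_config, fast=False)
        assert np.array_equal(m_fast.phi, m_ref.phi)
        assert np.array_equal(m_fast.psi, m_ref.psi)

    def test_vocabulary_is_corpus_support(self, tiny_corpus, tiny_config):
        m = train(tiny_corpus, tiny_config)
        assert set(m.ids) == set(tiny_corpus.counts)

    def test_training_reduces_mean_pair_loss(self, tiny_corpus):
        cfg = TrainConfig(dimension=8, window=3, negatives=4, epochs=3, seed=4)
        m0 = init_model(sorted(tiny_corpus.counts), 8, seed=4)
        m1 = train(tiny_corpus, cfg)
        rng = PCG32(11)
        vocab = sorted(tiny_corpus.counts)
        eval_pairs, negs = [], []
        for w in tiny_corpus.walks[:30]:
            for c, ctx in context_pairs(w, 3)[:4]:
                eval_pairs.append((c, ctx))
                negs.append(negative_sample(tiny_corpus.counts, 4, ctx, rng))
        assert mean_pair_loss(m1, eval_pairs, negs) < mean_pair_loss(m0, eval_pairs, negs)

    def test_empty_corpus_is_error(self, tiny_config):
        with pytest.raises(ValueError):
            train(WalkCorpus([]), tiny_config)

    def test_same_type_negative_mode_runs(self, tiny_corpus):
        cfg = TrainConfig(dimension=8, window=3, negatives=3, epochs=1, seed=1,
                          same_type_negatives=True)
        m = train(tiny_corpus, cfg)
        assert np.isfinite(m.phi).all()

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_two_community_corpus_separates_in_embedding_space(self, seed):
        """Within-community cosine similarity exceeds between-community."""
        net, blocks = generate_planted_network(
            SyntheticConfig(blocks=2, genes_per_block=8, phens_per_block=5,
                            p_gg_in=0.5, p_pp_in=0.5, q=0.8, q_noise=0.0,
                            seed=seed)
        )
        assert len({blocks[v] for v in net.vertices()}) == 2
        corpus = generate_corpus(net, WalkConfig(20, 20, WalkStrategy.MULTIPATH, seed))
        m = train(corpus, TrainConfig(dimension=16, window=4, negatives=5,
                                      epochs=2, seed=seed))
        within, between = [], []
        ids = [v for v in m.ids]
        for i, u in enumerate(ids):
            for v in ids[i + 1:]:
                sim = cosine_similarity(m.phi_of(u), m.phi_of(v))
                (within if blocks[u] == blocks[v] else between).append(sim)
        assert np.mean(within) > np.mean(between)


class TestSoftmax:
    def test_identical_psi_rows_give_uniform(self):
        phi = np.random.default_rng(0).normal(size=(4, 3))
        psi = np.tile([0.3, -0.2, 1.0], (4, 1))
        m = EmbeddingModel(["a", "b", "c", "d"], phi, psi)
        for t in m.ids:
            assert softmax_probability(m, "a", t) == pytest.approx(0.25)

    def test_normalization(self):
        rng = np.random.default_rng(1)
        m = EmbeddingModel(
            [f"v{i}" for i in range(7)], rng.normal(size=(7, 4)), rng.normal(size=(7, 4))
        )
        total = sum(softmax_probability(m, "v0", t) for t in m.ids)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_hand_computation(self):
        phi = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        psi = np.array([[0.2, -0.1], [1.0, 0.3], [-0.4, 0.8]])
        m = EmbeddingModel(["a", "b", "c"], phi, psi)
        scores = psi @ phi[0]
        expected = np.exp(scores[1]) / np.exp(scores).sum()
        assert softmax_probability(m, "a", "b") == pytest.approx(expected, rel=1e-12)


def test_noise_cum_is_normalized_cumulative_power_law():
    cum = _noise_cum([16, 1])
    assert cum[-1] == pytest.approx(1.0)
    assert cum[0] == pytest.approx(8 / 9)  # 16^0.75 = 8, 1^0.75 = 1


class TestEmbeddingIO:
    def test_text_round_trip(self, tiny_corpus, tiny_config, tmp_path):
        m = train(tiny_corpus, tiny_config)
        f = tmp_path / "phi.emb"
        m.save(f)
        loaded = EmbeddingModel.load(f)
        assert loaded.ids == m.ids and loaded.d == m.d
        assert np.allclose(loaded.phi, m.phi, atol=1e-6)

    def test_header_and_precision(self, tmp_path):
        m = init_model(["a", "b"], 3, 0)
        f = tmp_path / "phi.emb"
        m.save(f)
        lines = f.read_text().splitlines()
        assert lines[0] == "2 3"
        assert len(lines) == 3 and len(lines[1].split()) == 4
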