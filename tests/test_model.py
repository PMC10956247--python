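import numpy as np
import pytest

from gnnmotif.graph import MultiViewGraph, build_graph
from gnnmotif.model import (
    GraphTensors,
    ModelDims,
    ModelState,
    TrainConfig,
    bce,
    forward,
    init_state,
    iterloss,
    load_checkpoint,
    loss_and_grads,
    save_checkpoint,
    train,
)

TINY_DIMS = ModelDims(dc=2, ds=2, dj=2, dsq=6)


class TestInitState:
    def test_deterministic_and_seed_sensitive(self):
        a = init_state(10, TINY_DIMS, seed=4)
        b = init_state(10, TINY_DIMS, seed=4)
        c = init_state(10, TINY_DIMS, seed=5)
        assert np.array_equal(a.Wco_train, b.Wco_train)
        assert not np.array_equal(a.Wco_train, c.Wco_train)

    def test_shapes(self):
        s = init_state(10, TINY_DIMS, seed=0)
        assert s.Wco_train.shape == (10, 2)
        assert s.Winclu_train.shape == (6, 6)
        assert s.w_out.shape == (6,)

    def test_per_node_output_shapes(self):
        s = init_state(10, TINY_DIMS, seed=0, n=7, per_node_output=True)
        assert s.w_out.shape == (7, 6)
        assert s.b_out.shape == (7,)


class TestForward:
    def test_zero_weights_give_half_probability(self, tiny_corpus):
        g = build_graph(tiny_corpus, lenk=3)
        s = init_state(g.m, TINY_DIMS, seed=0)
        for p in s.params().values():
            p[...] = 0.0
        out = forward(g, s)
        assert np.allclose(out.y_hat, 0.5)
        assert np.allclose(out.Esq, 0.0)

    def test_concatenation_width(self, tiny_corpus):
        g = build_graph(tiny_corpus, lenk=3)
        out = forward(g, init_state(g.m, TINY_DIMS, seed=1))
        assert out.Msc.shape == (g.m, 6)
        assert out.Esq.shape == (g.n, 6)
        assert (out.Eco >= 0).all() and (out.Esq >= 0).all()
        assert ((out.y_hat > 0) & (out.y_hat < 1)).all()

    def test_views_are_isolated_until_concatenation(self, tiny_corpus):
        g = build_graph(tiny_corpus, lenk=3)
        s = init_state(g.m, TINY_DIMS, seed=1)
        out1 = forward(g, s)
        s.Wco_train *= -1
        out2 = forward(g, s)
        assert np.array_equal(out1.Esim, out2.Esim)
        assert np.array_equal(out1.Ejac, out2.Ejac)

    def test_shape_mismatch_rejected(self, tiny_corpus):
        g = build_graph(tiny_corpus, lenk=3)
        with pytest.raises(ValueError):
            forward(g, init_state(g.m + 1, TINY_DIMS, seed=0))

    def test_kmer_permutation_equivariance(self, tiny_corpus):
        g = build_graph(tiny_corpus, lenk=3)
        s = init_state(g.m, TINY_DIMS, seed=2)
        base = forward(g, s).y_hat
        rng = np.random.default_rng(0)
        p = rng.permutation(g.m)
        gp = MultiViewGraph(
            vocab=g.vocab,
            Wco=g.Wco[np.ix_(p, p)], Wsim=g.Wsim[np.ix_(p, p)],
            Wjac=g.Wjac[np.ix_(p, p)], Winclu=g.Winclu[p],
            Ect=g.Ect[np.ix_(p, p)], Est=g.Est[np.ix_(p, p)],
            Ejt=g.Ejt[np.ix_(p, p)], seq_ids=g.seq_ids,
        )
        sp = ModelState(
            Wco_train=s.Wco_train[p], Wsim_train=s.Wsim_train[p],
            Wjac_train=s.Wjac_train[p], Winclu_train=s.Winclu_train,
            w_out=s.w_out, b_out=s.b_out, dims=s.dims,
        )
        assert np.allclose(forward(gp, sp).y_hat, base, atol=1e-12)


class TestLosses:
    def test_bce_closed_forms(self):
        assert bce(np.array([1.0]), np.array([1 - 1e-12]))[0] == pytest.approx(0, abs=1e-9)
        assert bce(np.array([1.0]), np.array([0.5]))[0] == pytest.approx(np.log(2))
        assert bce(np.array([0.0]), np.array([0.5]))[0] == pytest.approx(np.log(2))

    def test_iterloss_initial_epoch_equals_bce(self):
        curr = np.array([0.3, 1.2])
        assert np.allclose(iterloss(np.zeros(2), curr), curr)

    def test_iterloss_carried_term_is_sigmoid_weighted(self):
        val = iterloss(np.array([1.0]), np.array([0.25]))[0]
        expected = 1.0 / (1.0 + np.exp(-1.0)) + 0.25
        assert val == pytest.approx(expected)
        assert iterloss(np.zeros(1), np.zeros(1))[0] == 0.0

    def test_iterloss_dominates_bce(self):
        prev = np.abs(np.random.default_rng(0).normal(size=20))
        curr = np.abs(np.random.default_rng(1).normal(size=20))
        assert (iterloss(prev, curr) >= curr).all()


class TestGradients:
    def test_finite_difference_agreement(self, tiny_corpus):
        """Hand-derived backprop must match central finite differences."""
        g = build_graph(tiny_corpus, lenk=3)
        assert g.m <= 20 and g.n <= 10
        gt = GraphTensors(g)
        state = init_state(g.m, TINY_DIMS, seed=3)
        y = tiny_corpus.labels.astype(float)
        mask = np.array([s == "train" for s in tiny_corpus.splits])
        _, grads, _ = loss_and_grads(gt, state, y, mask)

        def loss_at(st):
            return loss_and_grads(gt, st, y, mask)[0]

        rng = np.random.default_rng(0)
        eps = 1e-6
        checked = 0
        for name, param in state.params().items():
            flat = param.reshape(-1)
            for idx in rng.choice(flat.size, size=min(2, flat.size),
                                  replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_at(state)
                flat[idx] = orig - eps
                down = loss_at(state)
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                an = grads[name].reshape(-1)[idx]
                denom = max(abs(fd), abs(an), 1e-8)
                assert abs(fd - an) / denom < 1e-4, (name, idx, fd, an)
                checked += 1
        assert checked >= 10


class TestTrain:
    def test_first_epoch_step_identical_for_bce_and_iterloss(self, tiny_corpus):
        g = build_graph(tiny_corpus, lenk=3)
        kwargs = dict(dims=TINY_DIMS)
        s1, _ = train(g, tiny_corpus.labels, tiny_corpus.splits,
                      TrainConfig(epochs=1, seed=0, loss="bce"), **kwargs)
        s2, _ = train(g, tiny_corpus.labels, tiny_corpus.splits,
                      TrainConfig(epochs=1, seed=0, loss="iterloss"), **kwargs)
        for k in s1.params():
            assert np.array_equal(s1.params()[k], s2.params()[k])

    def test_masked_labels_do_not_influence_updates(self, tiny_corpus):
        g = build_graph(tiny_corpus, lenk=3)
        y = tiny_corpus.labels.copy()
        y_flipped = y.copy()
        for i, s in enumerate(tiny_corpus.splits):
            if s != "train":
                y_flipped[i] = 1 - y_flipped[i]
        s1, _ = train(g, y, tiny_corpus.splits,
                      TrainConfig(epochs=3, seed=0), dims=TINY_DIMS)
        s2, _ = train(g, y_flipped, tiny_corpus.splits,
                      TrainConfig(epochs=3, seed=0), dims=TINY_DIMS)
        for k in s1.params():
            assert np.array_equal(s1.params()[k], s2.params()[k])

    def test_history_records_decayed_lr_and_iterloss_floor(self, tiny_corpus):
        g = build_graph(tiny_corpus, lenk=3)
        _, hist = train(g, tiny_corpus.labels, tiny_corpus.splits,
                        TrainConfig(epochs=5, seed=1), dims=TINY_DIMS)
        assert [h["epoch"] for h in hist] == [1, 2, 3, 4, 5]
        assert hist[0]["lr"] == pytest.approx(0.001)
        assert hist[1]["lr"] == pytest.approx(0.001 * np.exp(-0.001))
        for h in hist:
            assert h["train_loss"] >= h["train_bce"] - 1e-12

    def test_deterministic_trajectory(self, tiny_corpus):
        g = build_graph(tiny_corpus, lenk=3)
        _, h1 = train(g, tiny_corpus.labels, tiny_corpus.splits,
                      TrainConfig(epochs=4, seed=2), dims=TINY_DIMS)
        _, h2 = train(g, tiny_corpus.labels, tiny_corpus.splits,
                      TrainConfig(epochs=4, seed=2), dims=TINY_DIMS)
        assert [h["train_loss"] for h in h1] == [h["train_loss"] for h in h2]

    def test_no_training_nodes_rejected(self, tiny_corpus):
        g = build_graph(tiny_corpus, lenk=3)
        with pytest.raises(ValueError):
            train(g, tiny_corpus.labels, ["test"] * len(tiny_corpus),
                  TrainConfig(epochs=1), dims=TINY_DIMS)


class TestCheckpoint:
    def test_round_trip(self, tiny_corpus, tmp_path):
        g = build_graph(tiny_corpus, lenk=3)
        state, _ = train(g, tiny_corpus.labels, tiny_corpus.splits,
                         TrainConfig(epochs=2, seed=3), dims=TINY_DIMS)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, state, epoch=2, seed=3)
        loaded, epoch, seed = load_checkpoint(path)
        assert (epoch, seed) == (2, 3)
        assert loaded.dims == state.dims
        for k in state.params():
            assert np.array_equal(loaded.params()[k], state.params()[k])
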