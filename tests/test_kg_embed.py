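"""Scorer oracles, gradient correctness, sampling and training contracts."""

import numpy as np
import pytest

import mtpnet as m
from mtpnet.kg_embed import _Trainer


def brute_rotate_distance(h, r, t):
    """Explicit (a+bi)(c+di) expansion, scalar loop."""
    total = 0.0
    for hi, ri, ti in zip(h, r, t):
        a, b = hi.real, hi.imag
        c, d = ri.real, ri.imag
        re = a * c - b * d - ti.real
        im = a * d + b * c - ti.imag
        total += np.hypot(re, im)
    return total


class TestScorers:
    def test_rotate_identity_rotation(self):
        h = np.array([1 + 2j, -0.5 + 0.25j])
        r = np.ones(2, dtype=complex)
        assert m.rotate_distance(h, r, h) == pytest.approx(0.0)

    def test_rotate_pi_rotation(self):
        assert m.rotate_distance(
            np.array([1 + 0j]), np.array([-1 + 0j]), np.array([-1 + 0j])
        ) == pytest.approx(0.0)

    def test_rotate_matches_expansion_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            h = rng.normal(size=4) + 1j * rng.normal(size=4)
            t = rng.normal(size=4) + 1j * rng.normal(size=4)
            r = np.exp(1j * rng.uniform(0, 2 * np.pi, 4))
            assert m.rotate_distance(h, r, t) == pytest.approx(
                brute_rotate_distance(h, r, t)
            )

    def test_rotate_rejects_non_unit_relation(self):
        with pytest.raises(ValueError, match="unit modulus"):
            m.rotate_distance(np.ones(2, complex), np.full(2, 2 + 0j), np.ones(2, complex))

    def test_rotate_global_phase_invariance(self):
        """|e^{i phi}(h*r - t)| = |h*r - t| for any global phase applied to
        both h and t."""
        rng = np.random.default_rng(1)
        h = rng.normal(size=6) + 1j * rng.normal(size=6)
        t = rng.normal(size=6) + 1j * rng.normal(size=6)
        r = np.exp(1j * rng.uniform(0, 2 * np.pi, 6))
        base = m.rotate_distance(h, r, t)
        for phi in rng.uniform(0, 2 * np.pi, 10):
            g = np.exp(1j * phi)
            assert m.rotate_distance(g * h, r, g * t) == pytest.approx(base)

    def test_transe_closed_forms_and_oracle(self):
        assert m.transe_distance(
            np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.array([0.0, 0.0])
        ) == pytest.approx(2.0)
        assert m.transe_distance(
            np.array([0.3, -0.2]), np.array([0.1, 0.4]), np.array([0.4, 0.2])
        ) == pytest.approx(0.0)
        rng = np.random.default_rng(2)
        for _ in range(100):
            h, r, t = rng.normal(size=(3, 5))
            assert m.transe_distance(h, r, t) == pytest.approx(
                sum(abs(h[i] + r[i] - t[i]) for i in range(5))
            )

    def test_distmult_closed_forms_and_oracle(self):
        ones = np.ones(2)
        assert m.distmult_score(ones, ones, ones) == pytest.approx(2.0)
        assert m.distmult_score(ones, np.zeros(2), ones) == pytest.approx(0.0)
        rng = np.random.default_rng(3)
        for _ in range(100):
            h, r, t = rng.normal(size=(3, 5))
            assert m.distmult_score(h, r, t) == pytest.approx(
                sum(h[i] * r[i] * t[i] for i in range(5))
            )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.transe_distance(np.ones(3), np.ones(2), np.ones(3))


class TestRGCNForward:
    @staticmethod
    def _identity_layers(d, rels, n_layers=1):
        eye = np.eye(d)
        return m.RGCNLayerStack(
            rel_weights=[{r: eye.copy() for r in rels} for _ in range(n_layers)],
            self_weights=[eye.copy() for _ in range(n_layers)],
            activation="identity",
        )

    def test_isolated_node_unchanged(self):
        net = m.MTPNetwork.from_triples(
            [("m1", "MT", "g1")], extra_nodes={"m2": "M"}
        )
        layers = self._identity_layers(3, ["MT", "MT_inv", "TT", "TP", "TP_inv"])
        initial = {e: np.arange(3) * 1.0 + i for i, e in enumerate(sorted(net.node_types))}
        out = m.rgcn_forward(net, layers, initial)
        assert out["m2"] == pytest.approx(initial["m2"])

    def test_single_neighbor_sum(self):
        net = m.MTPNetwork.from_triples([("m1", "MT", "g1")])
        layers = self._identity_layers(2, ["MT", "MT_inv"])
        initial = {"m1": np.array([1.0, 2.0]), "g1": np.array([0.5, -1.0])}
        out = m.rgcn_forward(net, layers, initial)
        # c = 1: h_self + h_neighbor in both directions
        assert out["g1"] == pytest.approx(initial["g1"] + initial["m1"])
        assert out["m1"] == pytest.approx(initial["m1"] + initial["g1"])

    def test_matches_double_loop_oracle(self):
        """Two-layer forward equals an explicit per-node, per-relation
        double loop on a 3-node line graph with random weights."""
        net = m.MTPNetwork.from_triples([("m1", "MT", "g1"), ("g1", "TP", "p1")])
        rng = np.random.default_rng(4)
        d = 3
        rels = ["MT", "MT_inv", "TP", "TP_inv"]
        layers = m.RGCNLayerStack(
            rel_weights=[
                {r: rng.normal(0, 0.3, (d, d)) for r in rels} for _ in range(2)
            ],
            self_weights=[rng.normal(0, 0.3, (d, d)) for _ in range(2)],
            activation="relu",
        )
        initial = {e: rng.normal(size=d) for e in net.node_types}
        out = m.rgcn_forward(net, layers, initial)

        neighbours = {
            "MT": {"g1": ["m1"]},
            "MT_inv": {"m1": ["g1"]},
            "TP": {"p1": ["g1"]},
            "TP_inv": {"g1": ["p1"]},
        }

        def layer(h, widx, act):
            nxt = {}
            for node in h:
                z = layers.self_weights[widx].T @ h[node]
                for rel in rels:
                    nbrs = neighbours[rel].get(node, [])
                    if nbrs:
                        msg = sum(
                            layers.rel_weights[widx][rel].T @ h[j] for j in nbrs
                        ) / len(nbrs)
                        z = z + msg
                nxt[node] = np.maximum(z, 0) if act else z
            return nxt

        h1 = layer(initial, 0, act=True)
        h2 = layer(h1, 1, act=False)
        for node in out:
            assert out[node] == pytest.approx(h2[node])


class TestSampleNegatives:
    def test_type_constraint_and_count(self, synthetic_net):
        net, *_ = synthetic_net
        rng = np.random.default_rng(0)
        triple = net.triples_of("MT")[0]
        negs = m.sample_negatives(triple, net, 16, rng)
        assert len(negs) == 16
        for h, r, t in negs:
            assert r == "MT"
            assert net.node_types[h] == "M" and net.node_types[t] == "T"
            assert (h, r, t) not in net.triple_set()

    def test_single_member_class_rejected(self):
        net = m.MTPNetwork.from_triples([("m1", "MT", "g1"), ("m1", "MT", "g2")])
        with pytest.raises(ValueError, match="single member"):
            m.sample_negatives(("m1", "MT", "g1"), net, 4, np.random.default_rng(0))

    def test_corruption_frequencies_uniform(self):
        """Over 10^4 draws, per-entity corruption frequencies stay within
        3 sigma of the multinomial expectation."""
        mirnas = [f"m{i}" for i in range(5)]
        genes = [f"g{i}" for i in range(20)]
        net = m.MTPNetwork.from_triples(
            [("m0", "MT", "g0")],
            extra_nodes={**{x: "M" for x in mirnas}, **{g: "T" for g in genes}},
        )
        rng = np.random.default_rng(7)
        counts = {}
        n_draws = 10_000
        negs = m.sample_negatives(("m0", "MT", "g0"), net, n_draws, rng)
        tail_draws = [t for h, r, t in negs if h == "m0"]
        for t in tail_draws:
            counts[t] = counts.get(t, 0) + 1
        n = len(tail_draws)
        # candidate tails exclude the true g0 (resampled as known triple)
        p = 1 / 19
        sigma = np.sqrt(n * p * (1 - p))
        for g in genes[1:]:
            assert abs(counts.get(g, 0) - n * p) < 3.5 * sigma


class TestGradients:
    """Analytic gradients match central finite differences for every model."""

    @pytest.mark.parametrize("model", ["rotate", "transe", "distmult", "rgcn"])
    def test_finite_difference_check(self, model):
        net = m.MTPNetwork.from_triples(
            [
                ("m1", "MT", "g1"), ("m1", "MT", "g2"), ("m2", "MT", "g2"),
                ("m2", "MT", "g3"), ("g1", "TT", "g2"), ("g2", "TT", "g3"),
                ("g1", "TP", "p1"), ("g3", "TP", "p2"), ("m3", "MT", "g3"),
            ]
        )
        cfg = m.TrainConfig(dim=4, negatives=3, batch_size=64, epochs=1, seed=5)
        trainer = _Trainer(net, model, cfg)
        batch = trainer.triples
        neg_h, neg_t = trainer._negatives(batch)

        B, n = batch.shape[0], cfg.negatives
        all_h = np.concatenate([batch[:, 0], neg_h.reshape(-1)])
        all_t = np.concatenate([batch[:, 2], neg_t.reshape(-1)])
        all_r = np.concatenate([batch[:, 1], np.repeat(batch[:, 1], n)])
        sig = lambda x: 1 / (1 + np.exp(-x))

        # adversarial weights are detached (no gradient flows through the
        # softmax), so freeze them at the initial parameters for both the
        # analytic gradient and the finite-difference loss
        raw = trainer._raw_scores(all_h, all_r, all_t)
        pos, neg = raw[:B], raw[B:].reshape(B, n)
        if model in ("rotate", "transe"):
            w0 = np.exp(cfg.alpha * (cfg.gamma - neg))
        else:
            w0 = np.exp(cfg.alpha * neg)
        w0 = w0 / w0.sum(axis=1, keepdims=True)

        def loss_at():
            raw = trainer._raw_scores(all_h, all_r, all_t)
            pos, neg = raw[:B], raw[B:].reshape(B, n)
            if model in ("rotate", "transe"):
                return float(
                    (-np.log(sig(cfg.gamma - pos))
                     - (w0 * np.log(sig(neg - cfg.gamma))).sum(1)).mean()
                )
            return float(
                (-np.log(sig(pos)) - (w0 * np.log(sig(-neg))).sum(1)).mean()
            )

        if model in ("rotate", "transe"):
            dpos = (1 - sig(cfg.gamma - pos)) / B
            dneg = -(w0 * (1 - sig(neg - cfg.gamma))) / B
        else:
            dpos = -(1 - sig(pos)) / B
            dneg = (w0 * sig(neg)) / B
        grads: dict = {}
        trainer._backward(
            all_h, all_r, all_t, np.concatenate([dpos, dneg.reshape(-1)]), grads
        )

        eps = 1e-6
        rng = np.random.default_rng(0)
        checked = 0
        for name, arr in trainer.params.items():
            if name not in grads:
                continue
            g = np.asarray(grads[name], dtype=float)
            flat = arr.reshape(-1)
            for _ in range(3):
                i = int(rng.integers(flat.size))
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_at()
                flat[i] = orig - eps
                dn = loss_at()
                flat[i] = orig
                numeric = (up - dn) / (2 * eps)
                analytic = g.reshape(-1)[i]
                assert analytic == pytest.approx(numeric, rel=2e-2, abs=2e-5)
                checked += 1
        assert checked >= 6


class TestTraining:
    @pytest.mark.parametrize("model", ["rotate", "transe", "distmult", "rgcn"])
    def test_loss_decreases(self, model, synthetic_net):
        net, *_ = synthetic_net
        emb = m.train(net, model, m.TrainConfig(epochs=10, seed=7))
        assert emb.loss_trajectory[-1] < emb.loss_trajectory[0]

    def test_deterministic_per_seed(self, synthetic_net):
        net, *_ = synthetic_net
        cfg = m.TrainConfig(epochs=3, seed=9)
        a = m.train(net, "rotate", cfg)
        b = m.train(net, "rotate", cfg)
        assert (a.ent_re == b.ent_re).all() and (a.ent_im == b.ent_im).all()

    def test_rotate_relations_remain_unit_modulus(self, synthetic_net):
        """The phase parameterization keeps |r_i| = 1 exactly after
        training."""
        net, *_ = synthetic_net
        emb = m.train(net, "rotate", m.TrainConfig(epochs=3, seed=1))
        for rel in emb.rel:
            assert np.abs(emb.relation_vector(rel)) == pytest.approx(
                np.ones(emb.dim), abs=1e-9
            )

    def test_heldout_triples_outscore_corruptions(self):
        """Trained RotatE scores held-out true MT triples above random
        type-consistent corruptions in >= 9/10 seeds."""
        wins = 0
        for seed in range(10):
            net, *_ = m.simulate_mtp(seed=seed)
            train_net, test = m.hold_out(net, "MT", 0.1, seed=seed)
            emb = m.train(train_net, "rotate", m.TrainConfig(epochs=50, seed=seed))
            rng = np.random.default_rng(seed)
            true_scores = [emb.score_ids(h, r, t) for h, r, t in test]
            targets = net.nodes_of_type("T")
            fake_scores = [
                emb.score_ids(h, r, targets[int(rng.integers(len(targets)))])
                for h, r, t in test
            ]
            wins += np.mean(true_scores) > np.mean(fake_scores)
        assert wins >= 9

    def test_unknown_model_rejected(self, toy_net):
        with pytest.raises(ValueError, match="unknown model"):
            m.train(toy_net, "kg2e", m.TrainConfig(epochs=1))
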