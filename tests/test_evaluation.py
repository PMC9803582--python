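"""Ranking protocol, CV harnesses, MLP classification and biomarker AUC."""

import numpy as np
import pandas as pd
import pytest

import mtpnet as m
from mtpnet.evaluation import RankEntry, RankList, _mean_rank_of


def _ranklist(ranks):
    return RankList(
        entries=[RankEntry("MT", "tail", r, 100) for r in ranks]
    )


class TestRankConventions:
    def test_strictly_best_gets_rank_one(self):
        assert _mean_rank_of(5.0, np.array([1.0, 2.0, 3.0])) == 1.0

    def test_all_tied_mean_rank(self):
        # n = 10 candidates all tied: rank = 1 + 9/2
        assert _mean_rank_of(0.5, np.full(9, 0.5)) == 1 + 9 / 2

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            scores = rng.integers(0, 5, size=8).astype(float)  # force ties
            true = float(rng.integers(0, 5))
            got = _mean_rank_of(true, scores)
            better = sum(s > true for s in scores)
            ties = sum(s == true for s in scores)
            assert got == 1 + better + ties / 2


class TestMetrics:
    def test_hits_closed_forms(self):
        rl = _ranklist([1, 3, 7])
        assert m.hits_at_k(rl, 5) == pytest.approx(2 / 3)
        assert m.hits_at_k(_ranklist([1, 1, 1]), 1) == 1.0
        assert m.hits_at_k(_ranklist([6]), 5) == 0.0

    def test_mr_mrr_closed_forms(self):
        mr, mrr = m.mr_mrr(_ranklist([1, 3, 7]))
        assert mr == pytest.approx(11 / 3)
        assert mrr == pytest.approx((1 + 1 / 3 + 1 / 7) / 3)
        assert m.mr_mrr(_ranklist([1, 1]))[0] == 1.0

    def test_hits_monotone_in_k(self):
        rng = np.random.default_rng(1)
        rl = _ranklist(rng.integers(1, 60, size=40).tolist())
        values = [m.hits_at_k(rl, k) for k in (1, 5, 10, 20, 50)]
        assert values == sorted(values)
        assert all(0 <= v <= 1 for v in values)

    def test_bounds(self):
        rl = _ranklist([2, 5, 9])
        mr, mrr = m.mr_mrr(rl)
        assert mr >= 1
        assert 0 < mrr <= 1


class TestRankTriples:
    @staticmethod
    def _tiny_trained():
        net, *_ = m.simulate_mtp(
            n_mirna=10, n_targets=20, n_pathways=4, n_communities=2,
            pool_size=10, p_in=0.7, p_out=0.05, seed=3,
        )
        emb = m.train(net, "transe", m.TrainConfig(dim=8, epochs=5, seed=3))
        return net, emb

    def test_filtered_rank_never_exceeds_raw(self):
        net, emb = self._tiny_trained()
        test = net.triples_of("MT")[:20]
        raw = m.rank_triples(test, emb, net, filtered=False)
        filt = m.rank_triples(test, emb, net, filtered=True)
        for a, b in zip(filt.entries, raw.entries):
            assert a.rank <= b.rank + 1e-9

    def test_ranks_match_sort_oracle(self):
        net, emb = self._tiny_trained()
        test = net.triples_of("MT")[:10]
        rl = m.rank_triples(test, emb, net, filtered=False)
        for entry, (h, r, t) in zip(
            [e for e in rl.entries if e.direction == "tail"], test
        ):
            cands = net.nodes_of_type("T")
            scores = {
                c: emb.score_ids(h, r, c) for c in cands
            }
            true = scores[t]
            expect = 1 + sum(v > true for c, v in scores.items() if c != t) + sum(
                v == true for c, v in scores.items() if c != t
            ) / 2
            assert entry.rank == pytest.approx(expect)

    def test_missing_entity_rejected(self):
        net, emb = self._tiny_trained()
        with pytest.raises(KeyError):
            m.rank_triples([("ghost", "MT", "g000")], emb, net)


class TestCrossvalLinkPrediction:
    def test_fold_partition_contract(self, synthetic_net):
        net, *_ = synthetic_net
        from mtpnet.evaluation import _fold_partition

        rng = np.random.default_rng(0)
        parts = _fold_partition(97, 10, rng)
        joined = np.concatenate(parts)
        assert sorted(joined.tolist()) == list(range(97))
        assert sum(p.size for p in parts) == 97

    def test_report_aggregates(self):
        rep = m.EvalReport(
            metric_names=["mrr"],
            per_fold=[{"mrr": 0.2}, {"mrr": 0.4}],
        )
        assert rep.mean("mrr") == pytest.approx(0.3)
        assert rep.sd("mrr") == pytest.approx(np.std([0.2, 0.4], ddof=1))

    def test_too_few_triples_rejected(self, toy_net):
        with pytest.raises(ValueError):
            m.crossval_link_prediction(toy_net, "TP", "transe", folds=10)


class TestMLP:
    def test_separable_labels_fit_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.3, (30, 4)), rng.normal(2, 0.3, (30, 4))])
        Y = np.vstack([np.zeros((30, 2)), np.ones((30, 2))])
        clf = m.MLPClassifier(4, 2, hidden=16, seed=0).fit(X, Y, epochs=200)
        assert m.multilabel_accuracy(clf.predict(X), Y) == 1.0

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(1)
        X, Y = rng.normal(size=(20, 5)), (rng.random((20, 3)) < 0.5).astype(float)
        p1 = m.MLPClassifier(5, 3, seed=4).fit(X, Y, epochs=50).predict(X)
        p2 = m.MLPClassifier(5, 3, seed=4).fit(X, Y, epochs=50).predict(X)
        assert (p1 == p2).all()

    def test_boundary_half_counts_positive(self):
        clf = m.MLPClassifier(2, 1, hidden=2, seed=0)
        # zero weights -> sigmoid(0) = 0.5 exactly -> predicted positive
        clf.W1[:] = 0; clf.b1[:] = 0; clf.W2[:] = 0; clf.b2[:] = 0
        assert clf.predict(np.zeros((1, 2)))[0, 0] == 1


class TestMultilabelAccuracy:
    def test_exact_match_and_complement(self):
        Y = (np.random.default_rng(0).random((6, 4)) < 0.5).astype(int)
        assert m.multilabel_accuracy(Y, Y) == 1.0
        assert m.multilabel_accuracy(1 - Y, Y) == 0.0

    def test_partial_row(self):
        truth = np.array([[1, 0, 1, 0]])
        pred = np.array([[1, 1, 1, 0]])
        assert m.multilabel_accuracy(pred, truth) == pytest.approx(0.75)

    def test_binarization_of_raw_labels(self):
        truth = np.array([[3, 0, 0.5, -1]])  # I(label > 0) -> 1,0,1,0
        pred = np.array([[1, 0, 1, 0]])
        assert m.multilabel_accuracy(pred, truth) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.multilabel_accuracy(np.zeros((2, 3)), np.zeros((3, 2)))


class TestCrossvalMultilabel:
    def test_community_labels_beat_majority_baseline(self, synthetic_net):
        """Embedding-based classification of block-driven tissue labels
        outperforms the per-label majority-class predictor."""
        net, t_labels, _, _ = synthetic_net
        cfg = m.TrainConfig(epochs=30, seed=2)
        rep = m.crossval_multilabel(net, t_labels, "rotate", config=cfg, folds=5)
        Y = (t_labels.matrix() > 0).astype(int)
        majority = (Y.mean(axis=0) >= 0.5).astype(int)
        baseline = float(
            (np.tile(majority, (Y.shape[0], 1)) == Y).mean(axis=1).mean()
        )
        assert rep.mean("accuracy") > baseline

    def test_random_labels_cannot_beat_base_rate(self, synthetic_net):
        """With labels shuffled across nodes the classifier gains no
        information: accuracy must not exceed the best blind (majority)
        predictor beyond fold noise."""
        net, t_labels, _, _ = synthetic_net
        rng = np.random.default_rng(5)
        shuffled = m.LabelMatrix(
            pd.DataFrame(
                rng.permutation(t_labels.matrix()),
                index=t_labels.node_ids,
                columns=t_labels.values.columns,
            ),
            node_type="T",
        )
        cfg = m.TrainConfig(epochs=30, seed=2)
        rep = m.crossval_multilabel(net, shuffled, "rotate", config=cfg, folds=5)
        Y = (shuffled.matrix() > 0).astype(float)
        p = Y.mean(axis=0)
        # best blind strategy: predict the majority side of each label
        base_rate = float(np.maximum(p, 1 - p).mean())
        assert rep.mean("accuracy") <= base_rate + max(2 * rep.sd("accuracy"), 0.02)


class TestBiomarkerMetrics:
    @staticmethod
    def _expr(case_vals, ctrl_vals):
        vals = list(case_vals) + list(ctrl_vals)
        samples = [f"s{i}" for i in range(len(vals))]
        groups = {
            s: ("case" if i < len(case_vals) else "control")
            for i, s in enumerate(samples)
        }
        return m.ExpressionMatrix(
            pd.DataFrame([vals, vals], index=["f1", "f2"], columns=samples), groups
        )

    def test_perfect_separation(self):
        expr = self._expr([5, 6, 7], [1, 2, 3])
        auc, aupr = m.biomarker_metrics(expr, "f1")
        assert auc == 1.0 and aupr == 1.0

    def test_pure_ties_give_half(self):
        expr = self._expr([2, 2, 2], [2, 2, 2])
        auc, _ = m.biomarker_metrics(expr, "f1")
        assert auc == pytest.approx(0.5)

    def test_matches_concordant_pair_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            case = rng.integers(0, 5, 6).astype(float)
            ctrl = rng.integers(0, 5, 5).astype(float)
            expr = self._expr(case, ctrl)
            auc, _ = m.biomarker_metrics(expr, "f1")
            pairs = [(c, k) for c in case for k in ctrl]
            oracle = np.mean(
                [1.0 if c > k else 0.5 if c == k else 0.0 for c, k in pairs]
            )
            assert auc == pytest.approx(oracle)

    def test_down_regulated_scores_below_half(self):
        # no orientation flipping: lower-in-case features get AUC < 0.5
        expr = self._expr([1, 2, 3], [5, 6, 7])
        auc, _ = m.biomarker_metrics(expr, "f1")
        assert auc == 0.0


class TestTopKAndPrediction:
    def test_topk_all_correct_and_empty_oracle(self):
        preds = {"h1": ["g1", "g2", "g3"], "h2": ["g4", "g5", "g6"]}
        oracle = {"h1": {"g1", "g2", "g3"}, "h2": {"g4", "g5", "g6"}}
        assert m.topk_validation(preds, oracle, ks=[1, 3]) == {1: 1.0, 3: 1.0}
        assert m.topk_validation(preds, {}, ks=[1])[1] == 0.0

    def test_topk_partial(self):
        preds = {"h1": ["g1", "gX", "g3"]}
        oracle = {"h1": {"g1", "g3"}}
        out = m.topk_validation(preds, oracle, ks=[1, 3])
        assert out[1] == 1.0
        assert out[3] == pytest.approx(2 / 3)

    def test_predict_targets_counts(self, synthetic_net):
        net, *_ = synthetic_net
        emb = m.train(net, "transe", m.TrainConfig(dim=8, epochs=3, seed=0))
        hubs = net.nodes_of_type("M")[:11]
        rows = m.predict_targets(hubs, emb, net, top_n=10)
        assert len(rows) == 110
        one = m.predict_targets(hubs[:1], emb, net, top_n=10)
        assert len(one) == 10
        assert len({t for _, t, _ in one}) <= 10

    def test_known_pairs_excluded(self, synthetic_net):
        net, *_ = synthetic_net
        emb = m.train(net, "transe", m.TrainConfig(dim=8, epochs=3, seed=0))
        hub = net.nodes_of_type("M")[0]
        known = {t for h, r, t in net.triples if r == "MT" and h == hub}
        rows = m.predict_targets([hub], emb, net, top_n=10, exclude_known=True)
        assert all(t not in known for _, t, _ in rows)
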