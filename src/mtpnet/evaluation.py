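"""Link-prediction ranking, cross-validation, multilabel classification and
biomarker metrics.

Ranking follows the standard knowledge-graph protocol: for each test triple
the true entity is scored against every type-consistent candidate in both
directions (head replaced, tail replaced). Under the *filtered* setting,
candidates forming another known-true triple are removed. Ties receive the
mean rank (1 + #strictly-better + #ties/2) to avoid optimistic bias.

Reported metrics: Hits@k (fraction of ranks <= k), MR (mean rank) and MRR
(mean reciprocal rank); multilabel node classification uses a per-node
label-matching accuracy averaged over nodes; biomarker potential of a
single miRNA is its case-vs-control AUC and AUPR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .kg_embed import EmbeddingSet, TrainConfig, train
from .mtp_core import ExpressionMatrix, LabelMatrix, MTPNetwork

logger = logging.getLogger("mtpnet")


# -- rank lists and metrics ------------------------------------------------


@dataclass
class RankEntry:
    relation: str
    direction: str  # "head" or "tail" (which slot was replaced)
    rank: float
    n_candidates: int


@dataclass
class RankList:
    entries: list[RankEntry] = field(default_factory=list)

    def ranks(self) -> np.ndarray:
        return np.array([e.rank for e in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


def _mean_rank_of(true_score: float, scores: np.ndarray) -> float:
    better = int((scores > true_score).sum())
    ties = int((scores == true_score).sum())  # excludes the true entity itself
    return 1.0 + better + ties / 2.0


def rank_triples(
    test: list[tuple[str, str, str]],
    emb: EmbeddingSet,
    net: MTPNetwork,
    known: set[tuple[str, str, str]] | None = None,
    filtered: bool = True,
) -> RankList:
    """Rank each test triple's true entity in both directions.

    ``known`` is the set of triples treated as true (typically train ∪ test)
    and removed from the candidate pool under the filtered protocol; the
    candidate pool for a slot is every node of the type the relation's
    schema requires for that slot.
    """
    known = known if known is not None else net.triple_set()
    pools = {t: net.nodes_of_type(t) for t in ("M", "T", "P")}
    out = RankList()
    for head, relation, tail in test:
        htype, ttype = net.schema[relation]
        for direction, slot_type, fixed in (
            ("head", htype, tail),
            ("tail", ttype, head),
        ):
            candidates = pools[slot_type]
            true_entity = head if direction == "head" else tail
            if true_entity not in emb.index:
                raise KeyError(f"entity {true_entity!r} missing from embeddings")
            if filtered:
                if direction == "head":
                    candidates = [
                        c
                        for c in candidates
                        if c == true_entity or (c, relation, fixed) not in known
                    ]
                else:
                    candidates = [
                        c
                        for c in candidates
                        if c == true_entity or (fixed, relation, c) not in known
                    ]
            idx = np.array([emb.index[c] for c in candidates], dtype=int)
            if direction == "head":
                scores = emb.score(idx, relation, np.full(idx.size, emb.index[fixed]))
            else:
                scores = emb.score(np.full(idx.size, emb.index[fixed]), relation, idx)
            true_pos = candidates.index(true_entity)
            true_score = scores[true_pos]
            others = np.delete(scores, true_pos)
            out.entries.append(
                RankEntry(
                    relation=relation,
                    direction=direction,
                    rank=_mean_rank_of(true_score, others),
                    n_candidates=len(candidates),
                )
            )
    return out


def hits_at_k(ranks: RankList, k: int) -> float:
    """Fraction of test ranks at or below ``k``."""
    r = ranks.ranks()
    if r.size == 0:
        raise ValueError("empty rank list")
    return float((r <= k).mean())


def mr_mrr(ranks: RankList) -> tuple[float, float]:
    """Mean rank and mean reciprocal rank."""
    r = ranks.ranks()
    if r.size == 0:
        raise ValueError("empty rank list")
    return float(r.mean()), float((1.0 / r).mean())


HITS_KS = (5, 10, 20, 50)


@dataclass
class EvalReport:
    """Per-fold metric values plus mean ± sd aggregates."""

    metric_names: list[str]
    per_fold: list[dict[str, float]]

    def mean(self, name: str) -> float:
        return float(np.mean([f[name] for f in self.per_fold]))

    def sd(self, name: str) -> float:
        return float(np.std([f[name] for f in self.per_fold], ddof=1))

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.sd(m)) for m in self.metric_names}

    def to_json_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "mean": {m: self.mean(m) for m in self.metric_names},
            "sd": {m: self.sd(m) for m in self.metric_names},
        }


def _fold_partition(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i::folds] for i in range(folds)]


def crossval_link_prediction(
    net: MTPNetwork,
    relation: str,
    model: str,
    config: TrainConfig | None = None,
    folds: int = 10,
    filtered: bool = True,
) -> EvalReport:
    """K-fold cross-validated link prediction for one relation.

    Each fold holds out 1/k of the relation's triples, trains on everything
    else (other relations included), ranks the held-out triples in both
    directions and reports Hits@{5,10,20,50}, MR and MRR.
    """
    config = config or TrainConfig()
    rel_triples = net.triples_of(relation)
    if len(rel_triples) < folds:
        raise ValueError(f"relation {relation!r} has fewer than {folds} triples")
    rng = np.random.default_rng(config.seed)
    parts = _fold_partition(len(rel_triples), folds, rng)
    all_known = net.triple_set()
    metric_names = [f"hits@{k}" for k in HITS_KS] + ["mr", "mrr"]
    per_fold = []
    for fold_idx, part in enumerate(parts):
        if part.size == 0:
            raise ValueError(f"fold {fold_idx} has zero test triples")
        test = [rel_triples[i] for i in part]
        test_set = set(test)
        train_net = net.subset([t for t in net.triples if t not in test_set])
        fold_cfg = TrainConfig(
            dim=config.dim,
            lr=config.lr,
            epochs=config.epochs,
            negatives=config.negatives,
            alpha=config.alpha,
            gamma=config.gamma,
            batch_size=config.batch_size,
            seed=config.seed + fold_idx,
        )
        emb = train(train_net, model, fold_cfg)
        ranks = rank_triples(test, emb, net, known=all_known, filtered=filtered)
        row = {f"hits@{k}": hits_at_k(ranks, k) for k in HITS_KS}
        row["mr"], row["mrr"] = mr_mrr(ranks)
        per_fold.append(row)
        logger.info(
            "%s %s fold %d/%d: MRR %.4f MR %.1f",
            model,
            relation,
            fold_idx + 1,
            folds,
            row["mrr"],
            row["mr"],
        )
    return EvalReport(metric_names=metric_names, per_fold=per_fold)


def random_baseline_mrr(net: MTPNetwork, relation: str) -> float:
    """Analytic E[1/rank] of a uniformly random ranking over the two
    directions' type-consistent candidate pools: mean of H(n)/n per slot."""
    htype, ttype = net.schema[relation]
    out = []
    for ntype in (htype, ttype):
        n = len(net.nodes_of_type(ntype))
        out.append(sum(1.0 / r for r in range(1, n + 1)) / n)
    return float(np.mean(out))


# -- multilabel classification ---------------------------------------------


class MLPClassifier:
    """Two-layer fully connected network with sigmoid outputs, trained with
    binary cross-entropy and Adam; deterministic per seed."""

    def __init__(self, n_in: int, n_out: int, hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        s1 = np.sqrt(2.0 / n_in)
        s2 = np.sqrt(2.0 / hidden)
        self.W1 = rng.normal(0, s1, (n_in, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0, s2, (hidden, n_out))
        self.b2 = np.zeros(n_out)

    def _forward(self, X: np.ndarray):
        Z1 = X @ self.W1 + self.b1
        H = np.maximum(Z1, 0.0)
        logits = H @ self.W2 + self.b2
        return Z1, H, logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, _, logits = self._forward(X)
        return 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def fit(self, X: np.ndarray, Y: np.ndarray, epochs: int = 200, lr: float = 0.01):
        m = {k: np.zeros_like(v) for k, v in self._params().items()}
        v = {k: np.zeros_like(v) for k, v in self._params().items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        n = X.shape[0]
        for t in range(1, epochs + 1):
            Z1, H, logits = self._forward(X)
            P = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
            G = (P - Y) / n  # BCE gradient wrt logits
            grads = {
                "W2": H.T @ G,
                "b2": G.sum(0),
            }
            GH = (G @ self.W2.T) * (Z1 > 0)
            grads["W1"] = X.T @ GH
            grads["b1"] = GH.sum(0)
            params = self._params()
            for k, g in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                params[k] -= lr * (m[k] / (1 - b1**t)) / (
                    np.sqrt(v[k] / (1 - b2**t)) + eps
                )
        return self

    def _params(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}


def train_mlp_classifier(
    embeddings: EmbeddingSet,
    labels: LabelMatrix,
    hidden: int = 64,
    epochs: int = 200,
    lr: float = 0.01,
    seed: int = 0,
) -> tuple[MLPClassifier, np.ndarray]:
    """Fit the 2-layer MLP on all labelled nodes; returns the classifier and
    its binary predictions (probability >= 0.5) on the same nodes."""
    ids = labels.node_ids
    missing = [e for e in ids if e not in embeddings.index]
    if missing:
        raise KeyError(f"labelled nodes missing embeddings: {missing[:5]}")
    X = embeddings.feature_matrix(ids)
    Y = (labels.matrix() > 0).astype(float)
    clf = MLPClassifier(X.shape[1], Y.shape[1], hidden=hidden, seed=seed)
    clf.fit(X, Y, epochs=epochs, lr=lr)
    return clf, clf.predict(X)


def multilabel_accuracy(pred: np.ndarray, labels: LabelMatrix | np.ndarray) -> float:
    """Mean over nodes of the per-node fraction of matching label bits.

    Labels are first binarized with I(label > 0).
    """
    truth = labels.matrix() if isinstance(labels, LabelMatrix) else np.asarray(labels)
    truth = (truth > 0).astype(int)
    pred = np.asarray(pred, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("prediction/label shape mismatch")
    return float((pred == truth).mean(axis=1).mean())


def crossval_multilabel(
    net: MTPNetwork,
    labels: LabelMatrix,
    model: str,
    config: TrainConfig | None = None,
    hidden: int = 64,
    mlp_epochs: int = 200,
    mlp_lr: float = 0.01,
    folds: int = 10,
    embeddings: EmbeddingSet | None = None,
) -> EvalReport:
    """K-fold multilabel node classification.

    Embeddings are trained once on the full triple set (transductive: test
    nodes are present in the graph during embedding, only their labels are
    held out); nodes are then split into folds, the MLP fit on k-1 folds and
    scored on the held-out fold with the label-matching accuracy.
    """
    config = config or TrainConfig()
    if embeddings is None:
        embeddings = train(net, model, config)
    ids = labels.node_ids
    if len(ids) < folds:
        raise ValueError("fewer labelled nodes than folds")
    X = embeddings.feature_matrix(ids)
    Y = (labels.matrix() > 0).astype(float)
    rng = np.random.default_rng(config.seed)
    parts = _fold_partition(len(ids), folds, rng)
    per_fold = []
    for fold_idx, part in enumerate(parts):
        test_mask = np.zeros(len(ids), dtype=bool)
        test_mask[part] = True
        clf = MLPClassifier(
            X.shape[1], Y.shape[1], hidden=hidden, seed=config.seed + fold_idx
        )
        clf.fit(X[~test_mask], Y[~test_mask], epochs=mlp_epochs, lr=mlp_lr)
        acc = multilabel_accuracy(clf.predict(X[test_mask]), Y[test_mask])
        per_fold.append({"accuracy": acc})
    return EvalReport(metric_names=["accuracy"], per_fold=per_fold)


# -- biomarker evaluation --------------------------------------------------


def biomarker_metrics(expr: ExpressionMatrix, feature: str) -> tuple[float, float]:
    """AUC and AUPR of one feature's expression for case vs. control.

    The expression value itself is the score and the case group the positive
    class; no orientation flipping, so a down-regulated biomarker scores
    below 0.5. AUC is the rank statistic with half credit for ties; AUPR is
    the step-integrated precision–recall curve.
    """
    if feature not in expr.values.index:
        raise KeyError(f"feature {feature!r} not in expression matrix")
    y = np.array([1 if expr.groups[s] == "case" else 0 for s in expr.sample_ids])
    if y.min() == y.max():
        raise ValueError("both groups must be present")
    scores = expr.values.loc[feature].to_numpy(dtype=float)
    return float(roc_auc_score(y, scores)), float(average_precision_score(y, scores))


def mean_biomarker_metrics(
    expr: ExpressionMatrix, features: list[str]
) -> tuple[float, float]:
    """Mean AUC / AUPR over a hub set (the hub-quality comparison metric)."""
    pairs = [biomarker_metrics(expr, f) for f in features]
    return float(np.mean([p[0] for p in pairs])), float(np.mean([p[1] for p in pairs]))


# -- TopK validation and target prediction ---------------------------------


def topk_validation(
    predictions: dict[str, list[str]],
    oracle: dict[str, set[str]],
    ks: list[int] = (1, 3, 5, 10),
) -> dict[int, float]:
    """Per k: mean over hubs of |top-k ∩ oracle(hub)| / k."""
    out = {}
    for k in ks:
        props = []
        for hub, ranked in predictions.items():
            if len(ranked) < k:
                raise ValueError(f"hub {hub!r} has fewer than {k} predictions")
            hits = len(set(ranked[:k]) & oracle.get(hub, set()))
            props.append(hits / k)
        out[k] = float(np.mean(props)) if props else 0.0
    return out


def predict_targets(
    hubs: list[str],
    emb: EmbeddingSet,
    net: MTPNetwork,
    top_n: int = 10,
    exclude_known: bool = True,
) -> list[tuple[str, str, float]]:
    """Top-scoring candidate targets per hub miRNA as (hub, target, score).

    Scores every T node as the tail of (hub, MT, ·); known MT pairs of the
    network are excluded by default so the output is novel predictions.
    """
    targets = net.nodes_of_type("T")
    known = {(h, t) for h, r, t in net.triples if r == "MT"}
    out: list[tuple[str, str, float]] = []
    for hub in hubs:
        if hub not in emb.index:
            raise KeyError(f"hub {hub!r} missing from embeddings")
        cands = [
            t for t in targets if not (exclude_known and (hub, t) in known)
        ]
        idx = np.array([emb.index[t] for t in cands], dtype=int)
        scores = emb.score(np.full(idx.size, emb.index[hub]), "MT", idx)
        order = np.argsort(-scores)[:top_n]
        out.extend((hub, cands[i], float(scores[i])) for i in order)
    return out
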