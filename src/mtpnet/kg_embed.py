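"""Knowledge-graph embedding models for the MTP triple store.

Implemented models:

* **RotatE** — entities are complex vectors, each relation a rotation in the
  complex plane (unit-modulus phase vector); the distance of a triple is the
  L1 composition of complex moduli ``d_r(h, t) = sum_i |h_i * r_i - t_i|``
  and the score is ``gamma - d``.
* **TransE** — relations as real translations, ``d = ||h + r - t||_1``.
* **DistMult** — diagonal bilinear semantic matching,
  ``f = sum_i h_i r_i t_i``.
* **RGCN** — a two-layer relational graph convolution producing node
  embeddings, scored with a per-relation diagonal bilinear decoder
  ``f(h, r, t) = (h^L)^T R_r t^L``. Messages flow along MT/TP edges in both
  directions (inverse relations) and symmetrically along TT edges, each
  normalized by the neighbour count ``c_{i,r} = |N_i^r|``.

All models are trained with the self-adversarial negative-sampling loss

    L = -log sigma(gamma - d(h,t)) - sum_j p_j log sigma(d(h'_j,t'_j) - gamma)

with ``p_j = softmax_j(alpha * (gamma - d_j))`` treated as constants
(no gradient through the weights); DistMult and RGCN use their score ``f``
in place of ``gamma - d``. Negatives corrupt the head or the tail (equal
probability) with a uniformly drawn entity of the type-consistent class for
that slot. Optimization is Adam, implemented here; gradients are derived
analytically and checked against finite differences in the test suite.
Everything is plain NumPy, deterministic per seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .mtp_core import MTPNetwork

logger = logging.getLogger("mtpnet")

MODELS = ("rotate", "transe", "distmult", "rgcn")
_EPS = 1e-12


# -- pure scorers (spec-level operations) ----------------------------------


def rotate_distance(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> float:
    """``sum_i |h_i * r_i - t_i|`` for complex vectors, ``|r_i| = 1``."""
    h, r, t = (np.asarray(v, dtype=complex) for v in (h, r, t))
    if not (h.shape == r.shape == t.shape):
        raise ValueError("dimension mismatch")
    if not np.allclose(np.abs(r), 1.0, atol=1e-9):
        raise ValueError("relation phases must have unit modulus")
    return float(np.abs(h * r - t).sum())


def transe_distance(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> float:
    """L1 translation distance ``||h + r - t||_1``."""
    h, r, t = (np.asarray(v, dtype=float) for v in (h, r, t))
    if not (h.shape == r.shape == t.shape):
        raise ValueError("dimension mismatch")
    return float(np.abs(h + r - t).sum())


def distmult_score(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> float:
    """Diagonal bilinear score ``sum_i h_i r_i t_i``."""
    h, r, t = (np.asarray(v, dtype=float) for v in (h, r, t))
    if not (h.shape == r.shape == t.shape):
        raise ValueError("dimension mismatch")
    return float((h * r * t).sum())


# -- configuration ---------------------------------------------------------


@dataclass
class TrainConfig:
    """Hyper-parameters of the shared training loop.

    Dimension 64, learning rate 0.001 and 50 epochs are the benchmark
    defaults; margin, adversarial temperature, negative count and batch
    size are set to common values for small graphs and are all logged.
    """

    dim: int = 64
    lr: float = 0.001
    epochs: int = 50
    negatives: int = 16
    alpha: float = 1.0
    gamma: float = 6.0
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dim, self.epochs, self.negatives, self.batch_size) <= 0:
            raise ValueError("dim, epochs, negatives and batch_size must be > 0")


@dataclass
class RGCNLayerStack:
    """Per-layer, per-relation transforms of the relational GCN."""

    rel_weights: list[dict[str, np.ndarray]]  # one dict per layer
    self_weights: list[np.ndarray]
    activation: str = "relu"  # applied between layers, identity at output

    @property
    def n_layers(self) -> int:
        return len(self.self_weights)


# -- embedding container ---------------------------------------------------


@dataclass
class EmbeddingSet:
    """Trained embeddings plus the model-specific scoring rule."""

    model: str
    entity_ids: list[str]
    dim: int
    gamma: float
    ent_re: np.ndarray  # (n, d); real part (or the real embedding)
    ent_im: np.ndarray | None = None  # (n, d) for RotatE
    rel: dict[str, np.ndarray] = field(default_factory=dict)
    loss_trajectory: list[float] = field(default_factory=list)
    layers: RGCNLayerStack | None = None  # populated for RGCN

    def __post_init__(self) -> None:
        self.index = {e: i for i, e in enumerate(self.entity_ids)}

    def relation_vector(self, relation: str) -> np.ndarray:
        """RotatE: the unit-modulus complex phases of a relation."""
        if self.model == "rotate":
            return np.exp(1j * self.rel[relation])
        return self.rel[relation]

    def score(self, heads: np.ndarray, relation: str, tails: np.ndarray) -> np.ndarray:
        """Vectorized triple scores; higher = more plausible."""
        heads = np.asarray(heads, dtype=int)
        tails = np.asarray(tails, dtype=int)
        if self.model == "rotate":
            theta = self.rel[relation]
            rc, rs = np.cos(theta), np.sin(theta)
            hre, him = self.ent_re[heads], self.ent_im[heads]
            zre = hre * rc - him * rs - self.ent_re[tails]
            zim = hre * rs + him * rc - self.ent_im[tails]
            d = np.sqrt(zre**2 + zim**2).sum(axis=-1)
            return self.gamma - d
        if self.model == "transe":
            d = np.abs(
                self.ent_re[heads] + self.rel[relation] - self.ent_re[tails]
            ).sum(axis=-1)
            return self.gamma - d
        if self.model in ("distmult", "rgcn"):
            return (self.ent_re[heads] * self.rel[relation] * self.ent_re[tails]).sum(
                axis=-1
            )
        raise ValueError(f"unknown model {self.model!r}")

    def score_ids(self, head: str, relation: str, tail: str) -> float:
        return float(
            self.score(
                np.array([self.index[head]]), relation, np.array([self.index[tail]])
            )[0]
        )

    def feature_matrix(self, ids: list[str]) -> np.ndarray:
        """Real-valued per-entity features for downstream classifiers
        (RotatE concatenates real and imaginary parts)."""
        idx = np.array([self.index[e] for e in ids], dtype=int)
        if self.model == "rotate":
            return np.concatenate([self.ent_re[idx], self.ent_im[idx]], axis=1)
        return self.ent_re[idx]


# -- RGCN forward pass (spec-level operation) ------------------------------


def _message_relations(net: MTPNetwork) -> dict[str, list[tuple[str, str]]]:
    """Directed (src → dst) edge lists per message relation: each directed
    relation also in inverse, TT symmetric."""
    out: dict[str, list[tuple[str, str]]] = {}
    for head, relation, tail in net.triples:
        if relation == "TT":
            out.setdefault("TT", []).extend([(head, tail), (tail, head)])
        else:
            out.setdefault(relation, []).append((head, tail))
            out.setdefault(relation + "_inv", []).append((tail, head))
    return out


def _relation_operators(
    net: MTPNetwork, index: dict[str, int]
) -> dict[str, sp.csr_matrix]:
    """Row-normalized sparse neighbourhood operators A_r with
    ``A_r[i, j] = 1/|N_i^r|`` for j a neighbour of i under r."""
    n = len(index)
    ops = {}
    for rel, pairs in _message_relations(net).items():
        rows = np.array([index[dst] for _, dst in pairs], dtype=int)
        cols = np.array([index[src] for src, _ in pairs], dtype=int)
        a = sp.csr_matrix(
            (np.ones(len(pairs)), (rows, cols)), shape=(n, n)
        )
        deg = np.asarray(a.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        ops[rel] = sp.diags(inv) @ a
    return ops


def _activate(z: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "identity":
        return z
    raise ValueError(f"unknown activation {name!r}")


def rgcn_forward(
    net: MTPNetwork,
    layers: RGCNLayerStack,
    initial: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Apply the relational GCN layer stack to initial entity embeddings.

    Per layer: ``h_i' = act( sum_r (1/|N_i^r|) sum_{j in N_i^r} W_r h_j
    + W_0 h_i )`` with the activation between layers and identity after the
    last layer.
    """
    ids = sorted(initial)
    index = {e: i for i, e in enumerate(ids)}
    H = np.stack([np.asarray(initial[e], dtype=float) for e in ids])
    ops = _relation_operators(net, index)
    for layer in range(layers.n_layers):
        Z = H @ layers.self_weights[layer]
        for rel, W in layers.rel_weights[layer].items():
            if rel in ops:
                Z += ops[rel] @ (H @ W)
        H = _activate(Z, layers.activation) if layer < layers.n_layers - 1 else Z
    return {e: H[index[e]] for e in ids}


# -- negative sampling -----------------------------------------------------


def _entity_index(net: MTPNetwork) -> tuple[list[str], dict[str, int], dict[str, np.ndarray]]:
    ids = sorted(net.node_types, key=lambda e: (net.node_types[e], e))
    index = {e: i for i, e in enumerate(ids)}
    pools = {
        t: np.array([index[e] for e in net.nodes_of_type(t)], dtype=int)
        for t in ("M", "T", "P")
    }
    return ids, index, pools


def sample_negatives(
    triple: tuple[str, str, str],
    net: MTPNetwork,
    n: int,
    rng: np.random.Generator,
    max_retries: int = 20,
) -> list[tuple[str, str, str]]:
    """Corrupt the head or tail (equal probability) of a triple ``n`` times.

    Replacement entities are drawn uniformly from the type-consistent class
    for the corrupted slot; corruptions that coincide with a known triple of
    the network are resampled up to ``max_retries`` times, then kept with a
    warning.
    """
    head, relation, tail = triple
    htype, ttype = net.schema[relation]
    _, _, pools = _entity_index(net)
    ids_by_type = {t: net.nodes_of_type(t) for t in (htype, ttype)}
    known = net.triple_set()
    out: list[tuple[str, str, str]] = []
    for _ in range(n):
        for attempt in range(max_retries + 1):
            corrupt_head = rng.random() < 0.5
            pool = ids_by_type[htype] if corrupt_head else ids_by_type[ttype]
            if len(pool) < 2:
                raise ValueError(
                    f"candidate class for slot has a single member ({relation})"
                )
            repl = pool[int(rng.integers(len(pool)))]
            cand = (repl, relation, tail) if corrupt_head else (head, relation, repl)
            if cand not in known and cand != triple:
                out.append(cand)
                break
        else:
            logger.warning("kept a false-negative corruption after retries")
            out.append(cand)
    return out


# -- Adam ------------------------------------------------------------------


class Adam:
    """Adaptive-moment gradient descent over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# -- training --------------------------------------------------------------


class _Trainer:
    """Shared training loop: batching, type-constrained self-adversarial
    negatives, loss/grad dispatch per model."""

    def __init__(self, net: MTPNetwork, model: str, config: TrainConfig):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
        if not net.triples:
            raise ValueError("cannot train on an empty network")
        self.net, self.model, self.cfg = net, model, config
        self.rng = np.random.default_rng(config.seed)
        self.ids, self.index, self.pools = _entity_index(net)
        self.n_ent = len(self.ids)
        self.relations = sorted({t[1] for t in net.triples})
        self.triples = np.array(
            [
                (self.index[h], self.relations.index(r), self.index[t])
                for h, r, t in net.triples
            ],
            dtype=int,
        )
        # integer codes of known triples for vectorized false-negative checks
        self.known = {
            ri: np.sort(
                self.triples[self.triples[:, 1] == ri][:, 0] * self.n_ent
                + self.triples[self.triples[:, 1] == ri][:, 2]
            )
            for ri in range(len(self.relations))
        }
        self.slot_pools = {}
        for ri, rel in enumerate(self.relations):
            htype, ttype = net.schema[rel]
            self.slot_pools[ri] = (self.pools[htype], self.pools[ttype])
            for pool, side in ((self.pools[htype], "head"), (self.pools[ttype], "tail")):
                if pool.size < 2:
                    raise ValueError(
                        f"{side} candidate class for {rel} has a single member"
                    )
        self._collisions = 0
        self._init_params()

    # .. parameters ........................................................

    def _init_params(self) -> None:
        d, rng = self.cfg.dim, self.rng
        # distance models: init scale tied to the margin so initial distances
        # are commensurate with gamma and the logistic loss is not saturated
        margin_eps = (self.cfg.gamma + 2.0) / d
        eps = 6.0 / np.sqrt(d)
        P: dict[str, np.ndarray] = {}
        if self.model == "rotate":
            P["ent_re"] = rng.uniform(-margin_eps, margin_eps, (self.n_ent, d))
            P["ent_im"] = rng.uniform(-margin_eps, margin_eps, (self.n_ent, d))
            for r in self.relations:
                P[f"rel:{r}"] = rng.uniform(0, 2 * np.pi, d)
        elif self.model == "transe":
            P["ent"] = rng.uniform(-margin_eps, margin_eps, (self.n_ent, d))
            for r in self.relations:
                P[f"rel:{r}"] = rng.uniform(-margin_eps, margin_eps, d)
        elif self.model == "distmult":
            P["ent"] = rng.uniform(-eps, eps, (self.n_ent, d))
            for r in self.relations:
                P[f"rel:{r}"] = rng.uniform(-eps, eps, d)
        else:  # rgcn
            P["ent0"] = rng.uniform(-eps, eps, (self.n_ent, d))
            self.msg_rels = sorted(_message_relations(self.net))
            for layer in (0, 1):
                P[f"W0:{layer}"] = rng.uniform(-eps / 4, eps / 4, (d, d))
                for r in self.msg_rels:
                    P[f"W:{layer}:{r}"] = rng.uniform(-eps / 4, eps / 4, (d, d))
            for r in self.relations:
                P[f"R:{r}"] = rng.uniform(-eps, eps, d)
            self.ops = _relation_operators(self.net, self.index)
        self.params = P

    # .. negatives .........................................................

    def _negatives(self, batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(B, n) corrupted head and tail index arrays for a batch; the
        uncorrupted slot repeats the positive entity."""
        B, n = batch.shape[0], self.cfg.negatives
        heads = np.repeat(batch[:, 0][:, None], n, axis=1)
        tails = np.repeat(batch[:, 2][:, None], n, axis=1)
        corrupt_head = self.rng.random((B, n)) < 0.5
        for ri in np.unique(batch[:, 1]):
            rows = np.flatnonzero(batch[:, 1] == ri)
            hpool, tpool = self.slot_pools[int(ri)]
            known = self.known[int(ri)]
            ch = corrupt_head[rows]
            h = heads[rows].copy()
            t = tails[rows].copy()
            pending = np.ones(h.shape, dtype=bool)
            cand_h = h
            cand_t = t
            for _ in range(8):
                if not pending.any():
                    break
                draw_h = hpool[self.rng.integers(hpool.size, size=h.shape)]
                draw_t = tpool[self.rng.integers(tpool.size, size=t.shape)]
                cand_h = np.where(ch, draw_h, h)
                cand_t = np.where(ch, t, draw_t)
                bad = np.isin(cand_h * self.n_ent + cand_t, known).reshape(h.shape)
                take = pending & ~bad
                h[take] = cand_h[take]
                t[take] = cand_t[take]
                pending &= bad
            if pending.any():
                # bounded retries exhausted: keep the last draws
                h[pending] = cand_h[pending]
                t[pending] = cand_t[pending]
                self._collisions += int(pending.sum())
            heads[rows], tails[rows] = h, t
        return heads, tails

    # .. scoring and gradients ............................................

    def _epoch(self, opt: Adam) -> float:
        order = self.rng.permutation(len(self.triples))
        total, count = 0.0, 0
        for start in range(0, len(order), self.cfg.batch_size):
            batch = self.triples[order[start : start + self.cfg.batch_size]]
            neg_h, neg_t = self._negatives(batch)
            loss = self._step(batch, neg_h, neg_t, opt)
            total += loss * batch.shape[0]
            count += batch.shape[0]
        return total / count

    def _step(self, batch, neg_h, neg_t, opt: Adam) -> float:
        cfg = self.cfg
        B, n = batch.shape[0], cfg.negatives
        rel_of = batch[:, 1]
        grads: dict[str, np.ndarray] = {}
        pos_h, pos_t = batch[:, 0], batch[:, 2]
        all_h = np.concatenate([pos_h, neg_h.reshape(-1)])
        all_t = np.concatenate([pos_t, neg_t.reshape(-1)])
        all_r = np.concatenate([rel_of, np.repeat(rel_of, n)])

        raw = self._raw_scores(all_h, all_r, all_t)  # d for distance models, f else
        pos_raw, neg_raw = raw[:B], raw[B:].reshape(B, n)

        if self.model in ("rotate", "transe"):
            # raw = distance d
            s_pos = cfg.gamma - pos_raw
            s_neg = neg_raw - cfg.gamma
            p = _softmax(cfg.alpha * (cfg.gamma - neg_raw), axis=1)
            loss = float((-_log_sigmoid(s_pos) - (p * _log_sigmoid(s_neg)).sum(1)).mean())
            dl_dpos = (1.0 - _sigmoid(s_pos)) / B
            dl_dneg = -(p * (1.0 - _sigmoid(s_neg))) / B
        else:
            # raw = score f
            p = _softmax(cfg.alpha * neg_raw, axis=1)
            loss = float(
                (-_log_sigmoid(pos_raw) - (p * _log_sigmoid(-neg_raw)).sum(1)).mean()
            )
            dl_dpos = -(1.0 - _sigmoid(pos_raw)) / B
            dl_dneg = (p * _sigmoid(neg_raw)) / B

        coeff = np.concatenate([dl_dpos, dl_dneg.reshape(-1)])
        self._backward(all_h, all_r, all_t, coeff, grads)
        opt.step(grads)
        return loss

    def _raw_scores(self, h, r, t) -> np.ndarray:
        P = self.params
        if self.model == "rotate":
            out = np.empty(h.shape[0])
            for ri in np.unique(r):
                sel = r == ri
                theta = P[f"rel:{self.relations[ri]}"]
                rc, rs = np.cos(theta), np.sin(theta)
                hre, him = P["ent_re"][h[sel]], P["ent_im"][h[sel]]
                zre = hre * rc - him * rs - P["ent_re"][t[sel]]
                zim = hre * rs + him * rc - P["ent_im"][t[sel]]
                out[sel] = np.sqrt(zre**2 + zim**2 + _EPS).sum(1)
            return out
        if self.model == "transe":
            out = np.empty(h.shape[0])
            for ri in np.unique(r):
                sel = r == ri
                out[sel] = np.abs(
                    P["ent"][h[sel]] + P[f"rel:{self.relations[ri]}"] - P["ent"][t[sel]]
                ).sum(1)
            return out
        if self.model == "distmult":
            out = np.empty(h.shape[0])
            for ri in np.unique(r):
                sel = r == ri
                out[sel] = (
                    P["ent"][h[sel]] * P[f"rel:{self.relations[ri]}"] * P["ent"][t[sel]]
                ).sum(1)
            return out
        # rgcn: full forward, cache for backward
        self._H0 = P["ent0"]
        Z1 = self._H0 @ P["W0:0"]
        for rel in self.msg_rels:
            Z1 += self.ops[rel] @ (self._H0 @ P[f"W:0:{rel}"])
        self._Z1 = Z1
        H1 = np.maximum(Z1, 0.0)
        self._H1 = H1
        H2 = H1 @ P["W0:1"]
        for rel in self.msg_rels:
            H2 += self.ops[rel] @ (H1 @ P[f"W:1:{rel}"])
        self._H2 = H2
        out = np.empty(h.shape[0])
        for ri in np.unique(r):
            sel = r == ri
            out[sel] = (
                H2[h[sel]] * P[f"R:{self.relations[ri]}"] * H2[t[sel]]
            ).sum(1)
        return out

    def _backward(self, h, r, t, coeff, grads) -> None:
        P = self.params
        if self.model == "rotate":
            g_re = np.zeros_like(P["ent_re"])
            g_im = np.zeros_like(P["ent_im"])
            for ri in np.unique(r):
                sel = r == ri
                rel = self.relations[ri]
                theta = P[f"rel:{rel}"]
                rc, rs = np.cos(theta), np.sin(theta)
                hi, ti, c = h[sel], t[sel], coeff[sel][:, None]
                hre, him = P["ent_re"][hi], P["ent_im"][hi]
                hr_re = hre * rc - him * rs
                hr_im = hre * rs + him * rc
                zre = hr_re - P["ent_re"][ti]
                zim = hr_im - P["ent_im"][ti]
                m = np.sqrt(zre**2 + zim**2 + _EPS)
                ure, uim = zre / m, zim / m
                np.add.at(g_re, hi, c * (ure * rc + uim * rs))
                np.add.at(g_im, hi, c * (-ure * rs + uim * rc))
                np.add.at(g_re, ti, -c * ure)
                np.add.at(g_im, ti, -c * uim)
                grads[f"rel:{rel}"] = grads.get(f"rel:{rel}", 0.0) + (
                    c * (-ure * hr_im + uim * hr_re)
                ).sum(0)
            grads["ent_re"], grads["ent_im"] = g_re, g_im
        elif self.model == "transe":
            g = np.zeros_like(P["ent"])
            for ri in np.unique(r):
                sel = r == ri
                rel = self.relations[ri]
                hi, ti, c = h[sel], t[sel], coeff[sel][:, None]
                s = np.sign(P["ent"][hi] + P[f"rel:{rel}"] - P["ent"][ti])
                np.add.at(g, hi, c * s)
                np.add.at(g, ti, -c * s)
                grads[f"rel:{rel}"] = grads.get(f"rel:{rel}", 0.0) + (c * s).sum(0)
            grads["ent"] = g
        elif self.model == "distmult":
            g = np.zeros_like(P["ent"])
            for ri in np.unique(r):
                sel = r == ri
                rel = self.relations[ri]
                hi, ti, c = h[sel], t[sel], coeff[sel][:, None]
                rv = P[f"rel:{rel}"]
                np.add.at(g, hi, c * rv * P["ent"][ti])
                np.add.at(g, ti, c * rv * P["ent"][hi])
                grads[f"rel:{rel}"] = grads.get(f"rel:{rel}", 0.0) + (
                    c * P["ent"][hi] * P["ent"][ti]
                ).sum(0)
            grads["ent"] = g
        else:  # rgcn
            H2, H1, Z1, H0 = self._H2, self._H1, self._Z1, self._H0
            G2 = np.zeros_like(H2)
            for ri in np.unique(r):
                sel = r == ri
                rel = self.relations[ri]
                hi, ti, c = h[sel], t[sel], coeff[sel][:, None]
                rv = P[f"R:{rel}"]
                np.add.at(G2, hi, c * rv * H2[ti])
                np.add.at(G2, ti, c * rv * H2[hi])
                grads[f"R:{rel}"] = grads.get(f"R:{rel}", 0.0) + (
                    c * H2[hi] * H2[ti]
                ).sum(0)
            grads["W0:1"] = H1.T @ G2
            G1 = G2 @ P["W0:1"].T
            for rel in self.msg_rels:
                AH1 = self.ops[rel] @ H1
                grads[f"W:1:{rel}"] = AH1.T @ G2
                G1 += (self.ops[rel].T @ G2) @ P[f"W:1:{rel}"].T
            G1 = G1 * (Z1 > 0)
            grads["W0:0"] = H0.T @ G1
            G0 = G1 @ P["W0:0"].T
            for rel in self.msg_rels:
                AH0 = self.ops[rel] @ H0
                grads[f"W:0:{rel}"] = AH0.T @ G1
                G0 += (self.ops[rel].T @ G1) @ P[f"W:0:{rel}"].T
            grads["ent0"] = G0

    # .. public ............................................................

    def run(self) -> EmbeddingSet:
        opt = Adam(self.params, lr=self.cfg.lr)
        trajectory = []
        for epoch in range(self.cfg.epochs):
            loss = self._epoch(opt)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch + 1}"
                )
            trajectory.append(loss)
        logger.info(
            "%s: epoch-1 loss %.4f -> epoch-%d loss %.4f",
            self.model,
            trajectory[0],
            self.cfg.epochs,
            trajectory[-1],
        )
        if self._collisions:
            logger.warning(
                "kept %d negative corruption(s) colliding with known triples "
                "after bounded retries",
                self._collisions,
            )
        return self._export(trajectory)

    def _export(self, trajectory: list[float]) -> EmbeddingSet:
        P = self.params
        if self.model == "rotate":
            emb = EmbeddingSet(
                model="rotate",
                entity_ids=self.ids,
                dim=self.cfg.dim,
                gamma=self.cfg.gamma,
                ent_re=P["ent_re"].copy(),
                ent_im=P["ent_im"].copy(),
                rel={r: P[f"rel:{r}"].copy() for r in self.relations},
            )
        elif self.model in ("transe", "distmult"):
            emb = EmbeddingSet(
                model=self.model,
                entity_ids=self.ids,
                dim=self.cfg.dim,
                gamma=self.cfg.gamma,
                ent_re=P["ent"].copy(),
                rel={r: P[f"rel:{r}"].copy() for r in self.relations},
            )
        else:
            # final RGCN node embeddings + diagonal decoder
            self._raw_scores(
                np.zeros(1, dtype=int), np.zeros(1, dtype=int), np.zeros(1, dtype=int)
            )
            layers = RGCNLayerStack(
                rel_weights=[
                    {r: P[f"W:0:{r}"].copy() for r in self.msg_rels},
                    {r: P[f"W:1:{r}"].copy() for r in self.msg_rels},
                ],
                self_weights=[P["W0:0"].copy(), P["W0:1"].copy()],
            )
            emb = EmbeddingSet(
                model="rgcn",
                entity_ids=self.ids,
                dim=self.cfg.dim,
                gamma=self.cfg.gamma,
                ent_re=self._H2.copy(),
                rel={r: P[f"R:{r}"].copy() for r in self.relations},
                layers=layers,
            )
        emb.loss_trajectory = trajectory
        return emb


def train(net: MTPNetwork, model: str, config: TrainConfig | None = None) -> EmbeddingSet:
    """Train one embedding model on the network; deterministic per seed."""
    return _Trainer(net, model, config or TrainConfig()).run()
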