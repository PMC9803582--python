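"""Compact weighted co-expression network analysis (signed, Pearson).

The stages implemented are the ones needed for hub-miRNA discovery:

1. signed adjacency ``a_ij = ((1 + cor_ij) / 2) ** beta``;
2. soft-threshold (``beta``) selection by scale-free topology fit, using the
   signed R^2 of the log–log degree-distribution regression with a target of
   0.9 by convention;
3. the topological overlap matrix (TOM);
4. module detection by average-linkage hierarchical clustering of
   ``1 - TOM`` with a static height cut and eigengene-based module merging;
5. intramodular-connectivity ranking of the top hub features per module.

The static height cut is a deliberate simplification of the dynamic hybrid
tree cut used by the reference R workflow; it is parameterized by
``cut_height`` and behaves identically on well-separated modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .mtp_core import ExpressionMatrix

logger = logging.getLogger("mtpnet")

UNASSIGNED = 0  # module label for features left out of every module ("grey")


def signed_adjacency(expr: ExpressionMatrix, beta: int) -> np.ndarray:
    """Signed weighted adjacency ``((1 + pearson) / 2) ** beta``.

    Entries lie in [0, 1]; anticorrelated pairs get weight near 0, perfectly
    correlated pairs weight 1 for any beta. The diagonal is set to 1.
    """
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    values = expr.matrix()
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = [expr.feature_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant feature(s) with undefined correlation: {bad}")
    cor = np.corrcoef(values)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.clip(adj, 0.0, 1.0, out=adj)
    np.fill_diagonal(adj, 1.0)
    return adj


@dataclass
class SoftThresholdScan:
    betas: list[int]
    signed_r2: list[float]  # NaN where the fit was undefined
    mean_connectivity: list[float]
    chosen_beta: int
    reached_target: bool
    r2_target: float = 0.9


def _scale_free_signed_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10(freq) ~ log10(mean k) over equal-width bins of k.

    Returns NaN when fewer than 3 nonempty bins remain (fit undefined).
    """
    k = connectivity[connectivity > 0]
    if k.size < 3:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    means, freqs = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            means.append(k[sel].mean())
            freqs.append(sel.mean())
    if len(means) < 3:
        return float("nan")
    x = np.log10(means)
    y = np.log10(freqs)
    fit = linregress(x, y)
    return float(fit.rvalue**2 * -np.sign(fit.slope))


def pick_soft_threshold(
    expr: ExpressionMatrix,
    betas: list[int] | None = None,
    r2_target: float = 0.9,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate betas and choose the smallest with signed R^2 >= target.

    Falls back to the beta with maximal signed R^2 (with a warning) when no
    candidate reaches the target; betas whose degree histogram leaves fewer
    than 3 nonempty bins are skipped with a warning.
    """
    if betas is None:
        betas = list(range(1, 21))
    if not betas:
        raise ValueError("betas must be nonempty")
    r2s, ks = [], []
    for beta in betas:
        adj = signed_adjacency(expr, beta)
        k = adj.sum(axis=0) - 1.0
        r2 = _scale_free_signed_r2(k, n_bins=n_bins)
        if np.isnan(r2):
            logger.warning("beta=%d: fewer than 3 nonempty degree bins, skipped", beta)
        r2s.append(r2)
        ks.append(float(k.mean()))
    arr = np.array(r2s)
    ok = np.flatnonzero(~np.isnan(arr) & (arr >= r2_target))
    if ok.size:
        chosen = betas[int(ok[0])]
        reached = True
    else:
        valid = np.flatnonzero(~np.isnan(arr))
        if not valid.size:
            raise ValueError("scale-free fit undefined for every candidate beta")
        chosen = betas[int(valid[np.argmax(arr[valid])])]
        reached = False
        logger.warning(
            "no beta reached signed R^2 target %.2f; falling back to beta=%d "
            "(max signed R^2 %.3f)",
            r2_target,
            chosen,
            float(np.nanmax(arr)),
        )
    return SoftThresholdScan(
        betas=list(betas),
        signed_r2=[float(v) for v in r2s],
        mean_connectivity=ks,
        chosen_beta=chosen,
        reached_target=reached,
        r2_target=r2_target,
    )


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency.

    ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for ``i != j``,
    with ``L_ij = sum_u a_iu a_uj`` over ``u != i, j`` and
    ``k_i = sum_u a_iu`` over ``u != i``; the diagonal is 1. High overlap
    means two features share most of their network neighbourhood.
    """
    adj = np.asarray(adj, dtype=float)
    if adj.shape[0] != adj.shape[1] or not np.allclose(adj, adj.T):
        raise ValueError("adjacency must be square symmetric")
    if adj.min() < -1e-12 or adj.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    b = adj.copy()
    np.fill_diagonal(b, 0.0)
    L = b @ b
    k = b.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - b
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + b) / denom
    tom[denom <= 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class ModuleAssignment:
    """Feature → module labels plus per-module ranked hub lists.

    Label 0 means unassigned; modules are numbered 1..k by decreasing size.
    """

    labels: dict[str, int]
    hubs: dict[int, list[tuple[str, float]]] = field(default_factory=dict)

    def members(self, module: int) -> list[str]:
        return sorted(f for f, m in self.labels.items() if m == module)

    def module_ids(self) -> list[int]:
        return sorted(m for m in set(self.labels.values()) if m != UNASSIGNED)

    def hub_ids(self) -> set[str]:
        return {f for ranked in self.hubs.values() for f, _ in ranked}


def _module_eigengene(values: np.ndarray) -> np.ndarray:
    """First principal-component score over samples of a standardized
    module sub-matrix (features × samples); sign-fixed to correlate
    positively with the module's mean expression profile."""
    z = (values - values.mean(axis=1, keepdims=True)) / values.std(
        axis=1, keepdims=True
    )
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    if np.corrcoef(eig, z.mean(axis=0))[0, 1] < 0:
        eig = -eig
    return eig


def detect_modules(
    tom: np.ndarray,
    expr: ExpressionMatrix,
    min_module_size: int = 5,
    cut_height: float = 0.99,
    merge_cor: float = 0.75,
) -> ModuleAssignment:
    """Average-linkage clustering of ``1 - TOM``, static cut, eigengene merge.

    Clusters smaller than ``min_module_size`` are left unassigned. Module
    pairs whose eigengenes correlate above ``merge_cor`` are merged
    iteratively (the conventional "merge at dissimilarity 0.25" rule).
    """
    features = expr.feature_ids
    n = len(features)
    if tom.shape != (n, n):
        raise ValueError("TOM shape does not match expression features")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    labels = np.zeros(n, dtype=int)
    next_label = 1
    for cl in np.unique(raw):
        members = np.flatnonzero(raw == cl)
        if members.size >= min_module_size:
            labels[members] = next_label
            next_label += 1
    if next_label == 1:
        logger.warning("no cluster reached min_module_size=%d", min_module_size)
        return ModuleAssignment(labels={f: UNASSIGNED for f in features})

    values = expr.matrix()
    # iterative eigengene merging
    while True:
        mods = [m for m in np.unique(labels) if m != UNASSIGNED]
        if len(mods) < 2:
            break
        eigs = {
            m: _module_eigengene(values[np.flatnonzero(labels == m)]) for m in mods
        }
        best, best_cor = None, merge_cor
        for i, a in enumerate(mods):
            for b in mods[i + 1 :]:
                c = float(np.corrcoef(eigs[a], eigs[b])[0, 1])
                if c > best_cor:
                    best, best_cor = (a, b), c
        if best is None:
            break
        labels[labels == best[1]] = best[0]

    # relabel 1..k by decreasing module size (ties by first appearance)
    mods = [m for m in np.unique(labels) if m != UNASSIGNED]
    sizes = {m: int((labels == m).sum()) for m in mods}
    order = sorted(mods, key=lambda m: (-sizes[m], m))
    remap = {m: i + 1 for i, m in enumerate(order)}
    final = {
        features[i]: remap.get(int(labels[i]), UNASSIGNED) for i in range(n)
    }
    return ModuleAssignment(labels=final)


def rank_hubs(
    assign: ModuleAssignment, adj: np.ndarray, feature_ids: list[str], top_n: int = 10
) -> ModuleAssignment:
    """Rank each module's features by intramodular connectivity.

    ``kIn_i = sum over module co-members j != i of a_ij``; the ``top_n``
    per module become the module's hubs, ties broken lexicographically.
    """
    index = {f: i for i, f in enumerate(feature_ids)}
    b = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(b, 0.0)
    hubs: dict[int, list[tuple[str, float]]] = {}
    for module in assign.module_ids():
        members = assign.members(module)
        idx = [index[f] for f in members]
        sub = b[np.ix_(idx, idx)]
        kin = sub.sum(axis=1)
        ranked = sorted(zip(members, kin), key=lambda t: (-t[1], t[0]))
        hubs[module] = [(f, float(k)) for f, k in ranked[:top_n]]
    assign.hubs = hubs
    return assign
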