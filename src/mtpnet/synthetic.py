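"""Synthetic benchmark generators with planted ground truth.

Real studies of this kind start from a case/control miRNA expression matrix
and a database-derived miRNA–target–pathway (MTP) network. Offline, both are
replaced by generators whose structure is known exactly:

* :func:`simulate_expression` plants correlated co-expression modules
  (shared latent factor per module) and biomarker miRNAs whose case-group
  mean is shifted by a known effect size on the log2 scale.
* :func:`simulate_mtp` plants miRNA communities defined by overlapping
  target pools, wires targets to each other with a stochastic block model
  (emulating protein–protein interactions) and to pathways preferentially
  within the community, and draws tissue/category label matrices whose
  probabilities depend on the planted block.

Every generator is a pure function of its arguments including ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mtp_core import ExpressionMatrix, LabelMatrix, MTPNetwork

#: per-block probability that an "on" tissue label fires, vs. background
_T_LABEL_ON, _T_LABEL_OFF = 0.8, 0.1
#: probability a pathway carries its own category label, vs. another one
_P_LABEL_ON, _P_LABEL_OFF = 0.9, 0.05
#: tissue labels switched on per target block
_T_LABELS_PER_BLOCK = 5


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    mirna_community: dict[str, int] = field(default_factory=dict)
    planted_hubs: dict[int, list[str]] = field(default_factory=dict)
    biomarkers: list[str] = field(default_factory=list)
    effect: float = 0.0
    target_block: dict[str, int] = field(default_factory=dict)
    pathway_community: dict[str, int] = field(default_factory=dict)
    pathway_category: dict[str, int] = field(default_factory=dict)
    held_out: list[tuple[str, str, str]] = field(default_factory=list)
    draw_counts: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "mirna_community": self.mirna_community,
            "planted_hubs": {str(k): v for k, v in self.planted_hubs.items()},
            "biomarkers": self.biomarkers,
            "effect": self.effect,
            "target_block": self.target_block,
            "pathway_community": self.pathway_community,
            "pathway_category": self.pathway_category,
            "held_out": [list(t) for t in self.held_out],
            "draw_counts": self.draw_counts,
        }


def simulate_expression(
    n_case: int = 6,
    n_control: int = 7,
    n_mirna: int = 100,
    n_modules: int = 4,
    within_module_cor: float = 0.8,
    n_biomarkers: int = 5,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a log2-scale miRNA expression matrix with planted modules.

    Each module ``m`` has a latent factor per sample; a member miRNA's
    profile is ``sqrt(rho) * factor + sqrt(1 - rho) * noise`` with
    ``rho = within_module_cor``, so the expected within-module Pearson
    correlation is ``rho``. Biomarker miRNAs additionally receive
    ``+effect`` on case samples, making the group mean difference (the
    log2 fold change) equal to ``effect`` in expectation.

    Default group sizes mirror a small plasma case/control array study
    (6 case vs. 7 control pools).
    """
    if n_biomarkers > n_mirna:
        raise ValueError("n_biomarkers exceeds n_mirna")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    rng = np.random.default_rng(seed)
    n_samples = n_case + n_control
    sample_ids = [f"case{i}" for i in range(n_case)] + [
        f"ctrl{i}" for i in range(n_control)
    ]
    groups = {s: ("case" if s.startswith("case") else "control") for s in sample_ids}
    mirna_ids = [f"m{i:03d}" for i in range(n_mirna)]

    module_of = np.arange(n_mirna) % n_modules
    factors = rng.normal(size=(n_modules, n_samples))
    noise = rng.normal(scale=noise_sd, size=(n_mirna, n_samples))
    rho = within_module_cor
    values = np.sqrt(rho) * factors[module_of] + np.sqrt(1.0 - rho) * noise

    biomarker_idx = rng.choice(n_mirna, size=n_biomarkers, replace=False)
    values[np.ix_(biomarker_idx, np.arange(n_case))] += effect

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=mirna_ids, columns=sample_ids),
        groups=groups,
    )
    truth = SyntheticTruth(
        mirna_community={mirna_ids[i]: int(module_of[i]) for i in range(n_mirna)},
        biomarkers=sorted(mirna_ids[i] for i in biomarker_idx),
        effect=effect,
    )
    return expr, truth


def simulate_mtp(
    n_mirna: int = 100,
    n_targets: int = 100,
    n_pathways: int = 20,
    n_communities: int = 4,
    pool_size: int = 25,
    p_in: float = 0.4,
    p_out: float = 0.01,
    ppi_p_in: float = 0.3,
    ppi_p_out: float = 0.02,
    seed: int = 0,
) -> tuple[MTPNetwork, LabelMatrix, LabelMatrix, SyntheticTruth]:
    """Simulate an MTP network with planted miRNA communities.

    miRNAs are partitioned into ``n_communities`` communities; community
    ``c`` owns a disjoint target pool of ``pool_size`` genes. A miRNA draws
    an MT edge to each gene of its own pool with probability ``p_in`` and to
    every other gene with probability ``p_out``, so communities are defined
    by overlapping target pools. One miRNA per community (the planted hub)
    regulates its entire pool, giving it the highest expected target
    coverage. TT edges follow a stochastic block model over target pools
    (``ppi_p_in`` within a pool, ``ppi_p_out`` across; leftover targets form
    a background block). Each pathway is assigned a community and draws TP
    edges from that community's pool with probability ``p_in`` (``p_out``
    elsewhere); its category is ``community mod 5``. Tissue labels for
    targets and category labels for pathways are drawn with block-dependent
    probabilities, so labels are predictable from network position.

    Default sizes are two orders of magnitude below a database-derived
    disease network (order 10^2–10^3 edges) so a full training run stays in
    the seconds range on one CPU.
    """
    if not 0 <= p_in <= 1 or not 0 <= p_out <= 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if not 0 <= ppi_p_in <= 1 or not 0 <= ppi_p_out <= 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if n_communities > n_mirna:
        raise ValueError("n_communities exceeds n_mirna")
    if n_communities * pool_size > n_targets:
        raise ValueError("n_communities * pool_size exceeds n_targets")
    rng = np.random.default_rng(seed)

    mirna_ids = [f"m{i:03d}" for i in range(n_mirna)]
    target_ids = [f"g{i:03d}" for i in range(n_targets)]
    pathway_ids = [f"p{i:03d}" for i in range(n_pathways)]

    community_of = np.arange(n_mirna) % n_communities
    # disjoint pools; targets beyond the pools form background block n_communities
    block_of_target = np.full(n_targets, n_communities, dtype=int)
    for c in range(n_communities):
        block_of_target[c * pool_size : (c + 1) * pool_size] = c

    planted_hubs: dict[int, list[str]] = {}
    hub_idx = set()
    for c in range(n_communities):
        members = np.flatnonzero(community_of == c)
        hub = int(members[0])
        hub_idx.add(hub)
        planted_hubs[c] = [mirna_ids[hub]]

    triples: list[tuple[str, str, str]] = []
    counts = {"MT": 0, "TT": 0, "TP": 0}

    # MT edges
    for i in range(n_mirna):
        c = community_of[i]
        own = block_of_target == c
        prob = np.where(own, 1.0 if i in hub_idx else p_in, p_out)
        hits = rng.random(n_targets) < prob
        for j in np.flatnonzero(hits):
            triples.append((mirna_ids[i], "MT", target_ids[j]))
            counts["MT"] += 1

    # TT stochastic block model over target pools (undirected, i < j)
    for i in range(n_targets):
        same = block_of_target[i + 1 :] == block_of_target[i]
        prob = np.where(same, ppi_p_in, ppi_p_out)
        hits = rng.random(n_targets - i - 1) < prob
        for off in np.flatnonzero(hits):
            j = i + 1 + off
            triples.append((target_ids[i], "TT", target_ids[j]))
            counts["TT"] += 1

    # pathways: community assignment round-robin, category = community mod 5
    pathway_community = np.arange(n_pathways) % n_communities
    pathway_category = pathway_community % 5
    for k in range(n_pathways):
        own = block_of_target == pathway_community[k]
        prob = np.where(own, p_in, p_out)
        hits = rng.random(n_targets) < prob
        for j in np.flatnonzero(hits):
            triples.append((target_ids[j], "TP", pathway_ids[k]))
            counts["TP"] += 1

    net = MTPNetwork.from_triples(
        triples,
        extra_nodes={
            **{m: "M" for m in mirna_ids},
            **{t: "T" for t in target_ids},
            **{p: "P" for p in pathway_ids},
        },
    )

    # tissue labels for targets: each block switches on a subset of tissues
    n_t_labels = 21
    on_labels = np.zeros((n_communities + 1, n_t_labels), dtype=bool)
    for b in range(n_communities + 1):
        on = rng.choice(n_t_labels, size=_T_LABELS_PER_BLOCK, replace=False)
        on_labels[b, on] = True
    t_prob = np.where(on_labels[block_of_target], _T_LABEL_ON, _T_LABEL_OFF)
    t_matrix = (rng.random((n_targets, n_t_labels)) < t_prob).astype(int)
    t_labels = LabelMatrix(
        pd.DataFrame(
            t_matrix,
            index=target_ids,
            columns=[f"tissue{j:02d}" for j in range(n_t_labels)],
        ),
        node_type="T",
    )

    # category labels for pathways
    n_p_labels = 5
    p_prob = np.full((n_pathways, n_p_labels), _P_LABEL_OFF)
    p_prob[np.arange(n_pathways), pathway_category] = _P_LABEL_ON
    p_matrix = (rng.random((n_pathways, n_p_labels)) < p_prob).astype(int)
    p_labels = LabelMatrix(
        pd.DataFrame(
            p_matrix,
            index=pathway_ids,
            columns=[f"category{j}" for j in range(n_p_labels)],
        ),
        node_type="P",
    )

    truth = SyntheticTruth(
        mirna_community={mirna_ids[i]: int(community_of[i]) for i in range(n_mirna)},
        planted_hubs=planted_hubs,
        target_block={target_ids[i]: int(block_of_target[i]) for i in range(n_targets)},
        pathway_community={
            pathway_ids[k]: int(pathway_community[k]) for k in range(n_pathways)
        },
        pathway_category={
            pathway_ids[k]: int(pathway_category[k]) for k in range(n_pathways)
        },
        draw_counts=counts,
    )
    return net, t_labels, p_labels, truth


def shuffle_relation(
    net: MTPNetwork, relation: str, seed: int = 0
) -> MTPNetwork:
    """Null network: redraw one relation's edges uniformly at random.

    The shuffled relation keeps its triple count (up to duplicate collapse)
    but head–tail pairs are drawn uniformly from the type-consistent node
    classes, destroying the planted structure while preserving network size;
    other relations are untouched. Used as a negative control: link
    prediction on the shuffled relation should sit at the random baseline.
    """
    rel_triples = net.triples_of(relation)
    if not rel_triples:
        raise ValueError(f"relation {relation!r} absent from network")
    rng = np.random.default_rng(seed)
    htype, ttype = net.schema[relation]
    heads = net.nodes_of_type(htype)
    tails = net.nodes_of_type(ttype)
    drawn: set[tuple[str, str, str]] = set()
    attempts = 0
    while len(drawn) < len(rel_triples) and attempts < 50 * len(rel_triples):
        h = heads[int(rng.integers(len(heads)))]
        t = tails[int(rng.integers(len(tails)))]
        if relation in net.schema and h != t:
            drawn.add((h, relation, t) if not (relation == "TT" and t < h) else (t, relation, h))
        attempts += 1
    keep = [t for t in net.triples if t[1] != relation] + sorted(drawn)
    return net.subset(keep)


def hold_out(
    net: MTPNetwork, relation: str, fraction: float, seed: int = 0
) -> tuple[MTPNetwork, list[tuple[str, str, str]]]:
    """Split one relation's triples into train network + held-out test list.

    A uniformly sampled ``round(fraction * n)`` of the relation's triples go
    to the test list; the training network keeps everything else (including
    all other relations and all node declarations). Train and test are
    disjoint and their union is the original triple set.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rel_triples = net.triples_of(relation)
    if not rel_triples:
        raise ValueError(f"relation {relation!r} absent from network")
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(fraction * len(rel_triples))))
    test_idx = set(rng.choice(len(rel_triples), size=n_test, replace=False).tolist())
    test = [rel_triples[i] for i in sorted(test_idx)]
    test_set = set(test)
    train = [t for t in net.triples if t not in test_set]
    return net.subset(train), test
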