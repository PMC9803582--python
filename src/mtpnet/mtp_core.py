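"""Core domain types for miRNA–target–pathway (MTP) heterogeneous networks.

The MTP network is a typed triple store with three node classes — miRNAs
(``M``), target genes (``T``) and pathways (``P``) — and three relations:

* ``MT`` — miRNA regulates target gene (directed M→T),
* ``TT`` — protein–protein interaction between targets (undirected),
* ``TP`` — target gene belongs to a pathway (directed T→P).

This module also carries the expression-matrix container used by the
co-expression analysis and biomarker evaluation, the differential-expression
screening filter, and the binary label matrices used for multilabel node
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mtpnet")

#: relation → (head node type, tail node type)
RELATION_SCHEMA: dict[str, tuple[str, str]] = {
    "MT": ("M", "T"),
    "TT": ("T", "T"),
    "TP": ("T", "P"),
}

#: relations treated as undirected and stored with head id ≤ tail id
UNDIRECTED_RELATIONS = frozenset({"TT"})

NODE_TYPES = ("M", "T", "P")


class ValidationError(ValueError):
    """Raised when a network, matrix or label table violates an invariant."""


class SchemaError(ValidationError):
    """Raised when a triple uses a relation absent from the schema."""


def _canonical(head: str, relation: str, tail: str) -> tuple[str, str, str]:
    if relation in UNDIRECTED_RELATIONS and tail < head:
        return (tail, relation, head)
    return (head, relation, tail)


@dataclass
class MTPNetwork:
    """Typed triple store over M/T/P nodes.

    ``node_types`` maps every node id to its class; ``triples`` holds unique
    (head, relation, tail) records with undirected relations canonicalized.
    """

    node_types: dict[str, str] = field(default_factory=dict)
    triples: list[tuple[str, str, str]] = field(default_factory=list)
    schema: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: dict(RELATION_SCHEMA)
    )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_triples(
        cls,
        triples: Iterable[tuple[str, str, str]],
        schema: Mapping[str, tuple[str, str]] | None = None,
        extra_nodes: Mapping[str, str] | None = None,
    ) -> "MTPNetwork":
        """Build a validated network from raw (head, relation, tail) records.

        Duplicate triples (after canonicalization of undirected relations)
        are collapsed; a node re-used under two different types is an error.
        """
        schema = dict(schema) if schema is not None else dict(RELATION_SCHEMA)
        net = cls(schema=schema)
        if extra_nodes:
            for node, ntype in extra_nodes.items():
                net._declare(node, ntype)
        seen: set[tuple[str, str, str]] = set()
        n_dup = 0
        for head, relation, tail in triples:
            if relation not in schema:
                raise SchemaError(f"unknown relation {relation!r}")
            htype, ttype = schema[relation]
            triple = _canonical(head, relation, tail)
            if relation in UNDIRECTED_RELATIONS:
                # canonical order never swaps types for TT (both T)
                pass
            net._declare(triple[0], htype)
            net._declare(triple[2], ttype)
            if triple in seen:
                n_dup += 1
                continue
            seen.add(triple)
            net.triples.append(triple)
        if n_dup:
            logger.info("collapsed %d duplicate triple(s)", n_dup)
        return net

    def _declare(self, node: str, ntype: str) -> None:
        prev = self.node_types.get(node)
        if prev is None:
            self.node_types[node] = ntype
        elif prev != ntype:
            raise ValidationError(
                f"node {node!r} used as both {prev!r} and {ntype!r}"
            )

    # -- accessors --------------------------------------------------------

    def nodes_of_type(self, ntype: str) -> list[str]:
        return sorted(n for n, t in self.node_types.items() if t == ntype)

    def triples_of(self, relation: str) -> list[tuple[str, str, str]]:
        return [t for t in self.triples if t[1] == relation]

    def triple_set(self) -> set[tuple[str, str, str]]:
        return set(self.triples)

    def __len__(self) -> int:
        return len(self.triples)

    def subset(self, triples: Sequence[tuple[str, str, str]]) -> "MTPNetwork":
        """A network restricted to the given triples, keeping all node
        declarations (so entities stay rankable after a hold-out split)."""
        net = MTPNetwork(
            node_types=dict(self.node_types),
            triples=list(triples),
            schema=dict(self.schema),
        )
        return net

    def validate(self) -> None:
        seen = set()
        for head, relation, tail in self.triples:
            if relation not in self.schema:
                raise SchemaError(f"unknown relation {relation!r}")
            htype, ttype = self.schema[relation]
            if self.node_types.get(head) != htype:
                raise ValidationError(
                    f"head {head!r} of {relation} triple is not typed {htype!r}"
                )
            if self.node_types.get(tail) != ttype:
                raise ValidationError(
                    f"tail {tail!r} of {relation} triple is not typed {ttype!r}"
                )
            if relation in UNDIRECTED_RELATIONS and head > tail:
                raise ValidationError(
                    f"TT triple ({head}, {tail}) not canonically ordered"
                )
            if (head, relation, tail) in seen:
                raise ValidationError(f"duplicate triple {(head, relation, tail)}")
            seen.add((head, relation, tail))


# -- triple I/O ------------------------------------------------------------


def read_triples(
    path, relation_schema: Mapping[str, tuple[str, str]] | None = None
) -> MTPNetwork:
    """Read a 3-column TSV (header ``head  relation  tail``) into a network."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["head", "relation", "tail"]
    if list(df.columns[:3]) != required:
        raise SchemaError(
            f"expected columns {required}, found {list(df.columns[:3])}"
        )
    return MTPNetwork.from_triples(
        df[required].itertuples(index=False, name=None), schema=relation_schema
    )


def write_triples(net: MTPNetwork, path) -> None:
    """Write the network as a TSV that :func:`read_triples` round-trips."""
    df = pd.DataFrame(net.triples, columns=["head", "relation", "tail"])
    df.to_csv(path, sep="\t", index=False)


# -- expression matrices ---------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A feature × sample log-scale expression matrix with case/control groups."""

    values: pd.DataFrame  # rows = features, columns = samples
    groups: dict[str, str]  # sample id → "case" | "control"

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate feature ids")
        for sample in self.values.columns:
            if sample not in self.groups:
                raise ValidationError(f"sample {sample!r} has no group assignment")
        counts = pd.Series(list(self.groups.values())).value_counts()
        for grp in ("case", "control"):
            if counts.get(grp, 0) < 2:
                raise ValidationError(f"group {grp!r} has fewer than 2 samples")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def read_expression(matrix_csv, groups_tsv) -> ExpressionMatrix:
    """Expression CSV (first column = feature id) + 2-column sample→group TSV."""
    values = pd.read_csv(matrix_csv, index_col=0)
    gdf = pd.read_csv(groups_tsv, sep="\t", dtype=str)
    groups = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1]))
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(expr: ExpressionMatrix, matrix_csv, groups_tsv) -> None:
    expr.values.to_csv(matrix_csv)
    pd.DataFrame(
        {"sample": expr.sample_ids, "group": [expr.groups[s] for s in expr.sample_ids]}
    ).to_csv(groups_tsv, sep="\t", index=False)


# -- differential-expression screening -------------------------------------


@dataclass
class DETable:
    """Per-feature differential-expression summary: log2 fold change and
    multiplicity-adjusted p value."""

    table: pd.DataFrame  # index = feature id, columns include logFC, adj_p

    def __post_init__(self) -> None:
        for col in ("logFC", "adj_p"):
            if col not in self.table.columns:
                raise ValidationError(f"DE table lacks column {col!r}")
        p = self.table["adj_p"]
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("adj_p outside [0, 1]")


def filter_differential(
    table: DETable, logfc_min: float = 2.0, adjp_max: float = 0.05
) -> list[str]:
    """Features with ``|logFC| > logfc_min`` and ``adj_p < adjp_max``.

    Both inequalities are strict: a feature exactly at either boundary is
    excluded.
    """
    df = table.table
    keep = (df["logFC"].abs() > logfc_min) & (df["adj_p"] < adjp_max)
    return list(df.index[keep])


# -- per-miRNA target / pathway sets ---------------------------------------


def target_sets(net: MTPNetwork) -> dict[str, set[str]]:
    """Map each miRNA to the set of targets it regulates (one MT hop)."""
    out: dict[str, set[str]] = {m: set() for m in net.nodes_of_type("M")}
    for head, relation, tail in net.triples:
        if relation == "MT":
            out[head].add(tail)
    return out


def pathway_sets(net: MTPNetwork) -> dict[str, set[str]]:
    """Map each miRNA to the pathways reachable via two hops M→T→P.

    A miRNA's pathway set is the union of pathways its targets belong to;
    miRNAs whose targets carry no TP edges map to the empty set.
    """
    t2p: dict[str, set[str]] = {}
    for head, relation, tail in net.triples:
        if relation == "TP":
            t2p.setdefault(head, set()).add(tail)
    out: dict[str, set[str]] = {}
    for mirna, targets in target_sets(net).items():
        out[mirna] = set().union(*(t2p.get(t, set()) for t in targets)) if targets else set()
    return out


# -- label matrices --------------------------------------------------------

#: label-count convention per node class: 21 tissue labels for targets,
#: 5 pathway-category labels for pathways
LABEL_COUNTS = {"T": 21, "P": 5}


@dataclass
class LabelMatrix:
    """Binary label matrix for one node class (tissues for T, categories for P)."""

    values: pd.DataFrame  # index = node id, columns = label names, entries 0/1
    node_type: str

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("label entries must be 0 or 1")
        expected = LABEL_COUNTS.get(self.node_type)
        if expected is not None and self.values.shape[1] != expected:
            raise ValidationError(
                f"{self.node_type} labels must have {expected} columns, "
                f"found {self.values.shape[1]}"
            )

    @property
    def node_ids(self) -> list[str]:
        return list(self.values.index)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def read_labels(path, node_type: str) -> LabelMatrix:
    return LabelMatrix(pd.read_csv(path, sep="\t", index_col=0), node_type)


def write_labels(labels: LabelMatrix, path) -> None:
    labels.values.to_csv(path, sep="\t")
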