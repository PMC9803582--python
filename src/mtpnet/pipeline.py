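"""End-to-end orchestration: simulate → WGCNA → SimCluster → intersect →
embed → evaluate → classify → predict targets.

The pipeline is driven by a flat key=value config file plus a master seed;
every stage's seed is derived deterministically from the master seed and
the stage name, stage outputs are cached by config hash, and a manifest
records seeds, hashes and wall times so two runs with the same config are
identical apart from timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, kg_embed, mtp_core, simcluster, synthetic, wgcna

logger = logging.getLogger("mtpnet")

STAGES = (
    "simulate",
    "wgcna",
    "simcluster",
    "intersect",
    "kg_train",
    "kg_eval",
    "classify",
    "predict_targets",
)


@dataclass
class PipelineConfig:
    """Flat configuration for a full run; unknown keys in a file are errors."""

    seed: int = 0
    # synthetic expression
    expr_n_case: int = 20
    expr_n_control: int = 20
    expr_n_mirna: int = 100
    expr_n_modules: int = 4
    expr_within_cor: float = 0.8
    expr_n_biomarkers: int = 5
    expr_effect: float = 2.0
    expr_noise_sd: float = 1.0
    # synthetic MTP network
    mtp_n_mirna: int = 100
    mtp_n_targets: int = 100
    mtp_n_pathways: int = 20
    mtp_n_communities: int = 4
    mtp_pool_size: int = 25
    mtp_p_in: float = 0.4
    mtp_p_out: float = 0.01
    mtp_ppi_p_in: float = 0.3
    mtp_ppi_p_out: float = 0.02
    # WGCNA
    wgcna_beta: int = 18  # 0 = choose automatically by scale-free fit
    wgcna_r2_target: float = 0.9
    wgcna_cut_height: float = 0.99
    wgcna_min_module_size: int = 5
    wgcna_merge_cor: float = 0.75
    wgcna_top_n: int = 10
    # SimCluster
    sim_order: int = 1
    sim_cor_min: float = 0.9
    sim_r2_min: float = 0.9
    # embedding training
    train_model: str = "rotate"
    train_dim: int = 64
    train_lr: float = 0.001
    train_epochs: int = 50
    train_gamma: float = 6.0
    train_alpha: float = 1.0
    train_negatives: int = 16
    train_batch: int = 512
    # evaluation
    eval_relation: str = "MT"
    eval_folds: int = 10
    eval_filtered: bool = True
    # target prediction
    predict_top_n: int = 10

    # -- file form --------------------------------------------------------

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        valid = {f.name: f.type for f in fields(cls)}
        casts = {f.name: type(getattr(cls(), f.name)) for f in fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in valid:
                raise ValueError(f"unknown config key {key!r}")
            cast = casts[key]
            kwargs[key] = value == "True" if cast is bool else cast(value)
        return cls(**kwargs)

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).hexdigest()
        return int(digest[:8], 16) % (2**31)

    def train_config(self, stage: str = "kg_train") -> kg_embed.TrainConfig:
        return kg_embed.TrainConfig(
            dim=self.train_dim,
            lr=self.train_lr,
            epochs=self.train_epochs,
            negatives=self.train_negatives,
            alpha=self.train_alpha,
            gamma=self.train_gamma,
            batch_size=self.train_batch,
            seed=self.stage_seed(stage),
        )


# -- stage hashing / caching ----------------------------------------------

#: config fields each stage depends on (beyond upstream hashes)
_STAGE_KEYS = {
    "simulate": [
        "seed",
        *(f.name for f in fields(PipelineConfig) if f.name.startswith(("expr_", "mtp_"))),
    ],
    "wgcna": [n for n in (f.name for f in fields(PipelineConfig)) if n.startswith("wgcna_")],
    "simcluster": [n for n in (f.name for f in fields(PipelineConfig)) if n.startswith("sim_")],
    "intersect": [],
    "kg_train": [n for n in (f.name for f in fields(PipelineConfig)) if n.startswith("train_")],
    "kg_eval": [n for n in (f.name for f in fields(PipelineConfig)) if n.startswith("eval_")],
    "classify": [],
    "predict_targets": ["predict_top_n"],
}

_STAGE_DEPS = {
    "simulate": [],
    "wgcna": ["simulate"],
    "simcluster": ["simulate"],
    "intersect": ["wgcna", "simcluster"],
    "kg_train": ["simulate"],
    "kg_eval": ["simulate", "kg_train"],
    "classify": ["simulate", "kg_train"],
    "predict_targets": ["intersect", "kg_train"],
}

_STAGE_OUTPUTS = {
    "simulate": [
        "triples.tsv",
        "expression.csv",
        "groups.tsv",
        "labels_T.tsv",
        "labels_P.tsv",
        "truth.json",
    ],
    "wgcna": ["wgcna_modules.tsv", "wgcna_scan.json", "wgcna_hubs.txt"],
    "simcluster": ["sim_scan.tsv", "sim_partition.tsv", "sim_hubs.txt"],
    "intersect": ["hubs_final.txt"],
    "kg_train": ["embeddings.tsv", "embeddings.json"],
    "kg_eval": ["kg_eval.json"],
    "classify": ["classify.json"],
    "predict_targets": ["predicted_targets.tsv"],
}


def _stage_hash(config: PipelineConfig, stage: str, upstream: dict[str, str]) -> str:
    payload = {k: getattr(config, k) for k in _STAGE_KEYS[stage]}
    payload["__deps__"] = [upstream[d] for d in _STAGE_DEPS[stage]]
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class PipelineRun:
    """Executes the stages in order against a run directory."""

    def __init__(self, config: PipelineConfig, out_dir):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.previous = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {"stages": {}}
        )
        self.manifest: dict = {"config": {f.name: getattr(config, f.name) for f in fields(config)}, "stages": {}}
        self._cache: dict = {}

    # .. helpers ...........................................................

    def _done(self, stage: str, h: str) -> bool:
        prev = self.previous["stages"].get(stage)
        if prev is None or prev.get("hash") != h:
            return False
        return all((self.out / f).exists() for f in _STAGE_OUTPUTS[stage])

    def run(self) -> dict:
        hashes: dict[str, str] = {}
        for stage in STAGES:
            h = _stage_hash(self.config, stage, hashes)
            hashes[stage] = h
            entry = {"hash": h, "seed": self.config.stage_seed(stage)}
            if self._done(stage, h):
                entry["skipped"] = True
                entry["wall_time_s"] = 0.0
                logger.info("stage %s: cache hit, skipped", stage)
            else:
                t0 = time.perf_counter()
                try:
                    getattr(self, f"_stage_{stage}")()
                except Exception:
                    self.manifest["stages"][stage] = {**entry, "failed": True}
                    self.manifest_path.write_text(json.dumps(self.manifest, indent=2))
                    logger.error("stage %s failed; partial outputs preserved", stage)
                    raise
                entry["skipped"] = False
                entry["wall_time_s"] = round(time.perf_counter() - t0, 3)
            entry["outputs"] = _STAGE_OUTPUTS[stage]
            self.manifest["stages"][stage] = entry
        self.manifest["versions"] = {"numpy": np.__version__, "pandas": pd.__version__}
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))
        return self.manifest

    # .. data loading (from stage outputs, so cached stages reload) ........

    def _net(self) -> mtp_core.MTPNetwork:
        if "net" not in self._cache:
            self._cache["net"] = mtp_core.read_triples(self.out / "triples.tsv")
        return self._cache["net"]

    def _expr(self) -> mtp_core.ExpressionMatrix:
        if "expr" not in self._cache:
            self._cache["expr"] = mtp_core.read_expression(
                self.out / "expression.csv", self.out / "groups.tsv"
            )
        return self._cache["expr"]

    # .. stages ............................................................

    def _stage_simulate(self) -> None:
        c = self.config
        expr, _ = synthetic.simulate_expression(
            n_case=c.expr_n_case,
            n_control=c.expr_n_control,
            n_mirna=c.expr_n_mirna,
            n_modules=c.expr_n_modules,
            within_module_cor=c.expr_within_cor,
            n_biomarkers=c.expr_n_biomarkers,
            effect=c.expr_effect,
            noise_sd=c.expr_noise_sd,
            seed=c.stage_seed("simulate"),
        )
        net, t_labels, p_labels, truth = synthetic.simulate_mtp(
            n_mirna=c.mtp_n_mirna,
            n_targets=c.mtp_n_targets,
            n_pathways=c.mtp_n_pathways,
            n_communities=c.mtp_n_communities,
            pool_size=c.mtp_pool_size,
            p_in=c.mtp_p_in,
            p_out=c.mtp_p_out,
            ppi_p_in=c.mtp_ppi_p_in,
            ppi_p_out=c.mtp_ppi_p_out,
            seed=c.stage_seed("simulate"),
        )
        mtp_core.write_triples(net, self.out / "triples.tsv")
        mtp_core.write_expression(
            expr, self.out / "expression.csv", self.out / "groups.tsv"
        )
        mtp_core.write_labels(t_labels, self.out / "labels_T.tsv")
        mtp_core.write_labels(p_labels, self.out / "labels_P.tsv")
        (self.out / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=2))

    def _stage_wgcna(self) -> None:
        c = self.config
        expr = self._expr()
        if c.wgcna_beta > 0:
            beta = c.wgcna_beta
            scan = {"betas": [beta], "chosen_beta": beta, "auto": False}
        else:
            result = wgcna.pick_soft_threshold(expr, r2_target=c.wgcna_r2_target)
            beta = result.chosen_beta
            scan = {
                "betas": result.betas,
                "signed_r2": result.signed_r2,
                "chosen_beta": beta,
                "reached_target": result.reached_target,
                "auto": True,
            }
        adj = wgcna.signed_adjacency(expr, beta)
        tom = wgcna.topological_overlap(adj)
        assign = wgcna.detect_modules(
            tom,
            expr,
            min_module_size=c.wgcna_min_module_size,
            cut_height=c.wgcna_cut_height,
            merge_cor=c.wgcna_merge_cor,
        )
        assign = wgcna.rank_hubs(assign, adj, expr.feature_ids, top_n=c.wgcna_top_n)
        kin = {f: 0.0 for f in expr.feature_ids}
        for ranked in assign.hubs.values():
            kin.update(dict(ranked))
        pd.DataFrame(
            {
                "feature": expr.feature_ids,
                "module": [assign.labels[f] for f in expr.feature_ids],
                "kIn": [kin[f] for f in expr.feature_ids],
            }
        ).to_csv(self.out / "wgcna_modules.tsv", sep="\t", index=False)
        (self.out / "wgcna_scan.json").write_text(json.dumps(scan, indent=2))
        (self.out / "wgcna_hubs.txt").write_text(
            "\n".join(sorted(assign.hub_ids())) + "\n"
        )

    def _stage_simcluster(self) -> None:
        c = self.config
        sim = simcluster.similarity_matrix(self._net(), order=c.sim_order)
        sim = simcluster.select_threshold(
            sim, cor_min=c.sim_cor_min, r2_min=c.sim_r2_min, on_fail="best"
        )
        best, results = simcluster.cluster_graph(
            sim.graph, seed=self.config.stage_seed("simcluster")
        )
        hubs = simcluster.module_hubs(best, sim.graph)
        pd.DataFrame(
            [
                (f.tau, abs(f.cor), f.r2, f.n_nodes, f.reliable)
                for f in sim.scan
            ],
            columns=["tau", "abs_cor", "r2", "n_nodes", "reliable"],
        ).to_csv(self.out / "sim_scan.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(best.membership.items()), columns=["mirna", "module"]
        ).to_csv(self.out / "sim_partition.tsv", sep="\t", index=False)
        (self.out / "sim_hubs.txt").write_text("\n".join(sorted(hubs)) + "\n")
        self._cache["sim_tau"] = sim.tau
        self._cache["sim_algorithms"] = {r.algorithm: r.modularity for r in results}

    def _stage_intersect(self) -> None:
        wg = set((self.out / "wgcna_hubs.txt").read_text().split())
        sc = set((self.out / "sim_hubs.txt").read_text().split())
        final = simcluster.intersect_hubs(wg, sc)
        if not final:
            logger.warning("hub intersection empty; falling back to SimCluster hubs")
            final = sc
        (self.out / "hubs_final.txt").write_text("\n".join(sorted(final)) + "\n")

    def _stage_kg_train(self) -> None:
        c = self.config
        emb = kg_embed.train(self._net(), c.train_model, c.train_config())
        self._cache["emb"] = emb
        feats = emb.feature_matrix(emb.entity_ids)
        pd.DataFrame(feats, index=emb.entity_ids).to_csv(
            self.out / "embeddings.tsv", sep="\t", header=False
        )
        (self.out / "embeddings.json").write_text(
            json.dumps(
                {
                    "model": emb.model,
                    "dim": emb.dim,
                    "gamma": emb.gamma,
                    "seed": c.stage_seed("kg_train"),
                    "final_loss": emb.loss_trajectory[-1],
                },
                indent=2,
            )
        )

    def _stage_kg_eval(self) -> None:
        c = self.config
        report = evaluation.crossval_link_prediction(
            self._net(),
            c.eval_relation,
            c.train_model,
            config=c.train_config("kg_eval"),
            folds=c.eval_folds,
            filtered=c.eval_filtered,
        )
        payload = report.to_json_dict()
        payload["relation"] = c.eval_relation
        payload["model"] = c.train_model
        payload["random_baseline_mrr"] = evaluation.random_baseline_mrr(
            self._net(), c.eval_relation
        )
        (self.out / "kg_eval.json").write_text(json.dumps(payload, indent=2))

    def _stage_classify(self) -> None:
        c = self.config
        labels = mtp_core.read_labels(self.out / "labels_T.tsv", "T")
        report = evaluation.crossval_multilabel(
            self._net(),
            labels,
            c.train_model,
            config=c.train_config("classify"),
            folds=c.eval_folds,
            embeddings=self._cache.get("emb"),
        )
        # transductive caveat: embeddings see the full graph, only labels are held out
        payload = report.to_json_dict()
        payload["node_type"] = "T"
        payload["transductive_embeddings"] = True
        (self.out / "classify.json").write_text(json.dumps(payload, indent=2))

    def _stage_predict_targets(self) -> None:
        c = self.config
        hubs = (self.out / "hubs_final.txt").read_text().split()
        emb = self._cache.get("emb")
        if emb is None:
            emb = kg_embed.train(self._net(), c.train_model, c.train_config())
        rows = evaluation.predict_targets(
            hubs, emb, self._net(), top_n=c.predict_top_n
        )
        pd.DataFrame(rows, columns=["hub", "target", "score"]).to_csv(
            self.out / "predicted_targets.tsv", sep="\t", index=False
        )


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full strategy; returns the manifest dict."""
    return PipelineRun(config, out_dir).run()


# -- experiment harnesses --------------------------------------------------


def compare_models(
    net: mtp_core.MTPNetwork,
    models: list[str],
    config: kg_embed.TrainConfig | None = None,
    relations: tuple[str, ...] = ("MT", "TT", "TP"),
    folds: int = 10,
) -> pd.DataFrame:
    """Cross-validated link prediction for each model × relation.

    Returns a long-format table with mean and sd per metric and a
    ``best`` flag marking, per (relation, metric), the winning model
    (max for Hits/MRR, min for MR).
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    rows = []
    for model in models:
        for relation in relations:
            report = evaluation.crossval_link_prediction(
                net, relation, model, config=config, folds=folds
            )
            for metric in report.metric_names:
                rows.append(
                    {
                        "model": model,
                        "relation": relation,
                        "metric": metric,
                        "mean": report.mean(metric),
                        "sd": report.sd(metric),
                    }
                )
    df = pd.DataFrame(rows)
    df["best"] = False
    for (relation, metric), group in df.groupby(["relation", "metric"]):
        idx = group["mean"].idxmin() if metric == "mr" else group["mean"].idxmax()
        df.loc[idx, "best"] = True
    return df


DEFAULT_SWEEP_GRID = {
    "dim": [32, 64, 96, 128],
    "epochs": [25, 50, 100, 200],
    "lr": [0.0001, 0.001, 0.01, 0.1],
}


def sweep_parameters(
    net: mtp_core.MTPNetwork,
    model: str = "rotate",
    base: kg_embed.TrainConfig | None = None,
    grid: dict[str, list] | None = None,
    relation: str = "MT",
    folds: int = 10,
) -> pd.DataFrame:
    """One-at-a-time parameter sweep around a base configuration.

    Each axis varies one of dim/epochs/lr while the others stay at the base
    value (no full cross-product); the base cell is computed once and reused
    on every axis. Flags the best cell per axis by MRR.
    """
    base = base or kg_embed.TrainConfig()
    grid = grid or DEFAULT_SWEEP_GRID
    if not grid:
        raise ValueError("empty sweep grid")
    cache: dict[tuple, evaluation.EvalReport] = {}

    def run_cell(dim, epochs, lr):
        key = (dim, epochs, lr)
        if key not in cache:
            cfg = kg_embed.TrainConfig(
                dim=dim,
                lr=lr,
                epochs=epochs,
                negatives=base.negatives,
                alpha=base.alpha,
                gamma=base.gamma,
                batch_size=base.batch_size,
                seed=base.seed,
            )
            cache[key] = evaluation.crossval_link_prediction(
                net, relation, model, config=cfg, folds=folds
            )
        return cache[key]

    rows = []
    for axis, values in grid.items():
        for value in values:
            cell = {"dim": base.dim, "epochs": base.epochs, "lr": base.lr}
            cell[axis] = value
            report = run_cell(cell["dim"], cell["epochs"], cell["lr"])
            rows.append(
                {
                    "axis": axis,
                    "value": value,
                    **cell,
                    "mr_mean": report.mean("mr"),
                    "mr_sd": report.sd("mr"),
                    "mrr_mean": report.mean("mrr"),
                    "mrr_sd": report.sd("mrr"),
                    "hits@5_mean": report.mean("hits@5"),
                }
            )
    df = pd.DataFrame(rows)
    df["best"] = False
    for axis, group in df.groupby("axis"):
        df.loc[group["mrr_mean"].idxmax(), "best"] = True
    return df
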