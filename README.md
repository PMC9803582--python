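# mtpnet

Hub-miRNA discovery and knowledge-graph modelling of miRNA–target–pathway
regulatory networks.

## The problem

MicroRNAs (miRNAs) post-transcriptionally repress target genes and thereby
shape entire pathways; in complex diseases a handful of *hub* miRNAs often
carry a disproportionate share of the regulatory burden and are natural
biomarker and drug-target candidates. `mtpnet` implements a two-part
strategy for finding and exploiting such hubs in a heterogeneous
**MTP network** — miRNA (M), target-gene (T) and pathway (P) nodes joined by
regulation (M–T), protein–protein interaction (T–T) and pathway-membership
(T–P) edges:

1. **Network analysis.** Hub miRNAs are identified twice, by two
   independent lines of evidence, and the results intersected:
   * a compact **WGCNA** core — signed adjacency
     `a_ij = ((1 + cor(x_i, x_j))/2)^β`, soft threshold β chosen by
     scale-free topology fit (signed R² ≥ 0.9), topological overlap matrix,
     average-linkage module detection with eigengene merging, and top-10
     intramodular-connectivity hubs per module;
   * **SimCluster** — pairwise Jaccard similarity of miRNAs' target sets
     (first order) or pathway sets (second order), a similarity threshold τ
     chosen so that the thresholded graph is scale-free (both |Cor| and R²
     of the lg(pK) ~ lg(K) regression above 0.9), modularity-based community
     detection (fast greedy, Louvain, label propagation, leading
     eigenvector; best Newman–Girvan Q wins), and per-module max-degree
     hubs with ties included.
2. **Network modelling.** The MTP triple store (h, r, t) is embedded with
   **RotatE** (relations as rotations in ℂ^d, distance
   `d_r(h,t) = Σ_i |h_i ∘ r_i − t_i|`), TransE, DistMult or a two-layer
   **RGCN**, trained with the self-adversarial negative-sampling loss
   `L = −log σ(γ − d(h,t)) − Σ_j p_j log σ(d(h'_j,t'_j) − γ)`.
   Link prediction is scored by ten-fold cross-validated Hits@k, MR and
   MRR under the filtered, type-constrained ranking protocol; multilabel
   node classification (21 tissue labels for targets, 5 category labels for
   pathways) uses a two-layer MLP on the embeddings with a per-node
   label-matching accuracy.

Database-derived inputs are replaced by a first-class synthetic generator
with planted ground truth (correlated expression modules, shifted-mean
biomarkers, miRNA communities defined by overlapping target pools), so
every stage is testable offline.

## Worked example

```python
import mtpnet as m

# synthetic MTP network: 100 miRNAs in 4 planted communities
net, t_labels, p_labels, truth = m.simulate_mtp(
    n_communities=4, pool_size=25, p_in=0.8, p_out=0.02, seed=0)

# SimCluster: similarity -> scale-free threshold -> clustering -> hubs
sim = m.similarity_matrix(net, order=1)
sim = m.select_threshold(sim, on_fail="best")
best, _ = m.cluster_graph(sim.graph, seed=0)
hubs = m.module_hubs(best, sim.graph)
print(f"tau={sim.tau:.2f} Q={best.modularity:.3f} hubs={sorted(hubs)}")

# ten-fold RotatE link prediction vs. the analytic random baseline
rep = m.crossval_link_prediction(
    net, "MT", "rotate", m.TrainConfig(dim=64, lr=0.001, epochs=50, seed=0))
print(f"MRR {rep.mean('mrr'):.4f} ± {rep.sd('mrr'):.4f} "
      f"(random baseline {m.random_baseline_mrr(net, 'MT'):.4f})")
```

Output:

```
tau=0.10 Q=0.743 hubs=['m018', 'm023', 'm045', 'm060']
MRR 0.4182 ± 0.0269 (random baseline 0.0519)
```

Clustering the thresholded similarity graph yields exactly one hub per
planted community (`m060`, `m045`, `m018`, `m023` sit in communities 0–3),
and cross-validated RotatE ranks held-out regulations roughly eight times
better than chance on this strongly structured network.

The same flow is available from the shell:

```bash
mtpnet pipeline --seed 1 --out runs/demo          # simulate -> ... -> predict
mtpnet kg-eval --triples runs/demo/triples.tsv --relation MT --out mt.json
```

## Layout

| module | contents |
| --- | --- |
| `mtpnet.mtp_core` | typed triple store, expression/label containers, I/O, DE screening filter |
| `mtpnet.synthetic` | planted-truth generators, hold-out splits, shuffled nulls |
| `mtpnet.wgcna` | signed adjacency, β scan, TOM, module detection, hub ranking |
| `mtpnet.simcluster` | Jaccard similarity, scale-free thresholding, clustering, hub extraction |
| `mtpnet.kg_embed` | RotatE / TransE / DistMult / RGCN with self-adversarial training (NumPy) |
| `mtpnet.evaluation` | filtered ranking, Hits@k/MR/MRR, CV harnesses, MLP, AUC/AUPR, TopK |
| `mtpnet.pipeline` | config-driven end-to-end runs, model comparison, parameter sweeps |
| `mtpnet.cli` | `mtpnet` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
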