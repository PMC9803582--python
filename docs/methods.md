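# Methods

## Scope and model

`mtpnet` studies a heterogeneous miRNA–target–pathway (MTP) network: a
typed triple store with node classes M (miRNA), T (target gene) and
P (pathway) and relations MT (regulation, directed M→T), TT
(protein–protein interaction, undirected, stored with head ≤ tail) and TP
(pathway membership, directed T→P). Node types are disjoint by
construction — reusing an identifier across classes is a validation error,
not a silent duplication.

Two questions are asked of this network. *Which miRNAs are hubs?* —
answered by intersecting a co-expression analysis (correlation evidence)
with a similarity-network analysis (shared-mechanism evidence). *Can the
network's missing links and node labels be predicted?* — answered by
knowledge-graph embedding models with standard ranking metrics.

## Hub discovery

### Co-expression side (WGCNA core)

Signed weighted adjacency `a_ij = ((1 + cor_ij)/2)^β` with Pearson
correlation; anticorrelated pairs receive weight ≈ 0 rather than being
folded into the same module. The soft threshold β is scored by the
scale-free topology fit: connectivities are binned into ≤ 10 equal-width
bins, log10(frequency) is regressed on log10(mean connectivity), and the
signed R² (R² × −sign(slope)) must reach 0.9; the smallest qualifying β
wins, otherwise the maximiser is used with a warning. On block-structured
synthetic data no β looks scale-free (four equal modules are the opposite
of a degree hierarchy), so the pipeline default is the conventional signed
network choice β = 18, which gives within/between-module adjacency
contrast of about 0.15 vs 4e−6 at ρ = 0.8 and recovers planted modules
essentially perfectly.

The topological overlap matrix
`TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` is clustered with
average linkage on `1 − TOM`. Modules come from a **static height cut**
(default 0.99) rather than the dynamic hybrid tree cut of the reference R
implementation — a deliberate simplification with one interpretable
parameter; clusters below `min_module_size` (default 5) stay unassigned.
Modules whose eigengenes (first principal-component score of the
standardized module submatrix) correlate above 0.75 are merged iteratively,
the usual "merge at dissimilarity 0.25" convention. Hubs are the top 10
features per module by intramodular connectivity (sum of adjacency to
co-members), ties broken lexicographically.

Note the cut height interacts with β: at small β the adjacency is
uniformly high, all dissimilarities fall below 0.99 and everything merges
into one module. The default pair (β = 18, cut 0.99) is calibrated to the
signed-network convention, not tuned per dataset.

### Similarity side (SimCluster)

First-order similarity is the Jaccard index of two miRNAs' target sets;
second-order similarity is the Jaccard index of their pathway sets, where
a miRNA's pathway set is the two-hop union M→T→P (no per-miRNA enrichment
step is defined, so membership of any target's pathway counts). Two empty
sets have similarity 0 by convention — an isolated miRNA is not "similar"
to every other isolated miRNA.

The similarity threshold τ is selected by a scale-free criterion on the
thresholded graph (edges where similarity ≥ τ; a `strict_gt` flag flips the
boundary): for each τ on the grid 0.05…0.95, isolated nodes are dropped
and lg(pK) is regressed on lg(K) over distinct degrees ≥ 1. A τ qualifies
when |Pearson Cor| ≥ 0.9, R² ≥ 0.9 **and** the slope is negative (degree
frequencies must decay; the absolute-correlation + negative-slope reading
resolves the sign ambiguity of a plotted correlation). Fits with fewer
than three distinct degree values are flagged unreliable and never
qualify, since a two-point regression is always exact. The smallest
qualifying τ is chosen. When no τ qualifies the function raises by
default; `on_fail="best"` keeps the best reliable decaying row instead
(largest min(|Cor|, R²)) with a warning — planted-block similarity
networks are genuinely not scale-free, and downstream clustering should
still be possible on them.

Community detection runs four algorithms (fast greedy, Louvain/multilevel,
label propagation, leading eigenvector — fast greedy is always included;
the quartet is a choice) via igraph; the partition with the largest
Newman–Girvan modularity `Q = Σ_c (e_c/m − (d_c/2m)²)` wins, with Q always
recomputed from the definition rather than trusted from the backend. An
algorithm that fails numerically (e.g. ARPACK non-convergence in leading
eigenvector) is skipped with a warning. Per module, **every** node
attaining the maximum graph-wide degree among the module's members is a
hub — degree is counted over the whole thresholded graph, not within the
module, and ties are all retained.

The final hub set is the intersection of the WGCNA and SimCluster hub
sets; an empty intersection yields a warning (the pipeline then falls back
to the SimCluster hubs so downstream stages still run).

## Knowledge-graph models

All four models and their training loop are implemented in NumPy with
analytic gradients (verified against central finite differences in the
test suite) and an Adam optimizer; the graphs here are hundreds of nodes,
where this is fast, exactly reproducible per seed, and dependency-free.

* **RotatE** — entities are complex d-vectors; each relation is a phase
  vector θ, applied as the unit-modulus rotation `r = e^{iθ}` (unit modulus
  is therefore exact by parameterization, not a constraint to monitor).
  Distance is the L1 composition of complex moduli
  `d_r(h,t) = Σ_i |h_i r_i − t_i|`; score = γ − d.
* **TransE** — `d = ‖h + r − t‖₁`, score = γ − d.
* **DistMult** — diagonal bilinear score `f = Σ_i h_i r_i t_i`.
* **RGCN** — two relational graph-convolution layers
  `h_i' = σ(Σ_r Σ_{j∈N_i^r} (1/|N_i^r|) W_r h_j + W_0 h_i)` with ReLU
  between layers and identity at the output; message relations are MT, TP,
  their inverses, and symmetric TT, so information flows both ways. No
  basis decomposition (only five message relations). Triples are scored by
  a per-relation diagonal bilinear decoder on the final embeddings.

Training minimizes the self-adversarial loss
`L = −log σ(γ − d) − Σ_j p_j log σ(d'_j − γ)` with
`p_j = softmax_j(α (γ − d'_j))` treated as constants (no gradient through
the weights); DistMult and RGCN substitute their score f for γ − d.
Negatives corrupt head or tail with equal probability, drawing uniformly
from the **type-consistent** class for the slot; corruptions equal to a
known triple are resampled up to a bounded retry, then kept with a
warning. Type-constrained pools are the only reading consistent with
mean ranks of order 10 on candidate sets of order 10².

Defaults: d = 64, learning rate 0.001, 50 epochs (the benchmark
configuration), margin γ = 6, temperature α = 1, 16 negatives per
positive, batch 512, all exposed in `TrainConfig` and logged. Entity
embeddings initialize uniformly in ±(γ+2)/d for the distance models — the
scale must be commensurate with the margin, otherwise initial distances
(~50 at ±6/√d) saturate the logistic loss and learning stalls at the
random baseline — and in ±6/√d for DistMult/RGCN, whose scores have no
margin; RotatE phases initialize uniformly in [0, 2π).

## Evaluation protocol

For each test triple both directions are ranked: fix (r, t) and score
every type-consistent head candidate, fix (h, r) and score every tail
candidate. Under the default **filtered** protocol, candidates forming
another known-true triple (train ∪ test) are removed; a `--raw` flag
disables this. Ties receive the mean rank `1 + #better + #ties/2`, which
removes the optimistic bias of counting a tied score as a win. Hits@k, MR
and MRR pool both directions. Ten-fold cross-validation partitions one
relation's triples (seeded); each fold trains on everything else and ranks
the held-out triples; reports carry per-fold values and mean ± sd. The
analytic random-ranking baseline `E[1/rank] = H(n)/n` per direction makes
"better than chance" a closed-form comparison rather than an empirical
one.

Multilabel classification is transductive by design: embeddings are
trained once on the full graph and only labels are held out across folds
(test nodes are visible as graph nodes during embedding — a caveat
recorded in each report). The classifier is a two-layer MLP
(d → 64 → #labels) with sigmoid outputs, binary cross-entropy and Adam;
predictions threshold at 0.5, with the boundary counted as positive.
Accuracy binarizes labels with I(label > 0), scores each node by its
fraction of matching label bits and averages over nodes.

Biomarker potential of a single miRNA is its case-vs-control AUC (rank
statistic, half credit for ties) and AUPR (step-integrated
precision–recall), computed by scikit-learn with the expression value as
the score and cases positive. **No orientation flipping**: a
down-regulated biomarker scores below 0.5 by design, matching how a raw
single-feature screen behaves. TopK validation is the mean over hubs of
|top-k predictions ∩ oracle|/k.

## Synthetic study conditions

`simulate_expression` builds log2-scale profiles: module members load on a
shared latent factor (`√ρ·factor + √(1−ρ)·noise`, so ρ is the expected
within-module correlation) and biomarkers get +effect added to case-sample
means, making the expected log2 fold change equal the effect size. With
effect 2 and unit noise, the single-feature AUC has the closed form
Φ(2/√2) ≈ 0.92. Defaults (modules ρ = 0.8, effect 2) are chosen as a
realistic strong-signal array study; group sizes default to the small
plasma-pool scale (6 vs 7) with larger sizes used where a property needs
statistical headroom.

`simulate_mtp` plants miRNA communities as disjoint target pools: a miRNA
hits its own pool with probability p_in and everything else with p_out, so
p_out = 0 gives exactly zero cross-community Jaccard similarity and
p_in = 1 gives identical within-community target sets. One miRNA per
community covers its entire pool (the planted hub, the ground truth for
max-degree hub extraction). TT edges follow a stochastic block model over
target pools — not over miRNA communities — so T–T prediction has
learnable structure of its own; targets beyond the pools form a background
block. Pathways attach to one community's pool preferentially; their
category (community mod 5) drives the 5 pathway labels, and each target
block switches on 5 of the 21 tissue labels (0.8 vs 0.1 firing
probability), so node labels are predictable from network position.
Default sizes (100 M, 100 T, 20 P, ~1–2 × 10³ edges) are one to two orders
below a database-derived disease network, keeping a full training run in
the seconds range on one CPU.

What the generator does **not** emulate: array-platform noise and probe
effects, the heavy-tailed degree distributions of real interaction
databases, literature-biased target annotation, or correlated label noise.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted structure, not performance on any real disease
dataset.

`shuffle_relation` provides the negative control: one relation's edges are
redrawn uniformly at random (type-respecting, duplicate-free), so any
cross-validated skill on the shuffled relation would indicate leakage;
the expectation is the analytic random baseline.

## Numerical choices and degenerate inputs

* TOM denominators ≤ 0 (isolated pairs) yield overlap 0; the matrix is
  symmetrized and clipped to [0, 1].
* Constant expression features make Pearson correlation undefined; the
  offending feature is named in the error rather than propagating NaNs.
* Jaccard of two empty sets is 0 (logged convention).
* Ranking tie handling is the mean rank; `hold_out` samples
  `round(fraction·n)` triples.
* Cluster-algorithm ties on Q resolve to the earlier algorithm in the
  list; hub-degree ties are all retained.
* Stage seeds derive from the master seed by hashing the stage name, so
  adding a stage never shifts another stage's randomness.

## Limitations

* The static height cut is coarser than dynamic tree cutting on modules of
  heterogeneous density.
* Exact reproduction of published benchmark tables from database-derived
  networks is out of reach without those networks and the unstated margin,
  temperature and batch hyperparameters; the harness fixes d = 64,
  lr = 0.001, 50 epochs and treats the rest as explicit configuration.
* KG2E and CompGCN comparators are not implemented.
* Multilabel CV inherits the transductive caveat above; reported accuracy
  is not an inductive generalization estimate.
* Training complexity is O(triples × negatives × d) per epoch in dense
  NumPy; beyond ~10⁵ triples a minibatched GPU implementation would be the
  right tool.
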