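# patientnets

Patient-specific signaling models and network-based stratification of
multi-omic cancer cohorts.

## The problem

Cohort-scale proteogenomics (transcriptomics, proteomics, phosphoproteomics
per patient) describes *what* is abundant, but prognosis tracks *which
signaling pathways are rewired*.  `patientnets` turns per-patient omic
matrices into mechanistic, signed causal network models, stratifies the
cohort by the network modules patients share, and distills each patient
subgroup into a transcriptomic biomarker signature that can classify new
patients from expression data alone.  It is aimed at computational biologists
working with CPTAC/TCGA-style cohorts or any multi-omic disease cohort with a
signed causal prior network.

## The workflow

1. **Harmonize** (`patientnets.harmonize`) — filter analytes with > 80%
   missing values, impute (phospho)proteomic gaps (seeded single imputation),
   and compute sample-wise z-scores centered on the median of each patient's
   distribution; |z| > 1.96 flags significantly modulated analytes.
   Phosphosites are standardized to `gene|accession|residue|position` with a
   15-mer sequence window centered on the phosphorylated residue.
2. **Infer activities** (`patientnets.activity`) — footprint scores for
   transcription factors (regulon size ≥ 10) and kinases/phosphatases
   (≥ 5): a signed weighted mean of target z-scores with a permutation null
   and optional hypergeometric correction; PhosphoScore for proteins with
   regulatory phosphosites; GOF/LOF mutations override scores at ±2.
3. **Build models** (`patientnets.network`) — contextualize a signed
   prior-knowledge network into each patient's mechanistic model by
   minimizing `Σ |final_score(v)|·1[σ(v) ≠ μ(v)] + β·|used edges|` subject to
   sign consistency and acyclicity (exact enumeration ≤ 15 nodes; a
   multi-start local-search solver beyond), then score hallmark phenotypes by
   path proximity against a state-shuffling null.
4. **Stratify** (`patientnets.communities`) — project the model collection
   to a patient–interaction bipartite graph (edges leaving inhibited nodes
   excluded), filter interaction nodes by patient frequency (t_L < d(j) <
   t_U), and maximize Barber's bipartite modularity

   Q_b = (1/m) Σ_{i∈P} Σ_{j∈I} [A_ij − γ·k_i·k_j/m] δ(c_i, c_j)

   with a seeded Louvain scheme.
5. **Signatures** (`patientnets.signatures`) — per gene, one-way ANOVA
   across communities (BH over genes, adj p < 0.01) plus a positive
   Tukey–Kramer contrast of the community against the background; at most 50
   genes per community ordered by expression difference.  New patients are
   assigned by preranked enrichment (weighted running sum, gene-permutation
   null, BH over signatures).
6. **Validate** (`patientnets.validation`, `patientnets.robustness`) —
   Kaplan–Meier/log-rank survival, Fisher association, cosine similarity of
   subtype compositions; 70/30 cross-validation of signatures and gene-wise
   expression shuffling studies.

A seeded generator (`patientnets.synthetic`) produces cohorts with planted
community modules, signature genes, and survival hazards so the entire
pipeline is testable offline.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from patientnets.communities import (FilterParams, aggregate_networks,
                                     build_bipartite, filter_interaction_nodes,
                                     louvain_bipartite)
from patientnets.signatures import extract_signatures
from patientnets.synthetic import generate_cohort

expr, nets, truth = generate_cohort(seed=7)     # 40 patients, 4 planted groups
b = build_bipartite(aggregate_networks(nets), patients=sorted(nets))
fb = filter_interaction_nodes(b, FilterParams(2, 21, "exclusive"))
part = louvain_bipartite(fb, gamma=1.0, seed=0)
ari = adjusted_rand_score([truth.membership[p] for p in fb.patients],
                          [part.labels[p] for p in fb.patients])
print(f"Q_b = {part.Q_b:.3f}, communities = {len(set(part.labels.values()))}, ARI = {ari:.2f}")
sigs = extract_signatures(expr, {p: part.labels[p] for p in fb.patients})
print([len(s) for s in sigs])
```

prints

```
Q_b = 0.680, communities = 4, ARI = 1.00
[20, 20, 18, 18]
```

i.e., the Louvain partition of the filtered bipartite graph scores a
bipartite modularity of 0.680, recovers the four planted patient groups
exactly (adjusted Rand index 1.0), and each group yields a signature of
18–20 up-regulated genes.

The same steps are available from the shell via the `ppf` CLI
(`ppf simulate`, `ppf harmonize`, `ppf communities`, `ppf signatures`,
`ppf validate`, `ppf robustness`).

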