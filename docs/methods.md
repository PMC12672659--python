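# Methods

This note documents the models, defaults, and design choices behind
`patientnets`, and what the synthetic benchmark does and does not show.

## Harmonization

Sample-wise z-scores — `z = (x − median(x_sample)) / sd(x_sample)` with the
sample standard deviation (n−1 denominator) — stand in for fold changes when
cohorts lack replicates and matched normals.  The median center is the
default because it is robust to the heavy tails of abundance data; mean
centering and analyte-wise (row) scoring are available.  |z| > 1.96 (strictly)
calls an analyte significantly modulated; 1.96 is the two-sided 5% normal
quantile.  Missing-value handling is asymmetric by design: transcripts with
more than 80% missing samples (strict) are dropped and remaining gaps set to
0 (an absent transcript), whereas (phospho)proteomic gaps are imputed.
Imputation is a *seeded single imputation* with three interchangeable
engines — a normal model fit to each analyte's observed values, a
predictive-mean-matching-like nearest-donor draw, and the row mean.  The
contract the pipeline relies on (observed entries untouched, bit-identical
results per seed) is engine-independent; multiple-imputation pooling is
deliberately out of scope.

Phosphosite identities are standardized as
`gene|accession|residue|position` with a 15-mer sequence window (flank 7,
`_`-padded at termini).  Sites with ambiguous residues (e.g., "S/T") are
dropped; duplicate (accession, residue, position) entries keep the longest
peptide and then the lowest multiplicity; a residue letter that contradicts
the supplied sequence is re-anchored to the nearest match within ±5 positions
(ties to the left) or dropped with a count in the report.

One knowingly naive choice: the zeros substituted for missing transcripts are
included in the per-sample median and standard deviation.  With sparse
transcriptomes this shrinks the center toward zero; callers who prefer
otherwise can filter before z-scoring.

## Activity inference

Footprint scoring estimates a regulator's activity from its targets rather
than its own abundance: `score = Σ_t mode_t·w_t·z_t / Σ_t w_t` over regulon
targets present in the profile.  Minimum regulon sizes are 10 for TFs and 5
for kinases/phosphatases — smaller regulons give unstable means.  The
p-value comes from a seeded permutation null (target z-values resampled from
the full profile); the optional hypergeometric correction tests whether
modulated targets (|z| > 1.96) are enriched in the regulon and is combined
with the permutation p by Fisher's method, damping the regulon-size
dependence of the weighted mean.  This engine is intentionally simple and
pluggable — the downstream pipeline only consumes (regulator, score, p).

PhosphoScore is the mean of `role·z` over a protein's regulatory
phosphosites, defaulting to activity-affecting sites only so the scale
matches footprint activities.  When both streams exist the final score is
their unweighted mean with a discordance flag when the signs differ.
Annotated mutations override scores at ±K with K = 2.0: deliberately beyond
the 1.96 modulation threshold so an override always counts as decisive
evidence; K is configurable.  An optional multiplicative down-weight
`1 − |z_prot|/max|z|` is provided for phosphosites co-modulated with their
protein's abundance.

## Mechanistic models

The prior-knowledge network (PKN) is a set of signed, directed causal edges
(SIGNOR-like TSV dialect); preprocessing can drop entities not measured in
any omic layer and restrict to direct interactions (indirect transcriptional
edges are kept by default in cohort use, where TF mutations matter).

The naive network is the union of all directed paths from source nodes
(e.g., mutated genes) to measured nodes within per-layer step budgets
(default 2 layers, budgets (1, 4)); an edge is on an admissible path iff
`dist_from_sources(u) + 1 + dist_to_targets(v) ≤ L`, which makes the
construction monotone in the budgets.  `connect_all` adds shortest paths
among retained intermediates.

Contextualization assigns states σ ∈ {+1, −1} (or absence) minimizing

    Σ_{v measured} |final_score(v)| · 1[σ(v) ≠ μ(v)]  +  β · |U|

subject to: every active non-source node has ≥ 1 used incoming edge with
`σ(u)·sign(u,v) = σ(v)`, and the used-edge graph is acyclic.  β defaults to
0.1 — small enough that explaining any measured node (weights ≥ 0.5 in
practice) is worth several edges, large enough to prune gratuitous edges.
The *exact* solver enumerates σ over the free nodes (≤ 15) with a
support-propagation projection that zeroes unexplainable nodes; because
support spreads outward from roots, picking one supporting parent per node
yields an acyclic used set, so enumeration over σ alone is complete.  The
*greedy* solver is a seeded multi-start local search: constructive starts
route each measured node to a consistent root by min-cost paths in the
sign-expanded graph (states (node, sign); cost β per edge plus the mismatch
weight of any contradicted measurement, recomputed after each committed
path), followed by single-node moves and a two-node polish.  In inverse mode
every in-degree-0 node is a free root (unspecified upstream driver); vanilla
mode fixes user-supplied source states.

Phenotype activation: for each phenotype with annotated proximity paths
(path table: protein, phenotype, path sign, length), the regulators are model
nodes with a path of length ≤ 3; the phenoscore is the mean (or median) of
`σ(n)·path_sign`; the null shuffles σ across model nodes 1000 times, and a
phenotype is significant at p < 0.05 with |z| ≥ 1.96.  `remove_cascade`
drops a regulator whenever another regulator of the same phenotype lies
downstream of it in the model, so a linear cascade is counted once at its
most downstream member — one reading of "collapsing" cascade paths, and
documented as such.

## Stratification

Aggregation keeps, per patient, only interactions leaving an *active*
(σ = +1) source node: regulation exerted by an inhibited protein is not a
functional driver.  The interaction identity is (source, sign, target) —
phospho-residues are ignored so the same regulation observed via different
sites aggregates — and the target's state is carried as a per-patient
attribute for the ambiguity analysis.

Interaction-node degree filtering removes rare (d ≤ t_L) and ubiquitous
(d ≥ t_U) interactions before clustering (exclusive bounds by default, so
t_L = 1 removes exactly the singletons; inclusive bounds available).
Defaults t_L = 4 and t_U = 30 are exposed alongside the cohort-size rule of
thumb (t_U ≈ half the cohort); `select_lower_threshold` scans candidates and
keeps the smallest with Q_b > 0.3, a conventional floor for meaningful
modular structure.

Louvain on Barber's bipartite modularity: local moves use the exact gain of
moving a (super-)node between communities under
`Q_b = (1/m) Σ_c [W_c − γ·KP_c·KI_c/m]`, where W_c is the within-community
patient–interaction edge weight and KP/KI the community's patient/interaction
degree sums; aggregation merges communities into super-nodes carrying both
degree kinds.  Nodes are visited in a seeded order; ties prefer the lowest
community id, except that an isolated node joins a neighboring community on
an exact tie (so a lone patient–interaction pair forms one community rather
than two, the sensible degenerate limit).  The optimizer runs a small number
of internally-derived restarts (default 5) and keeps the best partition —
still deterministic per seed; on all small fixtures this reaches the
exhaustive-search optimum.  γ scans a grid (default 0.6–1.4 by 0.1), keeping
the resolution whose partition maximizes modularity.

A community's ambiguity fraction is the share of genes in its interaction
subgraph that appear in both activity states across member models — a
noise/heterogeneity diagnostic, low on clean synthetic data.

## Signatures and assignment

Per gene, a one-way ANOVA across community labels with BH adjustment *over
genes* (padj < 0.01); per community, genes additionally need a positive and
significant Tukey–Kramer contrast of the community against the pooled
background (error variance and degrees of freedom from the full k-group
ANOVA; the q statistic referred to the studentized range with k groups, so
Tukey's family-wise calibration is retained — the contrast structure is a
design choice here), mean expression in the community > 0 (signatures are
positive), and an expression difference above a configurable floor
(default 0).  The top 50 genes by difference form the signature.  The
studentized-range survival function is evaluated only for genes passing the
cheap filters; ANOVA and BH are vectorized across genes — this is what keeps
the resampling studies tractable.

Assignment of a patient ranks its genes by z descending and computes, per
signature, a weighted Kolmogorov–Smirnov running sum (hit weight |z|^1); the
null permutes gene labels (seeded), the p-value is sign-matched, NES is the
ES over the mean same-sign null magnitude, and BH runs across signatures.
Only positively enriched signatures with adjusted p < 0.05 are assignable;
ties break by adjusted p, then |NES|, then id.  Note the permutation floor:
with n permutations the smallest attainable p is ≈ 1/(n+1), so n must
comfortably exceed `n_signatures / 0.05` for any assignment to survive BH —
the default is 1000 (200 in the resampling studies, enough for ≤ 7
signatures).

## Validation and robustness

Survival uses the Kaplan–Meier estimator and the multi-group Mantel–Haenszel
log-rank test (via lifelines); an optional horizon (60 months for five-year
analyses) recodes later events as censored at the horizon.  Fisher's exact
test (two-sided, hypergeometric) quantifies association between
stratifications and covariates; the reported odds ratio is the sample OR,
with 0.5 continuity only when a zero cell would make it undefined.  Cosine
similarity compares subtype-proportion vectors across cohorts
(scale-invariant, in [0, 1]).

Cross-validation stratifies each community (≥ 4 members) into 70/30 splits
(training size ⌈0.7·n⌉), 50 runs by default: signatures are re-derived from
training patients and test patients re-assigned against *all* signatures
(the harsher convention, matching the false-positive definition).  TP = test
patient assigned to its original community, FP = assigned elsewhere,
FN = unassigned; gene recovery is the percent of the full-data signature
recovered from the training split.

The randomization study shuffles ⌈frac·n_genes⌉ rows independently across
samples (gene-wise distributions preserved, sample structure destroyed) over
the seven-fraction grid (5–100%), re-extracts signatures, and tracks overlap
with the originals, the number of non-empty control signatures, and (when
survival data is supplied) the BH-adjusted log-rank p of the re-assigned
groups at the 60-month horizon.

## Synthetic cohorts

`generate_cohort` plants k disjoint interaction modules (one per community)
drawn from a generated PKN and gives each member the module edges with
probability 1 − dropout plus background interactions with probability equal
to the dropout rate (a single noise knob; separable for power studies).
Module edges have active sources and targets, so they survive aggregation;
background edges get random states.  Expression is N(0, noise_sd) z-like
values with each community's signature genes shifted by +effect in members.
Defaults — 40 patients, 4 communities, 300 genes, 30-interaction modules,
20-gene signatures, effect 2, noise sd 1, dropout 0.05 — are the benchmark
conditions used throughout the tests; 300 genes is the scale of a
variable-gene panel, chosen so the ANOVA screen at padj 0.01 operates in its
intended power regime.  Survival times are exponential with per-community
hazard multipliers and independent exponential censoring.

What the synthetic benchmark does **not** emulate: correlated gene modules,
heavy-tailed abundance distributions, structured (abundance-dependent)
phosphoproteome missingness, overlapping community modules, or batch
effects.  Passing the planted-structure tests shows the machinery is correct
and calibrated, not that real cohorts will separate this cleanly.

## Numerical conventions

Strict inequalities at every threshold (missing fraction, |z|, degree
bounds in exclusive mode); sample sd (n−1) everywhere; permutation p-values
use the add-one estimator (1 + #extreme)/(n + 1); zero-variance nulls are
reported non-significant rather than raising; BH is the step-up procedure
with monotonicity enforced.  All stochastic components take explicit seeds
and are reproducible bit-for-bit.

## Benchmark problem sizes

The test suite and acceptance script run the planted-block model at
60 patients × 300 interactions, the end-to-end cohort at the generator
defaults, cross-validation at 10 runs, the randomization grid at 10–20 runs
per fraction, and survival calibration at 60–100 replicate cohorts — sizes
chosen to make the statistical assertions stable while keeping a full run in
minutes on one CPU.
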