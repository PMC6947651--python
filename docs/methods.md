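# Methods

## Model and procedure

### Weighted-split CART forests

Trees are grown by binary recursive partitioning on a bootstrap sample of
size m drawn with replacement (no sample weighting). At each node, `mtry`
distinct candidate features are sampled with probability proportional to a
nonnegative weight vector; sampling uses exponential-race keys
(key_j = Exp(1)/w_j, keep the `mtry` smallest), which is distributionally
identical to sequential weighted draws without replacement with
renormalization but costs O(p) per node. Zero-weight features receive an
infinite key and can never be selected, so they provably never split a
node.

Candidate thresholds are the midpoints between consecutive distinct sorted
values of a candidate feature within the node. The impurity decrease is

* regression: SS(parent) − SS(left) − SS(right), raw sums of squared
  deviations (not variance × n);
* classification: Gini(parent) − (n_l/n)·Gini(left) − (n_r/n)·Gini(right),
  the child-fraction-weighted form.

The two conventions are on different scales (the regression form grows
with node size, the classification form does not); each is pinned by the
package's test oracles, and importance vectors are only ever compared
within one task.

A node is eligible for splitting when it holds at least
max(2, 2·`min_node_size`) samples and its target is not pure; there is no
separate minimum-child-size constraint on individual thresholds, and no
depth cap — trees grow to purity or node-size exhaustion. If no candidate
threshold yields a positive decrease the node becomes a leaf (mean /
majority-class prediction). Ties in impurity decrease break toward the
lowest feature index, then the lowest threshold, with a relative tolerance
of 1e-9: exactly tied splits (two features inducing the same sample
partition) would otherwise be ordered by floating-point summation noise.

Impurity importance of feature f = Σ over all internal nodes split on f,
over all trees, of the node's decrease, divided by the number of trees.

### Determinism and parallelism

The seed of tree t is derived from (master seed, t) through a
`numpy.random.SeedSequence` with a stream tag, and each tree runs a
private splitmix64 generator seeded from it — never global RNG state. The
forest is therefore a pure function of (data, weights, parameters, master
seed), and chunking trees over worker threads (the numba kernels release
the GIL) cannot change any result; aggregation is concatenation in tree
order. Iteration seeds and leave-one-out target seeds use separate stream
tags of the same master seed.

### Iterative reweighting (iRF)

Iteration 1 uses uniform weights; iteration k > 1 uses the previous
iteration's importance divided by its sum, with no floor, so zero is
absorbing and the active feature set shrinks monotonically. An all-zero
importance vector (possible on pure-noise data grown to leaves) falls back
to uniform weights with a warning rather than aborting the run. When a
weights path is configured, weights are written after each iteration as a
two-column (feature_id, weight) TSV at full `repr` precision and re-read
(round-trip parsing) before the next iteration, so the file-mediated run
is value-identical to the in-memory run.

### Tree-count heuristic

`recommend_tree_count(p, mtry, coverage)` answers: how many trees T give
each feature a `coverage` chance of appearing among the candidates in the
first two layers (3 decision nodes) of at least one tree? The number of
times a feature is drawn across 3T candidate sets is modeled as Poisson
with rate 3T·mtry/p, giving T = ⌈−ln(1 − coverage)·p/(3·mtry)⌉; when
mtry = p inclusion at the root is certain and one tree suffices. The
3-node reading of "first two layers" and the Poisson count model are this
package's interpretation of an informally stated heuristic; at the
motivating scale (p = 1,710,000, mtry = 1308, coverage 0.95) it recommends
1306 trees, consistent with the √p-scale choice of roughly a thousand
trees.

### Leave-one-out networks (iRF-LOOP)

One iRF per gene, that gene as target, the rest as predictors; the final
importance vectors form the n × n matrix, the diagonal is zero by
construction, and each positive-sum column is divided by its sum
(all-zero columns — e.g. from a constant target, which is skipped with a
warning — stay zero). Per-target master seeds are keyed by a stable md5
hash of the target gene id, and predictors are sorted by id inside each
run, so permuting the input gene order conjugately permutes the adjacency
matrix bit-exactly and target scheduling order is irrelevant.

Thresholding pools the strictly positive entries of the whole matrix
(zeros removed first), takes the ⌈fraction·|Z|⌉-th largest value as the
cutoff, and keeps all edges ≥ cutoff — ties included, so nominal edge
counts can be slightly exceeded and nested fractions give nested networks.
Thresholding on the pooled distribution (not per column) follows the
"top % of edge scores" reading.

### GO co-annotation scoring

Terms with 2 ≤ n < 1000 genes contribute all n(n−1)/2 pairs at weight
1/(n−1); multiply-shared pairs keep the maximum; the cutoff is strict
(n = 1000 contributes nothing). Directed predicted edges are collapsed to
unordered distinct pairs before scoring and before permutation, since the
GO network is undirected; a pair present in both directions counts once.
The permutation null relabels the predicted network's own node set by a
uniform random bijection — genes absent from the GO network are retained
(they dilute permuted scores rather than being pruned). Because a
bijection maps distinct pairs to distinct pairs, no deduplication is
needed after relabeling. The t-statistic uses the sample (n−1) standard
deviation of the permuted scores, the standard choice for an empirical
null of ~1000 draws; a normal-QQ helper (`null_qq`) supports checking
that the null is near-Gaussian before reading t as a z-score.

The Pearson comparator ranks all gene pairs by |r| (absolute correlation,
treating repression and activation symmetrically — the signed alternative
is a documented ambiguity) and keeps the top fraction with the same
tie-inclusion rule; constant genes are excluded with a warning.

## Synthetic data

The expression generator plants a random DAG: genes are ordered, edges
point forward, root genes are standard normal, and each child is the
effect-weighted sum of its parents plus Gaussian noise. Defaults — 20
genes, 15 edges, effect magnitudes uniform in [0.75, 1.25] with random
sign, noise s.d. 0.2, 200 samples — put planted signals well above the
noise floor, which is the regime the linear-Gaussian model is meant to
probe. The generator emulates the *dependency structure* of expression
data, not its marginal realism: no TPM-like skew or zero-inflation, no
hub-dominated degree distributions, no confounding covariance from batch
or population structure. Recovery results on it show that the pipeline
detects planted linear dependencies, not that it resolves the harder
correlated-noise structure of real RNAseq.

GO annotations are generated as terms of requested sizes with a
controllable overlap fraction (share of a term's members drawn from
already-annotated genes); with overlap 0 the terms are disjoint and the
record count is exactly the size sum. The eQTL generator draws dosages
binomial(2, maf) with per-SNP maf uniform in [0.05, 0.5] by default,
flags missing entries at a configurable rate, and builds the target as
the causal-effect-weighted dosage sum plus standard normal noise; it has
no linkage disequilibrium or stratification by design.

Genotype QC keeps SNPs with MAF strictly greater than 0.01 (computed from
non-missing dosages, folded at 0.5) and missingness strictly below 10%,
then imputes residual missing entries to the SNP's rounded mean dosage —
a deliberate, simple post-filter choice.

## Numerical and design choices

* `mtry` defaults to ⌊√p⌋ for both tasks; `min_node_size` defaults to 5
  (regression) / 1 (classification). Both configurable.
* Regression purity is declared at SS ≤ 1e-12·max(1, Σy²); split
  acceptance requires a decrease exceeding the 1e-9 relative tie
  tolerance.
* `normalize_importance` of an all-zero vector returns uniform weights
  with a warning (the degenerate case must not kill a multi-target loop).
* Estimator classes follow scikit-learn conventions (`fit`, `predict`,
  `get_params`/`set_params`, trailing-underscore fitted attributes) and
  compose with pipelines; the module-level functions are thin wrappers
  over the same code paths.
* VCF dosage reading keeps biallelic records only (multiallelic skips
  counted), maps GT 0/0→0, 0/1 or 1/0→1, 1/1→2, ./.→missing, and ids
  SNPs as CHROM:POS:REF:ALT.

## Problem sizes in the test suite

Tests exercise the documented contracts at sizes a laptop runs in
seconds: determinism at 1000 features × 200 samples × 100 trees × 3
iterations across 1, 2 and 4 workers; split-search equivalence against a
brute-force oracle on 200 random instances of ≤ 50 × 5; network recovery
on the 20-gene / 15-edge generator defaults over 5 seeds (mean AUROC
checked against 0.85); permutation-null calibration with 1000
permutations over 20 seeds; eQTL recovery at a scaled-down 500 SNPs × 300
samples with 3 planted effects over 10 seeds. The published-table
t-statistics are recomputed exactly from their summary triples.

## Known limitations

* Split search sorts candidate values per node (no global presorting or
  histogram binning), which is simple and exact but not competitive with
  HPC implementations at millions of features; the package targets desk
  scale.
* Classification importance uses the unscaled fractional Gini decrease,
  so deep small nodes contribute as much as the root per unit decrease;
  rankings are still consistent within a forest.
* No out-of-bag error tracking, permutation importance, or automatic
  choice of the iteration count.
* GO scoring uses literal shared annotations only — no ancestor-term
  propagation through the GO hierarchy — and reports no per-term
  enrichment p-values.
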