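# penirf

Iterative Random Forests with weighted feature sampling, leave-one-out
predictive-network inference, and permutation validation against Gene
Ontology co-annotation — for systems biologists inferring directed
gene–gene (or SNP–gene) relationships from expression and genotype
matrices, at desk scale.

## What it computes

**Weighted-split forests.** The base learner is a CART tree grown on a
bootstrap of the m samples; at each node, `mtry` candidate features are
drawn *without replacement from a weighted distribution* over the p
features, and the candidate/threshold pair maximizing the impurity decrease
(sum-of-squared-deviations for regression, Gini for classification) splits
the node. A feature with weight 0 is never considered. Impurity importance
for feature *f* is the sum of decreases over all nodes split on *f*, across
trees, divided by the number of trees.

**iRF (Iterative Random Forest).** Iteration 1 grows a forest with uniform
weights; iteration *k* > 1 uses the sum-normalized importance of iteration
*k* − 1 as its sampling weights. Like an ℓ₁ penalty in a linear model, the
loop progressively concentrates weight on informative features; weights
that reach zero stay zero.

**iRF-LOOP (Leave One Out Prediction).** For a matrix of n genes × m
samples, run one iRF per gene with that gene as target Y and the other
n − 1 genes as predictors X. The n final importance vectors form an n × n
matrix; the diagonal (self-prediction) is set to zero and each column is
normalized by its sum. The result is a directed adjacency matrix — a
Predictive Expression Network (PEN) in which edge A→B weighs gene A's
importance for predicting gene B, generally ≠ the reverse. Thresholded
networks keep the top 10%, 5%, 1%, 0.1% … of the pooled nonzero edge
scores (ties at the cutoff included, so the networks are nested).

**GO validation.** Genes sharing a GO term (terms with fewer than 1000
genes) are connected at weight 1/(n−1), n the term size, keeping the
maximum over multiply-shared terms. A predicted network's *intersect
score* sums the GO weights of the unordered pairs present in both
networks; a null distribution comes from re-scoring after 1000 uniform
random permutations of the predicted network's node labels, and

    t = (observed − null mean) / null s.d.

A Pearson co-expression network (top |r| pairs) serves as comparator.

All forest runs are reproducible: the seed of tree *t* is a pure function
of (master seed, *t*), so results are bit-identical for any worker count.

## Worked example

Infer a network from a planted 10-gene, 8-edge linear system and validate
it against annotations that group the truly interacting genes:

```python
import pandas as pd
from penirf import (random_planted_network, simulate_expression, IRFLoop,
                    build_go_network, score_against_go)

net = random_planted_network(n_genes=10, n_edges=8, noise_sd=0.2, seed=1)
data, truth = simulate_expression(net, n_samples=200, seed=2)

est = IRFLoop(n_iterations=3, n_trees=300, random_state=0).fit(data.to_frame())
edges = est.edge_list(top_fraction=0.1)
print(edges.to_string(index=False))
```

```
source target   weight
    g5     g9 0.988238
    g7     g8 0.979235
    g8     g7 0.970271
    g9     g5 0.942395
    g2     g3 0.883400
    g2     g0 0.831528
    g3     g2 0.512301
    g0     g2 0.484550
    g5     g4 0.479428
```

The top-10% network recovers five of the eight planted pairs (g5–g9,
g7–g8, g2–g3, g0–g2, g4–g5), several in both directions — prediction is
directional, so A→B and B→A are scored separately. Scoring against a GO
network whose terms pair the true interactors:

```python
ann = pd.DataFrame(
    [(g, f"T{i}") for i, row in truth.iterrows() for g in (row.source, row.target)],
    columns=["gene_id", "term_id"],
)
report = score_against_go(edges, build_go_network(ann),
                          n_permutations=1000, seed=3)
print(f"intersect={report.intersect_score:.4f} "
      f"null={report.null_mean:.4f}±{report.null_sd:.4f} "
      f"t={report.t_statistic:.2f}")
```

```
intersect=5.0000 null=1.4330±0.9500 t=3.75
```

The observed overlap (5 two-gene terms hit, each weight 1) sits about four
null standard deviations above what random relabeling achieves.

The same pipeline runs from the shell: `penirf simulate expression`,
`penirf loop`, `penirf score-go`, `penirf coexpr`, plus `penirf irf` for
single-target (e.g. SNP → gene expression, eQTL-style) importance and
`penirf filter-genotypes` for dosage QC (biallelic, MAF > 0.01, < 10%
missing, mean-dosage imputation). Every output file records the tool
version, command line, and master seed in its header.

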