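"""GO co-annotation networks and permutation validation of predicted networks.

A Gene Ontology co-annotation network joins two genes whenever they share an
annotation term.  A term annotating n genes contributes all n(n−1)/2 pairs at
weight 1/(n−1), so rare (specific) terms weigh more than broad ones; a pair
sharing several terms keeps the largest weight, and terms with 1000 or more
genes are excluded entirely.  A predicted network's *intersect score* sums
the GO weights of the unordered gene pairs present in both networks.

Significance is judged against a permutation null: the predicted network's
node labels are shuffled (a uniform random bijection of its own node set),
the relabeled network is re-scored, and the observed score is summarized as
t = (observed − null mean) / null s.d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Tuple

import numpy as np
import pandas as pd

from .dataset import Dataset
from .exceptions import DegenerateNullError, ParameterError

Pair = Tuple[str, str]


@dataclass
class GONetwork:
    """Undirected gene–gene network from shared GO terms.

    ``weights`` maps canonical (sorted) gene pairs to 1/(n−1) weights; the
    node set covers every gene of every contributing term.
    """

    weights: Dict[Pair, float]
    nodes: FrozenSet[str]

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights.values()))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((a, b, w) for (a, b), w in self.weights.items())
        return g


@dataclass
class ScoreReport:
    """Observed intersect score against its permutation null."""

    intersect_score: float
    null_scores: np.ndarray
    null_mean: float
    null_sd: float
    t_statistic: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "intersect_score": [self.intersect_score],
                "null_mean": [self.null_mean],
                "null_sd": [self.null_sd],
                "t_statistic": [self.t_statistic],
                "n_permutations": [len(self.null_scores)],
            }
        )


def build_go_network(annotations, max_term_size: int = 1000) -> GONetwork:
    """Weighted co-annotation network from (gene, term) records.

    Terms with 2 <= n < ``max_term_size`` genes contribute their n(n−1)/2
    pairs at weight 1/(n−1); a multiply-shared pair keeps the maximum weight.
    Duplicate (gene, term) records are collapsed first.
    """
    frame = _as_annotation_frame(annotations)
    weights: Dict[Pair, float] = {}
    nodes = set()
    for _, genes in frame.groupby("term_id", sort=False)["gene_id"]:
        members = sorted(set(genes))
        n = len(members)
        if n < 2 or n >= max_term_size:
            continue
        w = 1.0 / (n - 1)
        nodes.update(members)
        for i in range(n):
            for j in range(i + 1, n):
                pair = (members[i], members[j])
                if weights.get(pair, 0.0) < w:
                    weights[pair] = w
    return GONetwork(weights=weights, nodes=frozenset(nodes))


def _as_annotation_frame(annotations) -> pd.DataFrame:
    if isinstance(annotations, pd.DataFrame):
        frame = annotations.iloc[:, :2].copy()
        frame.columns = ["gene_id", "term_id"]
    else:
        frame = pd.DataFrame(list(annotations), columns=["gene_id", "term_id"])
    if frame.empty:
        raise ParameterError("annotation table is empty")
    return frame.astype(str).drop_duplicates()


def _pen_pairs(pen) -> set:
    """Collapse a directed edge list to distinct unordered gene pairs."""
    if isinstance(pen, pd.DataFrame):
        records = zip(pen.iloc[:, 0].astype(str), pen.iloc[:, 1].astype(str))
    else:
        records = ((str(a), str(b)) for a, b, *_ in pen)
    pairs = set()
    for a, b in records:
        if a != b:
            pairs.add((a, b) if a < b else (b, a))
    return pairs


def intersect_score(pen, go: GONetwork) -> float:
    """Sum of GO edge weights over pairs present in both networks.

    The predicted network is collapsed to unordered distinct pairs first, so
    A→B and B→A contribute the shared GO weight once.
    """
    w = go.weights
    return float(sum(w.get(pair, 0.0) for pair in _pen_pairs(pen)))


def null_distribution(
    pen, go: GONetwork, n_permutations: int = 1000, seed: int = 0
) -> np.ndarray:
    """Intersect scores of ``n_permutations`` node-relabeled copies of the PEN.

    Each replicate applies a uniform random bijection of the predicted
    network's own node set onto itself and re-scores the relabeled edges
    against the (fixed) GO network.
    """
    if int(n_permutations) < 1:
        raise ParameterError(f"n_permutations must be >= 1, got {n_permutations}")
    pairs = _pen_pairs(pen)
    nodes = sorted({g for pair in pairs for g in pair})
    if len(nodes) < 2:
        raise ParameterError("predicted network needs at least 2 nodes")
    index = {g: i for i, g in enumerate(nodes)}
    edges = np.array([(index[a], index[b]) for a, b in pairs], dtype=np.int64)
    node_set = set(nodes)
    # only GO pairs inside the PEN's node set can ever score
    local = {
        (index[a], index[b]): w
        for (a, b), w in go.weights.items()
        if a in node_set and b in node_set
    }
    rng = np.random.default_rng(int(seed))
    scores = np.empty(int(n_permutations), np.float64)
    for r in range(int(n_permutations)):
        perm = rng.permutation(len(nodes))
        pa = perm[edges[:, 0]]
        pb = perm[edges[:, 1]]
        lo = np.minimum(pa, pb)
        hi = np.maximum(pa, pb)
        s = 0.0
        for i in range(lo.size):
            s += local.get((int(lo[i]), int(hi[i])), 0.0)
        scores[r] = s
    return scores


def t_statistic(observed: float, null_scores) -> float:
    """(observed − null mean) / null s.d., sample s.d. with n−1 denominator."""
    null_scores = np.asarray(null_scores, dtype=np.float64)
    if null_scores.size < 2:
        raise ParameterError("need at least 2 null scores")
    sd = float(np.std(null_scores, ddof=1))
    if sd == 0.0:
        raise DegenerateNullError("null distribution has zero spread")
    return (float(observed) - float(np.mean(null_scores))) / sd


def t_statistic_from_moments(observed: float, null_mean: float, null_sd: float) -> float:
    """t-statistic from a pre-summarized null (e.g. a published mean/s.d.)."""
    if null_sd <= 0:
        raise DegenerateNullError("null s.d. must be positive")
    return (float(observed) - float(null_mean)) / float(null_sd)


def score_against_go(
    pen, go: GONetwork, n_permutations: int = 1000, seed: int = 0
) -> ScoreReport:
    """Observed intersect score, permutation null, and t-statistic in one call."""
    observed = intersect_score(pen, go)
    null = null_distribution(pen, go, n_permutations=n_permutations, seed=seed)
    return ScoreReport(
        intersect_score=observed,
        null_scores=null,
        null_mean=float(np.mean(null)),
        null_sd=float(np.std(null, ddof=1)),
        t_statistic=t_statistic(observed, null),
    )


def coexpression_network(expr, top_fraction: float) -> pd.DataFrame:
    """Top fraction of pairwise Pearson co-expression, ranked by |r|.

    All n(n−1)/2 gene pairs are evaluated over samples; constant genes are
    excluded with a warning.  Ties at the cutoff are kept, as in edge-list
    thresholding.  Output is undirected: one record per pair, columns
    (gene_a, gene_b, weight=|r|).
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ParameterError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if isinstance(expr, Dataset):
        matrix, genes = expr.X, list(expr.feature_ids)
    elif hasattr(expr, "columns"):
        matrix, genes = expr.to_numpy(dtype=np.float64), [str(c) for c in expr.columns]
    else:
        matrix = np.asarray(expr, dtype=np.float64)
        genes = [f"g{j}" for j in range(matrix.shape[1])]
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise ParameterError("need at least 2 genes and 3 samples")
    keep = np.ptp(matrix, axis=0) > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        warnings.warn(
            f"excluding {len(dropped)} constant gene(s) from correlation: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
    matrix = matrix[:, keep]
    genes = [g for g, k in zip(genes, keep) if k]
    corr = np.corrcoef(matrix, rowvar=False)
    iu, ju = np.triu_indices(len(genes), k=1)
    r = np.abs(corr[iu, ju])
    positive = r > 0
    iu, ju, r = iu[positive], ju[positive], r[positive]
    if r.size == 0:
        warnings.warn("no nonzero correlations", stacklevel=2)
        return pd.DataFrame(columns=["gene_a", "gene_b", "weight"])
    k = int(np.ceil(top_fraction * r.size))
    cutoff = np.partition(r, r.size - k)[r.size - k]
    sel = r >= cutoff
    gene_arr = np.asarray(genes, dtype=object)
    frame = pd.DataFrame(
        {"gene_a": gene_arr[iu[sel]], "gene_b": gene_arr[ju[sel]], "weight": r[sel]}
    )
    return frame.sort_values(
        ["weight", "gene_a", "gene_b"], ascending=[False, True, True]
    ).reset_index(drop=True)


def null_qq(null_scores) -> Tuple[np.ndarray, np.ndarray]:
    """Normal QQ coordinates for a null-score vector (diagnostic hook).

    Returns (theoretical standard-normal quantiles, sorted standardized
    scores); a near-diagonal plot supports summarizing the null by its mean
    and s.d. alone.
    """
    from scipy import stats

    null_scores = np.asarray(null_scores, dtype=np.float64)
    sd = np.std(null_scores, ddof=1)
    if sd == 0:
        raise DegenerateNullError("null distribution has zero spread")
    z = np.sort((null_scores - np.mean(null_scores)) / sd)
    n = z.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theo, z
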