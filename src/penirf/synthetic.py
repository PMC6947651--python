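"""Synthetic generators with the statistical structure the methods assume.

Three generators mirror the three kinds of input the analysis stages consume:

* expression matrices with a planted directed regulatory network
  (linear-Gaussian: root genes standard normal, children weighted sums of
  parents plus noise) — what leave-one-out network inference should recover;
* term-structured GO annotations with controllable term sizes and overlap —
  what the co-annotation network and permutation scoring consume;
* genotype dosage matrices with planted eQTL effects, minor-allele
  frequencies, and missingness — what the single-target eQTL mode consumes.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .dataset import Dataset
from .exceptions import DataError, ParameterError
from .loop import EDGE_COLUMNS


@dataclass
class PlantedNetwork:
    """A directed acyclic regulatory network with linear effect sizes."""

    gene_ids: List[str]
    edges: List[Tuple[str, str, float]]  # (parent, child, effect)
    noise_sd: float = 0.2

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")
        genes = set(self.gene_ids)
        for parent, child, effect in self.edges:
            if parent not in genes or child not in genes:
                raise DataError(f"edge ({parent!r}, {child!r}) uses unknown gene id")
            if effect == 0:
                raise DataError(f"edge ({parent!r}, {child!r}) has zero effect")
        graph = nx.DiGraph()
        graph.add_nodes_from(self.gene_ids)
        graph.add_edges_from((p, c) for p, c, _ in self.edges)
        if not nx.is_directed_acyclic_graph(graph):
            raise DataError("planted network contains a cycle")
        self._order = list(nx.topological_sort(graph))
        self._parents = {
            g: [(p, e) for p, c, e in self.edges if c == g] for g in self.gene_ids
        }

    def truth_edges(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.edges, columns=["source", "target", "effect"])
        frame["weight"] = frame["effect"].abs()
        return frame[EDGE_COLUMNS + ["effect"]]


def random_planted_network(
    n_genes: int = 20,
    n_edges: int = 15,
    noise_sd: float = 0.2,
    effect_range: Tuple[float, float] = (0.75, 1.25),
    seed: int = 0,
) -> PlantedNetwork:
    """Random DAG: genes ordered g00..g<n>, edges only forward in the order.

    Effect magnitudes are uniform in ``effect_range`` with random sign, so
    planted signals sit well above a 0.2-s.d. noise floor by default.
    """
    if n_genes < 2:
        raise ParameterError("need at least 2 genes")
    max_edges = n_genes * (n_genes - 1) // 2
    if not (1 <= n_edges <= max_edges):
        raise ParameterError(f"n_edges must be in [1, {max_edges}]")
    rng = np.random.default_rng(int(seed))
    width = len(str(n_genes - 1))
    genes = [f"g{j:0{width}d}" for j in range(n_genes)]
    all_pairs = [(i, j) for i in range(n_genes) for j in range(i + 1, n_genes)]
    chosen = rng.choice(len(all_pairs), size=n_edges, replace=False)
    lo, hi = effect_range
    edges = []
    for k in sorted(chosen):
        i, j = all_pairs[k]
        effect = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        edges.append((genes[i], genes[j], float(effect)))
    return PlantedNetwork(gene_ids=genes, edges=edges, noise_sd=noise_sd)


def simulate_expression(
    net: PlantedNetwork, n_samples: int, seed: int = 0
) -> Tuple[Dataset, pd.DataFrame]:
    """Sample an expression matrix from the planted linear-Gaussian model.

    Root genes are standard normal; each child is the effect-weighted sum of
    its parents plus Gaussian noise of s.d. ``net.noise_sd``.  Returns the
    samples × genes Dataset and the true directed edge list.
    """
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    rng = np.random.default_rng(int(seed))
    columns = {}
    for gene in net._order:
        parents = net._parents[gene]
        if not parents:
            columns[gene] = rng.standard_normal(n_samples)
        else:
            base = np.zeros(n_samples)
            for parent, effect in parents:
                base += effect * columns[parent]
            noise = (
                rng.normal(0.0, net.noise_sd, n_samples) if net.noise_sd > 0 else 0.0
            )
            columns[gene] = base + noise
    X = np.column_stack([columns[g] for g in net.gene_ids])
    data = Dataset(X, feature_ids=list(net.gene_ids))
    return data, net.truth_edges()


def generate_go_annotations(
    genes: Sequence[str],
    term_sizes: Sequence[int],
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Annotation table with terms of the requested sizes.

    For each term after the first, about ``overlap_fraction`` of its members
    are drawn from genes already annotated to earlier terms (inducing shared
    membership); the rest come from unused genes.  With overlap 0 the terms
    are disjoint, so the record count is exactly ``sum(term_sizes)``.
    """
    genes = [str(g) for g in genes]
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ParameterError("overlap_fraction must be in [0, 1]")
    for size in term_sizes:
        if size < 2:
            raise ParameterError(f"term sizes must be >= 2, got {size}")
        if size > len(genes):
            raise DataError(f"term size {size} exceeds the {len(genes)} genes")
    rng = np.random.default_rng(int(seed))
    unused = list(genes)
    used: List[str] = []
    records = []
    for t, size in enumerate(term_sizes):
        term = f"T{t:04d}"
        n_overlap = min(int(round(size * overlap_fraction)), len(used))
        n_fresh = size - n_overlap
        if n_fresh > len(unused):
            raise DataError(
                f"term {term} needs {n_fresh} fresh genes but only "
                f"{len(unused)} remain; lower term sizes or raise overlap"
            )
        members = []
        if n_overlap:
            members += list(rng.choice(used, size=n_overlap, replace=False))
        if n_fresh:
            fresh = list(rng.choice(unused, size=n_fresh, replace=False))
            members += fresh
            for g in fresh:
                unused.remove(g)
                used.append(g)
        records += [(g, term) for g in members]
    return pd.DataFrame(records, columns=["gene_id", "term_id"])


def generate_eqtl_dataset(
    n_snps: int,
    n_samples: int,
    causal: Sequence[Tuple[int, float]] = (),
    maf_range: Tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Dosage matrix (SNP × sample, NaN = missing) and expression target.

    Dosages are binomial(2, maf) with per-SNP maf uniform in ``maf_range``;
    the target is the causal-effect-weighted dosage sum plus standard normal
    noise.  Missing entries are flagged as NaN at ``missing_rate``.
    """
    for idx, _ in causal:
        if not (0 <= idx < n_snps):
            raise ParameterError(f"causal SNP index {idx} out of range")
    rng = np.random.default_rng(int(seed))
    mafs = rng.uniform(maf_range[0], maf_range[1], n_snps)
    dosages = rng.binomial(2, mafs[:, None], size=(n_snps, n_samples)).astype(float)
    y = rng.standard_normal(n_samples)
    for idx, effect in causal:
        y = y + effect * dosages[idx]
    if missing_rate > 0:
        mask = rng.random((n_snps, n_samples)) < missing_rate
        dosages[mask] = np.nan
    width = len(str(max(n_snps - 1, 1)))
    snp_ids = [f"snp{j:0{width}d}" for j in range(n_snps)]
    sample_ids = [f"s{i}" for i in range(n_samples)]
    genotypes = pd.DataFrame(dosages, index=snp_ids, columns=sample_ids)
    return genotypes, pd.Series(y, index=sample_ids, name="expression")


def filter_genotypes(
    genotypes: pd.DataFrame, maf_min: float = 0.01, max_missing: float = 0.10
) -> Dataset:
    """Biallelic-dosage QC: MAF and missingness filters, then mean imputation.

    Drops SNPs whose minor allele frequency (from non-missing dosages) is
    <= ``maf_min`` or whose missing fraction is >= ``max_missing`` (both
    bounds strict, "greater than 0.01" / "less than ten percent").  Remaining
    NaNs are imputed to the SNP's rounded mean dosage.  Returns a samples ×
    SNPs Dataset ready for forest fitting.
    """
    values = genotypes.to_numpy(dtype=np.float64)
    n_samples = values.shape[1]
    missing = np.isnan(values)
    missing_frac = missing.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing rows
        mean_dosage = np.nanmean(values, axis=1)
    alt_freq = mean_dosage / 2.0
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep = (maf > maf_min) & (missing_frac < max_missing) & ~np.isnan(mean_dosage)
    if not keep.any():
        warnings.warn("all SNPs removed by the MAF/missingness filters", stacklevel=2)
        return Dataset(
            np.empty((n_samples, 0)), feature_ids=[],
            sample_ids=[str(c) for c in genotypes.columns],
        )
    kept = values[keep]
    fill = np.round(np.nanmean(kept, axis=1))
    rows, cols = np.nonzero(np.isnan(kept))
    kept[rows, cols] = fill[rows]
    return Dataset(
        kept.T,
        feature_ids=[str(i) for i in genotypes.index[keep]],
        sample_ids=[str(c) for c in genotypes.columns],
    )
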