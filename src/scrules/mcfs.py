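"""Monte Carlo feature selection: gene ranking by relative importance.

Many small classification trees are grown, each on a bootstrap sample of
cells restricted to a random subset of ``m`` genes.  Every split a gene
contributes, across all trees, feeds its relative importance (RI) score;
sorting genes by descending RI yields the feature ranking the downstream
stages consume.

Two RI variants are provided:

* ``split_count`` — one point per split involving the gene (the literal
  "overall number of splits" reading).
* ``weighted`` (default) — each split contributes
  ``wAcc(tree)**u * gain(node) * (n_node / n_tree)**v``, where ``wAcc`` is
  the tree's class-balanced out-of-bag accuracy and ``gain`` the node's
  Gini improvement; this is the weighted formulation of the Monte Carlo
  feature selection literature.

Informative features are the maximal top-ranking prefix whose RI scores
significantly exceed a label-permutation null (one-sided t-test per gene
against its null RI sample).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .dataset import ExpressionDataset
from .simulate import permute_labels

__all__ = [
    "MCFSParams",
    "FeatureRanking",
    "InformativeSet",
    "run_mcfs",
    "select_informative",
]


@dataclass
class MCFSParams:
    """Knobs of the Monte Carlo ranking run.

    ``projection_size`` may be an absolute gene count (int) or a fraction of
    the total (float in (0,1)); ``None`` means ``max(ceil(0.05*n_genes), 1)``.
    ``n_projections=None`` sizes ``s`` so each gene is expected in at least
    15 projections.  ``u`` and ``v`` are the exponents of the weighted RI.
    """

    n_projections: int | None = None
    projection_size: int | float | None = None
    trees_per_projection: int = 5
    bootstrap_fraction: float = 0.66
    ri_variant: str = "weighted"  # or "split_count"
    u: float = 1.0
    v: float = 1.0
    min_expected_appearances: int = 15
    seed: int = 0

    def resolve(self, n_genes: int) -> tuple[int, int]:
        """Concrete (s, m) for a dataset with ``n_genes`` genes."""
        m = self.projection_size
        if m is None:
            m = max(math.ceil(0.05 * n_genes), 1)
        elif isinstance(m, float) and 0 < m < 1:
            m = max(math.ceil(m * n_genes), 1)
        else:
            m = int(m)
        if m < 1 or m > n_genes:
            raise ValueError(f"projection size {m} outside [1, {n_genes}]")
        s = self.n_projections
        if s is None:
            s = math.ceil(self.min_expected_appearances * n_genes / m)
        if s * self.trees_per_projection < 1:
            raise ValueError("s * t must be at least 1")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must lie in (0, 1]")
        if self.ri_variant not in ("weighted", "split_count"):
            raise ValueError(f"unknown ri_variant: {self.ri_variant!r}")
        if self.u < 0 or self.v < 0:
            raise ValueError("u and v must be non-negative")
        return int(s), int(m)


@dataclass
class FeatureRanking:
    """Genes ordered by descending RI; ties broken by gene id.

    Genes with RI = 0 never split any tree; they are retained in the
    ranking but flagged discardable, and downstream stages skip them.
    """

    gene_ids: list[str]
    scores: np.ndarray
    symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores must align")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")
        if np.any(self.scores < 0):
            raise ValueError("RI scores must be non-negative")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def score_of(self, gene_id: str) -> float:
        return float(self.scores[self.gene_ids.index(gene_id)])

    def usable_genes(self) -> list[str]:
        """Ranked genes with strictly positive RI (the non-discardable part)."""
        return [g for g, s in zip(self.gene_ids, self.scores) if s > 0]

    def rank_of(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class InformativeSet:
    """Top-ranking prefix passing the permutation-null t-test at ``alpha``."""

    gene_ids: list[str]
    p_values: np.ndarray
    alpha: float
    n_permutations: int

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if len(self.gene_ids) != len(self.p_values):
            raise ValueError("gene_ids and p_values must align")

    def __len__(self) -> int:
        return len(self.gene_ids)


def _tree_ri(
    X: np.ndarray,
    y01: np.ndarray,
    feature_cols: np.ndarray,
    params: MCFSParams,
    rng: np.random.Generator,
    ri: np.ndarray,
) -> None:
    """Grow one bootstrap tree and accumulate its RI contributions in place."""
    n = X.shape[0]
    n_boot = max(int(round(params.bootstrap_fraction * n)), 2)
    for _ in range(20):
        boot = rng.integers(0, n, size=n_boot)
        if len(np.unique(y01[boot])) == 2:
            break
    else:  # pathologically unbalanced bootstrap; skip this tree
        return
    Xb = X[np.ix_(boot, feature_cols)]
    yb = y01[boot]
    tree = DecisionTreeClassifier(
        criterion="gini",
        min_samples_leaf=2,
        random_state=int(rng.integers(2**31)),
    )
    tree.fit(Xb, yb)
    t = tree.tree_
    internal = t.children_left != -1
    if not internal.any():
        return
    if params.ri_variant == "split_count":
        for node in np.flatnonzero(internal):
            ri[feature_cols[t.feature[node]]] += 1.0
        return
    # weighted variant: class-balanced out-of-bag accuracy per tree
    oob = np.setdiff1d(np.arange(n), np.unique(boot), assume_unique=True)
    if oob.size == 0:
        return
    y_oob = y01[oob]
    pred = tree.predict(X[np.ix_(oob, feature_cols)])
    recalls = [
        np.mean(pred[y_oob == cls] == cls) for cls in np.unique(y_oob)
    ]
    w_acc = float(np.mean(recalls))
    if w_acc <= 0:
        return
    tree_factor = w_acc**params.u
    n_root = t.weighted_n_node_samples[0]
    for node in np.flatnonzero(internal):
        left, right = t.children_left[node], t.children_right[node]
        w_node = t.weighted_n_node_samples[node]
        gain = t.impurity[node] - (
            t.weighted_n_node_samples[left] * t.impurity[left]
            + t.weighted_n_node_samples[right] * t.impurity[right]
        ) / w_node
        if gain <= 0:
            continue
        ri[feature_cols[t.feature[node]]] += (
            tree_factor * gain * (w_node / n_root) ** params.v
        )


def run_mcfs(dataset: ExpressionDataset, params: MCFSParams) -> FeatureRanking:
    """Rank all genes by relative importance.

    Deterministic given ``params.seed`` and a fixed cell order.
    """
    dataset.require_two_classes()
    n_genes = dataset.n_genes
    s, m = params.resolve(n_genes)
    rng = np.random.default_rng(params.seed)
    X = dataset.values
    y01 = dataset.y()
    ri = np.zeros(n_genes)
    for _ in range(s):
        cols = rng.choice(n_genes, size=m, replace=False)
        for _ in range(params.trees_per_projection):
            _tree_ri(X, y01, cols, params, rng, ri)
    order = sorted(range(n_genes), key=lambda j: (-ri[j], dataset.gene_ids[j]))
    return FeatureRanking(
        gene_ids=[dataset.gene_ids[j] for j in order],
        scores=ri[order],
        symbols=None
        if dataset.symbols is None
        else [dataset.symbols[j] for j in order],
    )


def null_ri_matrix(
    dataset: ExpressionDataset,
    params: MCFSParams,
    n_permutations: int,
) -> np.ndarray:
    """RI scores from full reruns on label-permuted copies.

    Rows are permutations, columns follow ``dataset.gene_ids`` order.
    """
    rng = np.random.default_rng(params.seed)
    gene_index = {g: j for j, g in enumerate(dataset.gene_ids)}
    null = np.empty((n_permutations, dataset.n_genes))
    for p in range(n_permutations):
        perm_seed = int(rng.integers(2**31))
        mcfs_seed = int(rng.integers(2**31))
        shuffled = permute_labels(dataset, perm_seed)
        perm_ranking = run_mcfs(shuffled, replace(params, seed=mcfs_seed))
        for g, score in zip(perm_ranking.gene_ids, perm_ranking.scores):
            null[p, gene_index[g]] = score
    return null


def select_informative(
    dataset: ExpressionDataset,
    ranking: FeatureRanking,
    params: MCFSParams,
    n_permutations: int = 20,
    alpha: float = 0.05,
) -> InformativeSet:
    """Extract the informative features via a label-permutation null.

    The full Monte Carlo procedure is rerun ``n_permutations`` times on
    label-permuted copies of the data; each gene's observed RI is compared
    to its null sample with a one-sided t-test (alternative: observed
    greater than the null mean).  The informative set is the maximal prefix
    of the ranking all of whose members pass at ``alpha``, which enforces
    the defining property that informative features are always the
    top-ranking features.
    """
    if n_permutations < 2:
        raise ValueError("the t-test needs at least 2 permutations")
    null = null_ri_matrix(dataset, params, n_permutations)
    gene_index = {g: j for j, g in enumerate(dataset.gene_ids)}
    prefix_genes: list[str] = []
    prefix_p: list[float] = []
    for g, observed in zip(ranking.gene_ids, ranking.scores):
        if observed <= 0:
            break
        sample = null[:, gene_index[g]]
        if np.ptp(sample) == 0:
            p = 0.0 if observed > sample[0] else 1.0
        else:
            p = float(
                stats.ttest_1samp(sample, observed, alternative="less").pvalue
            )
        if alpha > 0 and p <= alpha:
            prefix_genes.append(g)
            prefix_p.append(p)
        else:
            break
    return InformativeSet(
        gene_ids=prefix_genes,
        p_values=np.array(prefix_p),
        alpha=alpha,
        n_permutations=n_permutations,
    )
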