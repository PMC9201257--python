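"""Synthetic single-cell expression data with planted ground truth.

The generator emulates the shape of the study data the pipeline targets: two
unbalanced classes of cells (949 positive / 651 negative by default), many
genes on a continuous RPKM-like scale, heavy zero-inflation, plus planted
structure the downstream stages should recover:

* background genes — i.i.d. zero-inflated log-normal, identical across
  classes, so they carry no class signal at all;
* planted differentially-expressed (DE) genes — log2-normal with unit
  log2-sd and a class mean shift, drawn without dropout so the planted
  shift equals the standardized mean difference between classes;
* planted rule genes — a one-sided threshold separates the classes exactly
  in the noiseless case, with an explicit empirical gap around the
  threshold (a stated fraction of cells may be flipped to degrade the
  separation).

Ground truth is returned as a separate record (and serialized separately)
so tests never have to infer it from the matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import ExpressionDataset

__all__ = [
    "SyntheticSpec",
    "PlantedRule",
    "generate",
    "permute_labels",
    "plant_conjunction",
]

POSITIVE = "T2D"
NEGATIVE = "non-diabetes"


@dataclass(frozen=True)
class PlantedRule:
    """A planted single-gene threshold rule.

    Cells of ``implied_class`` satisfy ``gene <op> threshold``; all other
    cells violate it (up to ``noise`` in :class:`SyntheticSpec`).
    """

    index: int
    threshold: float
    operator: str  # "<=" or ">="
    implied_class: str

    def __post_init__(self) -> None:
        if self.operator not in ("<=", ">="):
            raise ValueError(f"operator must be <= or >=: {self.operator!r}")
        if not np.isfinite(self.threshold) or self.threshold < 0:
            raise ValueError("threshold must be finite and non-negative")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset draw.

    Defaults mirror the targeted study design: 949 positive and 651
    negative cells, zero-inflated log-normal background with 70% dropout.
    """

    n_pos: int = 949
    n_neg: int = 651
    n_genes: int = 20000
    planted_de_genes: list[tuple[int, float]] = field(default_factory=list)
    planted_rule_genes: list[PlantedRule] = field(default_factory=list)
    dropout_rate: float = 0.7
    base_log_mean: float = 1.0
    base_log_sd: float = 1.0
    rule_noise: float = 0.0  # fraction of cells violating their planted side
    rule_gap: float = 0.05  # relative half-width of the empty band at the cut
    seed: int = 0

    def validate(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes need at least one cell")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if not 0.0 <= self.rule_noise <= 1.0:
            raise ValueError("rule_noise must lie in [0, 1]")
        planted = [i for i, _ in self.planted_de_genes] + [
            r.index for r in self.planted_rule_genes
        ]
        if len(planted) != len(set(planted)):
            raise ValueError("planted gene indices overlap")
        if planted and (min(planted) < 0 or max(planted) >= self.n_genes):
            raise ValueError("planted gene index out of range")


LOG2 = np.log(2.0)


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, dict]:
    """Draw one labeled dataset plus its ground-truth record.

    Deterministic given ``spec`` (including ``spec.seed``): the same spec
    always yields a bit-identical matrix.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    labels = np.array([POSITIVE] * spec.n_pos + [NEGATIVE] * spec.n_neg,
                      dtype=object)
    pos_mask = labels == POSITIVE

    # Background: zero-inflated log-normal, class-exchangeable.
    values = rng.lognormal(
        mean=spec.base_log_mean, sigma=spec.base_log_sd, size=(n, spec.n_genes)
    )
    dropout = rng.random(size=(n, spec.n_genes)) < spec.dropout_rate
    values[dropout] = 0.0

    # Planted DE genes: log2-normal, unit sd in log2 space, positive-class
    # mean shifted by the stated number of log2 units; no dropout, so the
    # planted shift is the between-class standardized mean difference.
    for index, shift in spec.planted_de_genes:
        log2_mu = np.full(n, spec.base_log_mean / LOG2)
        log2_mu[pos_mask] += shift
        values[:, index] = np.exp2(rng.normal(loc=log2_mu, scale=1.0))

    # Planted rule genes: implied class on the stated side of the threshold,
    # everyone else on the other side, with an empty relative band of width
    # 2*rule_gap*max(threshold, 1) around the cut.
    for rule in spec.planted_rule_genes:
        scale = max(rule.threshold, 1.0)
        gap = spec.rule_gap * scale
        satisfy = labels == rule.implied_class
        if spec.rule_noise > 0:
            flip = rng.random(n) < spec.rule_noise
            satisfy = satisfy ^ flip
        low_side = satisfy if rule.operator == "<=" else ~satisfy
        col = np.empty(n)
        hi = rule.threshold + gap + rng.uniform(0.0, 2.0 * scale, size=n)
        lo_top = max(rule.threshold - gap, 0.0)
        lo = rng.uniform(0.0, lo_top, size=n) if lo_top > 0 else np.zeros(n)
        col[low_side] = lo[low_side]
        col[~low_side] = hi[~low_side]
        values[:, rule.index] = col

    cell_ids = [f"cell{i + 1}" for i in range(n)]
    gene_ids = [f"g{j + 1}" for j in range(spec.n_genes)]
    dataset = ExpressionDataset(
        values=values,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        labels=labels,
        positive_class=POSITIVE,
    )
    truth = {
        "seed": spec.seed,
        "n_pos": spec.n_pos,
        "n_neg": spec.n_neg,
        "n_genes": spec.n_genes,
        "positive_class": POSITIVE,
        "negative_class": NEGATIVE,
        "dropout_rate": spec.dropout_rate,
        "de_genes": [
            {"gene_id": gene_ids[i], "index": i, "log2_shift": s}
            for i, s in spec.planted_de_genes
        ],
        "rule_genes": [
            {
                "gene_id": gene_ids[r.index],
                "index": r.index,
                "threshold": r.threshold,
                "operator": r.operator,
                "implied_class": r.implied_class,
            }
            for r in spec.planted_rule_genes
        ],
    }
    return dataset, truth


def plant_conjunction(
    dataset: ExpressionDataset,
    conditions: list[tuple[int, str, float]],
    target_class: str,
    seed: int = 0,
    gap_fraction: float = 0.05,
) -> dict:
    """Overwrite columns so a conjunction of threshold conditions holds.

    Cells of ``target_class`` satisfy every ``(gene index, op, threshold)``
    condition; every other cell violates at least one, the violated subset
    chosen uniformly at random per cell. Columns are rewritten in place;
    the planted structure is returned as a ground-truth record.
    """
    if dataset.labels is None:
        raise ValueError("dataset must be labeled")
    rng = np.random.default_rng(seed)
    n = dataset.n_cells
    target = np.asarray(dataset.labels) == target_class
    if not target.any() or target.all():
        raise ValueError("target class must be present and not universal")
    n_conditions = len(conditions)
    # choose, per non-target cell, a non-empty subset of conditions to violate
    violate = np.zeros((n, n_conditions), dtype=bool)
    others = np.flatnonzero(~target)
    for row in others:
        mask = rng.random(n_conditions) < 0.5
        if not mask.any():
            mask[rng.integers(n_conditions)] = True
        violate[row] = mask
    for j, (index, op, threshold) in enumerate(conditions):
        if op not in ("<=", ">="):
            raise ValueError(f"operator must be <= or >=: {op!r}")
        scale = max(threshold, 1.0)
        gap = gap_fraction * scale
        hi = threshold + gap + rng.uniform(0.0, 2.0 * scale, size=n)
        lo_top = max(threshold - gap, 0.0)
        lo = rng.uniform(0.0, lo_top, size=n) if lo_top > 0 else np.zeros(n)
        satisfies = ~violate[:, j]  # target cells satisfy everything
        low_side = satisfies if op == "<=" else ~satisfies
        col = np.where(low_side, lo, hi)
        dataset.values[:, index] = col
    return {
        "target_class": target_class,
        "conditions": [
            {
                "gene_id": dataset.gene_ids[i],
                "index": i,
                "operator": op,
                "threshold": t,
            }
            for i, op, t in conditions
        ],
    }


def permute_labels(dataset: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Return a copy with labels shuffled uniformly; the matrix is untouched.

    The label multiset is preserved exactly.  This is the null model used by
    the informative-feature permutation test.
    """
    if dataset.labels is None:
        raise ValueError("dataset must be labeled")
    rng = np.random.default_rng(seed)
    permuted = dataset.labels[rng.permutation(dataset.n_cells)]
    return dataset.with_labels(permuted)


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2))
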