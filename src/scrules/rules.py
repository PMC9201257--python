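"""Interpretable rule induction: Johnson reducer + RIPPER.

The informative genes are first reduced with the Johnson heuristic from
rough-set theory: each gene is discretized with entropy-MDL cuts, then a
greedy set cover picks, one at a time, the gene that discerns the most
still-uncovered pairs of differently-labeled cells, until every coverable
pair is discerned.

RIPPER (repeated incremental pruning to produce error reduction) then
learns an ordered list of conjunction-of-threshold rules for the minority
class, the majority class becoming the terminal default.  Each rule is
grown greedily on a growing split by adding the single condition
``gene <= thr`` / ``gene >= thr`` (thresholds are midpoints between
consecutive distinct sorted training values) with the highest FOIL
information gain, then pruned on a pruning split by deleting trailing
conditions to maximize (p - n)/(p + n).  Rule-set construction stops when
no positives remain, when the minimum-description-length of the rule set
exceeds the best found so far by 64 bits, or when a candidate rule's
pruning-set error exceeds 50%.  A global optimization pass then revises or
replaces each rule, keeping whichever variant minimizes the total
description length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .dataset import ExpressionDataset

__all__ = [
    "Condition",
    "Rule",
    "RuleSet",
    "RipperParams",
    "foil_gain",
    "mdl_discretize",
    "johnson_reduce",
    "ripper",
    "apply_rules",
    "evaluate_rules",
]

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# rule containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    gene_id: str
    operator: str  # "<=" or ">="
    threshold: float

    def __post_init__(self) -> None:
        if self.operator not in ("<=", ">="):
            raise ValueError(f"operator must be <= or >=: {self.operator!r}")
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def holds(self, column: np.ndarray) -> np.ndarray:
        if self.operator == "<=":
            return column <= self.threshold
        return column >= self.threshold


@dataclass
class Rule:
    """Ordered conjunction of threshold conditions predicting one class.

    ``p`` / ``n`` are the rule's positive / negative coverage on the
    training data it was accepted from.
    """

    conditions: list[Condition]
    predicted_class: str
    p: int = 0
    n: int = 0

    def covers(self, values: np.ndarray, gene_index: dict[str, int]) -> np.ndarray:
        mask = np.ones(values.shape[0], dtype=bool)
        for cond in self.conditions:
            if cond.gene_id not in gene_index:
                raise KeyError(f"rule gene absent from dataset: {cond.gene_id}")
            mask &= cond.holds(values[:, gene_index[cond.gene_id]])
        return mask


@dataclass
class RuleSet:
    """Ordered rule list with a default class: prediction is total."""

    rules: list[Rule]
    default_class: str

    def __len__(self) -> int:
        return len(self.rules)

    def predict(self, values: np.ndarray, gene_index: dict[str, int]) -> np.ndarray:
        out = np.full(values.shape[0], self.default_class, dtype=object)
        unmatched = np.ones(values.shape[0], dtype=bool)
        for rule in self.rules:
            hit = unmatched & rule.covers(values, gene_index)
            out[hit] = rule.predicted_class
            unmatched &= ~hit
        return out


@dataclass
class RipperParams:
    grow_fraction: float = 2.0 / 3.0
    dl_slack_bits: float = 64.0
    max_error_rate: float = 0.5
    optimization_rounds: int = 2
    min_rule_weight: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.grow_fraction < 1.0:
            raise ValueError("grow_fraction must lie in (0, 1)")
        if self.dl_slack_bits < 0:
            raise ValueError("dl_slack_bits must be non-negative")


# ---------------------------------------------------------------------------
# FOIL gain
# ---------------------------------------------------------------------------

def foil_gain(p0: float, n0: float, p1: float, n1: float) -> float:
    """Information gained about positives by specializing a rule.

    ``gain = p1 * (log2(p1/(p1+n1)) - log2(p0/(p0+n0)))`` where (p0, n0)
    and (p1, n1) are the positive/negative coverage before and after the
    added condition.  By convention the gain is 0 when ``p1 = 0``.
    """
    if p1 < 0 or n1 < 0 or p1 > p0 or n1 > n0 or p0 + n0 < 1:
        raise ValueError("invalid coverage counts")
    if p1 == 0:
        return 0.0
    if p0 == 0:
        return 0.0
    return p1 * (math.log2(p1 / (p1 + n1)) - math.log2(p0 / (p0 + n0)))


def _gain_vector(p0, n0, p1, n1):
    """Vectorized FOIL gain over candidate-threshold count arrays."""
    p1 = np.asarray(p1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        gains = p1 * (np.log2(p1 / (p1 + n1)) - math.log2(p0 / (p0 + n0)))
    gains[p1 == 0] = 0.0
    return gains


# ---------------------------------------------------------------------------
# entropy-MDL discretization (for the Johnson reducer)
# ---------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def mdl_discretize(values: np.ndarray, y01: np.ndarray) -> list[float]:
    """Entropy-based binary-recursive cut points with the MDL stopping rule.

    Returns the sorted list of accepted cut points (possibly empty: a
    feature whose class entropy never drops enough is left as one bin).
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = y01[order]

    def recurse(lo: int, hi: int, cuts: list[float]) -> None:
        n = hi - lo
        if n < 2:
            return
        seg_v, seg_y = v[lo:hi], y[lo:hi]
        boundaries = np.flatnonzero(np.diff(seg_v) > 0)
        if boundaries.size == 0:
            return
        cum1 = np.cumsum(seg_y)
        total1 = cum1[-1]
        left1 = cum1[boundaries]
        left_n = boundaries + 1
        right1 = total1 - left1
        right_n = n - left_n
        ent_parent = _entropy(np.array([total1, n - total1]))
        best_gain, best_b = -1.0, -1
        for b, l1, ln, r1, rn in zip(boundaries, left1, left_n, right1, right_n):
            e_l = _entropy(np.array([l1, ln - l1]))
            e_r = _entropy(np.array([r1, rn - r1]))
            gain = ent_parent - (ln * e_l + rn * e_r) / n
            if gain > best_gain:
                best_gain, best_b = gain, b
                best_el, best_er = e_l, e_r
        if best_b < 0:
            return
        k = len(np.unique(seg_y))
        kl = len(np.unique(seg_y[: best_b + 1]))
        kr = len(np.unique(seg_y[best_b + 1 :]))
        delta = (
            math.log2(3**k - 2)
            - (k * ent_parent - kl * best_el - kr * best_er)
        )
        threshold = (math.log2(n - 1) + delta) / n
        if best_gain <= threshold:
            return
        cut = (v[lo + best_b] + v[lo + best_b + 1]) / 2.0
        cuts.append(cut)
        recurse(lo, lo + best_b + 1, cuts)
        recurse(lo + best_b + 1, hi, cuts)

    cuts: list[float] = []
    recurse(0, len(v), cuts)
    return sorted(cuts)


# ---------------------------------------------------------------------------
# Johnson reducer
# ---------------------------------------------------------------------------

def johnson_reduce_arrays(
    X: np.ndarray, y01: np.ndarray, gene_ids: list[str]
) -> list[str]:
    """Greedy minimal-ish attribute subset discerning all coverable pairs.

    Features are considered in the given order, which should follow the RI
    ranking so ties resolve toward higher-ranked genes.
    """
    pos = np.flatnonzero(y01 == 1)
    neg = np.flatnonzero(y01 == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    bins = []
    for j in range(X.shape[1]):
        cuts = mdl_discretize(X[:, j], y01)
        bins.append(np.searchsorted(cuts, X[:, j], side="left"))
    discerns = [
        b[pos][:, None] != b[neg][None, :] for b in bins
    ]  # |P| x |N| boolean per feature
    uncovered = np.zeros((pos.size, neg.size), dtype=bool)
    for d in discerns:
        uncovered |= d
    if not uncovered.any():
        raise ValueError("classes indiscernible: no feature separates any pair")
    selected: list[str] = []
    remaining = list(range(X.shape[1]))
    while uncovered.any():
        counts = [int((discerns[j] & uncovered).sum()) for j in remaining]
        best_pos = int(np.argmax(counts))
        if counts[best_pos] == 0:
            break  # only uncoverable pairs remain
        j = remaining.pop(best_pos)
        selected.append(gene_ids[j])
        uncovered &= ~discerns[j]
    return selected


def johnson_reduce(dataset: ExpressionDataset, feature_order: list[str] | None = None) -> list[str]:
    """Johnson reduct of a labeled dataset (all of its genes considered)."""
    dataset.require_two_classes()
    genes = feature_order if feature_order is not None else list(dataset.gene_ids)
    sub = dataset.subset_genes(genes)
    return johnson_reduce_arrays(sub.values, dataset.y(), genes)


# ---------------------------------------------------------------------------
# RIPPER
# ---------------------------------------------------------------------------

def _log2_binomial(n: float, k: float) -> float:
    if k < 0 or k > n:
        return 0.0
    return float((gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / LN2)


def _theory_bits(rule: Rule, n_possible_conditions: int) -> float:
    """Description length of one rule (50% redundancy-discounted)."""
    k = len(rule.conditions)
    if k == 0:
        return 0.0
    bits = math.log2(k) if k > 1 else 0.0
    p = min(max(k / n_possible_conditions, 1e-12), 1 - 1e-12)
    bits += -k * math.log2(p) - (n_possible_conditions - k) * math.log2(1 - p)
    return 0.5 * bits


def _ruleset_dl(
    rules: list[Rule],
    X: np.ndarray,
    y_pos: np.ndarray,
    gene_index: dict[str, int],
    n_possible_conditions: int,
) -> float:
    """Total MDL of a rule list: theory bits plus exception coding.

    Exceptions follow the classical sender/receiver scheme: false positives
    are coded among the samples covered by the rules, false negatives among
    the uncovered ones, each with a count header plus a log-binomial.
    """
    covered = np.zeros(X.shape[0], dtype=bool)
    for rule in rules:
        covered |= rule.covers(X, gene_index)
    c = int(covered.sum())
    u = int(X.shape[0] - c)
    fp = int((covered & ~y_pos).sum())
    fn = int((~covered & y_pos).sum())
    data_bits = (
        math.log2(c + 1)
        + _log2_binomial(c, fp)
        + math.log2(u + 1)
        + _log2_binomial(u, fn)
    )
    theory = sum(_theory_bits(r, n_possible_conditions) for r in rules)
    return theory + data_bits


def _best_condition(
    X: np.ndarray,
    covered: np.ndarray,
    y_pos: np.ndarray,
    gene_ids: list[str],
) -> tuple[float, Condition | None, np.ndarray | None]:
    """Single condition with the highest FOIL gain on the covered samples.

    Thresholds are midpoints between consecutive distinct sorted values of
    the covered samples.  Ties break by feature order, then ``<=`` before
    ``>=``, then the smaller threshold, so growth is deterministic.
    """
    idx = np.flatnonzero(covered)
    yp = y_pos[idx]
    p0 = int(yp.sum())
    n0 = int(idx.size - p0)
    if p0 == 0:
        return 0.0, None, None
    best_gain = 0.0
    best: Condition | None = None
    for j in range(X.shape[1]):
        col = X[idx, j]
        order = np.argsort(col, kind="stable")
        v = col[order]
        yo = yp[order]
        change = np.flatnonzero(np.diff(v) > 0)
        if change.size == 0:
            continue
        cum_p = np.cumsum(yo)
        thresholds = (v[change] + v[change + 1]) / 2.0
        p_le = cum_p[change].astype(float)
        n_le = (change + 1) - p_le
        p_ge = p0 - p_le
        n_ge = n0 - n_le
        for op, p1s, n1s in (("<=", p_le, n_le), (">=", p_ge, n_ge)):
            gains = _gain_vector(p0, n0, p1s, n1s)
            b = int(np.argmax(gains))
            if gains[b] > best_gain + 1e-12:
                best_gain = float(gains[b])
                best = Condition(gene_ids[j], op, float(thresholds[b]))
    if best is None:
        return 0.0, None, None
    col = X[:, gene_ids.index(best.gene_id)]
    new_covered = covered & best.holds(col)
    return best_gain, best, new_covered


def _grow_rule(
    X: np.ndarray,
    y_pos: np.ndarray,
    gene_ids: list[str],
    target: str,
    start: list[Condition] | None = None,
) -> Rule:
    """Greedily add FOIL-gain-maximizing conditions until no negatives remain."""
    rule = Rule(conditions=list(start or []), predicted_class=target)
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    covered = rule.covers(X, gene_index) if rule.conditions else np.ones(
        X.shape[0], dtype=bool
    )
    while True:
        n_cov = int((covered & ~y_pos).sum())
        if n_cov == 0:
            break
        gain, cond, new_covered = _best_condition(X, covered, y_pos, gene_ids)
        if cond is None or gain <= 1e-12:
            break
        rule.conditions.append(cond)
        covered = new_covered
    return rule


def _prune_rule(
    rule: Rule,
    X: np.ndarray,
    y_pos: np.ndarray,
    gene_index: dict[str, int],
) -> Rule:
    """Reduced-error pruning: drop trailing conditions to maximize (p-n)/(p+n)."""
    best_rule = rule
    best_score = -np.inf
    for keep in range(len(rule.conditions), 0, -1):
        candidate = Rule(rule.conditions[:keep], rule.predicted_class)
        covered = candidate.covers(X, gene_index)
        p = int((covered & y_pos).sum())
        n = int((covered & ~y_pos).sum())
        score = (p - n) / (p + n) if p + n else -np.inf
        if score >= best_score:  # >= prefers the shorter (more pruned) rule
            best_score = score
            best_rule = candidate
    return Rule(list(best_rule.conditions), rule.predicted_class)


def _grow_prune_split(
    y_pos: np.ndarray, grow_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified growing/pruning split of the remaining samples."""
    n = y_pos.shape[0]
    grow_mask = np.zeros(n, dtype=bool)
    for cls in (True, False):
        members = np.flatnonzero(y_pos == cls)
        rng.shuffle(members)
        n_grow = max(int(round(grow_fraction * members.size)), 1) if members.size else 0
        grow_mask[members[:n_grow]] = True
    return grow_mask, ~grow_mask


def ripper(
    dataset: ExpressionDataset,
    params: RipperParams | None = None,
) -> RuleSet:
    """Learn an ordered threshold-rule list for the minority class.

    The majority class becomes the default; with one class only, the
    result is an empty rule list defaulting to that class.
    """
    params = params or RipperParams()
    params.validate()
    if dataset.labels is None:
        raise ValueError("dataset must be labeled")
    classes, counts = np.unique(dataset.labels.astype(str), return_counts=True)
    if len(classes) == 1:
        return RuleSet(rules=[], default_class=str(classes[0]))
    order = np.argsort(counts, kind="stable")  # minority first; ties by name
    target, default = str(classes[order[0]]), str(classes[order[1]])
    gene_ids = list(dataset.gene_ids)
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    X = dataset.values
    y_pos = np.asarray(dataset.labels, dtype=object) == target
    n_possible = max(2 * len(gene_ids), 2)
    rng = np.random.default_rng(params.seed)

    rules: list[Rule] = []
    active = np.ones(X.shape[0], dtype=bool)  # samples not yet covered
    min_dl = _ruleset_dl(rules, X, y_pos, gene_index, n_possible)
    while (active & y_pos).any():
        rows = np.flatnonzero(active)
        grow_mask, prune_mask = _grow_prune_split(
            y_pos[rows], params.grow_fraction, rng
        )
        grow_rows = rows[grow_mask]
        prune_rows = rows[prune_mask]
        if not y_pos[grow_rows].any():
            break
        rule = _grow_rule(X[grow_rows], y_pos[grow_rows], gene_ids, target)
        if not rule.conditions:
            break
        if prune_rows.size:
            rule = _prune_rule(rule, X[prune_rows], y_pos[prune_rows], gene_index)
        # error-rate stop on the pruning split (growing split if empty)
        check_rows = prune_rows if prune_rows.size else grow_rows
        cov = rule.covers(X[check_rows], gene_index)
        p = int((cov & y_pos[check_rows]).sum())
        n = int((cov & ~y_pos[check_rows]).sum())
        if p + n > 0 and n / (p + n) > params.max_error_rate:
            break
        dl = _ruleset_dl(rules + [rule], X, y_pos, gene_index, n_possible)
        if dl > min_dl + params.dl_slack_bits:
            break
        cov_all = rule.covers(X, gene_index)
        if int((cov_all & active & y_pos).sum()) < params.min_rule_weight:
            break
        rules.append(rule)
        min_dl = min(min_dl, dl)
        active &= ~cov_all

    rules = _optimize(
        rules, X, y_pos, gene_ids, gene_index, target, params, rng, n_possible
    )
    # final coverage bookkeeping on the full training data, in list order
    unclaimed = np.ones(X.shape[0], dtype=bool)
    final: list[Rule] = []
    for rule in rules:
        cov = rule.covers(X, gene_index) & unclaimed
        p = int((cov & y_pos).sum())
        n = int((cov & ~y_pos).sum())
        if p < params.min_rule_weight:
            continue
        unclaimed &= ~cov
        final.append(Rule(list(rule.conditions), target, p=p, n=n))
    return RuleSet(rules=final, default_class=default)


def _optimize(
    rules: list[Rule],
    X: np.ndarray,
    y_pos: np.ndarray,
    gene_ids: list[str],
    gene_index: dict[str, int],
    target: str,
    params: RipperParams,
    rng: np.random.Generator,
    n_possible: int,
) -> list[Rule]:
    """Global optimization: per rule, try a replacement and a revision.

    A variant is kept only if it lowers the total description length, so
    the accepted rule set's DL never increases across rounds.
    """
    for _ in range(params.optimization_rounds):
        for i in range(len(rules)):
            current_dl = _ruleset_dl(rules, X, y_pos, gene_index, n_possible)
            # samples this rule is responsible for: not covered by earlier rules
            earlier = np.zeros(X.shape[0], dtype=bool)
            for r in rules[:i]:
                earlier |= r.covers(X, gene_index)
            rows = np.flatnonzero(~earlier)
            if rows.size == 0 or not y_pos[rows].any():
                continue
            grow_mask, prune_mask = _grow_prune_split(
                y_pos[rows], params.grow_fraction, rng
            )
            grow_rows, prune_rows = rows[grow_mask], rows[prune_mask]
            if not y_pos[grow_rows].any():
                continue
            candidates = [rules[i]]
            replacement = _grow_rule(X[grow_rows], y_pos[grow_rows], gene_ids, target)
            revision = _grow_rule(
                X[grow_rows], y_pos[grow_rows], gene_ids, target,
                start=rules[i].conditions,
            )
            for cand in (replacement, revision):
                if cand.conditions and prune_rows.size:
                    cand = _prune_rule(
                        cand, X[prune_rows], y_pos[prune_rows], gene_index
                    )
                if cand.conditions:
                    candidates.append(cand)
            best_rule, best_dl = rules[i], current_dl
            for cand in candidates[1:]:
                trial = rules[:i] + [cand] + rules[i + 1 :]
                dl = _ruleset_dl(trial, X, y_pos, gene_index, n_possible)
                if dl < best_dl:
                    best_rule, best_dl = cand, dl
            rules = rules[:i] + [best_rule] + rules[i + 1 :]
    return rules


# ---------------------------------------------------------------------------
# application and cross-validated evaluation
# ---------------------------------------------------------------------------

def apply_rules(ruleset: RuleSet, dataset: ExpressionDataset) -> np.ndarray:
    """Predict every cell: first matching rule wins, else the default class."""
    gene_index = {g: j for j, g in enumerate(dataset.gene_ids)}
    return ruleset.predict(dataset.values, gene_index)


def evaluate_rules(
    dataset: ExpressionDataset,
    informative_genes: list[str],
    params: RipperParams | None = None,
    cv_k: int = 10,
    repeats: int = 3,
    seed: int = 0,
    fit_log: list | None = None,
):
    """Cross-validated metrics of the Johnson reducer + RIPPER combination.

    The reducer and the rule learner are refit inside every training fold;
    out-of-fold confusion counts are pooled across folds and repeats.  Each
    fitted rule set is appended to ``fit_log`` when given.
    """
    from .metrics import cross_validate

    params = params or RipperParams()
    base_positive = dataset.positive_class

    def fit_predict(X_train, y_train, X_test):
        y01 = (y_train == base_positive).astype(int)
        try:
            reduct = johnson_reduce_arrays(X_train, y01, list(informative_genes))
        except ValueError:
            # no feature discerns any pair: no rule is learnable, so fall
            # back to an empty rule list predicting the majority class
            classes, counts = np.unique(y_train.astype(str), return_counts=True)
            majority = str(classes[np.argmax(counts)])
            empty = RuleSet(rules=[], default_class=majority)
            if fit_log is not None:
                fit_log.append(empty)
            return np.full(X_test.shape[0], majority, dtype=object)
        cols = [informative_genes.index(g) for g in reduct]
        sub = ExpressionDataset(
            values=X_train[:, cols],
            gene_ids=list(reduct),
            cell_ids=[f"s{i}" for i in range(X_train.shape[0])],
            labels=y_train,
            positive_class=base_positive,
        )
        ruleset = ripper(sub, params)
        if fit_log is not None:
            fit_log.append(ruleset)
        gene_index = {g: j for j, g in enumerate(reduct)}
        return ruleset.predict(X_test[:, cols], gene_index)

    return cross_validate(
        dataset, informative_genes, fit_predict, k=cv_k, repeats=repeats,
        seed=seed,
    )
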