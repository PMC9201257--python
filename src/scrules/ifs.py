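"""Incremental feature selection over a ranked gene list.

Classifiers are evaluated on nested top-``step*i`` prefixes of the ranking
under stratified k-fold cross-validation; the prefix (and classifier) with
the best F1 is the optimal feature subset / optimal classifier.  The grid
of candidate classifiers is SVM (linear, polynomial, RBF, sigmoid kernels),
KNN (k = 1, 5, 10) and random forest (20–100 trees).

SVM and KNN see per-fold standardized inputs (the scaler is fit on training
folds only); random forests use raw expression values.  Ties on F1 are
broken toward the smaller subset, then by classifier-grid order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset import ExpressionDataset
from .mcfs import FeatureRanking, InformativeSet
from .metrics import CVResult, MetricSet, cross_validate

__all__ = [
    "ClassifierSpec",
    "IFSPoint",
    "IFSResult",
    "default_grid",
    "build_subsets",
    "run_ifs",
    "compare_informative",
]

SVM_KERNELS = ("linear", "polynomial", "RBF", "sigmoid")
KNN_K = (1, 5, 10)
RF_TREES = (20, 40, 60, 80, 100)

_KERNEL_MAP = {"linear": "linear", "polynomial": "poly",
               "RBF": "rbf", "sigmoid": "sigmoid"}


@dataclass(frozen=True)
class ClassifierSpec:
    """One point of the classifier grid: algorithm plus its tuned parameter."""

    algorithm: str  # "SVM" | "KNN" | "RF"
    kernel: str | None = None
    k: int | None = None
    n_trees: int | None = None

    def __post_init__(self) -> None:
        if self.algorithm == "SVM":
            if self.kernel not in SVM_KERNELS:
                raise ValueError(f"SVM kernel must be one of {SVM_KERNELS}")
        elif self.algorithm == "KNN":
            if not isinstance(self.k, int) or self.k < 1:
                raise ValueError("KNN needs a positive integer k")
        elif self.algorithm == "RF":
            if not isinstance(self.n_trees, int) or self.n_trees < 1:
                raise ValueError("RF needs a positive tree count")
        else:
            raise ValueError(f"unknown algorithm: {self.algorithm!r}")

    def param_string(self) -> str:
        if self.algorithm == "SVM":
            return f"kernel={self.kernel}"
        if self.algorithm == "KNN":
            return f"k={self.k}"
        return f"I={self.n_trees}"

    def label(self) -> str:
        return f"{self.algorithm}({self.param_string()})"

    def build(self, seed: int):
        """Instantiate the underlying estimator (remaining knobs at common
        defaults, recorded in run metadata)."""
        if self.algorithm == "SVM":
            return make_pipeline(
                StandardScaler(),
                SVC(kernel=_KERNEL_MAP[self.kernel], random_state=seed),
            )
        if self.algorithm == "KNN":
            return make_pipeline(
                StandardScaler(), KNeighborsClassifier(n_neighbors=self.k)
            )
        return RandomForestClassifier(
            n_estimators=self.n_trees, random_state=seed
        )

    def fit_predict_fn(self, seed: int):
        def fit_predict(X_train, y_train, X_test):
            model = self.build(seed)
            model.fit(X_train, y_train.astype(str))
            return model.predict(X_test)

        return fit_predict


def default_grid() -> list[ClassifierSpec]:
    """The full tuned-parameter grid: 4 SVM kernels, 3 k values, 5 forest sizes."""
    grid = [ClassifierSpec("SVM", kernel=k) for k in SVM_KERNELS]
    grid += [ClassifierSpec("KNN", k=k) for k in KNN_K]
    grid += [ClassifierSpec("RF", n_trees=i) for i in RF_TREES]
    return grid


@dataclass(frozen=True)
class IFSPoint:
    subset_size: int
    spec: ClassifierSpec
    metrics: MetricSet


@dataclass
class IFSResult:
    """The IFS curve(s), with per-spec and global optima selected by F1."""

    points: list[IFSPoint]
    optimal_point: IFSPoint
    optimal_features: list[str]
    per_spec_optimal: dict[str, IFSPoint] = field(default_factory=dict)


def build_subsets(
    ranking: FeatureRanking, step: int = 5, max_n: int = 5000
) -> list[int]:
    """Sizes of the nested prefixes: step, 2*step, ... up to the cap.

    Zero-RI genes are excluded from the usable ranking; if the cap is not a
    multiple of the step, a terminal prefix at the cap is appended.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    usable = len(ranking.usable_genes())
    cap = min(max_n, usable)
    if cap < 1:
        raise ValueError("ranking has no usable (positive-RI) genes")
    sizes = list(range(step, cap + 1, step))
    if not sizes or sizes[-1] != cap:
        sizes.append(cap)
    return sizes


def run_ifs(
    dataset: ExpressionDataset,
    ranking: FeatureRanking,
    specs: list[ClassifierSpec] | None = None,
    step: int = 5,
    max_n: int = 5000,
    cv_k: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> IFSResult:
    """Evaluate every classifier on every nested prefix; pick the optimum.

    The same fold assignment (derived from ``seed``) is reused across all
    subset sizes and specs so curves differ only through the feature sets.
    The global optimum maximizes F1, ties broken toward the smaller subset,
    then toward earlier grid order.
    """
    specs = specs if specs is not None else default_grid()
    usable = ranking.usable_genes()
    sizes = build_subsets(ranking, step=step, max_n=max_n)
    points: list[IFSPoint] = []
    for size in sizes:
        subset = usable[:size]
        for spec in specs:
            cv = cross_validate(
                dataset, subset, spec.fit_predict_fn(seed),
                k=cv_k, repeats=repeats, seed=seed,
            )
            points.append(IFSPoint(size, spec, cv.pooled))
    spec_order = {spec: i for i, spec in enumerate(specs)}
    best = min(
        points,
        key=lambda p: (-p.metrics.F1, p.subset_size, spec_order[p.spec]),
    )
    per_spec: dict[str, IFSPoint] = {}
    for spec in specs:
        own = [p for p in points if p.spec == spec]
        per_spec[spec.label()] = min(
            own, key=lambda p: (-p.metrics.F1, p.subset_size)
        )
    return IFSResult(
        points=points,
        optimal_point=best,
        optimal_features=usable[: best.subset_size],
        per_spec_optimal=per_spec,
    )


def compare_informative(
    dataset: ExpressionDataset,
    informative: InformativeSet,
    ifs_result: IFSResult,
    specs: list[ClassifierSpec] | None = None,
    cv_k: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> list[dict]:
    """Per-spec F1 on the informative set and the decrement vs the optimum.

    The decrement is (per-spec optimal F1) − (informative-set F1); on real
    signal it is expected to be non-negative up to cross-validation noise.
    """
    if len(informative) == 0:
        raise ValueError("informative set is empty")
    specs = specs if specs is not None else default_grid()
    rows = []
    for spec in specs:
        cv = cross_validate(
            dataset, informative.gene_ids, spec.fit_predict_fn(seed),
            k=cv_k, repeats=repeats, seed=seed,
        )
        optimal = ifs_result.per_spec_optimal[spec.label()]
        rows.append(
            {
                "classifier": spec.label(),
                "informative_f1": cv.pooled.F1,
                "optimal_f1": optimal.metrics.F1,
                "optimal_size": optimal.subset_size,
                "decrement": optimal.metrics.F1 - cv.pooled.F1,
            }
        )
    return rows
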