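"""Readers and writers for the pipeline's file formats.

Covers the tab-separated RPKM expression-table dialect used by GEO series
GSE81608 (first column gene identifier, header row of cell identifiers,
optionally gzip-compressed), two-column label tables, and the serialized
forms of rankings, IFS curves and rule sets.  All float columns are printed
at 4 decimal places in the human-oriented CSV/text forms; the JSON forms
keep full precision so every write/read round-trips.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for annotations
    from .ifs import IFSPoint
    from .mcfs import FeatureRanking, InformativeSet
    from .rules import RuleSet

FLOAT_DECIMALS = 4


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_rpkm_table(
    path: str | Path,
    orientation: str = "genes-in-rows",
) -> ExpressionDataset:
    """Read a tab-separated expression table into cells x genes orientation.

    Parameters
    ----------
    path
        TSV or TSV.gz file.  First column holds identifiers for whatever the
        rows are (genes or cells, per ``orientation``); the header row holds
        identifiers for the columns.
    orientation
        ``"genes-in-rows"`` (the GSE81608 dialect) or ``"cells-in-rows"``.

    Returns an unlabeled :class:`ExpressionDataset`; attach labels with
    :func:`attach_labels`.  Ragged rows, non-numeric cells, negative values
    and duplicate gene ids are hard errors, never silently repaired.
    """
    if orientation not in ("genes-in-rows", "cells-in-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header) - 1
        col_ids = header[1:]
        row_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols + 1:
                raise ValueError(
                    f"{path.name}:{lineno}: expected {n_cols + 1} fields, "
                    f"found {len(parts)} (ragged row)"
                )
            row_ids.append(parts[0])
            try:
                rows.append(np.array(parts[1:], dtype=float))
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric expression value"
                ) from exc
    matrix = np.vstack(rows) if rows else np.empty((0, n_cols))
    if orientation == "genes-in-rows":
        gene_ids, cell_ids = row_ids, col_ids
        matrix = matrix.T  # -> cells x genes
    else:
        gene_ids, cell_ids = col_ids, row_ids
    dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
    if dupes:
        raise ValueError(f"duplicate gene ids in {path.name}: {dupes}")
    return ExpressionDataset(
        values=matrix, gene_ids=list(gene_ids), cell_ids=list(cell_ids)
    )


def write_rpkm_table(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset as a genes-in-rows TSV (the GSE81608 dialect)."""
    frame = pd.DataFrame(
        dataset.values.T, index=dataset.gene_ids, columns=dataset.cell_ids
    )
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column cell_id,class CSV into a mapping."""
    frame = pd.read_csv(path, dtype=str)
    if frame.shape[1] != 2:
        raise ValueError("label table must have exactly two columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def write_label_table(dataset: ExpressionDataset, path: str | Path) -> None:
    if dataset.labels is None:
        raise ValueError("dataset is unlabeled")
    pd.DataFrame(
        {"cell_id": dataset.cell_ids, "class": list(dataset.labels)}
    ).to_csv(path, index=False)


def attach_labels(
    dataset: ExpressionDataset,
    label_table: dict[str, str],
    positive_class: str = "T2D",
) -> ExpressionDataset:
    """Attach per-cell class labels, aligned by cell id (not file order)."""
    missing = [c for c in dataset.cell_ids if c not in label_table]
    if missing:
        raise KeyError(f"cells missing from label table: {missing}")
    labels = np.array(
        [label_table[c] for c in dataset.cell_ids], dtype=object
    )
    classes = sorted(set(labels))
    if len(classes) > 2:
        raise ValueError(f"label table defines more than two classes: {classes}")
    out = dataset.with_labels(labels)
    out.positive_class = positive_class
    return out


# ---------------------------------------------------------------------------
# rankings and informative sets
# ---------------------------------------------------------------------------

def write_ranking(ranking: "FeatureRanking", path: str | Path) -> None:
    """Serialize a feature ranking as CSV (rank, gene_id, symbol, RI)."""
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, len(ranking.gene_ids) + 1),
            "gene_id": ranking.gene_ids,
            "symbol": ranking.symbols
            if ranking.symbols is not None
            else [""] * len(ranking.gene_ids),
            "RI": ranking.scores,
            "discardable": [int(s <= 0) for s in ranking.scores],
        }
    )
    frame.to_csv(path, index=False, float_format=f"%.{FLOAT_DECIMALS}f")


def read_ranking(path: str | Path) -> "FeatureRanking":
    from .mcfs import FeatureRanking

    frame = pd.read_csv(path, dtype={"gene_id": str, "symbol": str})
    symbols = frame["symbol"].fillna("").tolist()
    return FeatureRanking(
        gene_ids=frame["gene_id"].tolist(),
        scores=frame["RI"].to_numpy(dtype=float),
        symbols=None if all(s == "" for s in symbols) else symbols,
    )


def write_informative(info: "InformativeSet", path: str | Path) -> None:
    frame = pd.DataFrame(
        {"gene_id": info.gene_ids, "p_value": info.p_values}
    )
    frame.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# alpha={info.alpha} n_permutations={info.n_permutations}\n")
        frame.to_csv(fh, index=False)


def read_informative(path: str | Path) -> "InformativeSet":
    from .mcfs import InformativeSet

    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        frame = pd.read_csv(fh, dtype={"gene_id": str})
    return InformativeSet(
        gene_ids=frame["gene_id"].tolist(),
        p_values=frame["p_value"].to_numpy(dtype=float),
        alpha=float(meta["alpha"]),
        n_permutations=int(meta["n_permutations"]),
    )


# ---------------------------------------------------------------------------
# IFS curves
# ---------------------------------------------------------------------------

_IFS_COLUMNS = [
    "n_features", "classifier", "params",
    "SN", "SP", "ACC", "MCC", "precision", "F1",
]


def write_ifs_curve(points: "list[IFSPoint]", path: str | Path) -> None:
    """Serialize IFS curve points (one row per subset size x classifier)."""
    rows = []
    for pt in points:
        m = pt.metrics
        rows.append(
            {
                "n_features": pt.subset_size,
                "classifier": pt.spec.algorithm,
                "params": pt.spec.param_string(),
                "SN": m.SN, "SP": m.SP, "ACC": m.ACC,
                "MCC": m.MCC, "precision": m.precision, "F1": m.F1,
            }
        )
    pd.DataFrame(rows, columns=_IFS_COLUMNS).to_csv(
        path, index=False, float_format=f"%.{FLOAT_DECIMALS}f"
    )


def read_ifs_curve(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# rule sets
# ---------------------------------------------------------------------------

def format_rules(ruleset: "RuleSet", symbols: dict[str, str] | None = None) -> str:
    """Human-readable ordered rule listing with a terminal default line.

    Each condition prints as e.g. ``Gene Id 100128906 (LOC100128906) >= 2.7722``;
    the final line is ``Others -> <default class>``.
    """
    symbols = symbols or {}
    lines = []
    for i, rule in enumerate(ruleset.rules, start=1):
        conds = []
        for cond in rule.conditions:
            sym = symbols.get(cond.gene_id, "")
            tag = f"Gene Id {cond.gene_id}" + (f" ({sym})" if sym else "")
            op = "<=" if cond.operator == "<=" else ">="
            conds.append(f"{tag} {op} {cond.threshold:.{FLOAT_DECIMALS}f}")
        body = " AND ".join(conds) if conds else "(always)"
        lines.append(
            f"Rule {i}: {body} -> {rule.predicted_class} "
            f"(p={rule.p}, n={rule.n})"
        )
    lines.append(f"Others -> {ruleset.default_class}")
    return "\n".join(lines) + "\n"


def write_rules_text(
    ruleset: "RuleSet",
    path: str | Path,
    symbols: dict[str, str] | None = None,
) -> None:
    Path(path).write_text(format_rules(ruleset, symbols))


def write_rules_json(ruleset: "RuleSet", path: str | Path) -> None:
    """Machine-readable rule document; full float precision, round-trips."""
    doc = {
        "default_class": ruleset.default_class,
        "rules": [
            {
                "predicted_class": r.predicted_class,
                "p": r.p,
                "n": r.n,
                "conditions": [
                    {
                        "gene_id": c.gene_id,
                        "operator": c.operator,
                        "threshold": c.threshold,
                    }
                    for c in r.conditions
                ],
            }
            for r in ruleset.rules
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_rules_json(path: str | Path) -> "RuleSet":
    from .rules import Condition, Rule, RuleSet

    doc = json.loads(Path(path).read_text())
    rules = [
        Rule(
            conditions=[
                Condition(
                    gene_id=c["gene_id"],
                    operator=c["operator"],
                    threshold=float(c["threshold"]),
                )
                for c in r["conditions"]
            ],
            predicted_class=r["predicted_class"],
            p=int(r["p"]),
            n=int(r["n"]),
        )
        for r in doc["rules"]
    ]
    return RuleSet(rules=rules, default_class=doc["default_class"])
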