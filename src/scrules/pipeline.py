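"""End-to-end orchestration: simulate/load → rank → informative → IFS → rules.

A single declarative config (YAML-friendly dict) drives the whole run; every
stage writes its artifact into a run directory together with a manifest
capturing parameters and seeds, so a rerun with the same config reproduces
every artifact bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .dataset import ExpressionDataset
from .ifs import ClassifierSpec, default_grid, run_ifs, compare_informative
from .mcfs import MCFSParams, run_mcfs, select_informative
from .rules import RipperParams, johnson_reduce_arrays, ripper, evaluate_rules
from .simulate import SyntheticSpec, generate, write_truth

log = logging.getLogger("scrules")

ARTIFACTS = [
    "ranking.csv",
    "informative.csv",
    "ifs_curves.csv",
    "ifs_summary.json",
    "rules.txt",
    "rules.json",
    "metrics.json",
]


@dataclass
class PipelineConfig:
    """All stage settings in one place; defaults follow the reference design
    (step 5, top-5000 cap, 10-fold CV, full classifier grid, positive class
    T2D)."""

    expression_path: str | None = None
    label_path: str | None = None
    synthetic: SyntheticSpec | None = None
    mcfs: MCFSParams = field(default_factory=MCFSParams)
    n_permutations: int = 20
    alpha: float = 0.05
    ifs_step: int = 5
    ifs_max_n: int = 5000
    classifier_grid: list[ClassifierSpec] | None = None
    ripper: RipperParams = field(default_factory=RipperParams)
    cv_k: int = 10
    cv_repeats: int = 1
    rules_cv_repeats: int = 3
    positive_class: str = "T2D"
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        raw = dict(raw)
        if "synthetic" in raw and raw["synthetic"] is not None:
            from .simulate import PlantedRule

            synth = dict(raw.pop("synthetic"))
            synth["planted_de_genes"] = [
                tuple(entry) for entry in synth.get("planted_de_genes", [])
            ]
            synth["planted_rule_genes"] = [
                entry if isinstance(entry, PlantedRule) else PlantedRule(**entry)
                for entry in synth.get("planted_rule_genes", [])
            ]
            cfg.synthetic = SyntheticSpec(**synth)
        if "mcfs" in raw:
            cfg.mcfs = MCFSParams(**raw.pop("mcfs"))
        if "ripper" in raw:
            cfg.ripper = RipperParams(**raw.pop("ripper"))
        grid = raw.pop("classifier_grid", None)
        if grid is not None:
            cfg.classifier_grid = [ClassifierSpec(**g) for g in grid]
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key: {key}")
            setattr(cfg, key, value)
        return cfg


def _load_dataset(config: PipelineConfig, run_dir: Path) -> ExpressionDataset:
    if config.expression_path is not None:
        dataset = io.read_rpkm_table(config.expression_path)
        if config.label_path is None:
            raise ValueError("label_path required with expression_path")
        labels = io.read_label_table(config.label_path)
        return io.attach_labels(dataset, labels, config.positive_class)
    spec = config.synthetic or SyntheticSpec(seed=config.seed)
    dataset, truth = generate(spec)
    write_truth(truth, run_dir / "ground_truth.json")
    return dataset


def run_pipeline(config: PipelineConfig, run_dir: str | Path) -> dict:
    """Execute all stages, writing the declared artifacts plus a manifest.

    Any stage failure halts the run with the stage name; artifacts of the
    completed stages stay on disk.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "positive_class": config.positive_class,
        "stages": {},
        "artifacts": [],
    }
    stage = "load"
    try:
        dataset = _load_dataset(config, run_dir)
        dataset.positive_class = config.positive_class
        log.info("stage=load cells=%d genes=%d seed=%d",
                 dataset.n_cells, dataset.n_genes, config.seed)

        stage = "rank"
        ranking = run_mcfs(dataset, config.mcfs)
        n_zero = int(np.sum(ranking.scores <= 0))
        log.info("stage=rank seed=%d nonzero_ri=%d zero_ri_excluded=%d",
                 config.mcfs.seed, len(ranking) - n_zero, n_zero)
        io.write_ranking(ranking, run_dir / "ranking.csv")
        manifest["stages"]["rank"] = {
            "params": asdict(config.mcfs),
            "nonzero_ri": len(ranking) - n_zero,
            "zero_ri_discarded": n_zero,
        }

        stage = "informative"
        informative = select_informative(
            dataset, ranking, config.mcfs,
            n_permutations=config.n_permutations, alpha=config.alpha,
        )
        io.write_informative(informative, run_dir / "informative.csv")
        log.info("stage=informative size=%d alpha=%g", len(informative),
                 config.alpha)
        manifest["stages"]["informative"] = {
            "size": len(informative),
            "alpha": config.alpha,
            "n_permutations": config.n_permutations,
        }

        stage = "ifs"
        grid = config.classifier_grid or default_grid()
        ifs_result = run_ifs(
            dataset, ranking, grid,
            step=config.ifs_step, max_n=config.ifs_max_n,
            cv_k=config.cv_k, repeats=config.cv_repeats, seed=config.seed,
        )
        io.write_ifs_curve(ifs_result.points, run_dir / "ifs_curves.csv")
        best = ifs_result.optimal_point
        log.info("stage=ifs optimal=%s size=%d F1=%.4f",
                 best.spec.label(), best.subset_size, best.metrics.F1)
        summary = {
            "optimal_classifier": best.spec.label(),
            "optimal_size": best.subset_size,
            "optimal_metrics": best.metrics.as_dict(),
            "optimal_features": ifs_result.optimal_features,
            "per_spec": {
                label: {
                    "size": pt.subset_size,
                    "metrics": pt.metrics.as_dict(),
                }
                for label, pt in ifs_result.per_spec_optimal.items()
            },
        }
        if len(informative) > 0:
            summary["informative_comparison"] = compare_informative(
                dataset, informative, ifs_result, grid,
                cv_k=config.cv_k, repeats=config.cv_repeats, seed=config.seed,
            )
        (run_dir / "ifs_summary.json").write_text(json.dumps(summary, indent=2))
        manifest["stages"]["ifs"] = {
            "step": config.ifs_step,
            "max_n": config.ifs_max_n,
            "optimal": best.spec.label(),
            "optimal_size": best.subset_size,
        }

        stage = "rules"
        rule_genes = informative.gene_ids or ifs_result.optimal_features
        cv = evaluate_rules(
            dataset, rule_genes, config.ripper,
            cv_k=config.cv_k, repeats=config.rules_cv_repeats,
            seed=config.seed,
        )
        # final fit on all samples for the reported rule list
        y01 = dataset.y()
        sub = dataset.subset_genes(rule_genes)
        reduct = johnson_reduce_arrays(sub.values, y01, rule_genes)
        final_rules = ripper(
            dataset.subset_genes(reduct).with_labels(dataset.labels),
            config.ripper,
        )
        symbols = (
            dict(zip(dataset.gene_ids, dataset.symbols))
            if dataset.symbols
            else None
        )
        io.write_rules_text(final_rules, run_dir / "rules.txt", symbols)
        io.write_rules_json(final_rules, run_dir / "rules.json")
        log.info("stage=rules n_rules=%d default=%s cv_f1=%.4f",
                 len(final_rules), final_rules.default_class, cv.pooled.F1)
        metrics_doc = {
            "positive_class": config.positive_class,
            "rules_cv": cv.pooled.as_dict(),
            "rules_cv_per_repeat": [m.as_dict() for m in cv.per_repeat],
            "ifs_optimal": best.metrics.as_dict(),
        }
        (run_dir / "metrics.json").write_text(json.dumps(metrics_doc, indent=2))
        manifest["stages"]["rules"] = {
            "params": asdict(config.ripper),
            "n_rules": len(final_rules),
            "default_class": final_rules.default_class,
            "reduct": reduct,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest["artifacts"] = [
        name for name in ARTIFACTS if (run_dir / name).exists()
    ]
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def report(run_dir: str | Path) -> str:
    """Human-readable summary assembled purely from the run's artifacts."""
    run_dir = Path(run_dir)
    missing = [a for a in ARTIFACTS if not (run_dir / a).exists()]
    lines: list[str] = []
    ranking_path = run_dir / "ranking.csv"
    if ranking_path.exists():
        import pandas as pd

        ranking = pd.read_csv(ranking_path, nrows=10, keep_default_na=False)
        lines.append("Top-ranked genes (rank, gene_id, symbol, RI):")
        for _, row in ranking.iterrows():
            lines.append(
                f"  {int(row['rank']):>4}  {row['gene_id']}  "
                f"{row.get('symbol', '') or ''}  {row['RI']:.4f}"
            )
    summary_path = run_dir / "ifs_summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        lines.append("")
        lines.append("Per-classifier optima (classifier, n features, F1):")
        for label, entry in summary["per_spec"].items():
            lines.append(
                f"  {label:<24} {entry['size']:>6}  "
                f"{entry['metrics']['F1']:.4f}"
            )
        lines.append(
            f"Global optimum: {summary['optimal_classifier']} with "
            f"{summary['optimal_size']} features "
            f"(F1={summary['optimal_metrics']['F1']:.4f})"
        )
        if "informative_comparison" in summary:
            lines.append("")
            lines.append("Informative-set comparison (classifier, F1, decrement):")
            for row in summary["informative_comparison"]:
                lines.append(
                    f"  {row['classifier']:<24} {row['informative_f1']:.4f}  "
                    f"{row['decrement']:+.4f}"
                )
    rules_path = run_dir / "rules.txt"
    if rules_path.exists():
        lines.append("")
        lines.append("Rule listing:")
        lines.append(rules_path.read_text().rstrip())
    else:
        lines.append("")
        lines.append("Rules: not run")
    if missing:
        lines.append("")
        lines.append(f"Missing artifacts: {missing}")
    return "\n".join(lines) + "\n"
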