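"""End-to-end pipeline orchestration.

``run_pipeline`` executes the full modelling sequence on one compound
table: descriptor filtration → Spearman intercorrelation pruning →
chemical-space construction and outlier designation → random train/test
split → candidate subset selection (GFA + RFE, or user-supplied subsets) →
per-subset grid search → hierarchical-ensemble construction → the
validation battery and combined criteria report.  Every artefact is
written to the output directory together with a manifest; every consumed
seed is logged so any run can be replayed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .ensemble import default_meta_grid
from .feature_selection import GFAConfig, gfa_select, rfe_select
from .metrics import CriteriaThresholds
from .model import HSVR, HSVRResults
from .partition import (
    build_chemical_space,
    similarity_report,
    split_train_test,
    tukey_outlier_mask,
)
from .preprocess import (
    apply_normalization,
    drop_uninformative,
    fit_normalization,
    prune_intercorrelated,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run (all thresholds at their defaults
    mirror the modelling protocol described in the package docs)."""

    output_dir: str = "permsvr_out"
    seed: int = 0
    # preprocessing
    r2_max: float = 0.64
    min_distinct: int = 3
    # partition
    pca_components: int = 3
    split_ratio: float = 0.8
    outlier_iqr_factor: float = 3.0
    # selection: explicit subsets bypass GFA/RFE
    candidate_subsets: list | None = None
    gfa: GFAConfig = field(default_factory=GFAConfig)
    rfe_tolerance: float = 0.0
    n_subsets: int = 3
    # modelling
    grid: dict | None = None
    meta_grid: dict | None = None
    max_members: int = 4
    cv_folds: int = 5
    thresholds: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    yscramble_rounds: int = 25


def _stage(log: list[str], msg: str) -> None:
    log.append(msg)


def run_pipeline(table: pio.CompoundTable, config: PipelineConfig) -> HSVRResults:
    """Run the complete modelling pipeline on one compound table."""
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed: {cfg.seed}"]
    y_all = table.response
    if np.any(np.isnan(y_all)):
        raise RuntimeError("pipeline stage 'input': table has missing responses")

    # 1. descriptor filtration
    try:
        table_f, drop_report = drop_uninformative(
            table, min_distinct=cfg.min_distinct, return_report=True
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'filtration' failed: {exc}") from exc
    _stage(log, f"filtration: kept {len(table_f.descriptor_names)} descriptors, "
                f"dropped {len(drop_report)}")

    # 2. intercorrelation pruning
    try:
        kept, removals = prune_intercorrelated(
            table_f, y_all, r2_max=cfg.r2_max, return_report=True
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'pruning' failed: {exc}") from exc
    table_p = table_f.subset_descriptors(kept)
    pd.DataFrame(
        [{"removed": r.removed, "kept": r.kept, "rho2": r.rho2} for r in removals]
    ).to_csv(out / "pruning_report.csv", index=False)
    _stage(log, f"pruning: {len(kept)} descriptors survive rho2 < {cfg.r2_max}")

    # 3. chemical space + outliers (normalized descriptors)
    stats = fit_normalization(table_p)
    normed = apply_normalization(stats, table_p)
    space = build_chemical_space(normed, k=min(cfg.pca_components, len(kept)))
    outlier_mask = tukey_outlier_mask(space.scores, factor=cfg.outlier_iqr_factor)
    outlier_ids = [cid for cid, m in zip(table_p.ids, outlier_mask) if m]
    core_ids = [cid for cid, m in zip(table_p.ids, outlier_mask) if not m]
    space.scores.to_csv(out / "chemical_space.csv")
    _stage(log, f"chemical space: {space.k} components explain "
                f"{space.explained_variance_ratio.sum():.1%} of variance; "
                f"{len(outlier_ids)} outliers")

    # 4. split
    split = split_train_test(core_ids, ratio=cfg.split_ratio, seed=cfg.seed)
    split.outlier_ids = outlier_ids
    for name, ids in (
        ("train_ids.txt", split.train_ids),
        ("test_ids.txt", split.test_ids),
        ("outlier_ids.txt", outlier_ids),
    ):
        (out / name).write_text("\n".join(ids) + ("\n" if ids else ""))
    _stage(log, f"split: {len(split.train_ids)}/{len(split.test_ids)} "
                f"train/test at ratio {cfg.split_ratio} (seed {cfg.seed})")

    train = table_p.select_rows(split.train_ids)
    test = table_p.select_rows(split.test_ids)
    similarity_report(split, table_p, y_all).to_csv(out / "similarity_report.csv")

    # 5. subset selection
    if cfg.candidate_subsets is not None:
        subsets = [tuple(s) for s in cfg.candidate_subsets]
        _stage(log, f"selection: {len(subsets)} user-supplied subsets")
    else:
        try:
            archive = gfa_select(train, train.response, config=cfg.gfa, seed=cfg.seed)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'gfa' failed: {exc}") from exc
        pd.DataFrame(
            [
                {"subset": "|".join(c.names), "fitness": c.fitness, "generation": c.generation}
                for c in archive
            ]
        ).to_csv(out / "gfa_archive.csv", index=False)
        subsets = []
        for cand in archive:
            refined = rfe_select(
                train, train.response, cand.names,
                tolerance=cfg.rfe_tolerance, cv_folds=cfg.cv_folds, seed=cfg.seed,
            )
            if refined not in subsets:
                subsets.append(refined)
            if len(subsets) >= cfg.n_subsets:
                break
        _stage(log, f"selection: GFA archive {len(archive)}, "
                    f"{len(subsets)} refined subsets")

    # 6-7. grid search + ensemble + validation via the model object
    model = HSVR(
        train,
        test,
        candidate_subsets=subsets,
        grid=cfg.grid,
        meta_grid=cfg.meta_grid or default_meta_grid(),
        thresholds=cfg.thresholds,
        max_members=cfg.max_members,
        cv_folds=cfg.cv_folds,
    )
    results = model.fit(seed=cfg.seed, yscramble_rounds=cfg.yscramble_rounds)

    pio.write_predictions(results.training_predictions, out / "train_predictions.csv")
    pio.write_predictions(results.test_predictions, out / "test_predictions.csv")
    results.save(out / "hsvr_model.bin")
    metrics = {
        "training": results.training_report.to_dict(),
        "test": results.test_report.to_dict(),
        "conforming": results.conforming,
        "build_report": results.ensemble.build_report,
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))
    criteria_txt = (
        "training\n" + results.verdicts["training"].to_table()
        + "\n\nexternal\n" + results.verdicts["external"].to_table() + "\n"
    )
    (out / "criteria_report.txt").write_text(criteria_txt)
    _stage(log, f"ensemble: {len(results.ensemble.members)} members, "
                f"conforming={results.conforming}, "
                f"test q2={results.test_report.r2:.3f}")

    (out / "manifest.txt").write_text("\n".join(log) + "\n")
    return results
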