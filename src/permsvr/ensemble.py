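"""Hierarchical SVR: base-learner ensemble plus meta-SVR stacking.

A hierarchical model consists of 2–4 base SVR learners (the SVR ensemble,
each typically trained on a different descriptor subset) and a meta-SVR
regressing the observed response on the base learners' predictions.  The
ensemble is grown by Occam's razor: all two-member combinations are tried
in candidate-rank order and the first whose statistics pass the combined
validation criteria on training (including leave-one-out agreement) and
test is accepted; only if every pair fails are three- and four-member
combinations considered.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CompoundTable, PredictionSet
from .metrics import (
    CriteriaThresholds,
    MetricsReport,
    check_criteria,
    external_report,
    loo_cv,
    r2_q2,
    training_report,
)
from .svr import GridResult, SVRSpec, TrainedSVR, grid_search, train_svr

__all__ = [
    "HSVREnsemble",
    "stack_features",
    "fit_ensemble",
    "build_ensemble",
    "predict_ensemble",
    "default_meta_grid",
]

_META_PREFIX = "member_"


def default_meta_grid() -> dict:
    """Compact grid for the meta learner (a 2–4 dimensional problem)."""
    return {
        "C_values": [0.1, 1.0, 10.0, 100.0],
        "gamma_values": [0.01, 0.1, 0.5, 1.0, 2.0],
        "epsilon_values": [0.05, 0.1],
        "nu_values": [],
    }


@dataclass
class HSVREnsemble:
    """Ordered base learners plus the meta learner stacked on top."""

    members: list[TrainedSVR]
    meta: TrainedSVR
    build_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if len(self.meta.subset) != len(self.members):
            raise ValueError("meta input dimension must equal member count")

    @property
    def member_subsets(self) -> list[tuple[str, ...]]:
        return [m.subset for m in self.members]

    @property
    def required_descriptors(self) -> list[str]:
        seen: list[str] = []
        for sub in self.member_subsets:
            for name in sub:
                if name not in seen:
                    seen.append(name)
        return seen

    def predict(self, table: CompoundTable) -> np.ndarray:
        stacked = stack_features(self.members, table)
        return self.meta.predict(stacked)


def stack_features(members: Sequence[TrainedSVR], table: CompoundTable) -> CompoundTable:
    """Base predictions as a meta-input table (column j = member j)."""
    cols = {}
    for j, member in enumerate(members):
        try:
            cols[f"{_META_PREFIX}{j + 1}"] = member.predict(table)
        except Exception as exc:
            raise RuntimeError(f"member {j + 1} failed to predict: {exc}") from exc
    stacked = pd.DataFrame(cols, index=table.descriptors.index)
    return CompoundTable._from_parts(table.records, stacked)


def predict_ensemble(model: HSVREnsemble, table: CompoundTable) -> PredictionSet:
    yhat = model.predict(table)
    return PredictionSet(table.ids, table.response, yhat)


def fit_ensemble(
    train: CompoundTable,
    response: np.ndarray,
    member_specs: Sequence[SVRSpec],
    meta_spec: SVRSpec,
) -> HSVREnsemble:
    """Refit an ensemble with fixed hyperparameters on given data.

    Used by leave-one-out cross-validation and Y-scrambling, which must
    re-train the final architecture without re-searching anything.
    """
    members = [train_svr(train, response, spec) for spec in member_specs]
    stacked = stack_features(members, train)
    meta = train_svr(stacked, response, meta_spec)
    return HSVREnsemble(members=members, meta=meta)


def _oof_stack(
    members: Sequence[TrainedSVR],
    train: CompoundTable,
    response: np.ndarray,
    cv_folds: int,
    seed: int,
) -> CompoundTable:
    """Out-of-fold base predictions: each member is refitted with its own
    hyperparameters on k−1 folds and predicts the held-out fold, so no
    stacked value comes from a model that saw the compound."""
    from sklearn.model_selection import KFold

    ids = train.ids
    n = train.n
    oof = np.empty((n, len(members)))
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for tr_idx, te_idx in kf.split(np.arange(n)):
        sub = train.select_rows([ids[i] for i in tr_idx])
        held = train.select_rows([ids[i] for i in te_idx])
        for j, member in enumerate(members):
            refit = train_svr(sub, response[tr_idx], member.spec)
            oof[te_idx, j] = refit.predict(held)
    cols = pd.DataFrame(
        {f"{_META_PREFIX}{j + 1}": oof[:, j] for j in range(len(members))},
        index=train.descriptors.index,
    )
    return CompoundTable._from_parts(train.records, cols)


def _fit_meta(
    members: list[TrainedSVR],
    train: CompoundTable,
    response: np.ndarray,
    meta_grid: dict,
    cv_folds: int,
    seed: int,
    stacking: str = "insample",
) -> TrainedSVR:
    """Grid-search and fit the meta learner.

    Hyperparameters are always selected by cross-validation on out-of-fold
    base predictions (selection on in-sample predictions would leak: the
    members have seen every validation fold).  The final meta fit uses
    in-sample member predictions by default; ``stacking="oof"`` trains it
    on the out-of-fold predictions instead.
    """
    if stacking not in ("insample", "oof"):
        raise ValueError(f"unknown stacking mode {stacking!r}")
    oof = _oof_stack(members, train, response, cv_folds, seed)
    ranked = grid_search(
        oof, response, grid=meta_grid, cv_folds=cv_folds, seed=seed, top=1
    )
    best = ranked[0]
    fit_table = oof if stacking == "oof" else stack_features(members, train)
    meta = train_svr(fit_table, response, best.spec)
    meta.cv_rmse = best.cv_rmse
    return meta


def build_ensemble(
    candidates: Sequence[TrainedSVR],
    train: CompoundTable,
    test: CompoundTable,
    response: np.ndarray | None = None,
    test_response: np.ndarray | None = None,
    meta_grid: dict | None = None,
    thresholds: CriteriaThresholds | None = None,
    max_members: int = 4,
    seed: int = 0,
    cv_folds: int = 5,
    convention: str = "strict",
    stacking: str = "insample",
) -> HSVREnsemble:
    """Grow the hierarchical model per Occam's razor.

    Member combinations of size 2 are enumerated in candidate-rank order;
    for each, a meta-SVR is grid-searched on the stacked training
    predictions and the resulting hierarchical model is scored by the
    combined validation criteria — external criteria on the test set
    first (cheap), then the training-set criteria including the LOO
    agreement (expensive, so only evaluated for externally conforming
    combinations).  The first combination passing everything is accepted;
    failing that, sizes 3 then 4 are tried; if nothing conforms, the
    combination with the highest test q² is returned flagged
    ``conforming=False`` in its build report.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate base learners")
    y_tr = np.asarray(response if response is not None else train.response, dtype=float)
    y_te = np.asarray(
        test_response if test_response is not None else test.response, dtype=float
    )
    if np.any(np.isnan(y_tr)) or np.any(np.isnan(y_te)):
        raise ValueError("training and test responses must be fully observed")
    meta_grid = meta_grid or default_meta_grid()
    th = thresholds or CriteriaThresholds()

    trials: list[dict] = []
    fallback = None  # (test_q2, ensemble, trial_record)

    max_members = min(max_members, len(candidates))
    for size in range(2, max_members + 1):
        for combo in itertools.combinations(range(len(candidates)), size):
            members = [candidates[i] for i in combo]
            meta = _fit_meta(
                members, train, y_tr, meta_grid, cv_folds, seed, stacking=stacking
            )
            ensemble = HSVREnsemble(members=members, meta=meta)

            pred_tr = PredictionSet(train.ids, y_tr, ensemble.predict(train))
            pred_te = PredictionSet(test.ids, y_te, ensemble.predict(test))
            rep_te = external_report(pred_te, y_tr, convention=convention)
            ext_verdict = check_criteria(external=rep_te, thresholds=th)["external"]

            record = {
                "members": [list(m.subset) for m in members],
                "combo": list(combo),
                "test_q2": rep_te.r2,
                "external_pass": ext_verdict.overall_pass,
                "training_pass": None,
            }

            accepted = False
            rep_tr = None
            if ext_verdict.overall_pass:
                member_specs = [m.spec for m in members]
                qcv2 = loo_cv(
                    train,
                    y_tr,
                    lambda tb, yy: fit_ensemble(tb, yy, member_specs, meta.spec),
                    convention=convention,
                )
                rep_tr = training_report(pred_tr, qcv2=qcv2, convention=convention)
                tr_verdict = check_criteria(training=rep_tr, thresholds=th)["training"]
                record["training_pass"] = tr_verdict.overall_pass
                record["qcv2"] = qcv2
                accepted = tr_verdict.overall_pass
            trials.append(record)

            if fallback is None or rep_te.r2 > fallback[0]:
                fallback = (rep_te.r2, ensemble, record)

            if accepted:
                ensemble.build_report = _make_report(
                    candidates, trials, record, conforming=True, members=members
                )
                return ensemble
        # only grow the ensemble when every smaller combination failed

    test_q2, ensemble, record = fallback
    ensemble.build_report = _make_report(
        candidates, trials, record, conforming=False, members=ensemble.members
    )
    return ensemble


def _make_report(candidates, trials, accepted_record, conforming, members) -> dict:
    distinct = {m.subset for m in members}
    report = {
        "n_candidates": len(candidates),
        "candidate_subsets": [list(c.subset) for c in candidates],
        "trials": trials,
        "accepted": accepted_record,
        "conforming": conforming,
        "member_count": len(members),
    }
    if len(distinct) < len(members):
        report["zero_diversity"] = True
    return report
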