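"""Model-object interface: ``HSVR`` (the model) and ``HSVRResults``.

``HSVR`` bundles a training table, an external test table and a list of
candidate descriptor subsets; ``fit`` grid-searches a base SVR per subset,
ranks the fitted candidates by external q², builds the hierarchical
ensemble under the combined validation criteria, and returns an
``HSVRResults`` carrying the ensemble, the full statistics battery for
both sets, the criteria verdicts and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as pio
from .ensemble import HSVREnsemble, build_ensemble, default_meta_grid, fit_ensemble
from .metrics import (
    CriteriaThresholds,
    CriteriaVerdict,
    MetricsReport,
    check_criteria,
    external_report,
    loo_cv,
    r2_q2,
    training_report,
    y_scramble,
)
from .io import CompoundTable, PredictionSet
from .svr import TrainedSVR, grid_search, predict_svr, train_svr

__all__ = ["HSVR", "HSVRResults", "CandidateFit"]


@dataclass
class CandidateFit:
    """One fitted base-learner candidate with its external score."""

    model: TrainedSVR
    test_q2: float
    training_r2: float


class HSVR:
    """Hierarchical SVR model over a training and an external test table.

    Parameters
    ----------
    train, test : CompoundTable
        Tables with observed log Peff responses.
    candidate_subsets : sequence of descriptor-name sequences
        One base-learner candidate is grid-searched per subset; ``None``
        uses the full descriptor set as a single (degenerate) subset.
    grid, meta_grid : dict, optional
        Hyperparameter grids for base and meta learners.
    thresholds : CriteriaThresholds, optional
        Combined validation-criteria thresholds.
    """

    def __init__(
        self,
        train: CompoundTable,
        test: CompoundTable,
        candidate_subsets=None,
        grid: dict | None = None,
        meta_grid: dict | None = None,
        thresholds: CriteriaThresholds | None = None,
        max_members: int = 4,
        cv_folds: int = 5,
        convention: str = "strict",
    ):
        if np.any(np.isnan(train.response)) or np.any(np.isnan(test.response)):
            raise ValueError("training and test tables need observed responses")
        self.train = train
        self.test = test
        if candidate_subsets is None:
            candidate_subsets = [tuple(train.descriptor_names)]
        self.candidate_subsets = [tuple(s) for s in candidate_subsets]
        self.grid = grid
        self.meta_grid = meta_grid or default_meta_grid()
        self.thresholds = thresholds or CriteriaThresholds()
        self.max_members = max_members
        self.cv_folds = cv_folds
        self.convention = convention

    @classmethod
    def from_dataframes(
        cls,
        train: pd.DataFrame,
        test: pd.DataFrame,
        response_column: str = "log_peff",
        id_column: str = "compound_id",
        **kwargs,
    ) -> "HSVR":
        def to_table(df: pd.DataFrame) -> CompoundTable:
            df = df.reset_index() if id_column == df.index.name else df
            records = [
                pio.CompoundRecord(str(r[id_column]), log_peff=float(r[response_column]))
                for _, r in df.iterrows()
            ]
            desc = df.drop(columns=[id_column, response_column])
            return CompoundTable(records, desc)

        return cls(to_table(train), to_table(test), **kwargs)

    def fit(self, seed: int = 0, yscramble_rounds: int = 0) -> "HSVRResults":
        """Grid-search candidates, build the ensemble, assemble results."""
        y_tr, y_te = self.train.response, self.test.response

        fits: list[CandidateFit] = []
        for subset in self.candidate_subsets:
            ranked = grid_search(
                self.train, y_tr, subset=subset, grid=self.grid,
                cv_folds=self.cv_folds, seed=seed, top=1,
            )
            model = train_svr(self.train, y_tr, ranked[0].spec)
            model.cv_rmse = ranked[0].cv_rmse
            pred_te = PredictionSet(self.test.ids, y_te, model.predict(self.test))
            pred_tr = PredictionSet(self.train.ids, y_tr, model.predict(self.train))
            fits.append(
                CandidateFit(
                    model,
                    test_q2=r2_q2(pred_te, convention=self.convention),
                    training_r2=r2_q2(pred_tr, convention=self.convention),
                )
            )
        # rank candidates by external performance (deduplicated by subset
        # upstream: one candidate per subset); ties by CV-RMSE
        fits.sort(key=lambda f: (-f.test_q2, f.model.cv_rmse))

        ensemble = build_ensemble(
            [f.model for f in fits],
            self.train,
            self.test,
            meta_grid=self.meta_grid,
            thresholds=self.thresholds,
            max_members=self.max_members,
            seed=seed,
            cv_folds=self.cv_folds,
            convention=self.convention,
        )

        pred_tr = PredictionSet(self.train.ids, y_tr, ensemble.predict(self.train))
        pred_te = PredictionSet(self.test.ids, y_te, ensemble.predict(self.test))

        member_specs = [m.spec for m in ensemble.members]
        meta_spec = ensemble.meta.spec

        def factory(tb, yy):
            return fit_ensemble(tb, yy, member_specs, meta_spec)

        # the accepted combination's LOO was already computed during the
        # criteria-gated build; recompute only for non-conforming fallbacks
        qcv2 = ensemble.build_report.get("accepted", {}).get("qcv2")
        if qcv2 is None:
            qcv2 = loo_cv(self.train, y_tr, factory, convention=self.convention)
        rs2_mean = None
        rs2_rounds = None
        if yscramble_rounds:
            rs2_mean, rs2_rounds = y_scramble(
                self.train, y_tr, factory, n_rounds=yscramble_rounds,
                seed=seed, convention=self.convention,
            )

        rep_tr = training_report(
            pred_tr, qcv2=qcv2, rs2_mean=rs2_mean, convention=self.convention
        )
        rep_te = external_report(pred_te, y_tr, convention=self.convention)
        verdicts = check_criteria(
            training=rep_tr, external=rep_te, thresholds=self.thresholds
        )
        return HSVRResults(
            model=self,
            ensemble=ensemble,
            candidates=fits,
            training_predictions=pred_tr,
            test_predictions=pred_te,
            training_report=rep_tr,
            test_report=rep_te,
            verdicts=verdicts,
            rs2_rounds=rs2_rounds,
            seed=seed,
        )


@dataclass
class HSVRResults:
    """Fitted hierarchical model with its validation statistics."""

    model: HSVR
    ensemble: HSVREnsemble
    candidates: list[CandidateFit]
    training_predictions: PredictionSet
    test_predictions: PredictionSet
    training_report: MetricsReport
    test_report: MetricsReport
    verdicts: dict[str, CriteriaVerdict]
    rs2_rounds: np.ndarray | None = None
    seed: int = 0

    @property
    def conforming(self) -> bool:
        """Whether the accepted ensemble passed every applicable criterion."""
        return bool(self.ensemble.build_report.get("conforming", False))

    @property
    def best_candidate_test_q2(self) -> float:
        return max(f.test_q2 for f in self.candidates)

    def predict(self, table: CompoundTable) -> np.ndarray:
        return self.ensemble.predict(table)

    def save(self, path) -> None:
        pio.save_ensemble(self.ensemble, path)

    def summary(self) -> str:
        tr, te = self.training_report, self.test_report
        rows = [
            ("n", tr.n, te.n),
            ("r2 / q2", tr.r2, te.r2),
            ("RMSE", tr.rmse, te.rmse),
            ("MAE", tr.mae, te.mae),
            ("s", tr.s, te.s),
            ("Delta_max", tr.delta_max, te.delta_max),
            ("mean residual", tr.mean_residual, te.mean_residual),
            ("qCV2 (LOO)", tr.qcv2, None),
            ("<rs2> (Y-scrambling)", tr.rs2_mean, None),
            ("qF1^2", None, te.qf12),
            ("qF2^2", None, te.qf22),
            ("qF3^2", None, te.qf32),
            ("CCC", None, te.ccc),
            ("ro2", tr.ro2, te.ro2),
            ("k", tr.k, te.k),
            ("rm2", tr.rm2, te.rm2),
            ("<rm2>", tr.rm2_mean, te.rm2_mean),
            ("delta rm2", tr.rm2_delta, te.rm2_delta),
        ]

        def fmt(v):
            return "    --" if v is None else f"{v:6.3f}"

        lines = [
            "Hierarchical SVR results",
            "=" * 54,
            f"members: {len(self.ensemble.members)}  "
            f"(subsets: {['/'.join(s) for s in self.ensemble.member_subsets]})",
            f"conforming to combined criteria: {self.conforming}",
            "-" * 54,
            f"{'statistic':<24}{'training':>12}{'test':>12}",
        ]
        for name, a, b in rows:
            lines.append(f"{name:<24}{fmt(a):>12}{fmt(b):>12}")
        lines.append("-" * 54)
        lines.append("criteria (training):")
        lines.append(self.verdicts["training"].to_table())
        lines.append("criteria (test):")
        lines.append(self.verdicts["external"].to_table())
        return "\n".join(lines)
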