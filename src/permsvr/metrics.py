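"""External-validation statistics battery for QSAR regression models.

Implements the residual summaries (RMSE, MAE, s, Δmax), the squared
correlation r²/q², the origin-constrained Golbraikh–Tropsha statistics
(ro², r'o², slope k), the Roy rm² family, the external predictivity
coefficients qF1²/qF2²/qF3², Lin's concordance correlation coefficient
(CCC), leave-one-out cross-validation, Y-scrambling, and the combined
acceptance-criteria checker.

Two conventions for the squared correlation are provided.  The default
("strict") computes 1 − Σ(ŷ−y)²/Σ(y−⟨ŷ⟩)², i.e. the total sum of squares
is taken about the mean *predicted* value; ``convention="classic"`` uses
the textbook definition with ⟨y⟩.  For a well-fitted model the two are
nearly identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Callable, Sequence

import numpy as np

from .io import CompoundTable, PredictionSet

__all__ = [
    "MetricsReport",
    "CriteriaVerdict",
    "CriterionResult",
    "CriteriaThresholds",
    "basic_metrics",
    "r2_q2",
    "origin_stats",
    "rm2_family",
    "rm2_mean_delta",
    "external_metrics",
    "loo_cv",
    "y_scramble",
    "training_report",
    "external_report",
    "check_criteria",
]


# ---------------------------------------------------------------------------
# report containers
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """All validation statistics for one (observed, predicted) pairing.

    ``context`` is "training" or "external"; the q-family external fields
    (qf12, qf22, qf32, ccc) and the resampling fields (qcv2, rs2_mean) are
    populated only where they apply.
    """

    context: str
    n: int
    r2: float | None = None          # r² (training) or q² (external)
    rmse: float | None = None
    mae: float | None = None
    s: float | None = None           # sample SD of absolute residuals
    delta_max: float | None = None
    mean_residual: float | None = None
    ro2: float | None = None
    ro2_prime: float | None = None
    k: float | None = None
    k_prime: float | None = None
    rm2: float | None = None
    rm2_prime: float | None = None
    rm2_mean: float | None = None
    rm2_delta: float | None = None
    qcv2: float | None = None        # LOO cross-validated q² (training only)
    rs2_mean: float | None = None    # mean Y-scrambling r² (training only)
    qf12: float | None = None
    qf22: float | None = None
    qf32: float | None = None
    ccc: float | None = None
    n_tr: int | None = None
    n_ext: int | None = None
    mean_y_tr: float | None = None
    mean_y_ext: float | None = None
    mean_yhat_ext: float | None = None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class CriterionResult:
    name: str
    description: str
    applicable: bool
    passed: bool | None
    observed: dict


@dataclass
class CriteriaVerdict:
    """Outcome of the combined acceptance-criteria check.

    ``overall_pass`` is true iff every applicable criterion passes;
    not-applicable entries (LOO agreement for external sets, CCC for the
    training set) are excluded, mirroring standard practice.
    """

    results: list[CriterionResult]

    @property
    def overall_pass(self) -> bool:
        return all(r.passed for r in self.results if r.applicable)

    def __getitem__(self, name: str) -> CriterionResult:
        for r in self.results:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_table(self) -> str:
        lines = [f"{'criterion':<28}{'status':<8}detail"]
        for r in self.results:
            status = "N/A" if not r.applicable else ("pass" if r.passed else "FAIL")
            detail = ", ".join(f"{k}={v:.3g}" for k, v in r.observed.items())
            lines.append(f"{r.name:<28}{status:<8}{detail}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def _check_pred(pred: PredictionSet, minimum: int = 2) -> None:
    if pred.n < minimum:
        raise ValueError(f"need at least {minimum} points, got {pred.n}")


def basic_metrics(pred: PredictionSet) -> MetricsReport:
    """Residual summaries: RMSE, MAE, s, Δmax and the mean residual.

    ``s`` is the sample standard deviation (n−1 denominator) of the
    absolute residuals, which satisfies RMSE² = MAE² + ((n−1)/n)·s².
    """
    _check_pred(pred)
    delta = pred.residuals
    n = pred.n
    rmse = float(np.sqrt(np.sum(delta**2) / n))
    mae = float(np.mean(np.abs(delta)))
    s = float(np.std(np.abs(delta), ddof=1))
    return MetricsReport(
        context="partial",
        n=n,
        rmse=rmse,
        mae=mae,
        s=s,
        delta_max=float(np.max(np.abs(delta))),
        mean_residual=float(np.mean(delta)),
    )


def s_from_rmse_mae(rmse: float, mae: float, n: int) -> float:
    """Recover s (sample SD of absolute residuals) from RMSE, MAE and n.

    Inverts RMSE² = MAE² + ((n−1)/n)·s²; useful for cross-checking
    published error summaries.
    """
    gap = rmse**2 - mae**2
    if gap < 0:
        raise ValueError("RMSE must be at least MAE")
    return float(np.sqrt(n * gap / (n - 1)))


def r2_q2(pred: PredictionSet, convention: str = "strict") -> float:
    """Squared correlation r² (training) / q² (external).

    ``strict`` (default): 1 − Σ(ŷ−y)² / Σ(y−⟨ŷ⟩)², with the denominator
    about the mean prediction.  ``classic``: denominator about ⟨y⟩.
    """
    _check_pred(pred)
    y, yhat = pred.observed, pred.predicted
    centre = yhat.mean() if convention == "strict" else y.mean()
    denom = np.sum((y - centre) ** 2)
    if denom == 0:
        raise ValueError("zero denominator: observed values coincide with centre")
    return float(1.0 - np.sum((yhat - y) ** 2) / denom)


def origin_stats(pred: PredictionSet) -> tuple[float, float, float, float]:
    """Origin-constrained regression statistics (ro², r'o², k, k').

    k is the slope of the no-intercept fit of predicted-vs-observed data
    (k = Σyŷ/Σŷ²); ro² scores the observations against k·ŷ.  The primed
    quantities swap the roles of observed and predicted.
    """
    _check_pred(pred)
    y, yhat = pred.observed, pred.predicted
    if np.sum(yhat**2) == 0 or np.sum(y**2) == 0:
        raise ValueError("zero sum of squares: origin regression undefined")
    k = float(np.sum(y * yhat) / np.sum(yhat**2))
    k_prime = float(np.sum(y * yhat) / np.sum(y**2))
    d1 = np.sum((y - y.mean()) ** 2)
    d2 = np.sum((yhat - yhat.mean()) ** 2)
    if d1 == 0 or d2 == 0:
        raise ValueError("constant observed or predicted values")
    ro2 = float(1.0 - np.sum((y - k * yhat) ** 2) / d1)
    ro2_prime = float(1.0 - np.sum((yhat - k_prime * y) ** 2) / d2)
    return ro2, ro2_prime, k, k_prime


def rm2_family(
    r2_like: float, ro2: float, ro2_prime: float
) -> tuple[float, float, float, float]:
    """Roy rm² statistics: rm², r'm², their mean and absolute difference.

    rm² = r²(1 − |r² − ro²|) and r'm² = r²(1 − |r² − r'o²|).
    """
    rm2 = r2_like * (1.0 - abs(r2_like - ro2))
    rm2_prime = r2_like * (1.0 - abs(r2_like - ro2_prime))
    return rm2, rm2_prime, (rm2 + rm2_prime) / 2.0, abs(rm2 - rm2_prime)


def rm2_mean_delta(rm2: float, rm2_prime: float) -> tuple[float, float]:
    """⟨rm²⟩ and Δrm² from an (rm², r'm²) pair: their mean and absolute
    difference.  Useful when the pair is given directly (e.g. from a
    published table) rather than derived from r²/ro²."""
    return (rm2 + rm2_prime) / 2.0, abs(rm2 - rm2_prime)


def external_metrics(
    pred_ext: PredictionSet, train_observed: np.ndarray
) -> tuple[float, float, float, float]:
    """External predictivity coefficients qF1², qF2², qF3² and CCC.

    qF1² references the external deviations to the training mean ⟨y_TR⟩,
    qF2² to the external mean ⟨y_EXT⟩, and qF3² compares per-compound
    external error with per-compound training variance.  CCC is Lin's
    concordance correlation coefficient.
    """
    _check_pred(pred_ext)
    y_tr = np.asarray(train_observed, dtype=float)
    if len(y_tr) < 2:
        raise ValueError("need at least two training observations")
    y, yhat = pred_ext.observed, pred_ext.predicted
    n_ext, n_tr = pred_ext.n, len(y_tr)
    press = np.sum((y - yhat) ** 2)

    d_f1 = np.sum((y - y_tr.mean()) ** 2)
    d_f2 = np.sum((y - y.mean()) ** 2)
    d_f3 = np.sum((y_tr - y_tr.mean()) ** 2)
    if d_f1 == 0 or d_f2 == 0 or d_f3 == 0:
        raise ValueError("zero denominator in external predictivity coefficient")
    qf12 = float(1.0 - press / d_f1)
    qf22 = float(1.0 - press / d_f2)
    qf32 = float(1.0 - (press / n_ext) / (d_f3 / n_tr))

    dy = y - y.mean()
    dyh = yhat - yhat.mean()
    denom = np.sum(dy**2) + np.sum(dyh**2) + n_ext * (y.mean() - yhat.mean()) ** 2
    if denom == 0:
        raise ValueError("zero denominator in CCC")
    ccc = float(2.0 * np.sum(dy * dyh) / denom)
    return qf12, qf22, qf32, ccc


# ---------------------------------------------------------------------------
# resampling procedures
# ---------------------------------------------------------------------------

ModelFactory = Callable[[CompoundTable, np.ndarray], object]
"""Callable refitting the final model (fixed hyperparameters and
descriptors) on a table/response pair; the returned object must expose
``predict(table) -> ndarray``."""


def loo_cv(
    train: CompoundTable,
    response: np.ndarray,
    model_factory: ModelFactory,
    convention: str = "strict",
) -> float:
    """Leave-one-out cross-validated q²CV on the training set.

    Each compound is held out in turn, the model is refitted on the rest
    by ``model_factory`` and the held-out prediction recorded; the n
    out-of-sample predictions are then scored like any prediction set.
    """
    y = np.asarray(response, dtype=float)
    n = train.n
    if n < 3:
        raise ValueError("LOO cross-validation needs at least 3 compounds")
    if len(y) != n:
        raise ValueError("response not aligned with table")
    ids = train.ids
    preds = np.empty(n)
    for i in range(n):
        keep = [ids[j] for j in range(n) if j != i]
        sub = train.select_rows(keep)
        y_sub = np.delete(y, i)
        try:
            model = model_factory(sub, y_sub)
            preds[i] = float(np.asarray(model.predict(train.select_rows([ids[i]])))[0])
        except Exception as exc:
            raise RuntimeError(f"LOO fold {i} (held-out {ids[i]!r}) failed: {exc}") from exc
    pred = PredictionSet(ids, y, preds)
    return r2_q2(pred, convention=convention)


def y_scramble(
    train: CompoundTable,
    response: np.ndarray,
    model_factory: ModelFactory,
    n_rounds: int = 25,
    seed: int = 0,
    convention: str = "strict",
) -> tuple[float, np.ndarray]:
    """Y-scrambling (Y-randomization) chance-correlation estimate.

    The response vector is randomly permuted ``n_rounds`` times (descriptors
    untouched), the model refitted with unchanged hyperparameters, and the
    training r² recorded per round.  Returns (⟨rs²⟩, per-round values); an
    informative model on true labels should dwarf ⟨rs²⟩.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be at least 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(response, dtype=float)
    rs2 = np.empty(n_rounds)
    for r in range(n_rounds):
        perm = rng.permutation(train.n)
        y_perm = y[perm]
        model = model_factory(train, y_perm)
        yhat = np.asarray(model.predict(train))
        rs2[r] = r2_q2(PredictionSet(train.ids, y_perm, yhat), convention=convention)
    return float(rs2.mean()), rs2


# ---------------------------------------------------------------------------
# full reports
# ---------------------------------------------------------------------------

def training_report(
    pred: PredictionSet,
    qcv2: float | None = None,
    rs2_mean: float | None = None,
    convention: str = "strict",
) -> MetricsReport:
    """Full statistics battery for training-set (fitted) predictions."""
    rep = basic_metrics(pred)
    rep.context = "training"
    rep.r2 = r2_q2(pred, convention=convention)
    rep.ro2, rep.ro2_prime, rep.k, rep.k_prime = origin_stats(pred)
    rep.rm2, rep.rm2_prime, rep.rm2_mean, rep.rm2_delta = rm2_family(
        rep.r2, rep.ro2, rep.ro2_prime
    )
    rep.qcv2 = qcv2
    rep.rs2_mean = rs2_mean
    return rep


def external_report(
    pred: PredictionSet,
    train_observed: np.ndarray,
    convention: str = "strict",
) -> MetricsReport:
    """Full statistics battery for an external (test or outlier) set."""
    rep = basic_metrics(pred)
    rep.context = "external"
    rep.r2 = r2_q2(pred, convention=convention)
    rep.ro2, rep.ro2_prime, rep.k, rep.k_prime = origin_stats(pred)
    rep.rm2, rep.rm2_prime, rep.rm2_mean, rep.rm2_delta = rm2_family(
        rep.r2, rep.ro2, rep.ro2_prime
    )
    rep.qf12, rep.qf22, rep.qf32, rep.ccc = external_metrics(pred, train_observed)
    y_tr = np.asarray(train_observed, dtype=float)
    rep.n_tr = len(y_tr)
    rep.n_ext = pred.n
    rep.mean_y_tr = float(y_tr.mean())
    rep.mean_y_ext = float(pred.observed.mean())
    rep.mean_yhat_ext = float(pred.predicted.mean())
    return rep


# ---------------------------------------------------------------------------
# combined criteria checker
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CriteriaThresholds:
    """Thresholds of the combined stringent-validation rule set."""

    min_correlation: float = 0.70       # r², qCV², q², qFn²
    max_loo_gap: float = 0.10           # |r² − qCV²|
    max_origin_gap: float = 0.10        # (r² − ro²)/r²
    k_low: float = 0.85
    k_high: float = 1.15
    max_ro2_diff: float = 0.30          # |ro² − r'o²|
    min_rm2: float = 0.65
    min_rm2_mean: float = 0.65
    max_rm2_delta: float = 0.20
    min_ccc: float = 0.85


def _criteria_for(report: MetricsReport, th: CriteriaThresholds) -> list[CriterionResult]:
    ext = report.context == "external"
    out: list[CriterionResult] = []

    corr = {"r2" if not ext else "q2": report.r2}
    if ext:
        corr.update(qf12=report.qf12, qf22=report.qf22, qf32=report.qf32)
    elif report.qcv2 is not None:
        corr["qcv2"] = report.qcv2
    missing = [k for k, v in corr.items() if v is None]
    if missing:
        raise ValueError(f"criteria check missing field(s): {missing}")
    out.append(
        CriterionResult(
            "correlation_floor",
            f"all squared correlations >= {th.min_correlation}",
            True,
            all(v >= th.min_correlation for v in corr.values()),
            corr,
        )
    )

    if not ext:
        if report.qcv2 is None:
            raise ValueError("criteria check missing field(s): ['qcv2']")
        gap = abs(report.r2 - report.qcv2)
        out.append(
            CriterionResult(
                "loo_agreement",
                f"|r2 - qcv2| < {th.max_loo_gap}",
                True,
                gap < th.max_loo_gap,
                {"r2": report.r2, "qcv2": report.qcv2, "gap": gap},
            )
        )
    else:
        out.append(
            CriterionResult(
                "loo_agreement", "training-set only", False, None, {}
            )
        )

    for name in ("ro2", "ro2_prime", "k", "rm2", "rm2_mean", "rm2_delta"):
        if getattr(report, name) is None:
            raise ValueError(f"criteria check missing field(s): ['{name}']")
    rel_gap = (report.r2 - report.ro2) / report.r2
    out.append(
        CriterionResult(
            "origin_regression",
            f"(r2-ro2)/r2 < {th.max_origin_gap} and {th.k_low} <= k <= {th.k_high}",
            True,
            rel_gap < th.max_origin_gap and th.k_low <= report.k <= th.k_high,
            {"rel_gap": rel_gap, "k": report.k},
        )
    )
    diff = abs(report.ro2 - report.ro2_prime)
    out.append(
        CriterionResult(
            "origin_symmetry",
            f"|ro2 - ro2_prime| < {th.max_ro2_diff}",
            True,
            diff < th.max_ro2_diff,
            {"ro2": report.ro2, "ro2_prime": report.ro2_prime, "diff": diff},
        )
    )
    out.append(
        CriterionResult(
            "rm2_floor",
            f"rm2 >= {th.min_rm2}",
            True,
            report.rm2 >= th.min_rm2,
            {"rm2": report.rm2},
        )
    )
    out.append(
        CriterionResult(
            "rm2_mean_delta",
            f"<rm2> >= {th.min_rm2_mean} and delta rm2 < {th.max_rm2_delta}",
            True,
            report.rm2_mean >= th.min_rm2_mean and report.rm2_delta < th.max_rm2_delta,
            {"rm2_mean": report.rm2_mean, "rm2_delta": report.rm2_delta},
        )
    )
    if ext:
        if report.ccc is None:
            raise ValueError("criteria check missing field(s): ['ccc']")
        out.append(
            CriterionResult(
                "concordance",
                f"CCC >= {th.min_ccc}",
                True,
                report.ccc >= th.min_ccc,
                {"ccc": report.ccc},
            )
        )
    else:
        out.append(
            CriterionResult("concordance", "external sets only", False, None, {})
        )
    return out


def check_criteria(
    training: MetricsReport | None = None,
    external: MetricsReport | None = None,
    thresholds: CriteriaThresholds | None = None,
) -> dict[str, CriteriaVerdict]:
    """Evaluate the combined stringent validation criteria.

    The LOO-agreement criterion applies to the training set only; the
    concordance (CCC) criterion to external sets only.  Returns one verdict
    per supplied report, keyed "training" / "external".
    """
    th = thresholds or CriteriaThresholds()
    out: dict[str, CriteriaVerdict] = {}
    if training is not None:
        if training.context != "training":
            raise ValueError("training report has wrong context tag")
        out["training"] = CriteriaVerdict(_criteria_for(training, th))
    if external is not None:
        if external.context != "external":
            raise ValueError("external report has wrong context tag")
        out["external"] = CriteriaVerdict(_criteria_for(external, th))
    if not out:
        raise ValueError("supply at least one report")
    return out
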