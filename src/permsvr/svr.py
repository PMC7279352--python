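"""Base support-vector-regression learners and systematic grid search.

Each learner is an RBF-kernel SVR in either ε-regression (tube width ε) or
ν-regression (support-vector fraction ν) mode, operating on a named subset
of descriptors.  The solver is the libsvm implementation behind
scikit-learn's ``SVR``/``NuSVR``; everything around it — hyperparameter
records, per-model autoscaling, name-based descriptor binding and the
systematic grid search ranked by cross-validated RMSE — lives here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR, NuSVR

from .io import CompoundTable, PredictionSet
from .preprocess import NormalizationStats, apply_normalization, fit_normalization

__all__ = [
    "SVRSpec",
    "TrainedSVR",
    "GridResult",
    "default_grid",
    "grid_search",
    "cv_rmse",
    "train_svr",
    "predict_svr",
]

DEFAULT_C = 10.0
DEFAULT_EPSILON = 0.1


@dataclass(frozen=True)
class SVRSpec:
    """Hyperparameter record for one RBF-SVR base learner.

    Exactly one of ``epsilon`` / ``nu`` is set, matching ``mode``.
    ``subset`` names the descriptor columns the learner consumes.
    """

    mode: str                      # "epsilon" or "nu"
    C: float
    gamma: float
    epsilon: float | None = None
    nu: float | None = None
    subset: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("epsilon", "nu"):
            raise ValueError(f"unknown SVR mode {self.mode!r}")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.mode == "epsilon":
            if self.epsilon is None or self.nu is not None:
                raise ValueError("epsilon mode requires epsilon and no nu")
            if self.epsilon < 0:
                raise ValueError("epsilon must be non-negative")
        else:
            if self.nu is None or self.epsilon is not None:
                raise ValueError("nu mode requires nu and no epsilon")
            if not 0.0 < self.nu <= 1.0:
                raise ValueError("nu must lie in (0, 1]")
        if len(set(self.subset)) != len(self.subset):
            raise ValueError("descriptor subset contains duplicates")

    def make_estimator(self):
        if self.mode == "epsilon":
            return SVR(kernel="rbf", C=self.C, gamma=self.gamma, epsilon=self.epsilon)
        return NuSVR(kernel="rbf", C=self.C, gamma=self.gamma, nu=self.nu)

    def _sort_key(self) -> tuple:
        # total order used for deterministic tie-breaking
        return (self.C, self.gamma, self.mode,
                self.epsilon if self.epsilon is not None else self.nu)


@dataclass
class TrainedSVR:
    """A fitted base learner: spec, solver state and normalization reference.

    Prediction binds descriptors by name, applies the stored training-set
    normalization and is insensitive to column order or extra columns.
    """

    spec: SVRSpec
    estimator: object
    normalization: NormalizationStats
    cv_rmse: float | None = None
    qcv2: float | None = None

    @property
    def subset(self) -> tuple[str, ...]:
        return self.spec.subset

    def _design(self, table: CompoundTable) -> np.ndarray:
        missing = [c for c in self.subset if c not in table.descriptor_names]
        if missing:
            raise KeyError(f"table lacks descriptor(s) {missing}")
        sub = table.subset_descriptors(self.subset)
        normed = apply_normalization(self.normalization, sub)
        X = normed.descriptors.to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite descriptor values")
        return X

    def predict(self, table: CompoundTable) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._design(table)), dtype=float)


def train_svr(
    train: CompoundTable,
    response: np.ndarray,
    spec: SVRSpec,
    normalization: NormalizationStats | None = None,
) -> TrainedSVR:
    """Fit one base learner.

    Normalization statistics are fitted on the training table's subset
    columns unless supplied; they travel with the model and are applied
    to every prediction input.
    """
    y = np.asarray(response, dtype=float)
    if len(y) != train.n:
        raise ValueError("response not aligned with training table")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if not spec.subset:
        spec = replace(spec, subset=tuple(train.descriptor_names))
    sub = train.subset_descriptors(spec.subset)
    if not np.all(np.isfinite(sub.descriptors.to_numpy(dtype=float))):
        raise ValueError("non-finite descriptor values in training table")
    stats = normalization or fit_normalization(sub)
    model = TrainedSVR(spec=spec, estimator=spec.make_estimator(), normalization=stats)
    model.estimator.fit(model._design(train), y)
    return model


def predict_svr(model: TrainedSVR, table: CompoundTable) -> PredictionSet:
    """Predict a table, pairing predictions with observed values."""
    yhat = model.predict(table)
    return PredictionSet(table.ids, table.response, yhat)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def default_grid() -> dict:
    """The standard libsvm-style search grid.

    C over 2⁻⁵…2¹⁵ and γ over 2⁻¹⁵…2³ in powers of four, ε over a short
    list of tube widths and ν over four support-vector fractions.
    """
    return {
        "C_values": [2.0**p for p in range(-5, 16, 2)],
        "gamma_values": [2.0**p for p in range(-15, 4, 2)],
        "epsilon_values": [0.01, 0.05, 0.1, 0.2, 0.5],
        "nu_values": [0.2, 0.4, 0.6, 0.8],
    }


def cv_rmse(
    train: CompoundTable,
    response: np.ndarray,
    spec: SVRSpec,
    cv_folds: int = 5,
    seed: int = 0,
) -> float:
    """k-fold cross-validated RMSE of one spec (seeded shuffled folds)."""
    y = np.asarray(response, dtype=float)
    n = train.n
    if cv_folds > n:
        raise ValueError(f"cv_folds={cv_folds} exceeds sample count {n}")
    ids = train.ids
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    sq = 0.0
    for tr_idx, te_idx in kf.split(np.arange(n)):
        model = train_svr(
            train.select_rows([ids[i] for i in tr_idx]), y[tr_idx], spec
        )
        pred = model.predict(train.select_rows([ids[i] for i in te_idx]))
        sq += float(np.sum((pred - y[te_idx]) ** 2))
    return float(np.sqrt(sq / n))


@dataclass(frozen=True)
class GridResult:
    spec: SVRSpec
    cv_rmse: float


def _expand_grid(grid: dict, subset: Sequence[str]) -> list[SVRSpec]:
    specs: list[SVRSpec] = []
    Cs = grid.get("C_values") or []
    gammas = grid.get("gamma_values") or []
    for C, g in itertools.product(Cs, gammas):
        for eps in grid.get("epsilon_values") or []:
            specs.append(SVRSpec("epsilon", C, g, epsilon=eps, subset=tuple(subset)))
        for nu in grid.get("nu_values") or []:
            specs.append(SVRSpec("nu", C, g, nu=nu, subset=tuple(subset)))
    return specs


def grid_search(
    train: CompoundTable,
    response: np.ndarray,
    subset: Sequence[str] | None = None,
    grid: dict | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    top: int | None = None,
) -> list[GridResult]:
    """Systematic grid search over (mode, C, γ, ε/ν) ranked by CV-RMSE.

    Every grid combination is scored by seeded k-fold cross-validation on
    the training set (the external set stays untouched).  Ranking is
    stable: ties are broken by smaller C, then smaller γ, then mode, so
    the result is independent of evaluation order.
    """
    subset = tuple(subset) if subset is not None else tuple(train.descriptor_names)
    grid = grid or default_grid()
    specs = _expand_grid(grid, subset)
    if not specs:
        raise ValueError("empty hyperparameter grid")
    results = [
        GridResult(spec, cv_rmse(train, response, spec, cv_folds=cv_folds, seed=seed))
        for spec in specs
    ]
    results.sort(key=lambda r: (r.cv_rmse, *r.spec._sort_key()))
    return results[:top] if top else results
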