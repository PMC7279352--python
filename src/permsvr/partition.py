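"""Chemical-space construction, applicability-domain outliers and data splits.

The applicability domain is defined geometrically: compounds are projected
onto the leading principal components of the (normalized) descriptor
matrix, and a compound is an outlier when its score vector falls outside
the perimeter of the training scores.  Two perimeter notions are offered —
the axis-aligned bounding box (default; deterministic and monotone) and
the convex hull.  The remaining compounds are split at random into
training and test sets at a configurable ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay, QhullError

from .io import CompoundTable

__all__ = [
    "ChemicalSpace",
    "DataSplit",
    "build_chemical_space",
    "project_scores",
    "flag_outliers",
    "tukey_outlier_mask",
    "split_train_test",
    "similarity_report",
]


@dataclass
class ChemicalSpace:
    """PCA chemical space: loadings, per-compound scores and explained
    variance fractions for the top k components."""

    loadings: pd.DataFrame        # descriptors x components
    scores: pd.DataFrame          # compounds x components
    explained_variance_ratio: np.ndarray
    centre: pd.Series             # per-descriptor mean removed before projection

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclass
class DataSplit:
    """Disjoint training / test / outlier partition of a compound table."""

    train_ids: list[str]
    test_ids: list[str]
    outlier_ids: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.test_ids), set(self.outlier_ids)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("train/test/outlier id sets must be pairwise disjoint")


def build_chemical_space(table: CompoundTable, k: int = 3) -> ChemicalSpace:
    """Project compounds onto the top-k principal components.

    Components are eigenvectors of the descriptor covariance matrix
    (computed on the table as given — normalize first for scale-free
    loadings).  Component signs are fixed so the largest-magnitude loading
    is positive, making the decomposition reproducible.
    """
    names = table.descriptor_names
    if k > len(names):
        raise ValueError(f"k={k} exceeds descriptor count {len(names)}")
    if table.n < k + 1:
        raise ValueError(f"need at least {k + 1} compounds for k={k} components")
    X = table.descriptors.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("descriptor matrix contains non-finite values")
    centre = X.mean(axis=0)
    Xc = X - centre
    # SVD of the centred matrix == eigendecomposition of the covariance
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    var = svals**2 / (table.n - 1)
    total = np.sum(Xc.var(axis=0, ddof=1))
    ratio = var / total if total > 0 else np.zeros_like(var)
    comps = vt[:k].T  # descriptors x k
    for j in range(comps.shape[1]):  # deterministic sign convention
        pivot = np.argmax(np.abs(comps[:, j]))
        if comps[pivot, j] < 0:
            comps[:, j] = -comps[:, j]
    pc_names = [f"PC{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(comps, index=names, columns=pc_names)
    scores = pd.DataFrame(Xc @ comps, index=table.descriptors.index, columns=pc_names)
    return ChemicalSpace(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=ratio[:k],
        centre=pd.Series(centre, index=names),
    )


def project_scores(space: ChemicalSpace, table: CompoundTable) -> pd.DataFrame:
    """Score new compounds in an existing chemical space."""
    missing = [c for c in space.loadings.index if c not in table.descriptor_names]
    if missing:
        raise KeyError(f"table lacks descriptor(s) {missing}")
    X = table.descriptors[list(space.loadings.index)].to_numpy(dtype=float)
    Xc = X - space.centre.to_numpy()
    return pd.DataFrame(
        Xc @ space.loadings.to_numpy(),
        index=table.descriptors.index,
        columns=space.loadings.columns,
    )


def flag_outliers(
    space: ChemicalSpace,
    candidate_scores: pd.DataFrame | np.ndarray,
    margin: float = 0.0,
    method: str = "box",
) -> np.ndarray:
    """Flag candidates lying outside the perimeter of the reference scores.

    ``box`` (default): outside the axis-aligned bounding box of the
    reference scores — expanded by ``margin`` (a fraction of each
    component's range) — in at least one component.  ``hull``: outside the
    convex hull of the reference scores.  Returns a boolean array aligned
    with the candidate rows.
    """
    ref = space.scores.to_numpy(dtype=float)
    if ref.shape[0] < 2:
        raise ValueError("need at least 2 reference compounds")
    cand = np.asarray(
        candidate_scores.to_numpy() if isinstance(candidate_scores, pd.DataFrame)
        else candidate_scores,
        dtype=float,
    )
    if cand.ndim == 1:
        cand = cand[None, :]
    if cand.shape[1] != ref.shape[1]:
        raise ValueError("candidate scores have wrong component count")

    if method == "box":
        lo, hi = ref.min(axis=0), ref.max(axis=0)
        pad = margin * (hi - lo)
        return np.any((cand < lo - pad) | (cand > hi + pad), axis=1)
    if method == "hull":
        try:
            tri = Delaunay(ref)
        except QhullError as exc:
            raise ValueError(
                "convex hull degenerate; use method='box' instead"
            ) from exc
        return tri.find_simplex(cand) < 0
    raise ValueError(f"unknown perimeter method {method!r}")


def tukey_outlier_mask(scores: pd.DataFrame | np.ndarray, factor: float = 3.0) -> np.ndarray:
    """Self-referential outlier screen on chemical-space scores.

    A compound is flagged when one of its component scores falls outside
    the Tukey fences [Q1 − factor·IQR, Q3 + factor·IQR] of that component.
    Used when outliers must be designated before any training set exists;
    ``flag_outliers`` handles the candidate-versus-reference case.
    """
    S = np.asarray(scores.to_numpy() if isinstance(scores, pd.DataFrame) else scores,
                   dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    q1 = np.percentile(S, 25, axis=0)
    q3 = np.percentile(S, 75, axis=0)
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    return np.any((S < lo) | (S > hi), axis=1)


def split_train_test(ids: list[str], ratio: float = 0.8, seed: int = 0) -> DataSplit:
    """Random train/test partition with training size round(ratio·n).

    The split is uniform over partitions of the given sizes and fully
    determined by ``seed``.  Outliers are expected to have been removed
    from ``ids`` beforehand.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    ids = [str(i) for i in ids]
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 compounds to split")
    n_train = int(np.floor(ratio * n + 0.5))  # round half up
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = sorted(perm[:n_train])
    test = sorted(perm[n_train:])
    return DataSplit(
        train_ids=[ids[i] for i in train],
        test_ids=[ids[i] for i in test],
        outlier_ids=[],
        seed=seed,
    )


def similarity_report(
    split: DataSplit, table: CompoundTable, response: np.ndarray | None = None
) -> pd.DataFrame:
    """Train-versus-test distribution diagnostics.

    For the response (when given) and every descriptor: min/max/mean/median
    in each partition plus the two-sample Kolmogorov–Smirnov distance.
    Purely diagnostic — no pass/fail decision is made.
    """
    if not split.train_ids or not split.test_ids:
        raise ValueError("both partitions must be non-empty")
    train = table.select_rows(split.train_ids)
    test = table.select_rows(split.test_ids)

    variables: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if response is not None:
        y = np.asarray(response, dtype=float)
        if len(y) != table.n:
            raise ValueError("response not aligned with table")
        pos = {cid: i for i, cid in enumerate(table.ids)}
        variables["response"] = (
            y[[pos[i] for i in split.train_ids]],
            y[[pos[i] for i in split.test_ids]],
        )
    for col in table.descriptor_names:
        variables[col] = (
            train.descriptors[col].to_numpy(dtype=float),
            test.descriptors[col].to_numpy(dtype=float),
        )

    rows = []
    for name, (a, b) in variables.items():
        ks = stats.ks_2samp(a, b, method="asymp").statistic if len(a) and len(b) else np.nan
        rows.append(
            {
                "variable": name,
                "train_min": a.min(), "train_max": a.max(),
                "train_mean": a.mean(), "train_median": np.median(a),
                "test_min": b.min(), "test_max": b.max(),
                "test_mean": b.mean(), "test_median": np.median(b),
                "ks_distance": float(ks),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
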