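"""Descriptor preprocessing and perfusion-permeability utilities.

Covers the steps that precede any model fitting:

* effective permeability from single-pass intestinal perfusion (SPIP)
  measurements: Peff = −Q·ln(c_out/c_in)/(2πRL), in cm/s;
* filtration of uninformative descriptors (missing values, near-constant
  columns);
* Spearman intercorrelation pruning at a configurable ρ² threshold;
* autoscaling (z-score with the n−1 standard deviation) fitted on a
  reference set and applied unchanged elsewhere;
* ion-class assignment (neutral / zwitterion / acid / base) from pKa lists;
* binned average-response profiles for descriptor diagnostics.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CompoundTable

__all__ = [
    "PerfusionParams",
    "compute_peff",
    "drop_uninformative",
    "prune_intercorrelated",
    "PruneRemoval",
    "NormalizationStats",
    "fit_normalization",
    "apply_normalization",
    "IonClass",
    "assign_ion_class",
    "binned_response_profile",
]


# ---------------------------------------------------------------------------
# perfusion permeability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerfusionParams:
    """SPIP measurement: flow Q (cm³/s), inlet/outlet concentrations (same
    units), segment radius R and length L (cm)."""

    Q: float
    c_in: float
    c_out: float
    R: float
    L: float

    def __post_init__(self) -> None:
        if self.Q <= 0 or self.R <= 0 or self.L <= 0:
            raise ValueError("Q, R and L must be positive")
        if self.c_in <= 0:
            raise ValueError("inlet concentration must be positive")
        if self.c_out < 0:
            raise ValueError("outlet concentration must be non-negative")


def compute_peff(p: PerfusionParams) -> float:
    """Effective permeability (cm/s) from a single-pass perfusion record.

    Peff = −Q·ln(c_out/c_in) / A with mantle area A = 2πRL.  An outlet
    concentration above the inlet one yields a (physically suspect)
    negative Peff; a warning is emitted rather than an error.
    """
    if p.c_out == 0:
        raise ValueError("outlet concentration is zero: ln(c_out/c_in) undefined")
    area = 2.0 * math.pi * p.R * p.L
    peff = -p.Q * math.log(p.c_out / p.c_in) / area
    if p.c_out > p.c_in:
        warnings.warn(
            "c_out > c_in: negative effective permeability", stacklevel=2
        )
    return peff


# ---------------------------------------------------------------------------
# descriptor filtration
# ---------------------------------------------------------------------------

def drop_uninformative(
    table: CompoundTable, min_distinct: int = 3, return_report: bool = False
):
    """Remove descriptors with any missing value or too few distinct values.

    A column is kept only if it is complete and takes at least
    ``min_distinct`` distinct values across the table (columns failing the
    latter barely discriminate between compounds).  Column order of the
    survivors is preserved.
    """
    if table.n == 0:
        raise ValueError("table is empty")
    report: list[tuple[str, str]] = []
    keep: list[str] = []
    for col in table.descriptor_names:
        series = table.descriptors[col]
        if series.isna().any():
            report.append((col, "missing value(s)"))
        elif series.nunique(dropna=True) < min_distinct:
            report.append(
                (col, f"fewer than {min_distinct} distinct values")
            )
        else:
            keep.append(col)
    if not keep:
        raise ValueError("all descriptors were dropped as uninformative")
    out = table.subset_descriptors(keep)
    return (out, report) if return_report else out


@dataclass(frozen=True)
class PruneRemoval:
    """One intercorrelation-pruning event: which descriptor was removed and
    the correlated pair that triggered it."""

    removed: str
    kept: str
    rho2: float


def prune_intercorrelated(
    table: CompoundTable,
    response: np.ndarray,
    r2_max: float = 0.64,
    return_report: bool = False,
):
    """Prune descriptors until all pairwise Spearman ρ² fall below ``r2_max``.

    While any pair of surviving descriptors has rank-correlation ρ² at or
    above the threshold, the pair with the largest ρ² is examined (ties
    broken by column order) and the member with the smaller \\|Spearman ρ\\|
    against the response is removed (ties remove the later column).  The
    survivor set therefore has all pairwise ρ² < ``r2_max``.
    """
    names = table.descriptor_names
    if len(names) < 2:
        raise ValueError("need at least two descriptors to prune")
    X = table.descriptors.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    if len(y) != table.n:
        raise ValueError("response not aligned with table rows")
    for j, col in enumerate(names):
        if np.nanstd(X[:, j]) == 0:
            raise ValueError(
                f"descriptor {col!r} is constant; run drop_uninformative first"
            )

    # ranks once; Spearman rho = Pearson on ranks
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    rank_y = stats.rankdata(y)
    with np.errstate(invalid="ignore"):
        full = np.corrcoef(np.column_stack([ranks, rank_y]), rowvar=False)
    rho_xx = full[: len(names), : len(names)]
    rho_xy = full[: len(names), -1]

    alive = list(range(len(names)))
    removals: list[PruneRemoval] = []
    while True:
        best = None  # (rho2, i_pos, j_pos)
        for a in range(len(alive)):
            for b in range(a + 1, len(alive)):
                r2 = rho_xx[alive[a], alive[b]] ** 2
                if r2 >= r2_max and (best is None or r2 > best[0] + 1e-15):
                    best = (r2, a, b)
        if best is None:
            break
        r2, a, b = best
        i, j = alive[a], alive[b]
        # drop the member less rank-correlated with the response;
        # tie -> drop the later column
        if abs(rho_xy[i]) < abs(rho_xy[j]):
            drop, keep_ = i, j
        elif abs(rho_xy[j]) < abs(rho_xy[i]):
            drop, keep_ = j, i
        else:
            drop, keep_ = j, i  # j is the later column
        removals.append(PruneRemoval(names[drop], names[keep_], float(r2)))
        alive.remove(drop)

    kept = [names[i] for i in alive]
    return (kept, removals) if return_report else kept


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationStats:
    """Per-descriptor centre and scale fitted on a reference (training) set.

    ``scale`` is the sample standard deviation with the n−1 denominator, so
    applying the statistics back to the fitting table yields columns with
    mean 0 and sample SD 1.
    """

    mean: pd.Series
    scale: pd.Series
    n: int

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.scale.index):
            raise ValueError("mean and scale must cover the same descriptors")
        if (self.scale <= 0).any():
            bad = list(self.scale.index[self.scale <= 0])
            raise ValueError(f"non-positive scale for descriptor(s) {bad}")


def fit_normalization(table: CompoundTable) -> NormalizationStats:
    """Fit autoscaling statistics χ = (x − ⟨x⟩)/s on the given table."""
    desc = table.descriptors
    mean = desc.mean(axis=0)
    scale = desc.std(axis=0, ddof=1)
    zero = list(scale.index[(scale == 0) | scale.isna()])
    if zero:
        raise ValueError(f"zero scale (constant column) for descriptor(s) {zero}")
    return NormalizationStats(mean=mean, scale=scale, n=table.n)


def apply_normalization(stats_: NormalizationStats, table: CompoundTable) -> CompoundTable:
    """Apply previously fitted statistics; never refits on the new table."""
    missing = [c for c in table.descriptor_names if c not in stats_.mean.index]
    if missing:
        raise KeyError(f"no normalization statistics for descriptor(s) {missing}")
    desc = table.descriptors
    normed = (desc - stats_.mean[desc.columns]) / stats_.scale[desc.columns]
    return CompoundTable._from_parts(table.records, normed)


# ---------------------------------------------------------------------------
# ion classes
# ---------------------------------------------------------------------------

class IonClass(enum.Enum):
    NEUTRAL = "neutral"
    ZWITTERION = "zwitterion"
    ACID = "acid"
    BASE = "base"


def assign_ion_class(pkas: list[float], boundary: float = 7.0) -> IonClass:
    """Assign an ion class from a compound's pKa list.

    The rule: a single pKa value means neutral; otherwise the compound is a
    zwitterion when the largest pKa exceeds the boundary and the smallest
    falls below it, an acid when both fall below, and a base when both
    exceed it.  Values exactly at the boundary count as "larger than".
    """
    if not pkas:
        raise ValueError("empty pKa list")
    vals = [float(p) for p in pkas]
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("pKa values must be finite")
    if len(vals) == 1:
        return IonClass.NEUTRAL
    hi, lo = max(vals), min(vals)
    hi_basic = hi >= boundary
    lo_basic = lo >= boundary
    if hi_basic and not lo_basic:
        return IonClass.ZWITTERION
    if hi_basic and lo_basic:
        return IonClass.BASE
    return IonClass.ACID


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def binned_response_profile(
    values: np.ndarray, response: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Average response per equal-width descriptor bin.

    Returns a frame with bin edges, per-bin counts and the arithmetic mean
    response (NaN for empty bins, flagged in the ``empty`` column).  Used to
    reproduce average-permeability-versus-descriptor profiles.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(x) != len(y):
        raise ValueError("descriptor and response must align")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise ValueError("descriptor is constant: a single bin is meaningless")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "mean_response": means,
            "empty": counts == 0,
        }
    )
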