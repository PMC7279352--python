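"""Synthetic intestinal-permeability data generator.

Produces descriptor/response tables with the statistical structure the
modelling pipeline is designed for: a smooth, partly non-monotone
passive-diffusion dependence of log10 effective permeability on physical
descriptors (log D, molecular shape, molar refractivity, heteroatom
count), plus latent transporter classes — efflux (P-gp-like), none, influx
(PepT1-like) — that act through the hydrogen-bond-donor count and make its
marginal effect non-monotone.  All constants are simulator fixtures, not
measured values.

Descriptors
-----------
logD      n-octanol/water distribution coefficient at pH 6.5, ~N(1.5, 1.5²)
HBD       hydrogen-bond donor count, ~Poisson(2)
MR        molar refractivity, ~N(80, 20²)
shadow_v  ratio of largest to smallest molecular dimension, ~U(1, 4)
n_NO      nitrogen + oxygen count, ~Poisson(4)
mu        dipole moment (debye), ~|N(3, 2²)|
noise_*   pure-noise standard-normal columns (no response effect)

Response
--------
log_peff = −4.2 + 0.35·logD − 0.08·(logD − 2)² + 0.25·shadow_v
           − 0.012·max(0, MR − 90) − 0.05·n_NO + 0.15·t·HBD + ε,
with latent transporter class t ∈ {−1 (efflux), 0, +1 (influx)} and
ε ~ N(0, noise_sd²).  The dipole and noise columns are decoys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CompoundRecord, CompoundTable
from .partition import DataSplit, split_train_test

__all__ = ["SimConfig", "LatentTruth", "generate", "two_regime_benchmark"]

#: descriptor combinations used by the benchmark's subset-specialized base
#: learners (two four-descriptor combinations sharing logD and mu, one
#: carrying shape/heteroatom information, the other HBD/molar refractivity)
BENCHMARK_SUBSETS = (
    ("mu", "logD", "n_NO", "shadow_v"),
    ("mu", "logD", "HBD", "MR"),
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``class_probs`` are the probabilities of the latent efflux / none /
    influx transporter classes; ``noise_sd`` is the response noise in
    log10 units; ``n_noise_descriptors`` pure-noise columns are appended.
    """

    n_compounds: int = 400
    noise_sd: float = 0.1
    class_probs: tuple[float, float, float] = (0.4, 0.2, 0.4)
    seed: int = 0
    n_noise_descriptors: int = 4

    def __post_init__(self) -> None:
        if self.n_compounds < 10:
            raise ValueError("n_compounds must be at least 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        p = np.asarray(self.class_probs, dtype=float)
        if len(p) != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_probs must be 3 non-negative values summing to 1")
        if self.n_noise_descriptors < 0:
            raise ValueError("n_noise_descriptors must be non-negative")


@dataclass(frozen=True)
class LatentTruth:
    """Ground truth accompanying a generated table."""

    transporter_class: np.ndarray    # -1 efflux, 0 none, +1 influx
    noiseless_response: np.ndarray


def _response_surface(desc: pd.DataFrame, t: np.ndarray) -> np.ndarray:
    logd = desc["logD"].to_numpy()
    return (
        -4.2
        + 0.35 * logd
        - 0.08 * (logd - 2.0) ** 2
        + 0.25 * desc["shadow_v"].to_numpy()
        - 0.012 * np.maximum(0.0, desc["MR"].to_numpy() - 90.0)
        - 0.05 * desc["n_NO"].to_numpy()
        + 0.15 * t * desc["HBD"].to_numpy()
    )


def generate(config: SimConfig) -> tuple[CompoundTable, LatentTruth]:
    """Draw one synthetic compound table plus its latent truth."""
    n = config.n_compounds
    rng = np.random.default_rng(config.seed)
    desc = pd.DataFrame(
        {
            "logD": rng.normal(1.5, 1.5, n),
            "HBD": rng.poisson(2.0, n).astype(float),
            "MR": rng.normal(80.0, 20.0, n),
            "shadow_v": rng.uniform(1.0, 4.0, n),
            "n_NO": rng.poisson(4.0, n).astype(float),
            "mu": np.abs(rng.normal(3.0, 2.0, n)),
        }
    )
    for j in range(config.n_noise_descriptors):
        desc[f"noise_{j}"] = rng.normal(0.0, 1.0, n)

    t = rng.choice([-1, 0, 1], size=n, p=list(config.class_probs))
    clean = _response_surface(desc, t)
    y = clean + rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else clean.copy()

    records = [
        CompoundRecord(f"cmpd_{i:04d}", log_peff=float(y[i])) for i in range(n)
    ]
    return CompoundTable(records, desc), LatentTruth(t, clean)


@dataclass(frozen=True)
class BenchmarkData:
    train: CompoundTable
    test: CompoundTable
    split: DataSplit
    truth: LatentTruth
    full_table: CompoundTable


def two_regime_benchmark(n: int = 400, seed: int = 0) -> BenchmarkData:
    """Standard benchmark: pronounced efflux/influx regimes, 4:1 split.

    Generates ``n`` compounds with class probabilities (0.4, 0.2, 0.4) and
    response noise 0.1 log units, then splits 4:1 at random under the same
    seed.  The latent truth rides along for oracle scoring.
    """
    if n < 100:
        raise ValueError("benchmark needs at least 100 compounds")
    cfg = SimConfig(
        n_compounds=n, noise_sd=0.1, class_probs=(0.4, 0.2, 0.4), seed=seed
    )
    table, truth = generate(cfg)
    split = split_train_test(table.ids, ratio=0.8, seed=seed)
    return BenchmarkData(
        train=table.select_rows(split.train_ids),
        test=table.select_rows(split.test_ids),
        split=split,
        truth=truth,
        full_table=table,
    )
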