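import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from permsvr.io import CompoundRecord, CompoundTable
from permsvr.preprocess import (
    IonClass,
    PerfusionParams,
    apply_normalization,
    assign_ion_class,
    binned_response_profile,
    compute_peff,
    drop_uninformative,
    fit_normalization,
    prune_intercorrelated,
)

from conftest import make_table


class TestComputePeff:
    def test_equal_concentrations_give_zero(self):
        p = PerfusionParams(Q=0.01, c_in=1.0, c_out=1.0, R=0.2, L=10.0)
        assert compute_peff(p) == 0.0

    def test_hand_evaluated_perfusion_example(self):
        # Q = 0.2 mL/min = 0.2/60 cm3/s, 20% absorbed over a 0.2 x 10 cm segment
        p = PerfusionParams(Q=0.2 / 60, c_in=1.0, c_out=0.8, R=0.2, L=10.0)
        assert compute_peff(p) == pytest.approx(5.92e-5, rel=1e-2)

    def test_sign_flips_when_concentrations_swap(self):
        a = PerfusionParams(Q=0.01, c_in=1.0, c_out=0.5, R=0.2, L=10.0)
        b = PerfusionParams(Q=0.01, c_in=0.5, c_out=1.0, R=0.2, L=10.0)
        with pytest.warns(UserWarning):
            neg = compute_peff(b)
        assert neg == pytest.approx(-compute_peff(a))

    def test_zero_outlet_concentration_errors(self):
        p = PerfusionParams(Q=0.01, c_in=1.0, c_out=0.0, R=0.2, L=10.0)
        with pytest.raises(ValueError):
            compute_peff(p)

    @pytest.mark.parametrize("bad", [dict(Q=0), dict(R=-1), dict(L=0), dict(c_in=0)])
    def test_non_positive_geometry_rejected(self, bad):
        kwargs = dict(Q=0.01, c_in=1.0, c_out=0.5, R=0.2, L=10.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            PerfusionParams(**kwargs)


class TestDropUninformative:
    def test_constant_and_missing_columns_dropped(self):
        desc = pd.DataFrame(
            {
                "ok1": [1.0, 2.0, 3.0, 4.0],
                "const": [5.0, 5.0, 5.0, 5.0],
                "ok2": [0.1, 0.4, 0.2, 0.9],
                "gap": [1.0, np.nan, 3.0, 4.0],
                "ok3": [7.0, 8.0, 9.0, 1.0],
                "binary": [0.0, 1.0, 0.0, 1.0],
            }
        )
        t = CompoundTable([CompoundRecord(f"c{i}") for i in range(4)], desc)
        out, report = drop_uninformative(t, min_distinct=3, return_report=True)
        assert out.descriptor_names == ["ok1", "ok2", "ok3"]  # order preserved
        assert {name for name, _ in report} == {"const", "gap", "binary"}

    def test_all_dropped_errors(self):
        t = make_table(np.ones((3, 2)))
        with pytest.raises(ValueError):
            drop_uninformative(t)


def brute_force_prune(X, y, names, r2_max):
    """Literal re-application of the pruning rule, kept independent of the
    implementation: repeatedly find the most correlated surviving pair and
    drop the member less rank-correlated with the response."""
    alive = list(range(len(names)))
    while True:
        worst = None
        for a in range(len(alive)):
            for b in range(a + 1, len(alive)):
                i, j = alive[a], alive[b]
                rho = sps.spearmanr(X[:, i], X[:, j]).statistic
                if rho**2 >= r2_max and (worst is None or rho**2 > worst[0]):
                    worst = (rho**2, i, j)
        if worst is None:
            return [names[i] for i in alive]
        _, i, j = worst
        ri = abs(sps.spearmanr(X[:, i], y).statistic)
        rj = abs(sps.spearmanr(X[:, j], y).statistic)
        alive.remove(i if ri < rj else j)


class TestPruneIntercorrelated:
    def test_duplicated_column_loses_one_copy(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, x, rng.normal(size=30)])
        y = x + rng.normal(size=30)
        kept = prune_intercorrelated(make_table(X), y, r2_max=0.64)
        assert len(kept) == 2 and "d2" in kept

    def test_pair_below_threshold_kept(self, rng):
        x = rng.normal(size=200)
        # correlate at rho ~ 0.6 (rho2 ~ 0.36 < 0.64)
        z = 0.6 * x + 0.8 * rng.normal(size=200)
        kept = prune_intercorrelated(make_table(np.column_stack([x, z])),
                                     rng.normal(size=200), r2_max=0.64)
        assert kept == ["d0", "d1"]

    def test_matches_brute_force_oracle_on_planted_structure(self, rng):
        n = 80
        base = rng.normal(size=n)
        X = np.column_stack(
            [
                base,
                base + 0.05 * rng.normal(size=n),      # near-duplicate of d0
                rng.normal(size=n),
                -base + 0.1 * rng.normal(size=n),      # anti-correlated with d0
                rng.normal(size=n),
            ]
        )
        y = base + 0.3 * X[:, 2] + 0.1 * rng.normal(size=n)
        names = [f"d{j}" for j in range(5)]
        kept = prune_intercorrelated(make_table(X), y, r2_max=0.64)
        assert kept == brute_force_prune(X, y, names, 0.64)

    def test_survivors_all_below_threshold(self, rng):
        X = rng.multivariate_normal(
            np.zeros(4), [[1, .9, .2, 0], [.9, 1, .2, 0], [.2, .2, 1, .3], [0, 0, .3, 1]],
            size=60,
        )
        y = X[:, 0] + rng.normal(size=60)
        kept = prune_intercorrelated(make_table(X), y, r2_max=0.5)
        idx = [int(k[1]) for k in kept]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                rho = sps.spearmanr(X[:, idx[a]], X[:, idx[b]]).statistic
                assert rho**2 < 0.5

    def test_constant_column_directs_to_filtration(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="drop_uninformative"):
            prune_intercorrelated(make_table(X), np.arange(10.0))


class TestNormalization:
    def test_two_point_column_hand_example(self):
        t = make_table([[0.0], [2.0]])
        stats_ = fit_normalization(t)
        assert stats_.mean.iloc[0] == 1.0
        assert stats_.scale.iloc[0] == pytest.approx(math.sqrt(2.0))
        normed = apply_normalization(stats_, t)
        np.testing.assert_allclose(
            normed.descriptors["d0"], [-0.7071, 0.7071], atol=1e-4
        )

    def test_fit_apply_yields_zero_mean_unit_sample_sd(self, rng):
        t = make_table(rng.normal(3.0, 5.0, size=(40, 6)))
        normed = apply_normalization(fit_normalization(t), t)
        means = normed.descriptors.mean(axis=0)
        sds = normed.descriptors.std(axis=0, ddof=1)
        assert np.all(np.abs(means) < 1e-10)
        assert np.all(np.abs(sds - 1.0) < 1e-10)

    def test_constant_column_errors(self):
        with pytest.raises(ValueError, match="scale"):
            fit_normalization(make_table(np.ones((5, 1))))

    def test_training_stats_do_not_recenter_test_table(self, rng):
        train = make_table(rng.normal(size=(30, 2)))
        test = make_table(rng.normal(5.0, 1.0, size=(10, 2)))
        stats_ = fit_normalization(train)
        shifted = apply_normalization(stats_, test)
        # test table keeps its offset relative to the training centre
        assert shifted.descriptors.mean().mean() > 1.0

    def test_unknown_descriptor_errors(self, rng):
        stats_ = fit_normalization(make_table(rng.normal(size=(10, 1))))
        with pytest.raises(KeyError):
            apply_normalization(stats_, make_table(np.ones((3, 1)), names=["zz"]))


class TestIonClass:
    @pytest.mark.parametrize(
        "pkas,expected",
        [
            ([5.0], IonClass.NEUTRAL),
            ([9.0], IonClass.NEUTRAL),
            ([3.0, 9.0], IonClass.ZWITTERION),
            ([3.0, 4.5], IonClass.ACID),
            ([8.0, 9.5], IonClass.BASE),
            ([2.0, 5.0, 10.0], IonClass.ZWITTERION),
            ([7.0, 7.0], IonClass.BASE),  # boundary counts as basic
            ([3.0, 7.0], IonClass.ZWITTERION),
        ],
    )
    def test_printed_rule(self, pkas, expected):
        assert assign_ion_class(pkas) is expected

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            assign_ion_class([])

    def test_non_finite_errors(self):
        with pytest.raises(ValueError):
            assign_ion_class([3.0, float("nan")])


class TestBinnedProfile:
    def test_constant_response_gives_constant_bin_means(self, rng):
        x = rng.normal(size=50)
        prof = binned_response_profile(x, np.full(50, -4.0), n_bins=5)
        filled = prof.loc[~prof["empty"], "mean_response"]
        np.testing.assert_allclose(filled, -4.0)

    def test_linear_response_gives_monotone_means(self):
        x = np.linspace(0, 1, 100)
        prof = binned_response_profile(x, 2 * x, n_bins=4)
        means = prof["mean_response"].to_numpy()
        assert np.all(np.diff(means) > 0)

    def test_six_point_hand_binned_oracle(self):
        x = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        prof = binned_response_profile(x, y, n_bins=2)
        # bins [0,0.5) and [0.5,1]: means of (1,2,3) and (4,5,6)
        np.testing.assert_allclose(prof["mean_response"], [2.0, 5.0])
        np.testing.assert_allclose(prof["count"], [3, 3])

    def test_constant_descriptor_errors(self):
        with pytest.raises(ValueError):
            binned_response_profile(np.ones(10), np.arange(10.0))
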