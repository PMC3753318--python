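import math

import numpy as np
import pytest
from scipy.stats import chi2

from hkascan.hka import (
    HkaLocusData,
    MLHKA,
    fit_neutral,
    fit_selection,
    hka_loglik,
    hka_test,
    lrt_test,
    locus_data_from_frame,
    read_count_table,
    write_count_table,
)
from hkascan.simulate import SimConfig, simulate_counts


def textbook_loglik(data, theta, T, k):
    """Independent re-implementation: plain Poisson pmf per locus."""

    def logpois(x, mu):
        return x * math.log(mu) - mu - math.lgamma(x + 1)

    ll = 0.0
    for d, th, kk in zip(data, theta, k):
        ll += logpois(d.S, kk * th * d.a_n)
        ll += logpois(d.D, th * (T + (1 + kk) / 2))
    return ll


def grid_search_lnL(data, focal=None, passes=4):
    """Exhaustive grid search over all free parameters with refinement."""
    m = len(data)
    ranges = [(math.log(0.1), math.log(100.0))] * m  # log theta_i
    ranges.append((math.log(0.01), math.log(500.0)))  # log T
    if focal is not None:
        ranges.append((math.log(1e-4), math.log(100.0)))  # log k
    ifocal = [d.locus_id for d in data].index(focal) if focal is not None else None

    def value(x):
        theta = np.exp(x[:m])
        T = math.exp(x[m])
        k = np.ones(m)
        if ifocal is not None:
            k[ifocal] = math.exp(x[m + 1])
        return hka_loglik(data, theta, T, k)

    npts = 9
    best_x, best_v = None, -np.inf
    for _ in range(passes):
        axes = [np.linspace(lo, hi, npts) for lo, hi in ranges]
        grid = np.meshgrid(*axes, indexing="ij")
        flat = np.stack([g.ravel() for g in grid], axis=1)
        for x in flat:
            v = value(x)
            if v > best_v:
                best_v, best_x = v, x
        # refine around the current best
        new_ranges = []
        for (lo, hi), xb in zip(ranges, best_x):
            step = (hi - lo) / (npts - 1)
            new_ranges.append((xb - step, xb + step))
        ranges = new_ranges
    return best_v


@pytest.fixture
def one_locus():
    return [HkaLocusData("a", S=5, D=10, L=100, n=2)]


class TestLoglik:
    def test_hand_value(self, one_locus):
        # logPois(5;5) + logPois(10;10)
        assert hka_loglik(one_locus, [5.0], 1.0, [1.0]) == pytest.approx(-3.8189, abs=1e-4)

    def test_neutral_k_identity(self):
        data = [HkaLocusData(f"l{i}", S=4 + i, D=12 + i, L=500, n=6) for i in range(3)]
        theta = np.array([4.0, 5.0, 6.0])
        assert hka_loglik(data, theta, 2.0, np.ones(3)) == pytest.approx(
            hka_loglik(data, theta, 2.0, [1.0, 1.0, 1.0])
        )

    def test_matches_textbook_reimplementation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = int(rng.integers(1, 5))
            data = [
                HkaLocusData(f"l{i}", S=int(rng.integers(0, 30)), D=int(rng.integers(0, 80)),
                             L=500, n=int(rng.integers(2, 10)))
                for i in range(m)
            ]
            theta = rng.uniform(0.5, 20, m)
            T = rng.uniform(0.1, 20)
            k = rng.uniform(0.05, 3, m)
            assert hka_loglik(data, theta, T, k) == pytest.approx(
                textbook_loglik(data, theta, T, k), abs=1e-12
            )

    def test_nonpositive_expectation_rejected(self, one_locus):
        with pytest.raises(ValueError):
            hka_loglik(one_locus, [0.0], 1.0, [1.0])


class TestNeutralFit:
    def test_one_locus_closed_form(self, one_locus):
        # moment equations S = theta, D = theta (T + 1) solve exactly
        fit = fit_neutral(one_locus, seed=1)
        assert fit.theta[0] == pytest.approx(5.0, rel=1e-4)
        assert fit.T == pytest.approx(1.0, rel=1e-3)
        assert fit.converged

    def test_parameter_recovery(self):
        # data simulated at theta=8, T=5 across 20 loci
        errs_theta, errs_T = [], []
        for s in range(30):
            rng = np.random.default_rng(1000 + s)
            data = [
                HkaLocusData(f"l{i}", S=int(rng.poisson(8.0)), D=int(rng.poisson(8.0 * 6)), L=700, n=2)
                for i in range(20)
            ]
            fit = fit_neutral(data, seed=1, n_starts=4)
            errs_theta.append(np.median(np.abs(fit.theta - 8) / 8))
            errs_T.append(abs(fit.T - 5) / 5)
        assert np.median(errs_theta) < 0.25
        assert np.median(errs_T) < 0.25

    def test_duplicating_loci_preserves_T(self):
        data = [HkaLocusData(f"l{i}", S=6 + 2 * i, D=30 + i, L=500, n=6) for i in range(4)]
        doubled = data + [
            HkaLocusData(f"m{i}", S=d.S, D=d.D, L=d.L, n=d.n) for i, d in enumerate(data)
        ]
        f1 = fit_neutral(data, seed=1)
        f2 = fit_neutral(doubled, seed=1)
        assert f2.T == pytest.approx(f1.T, rel=1e-4)


class TestSelectionFit:
    def test_zero_polymorphism_drives_k_down(self):
        data = [HkaLocusData(f"n{i}", S=8, D=30, L=500, n=6) for i in range(5)]
        data.append(HkaLocusData("focal", S=0, D=40, L=500, n=6))
        fit0 = fit_neutral(data, seed=1)
        fit1 = fit_selection(data, "focal", seed=1)
        assert fit1.k_focal < 0.05
        assert fit1.lnL > fit0.lnL

    def test_k_recovery_under_neutrality(self):
        ks = []
        for s in range(200):
            cfg = SimConfig(seed=50_000 + s, n_neutral=7, n_dom=0, n_imp=1, sweeps_enabled=False)
            counts, _ = simulate_counts(cfg)
            data = locus_data_from_frame(counts, "wild")
            ks.append(fit_selection(data, "imp01", seed=1, n_starts=4).k_focal)
        assert 0.7 <= float(np.median(ks)) <= 1.4

    def test_k_monotone_in_focal_S(self):
        base = [HkaLocusData(f"n{i}", S=8, D=30, L=500, n=6) for i in range(5)]
        k_hats = []
        for S in (20, 12, 8, 4, 2, 0):
            data = base + [HkaLocusData("focal", S=S, D=30, L=500, n=6)]
            k_hats.append(fit_selection(data, "focal", seed=1).k_focal)
        assert all(a >= b - 1e-6 for a, b in zip(k_hats, k_hats[1:]))

    @pytest.mark.parametrize("case", [
        dict(loci=[("a", 5, 10), ("b", 7, 25)], focal=None),
        dict(loci=[("a", 5, 10), ("b", 7, 25)], focal="a"),
        dict(loci=[("a", 0, 30), ("b", 9, 28), ("c", 12, 40)], focal="a"),
        dict(loci=[("a", 15, 12), ("b", 3, 30), ("c", 6, 22)], focal=None),
    ])
    def test_optimizer_matches_grid_search(self, case):
        data = [HkaLocusData(lid, S=S, D=D, L=500, n=6) for lid, S, D in case["loci"]]
        if case["focal"] is None:
            opt = fit_neutral(data, seed=1).lnL
        else:
            opt = fit_selection(data, case["focal"], seed=1).lnL
        grid = grid_search_lnL(data, focal=case["focal"])
        assert opt >= grid - 1e-3
        assert abs(opt - grid) < 1e-2  # refined grid converges to the same optimum


class TestLRT:
    def test_chi2_quantile_identity(self):
        data = [HkaLocusData(f"n{i}", S=8, D=30, L=500, n=6) for i in range(4)]
        fit0 = fit_neutral(data, seed=1)
        fit1 = fit_selection(data, "n0", seed=1)
        res = lrt_test(fit0, fit1, df=2)
        assert res.p_value == pytest.approx(chi2.sf(res.lrt, 2))
        assert chi2.sf(5.991, 2) == pytest.approx(0.05, abs=1e-4)

    def test_zero_lrt_gives_p_one(self):
        data = [HkaLocusData(f"n{i}", S=8, D=30, L=500, n=6) for i in range(4)]
        fit0 = fit_neutral(data, seed=1)
        res = lrt_test(fit0, fit_selection(data, "n0", seed=1), df=2)
        # identical loci: the selection model cannot beat neutrality by much
        assert res.lrt < 0.5 and res.p_value > 0.7

    def test_negative_delta_clamped_with_warning(self):
        data = [HkaLocusData(f"n{i}", S=8, D=30, L=500, n=6) for i in range(4)]
        fit0 = fit_neutral(data, seed=1)
        fit1 = fit_selection(data, "n0", seed=1)
        fit1.lnL = fit0.lnL - 1e-3  # emulate optimizer noise
        with pytest.warns(RuntimeWarning):
            res = lrt_test(fit0, fit1, df=2)
        assert res.lrt == 0.0 and res.p_value == 1.0

    def test_type_i_error_conservative(self):
        """df=2 with one free parameter is conservative under the null."""
        N, rej = 300, 0
        for s in range(N):
            cfg = SimConfig(seed=60_000 + s, n_neutral=7, n_dom=0, n_imp=1, sweeps_enabled=False)
            counts, _ = simulate_counts(cfg)
            data = locus_data_from_frame(counts, "improved")
            rej += hka_test(data, "imp01", seed=1, n_starts=4).p_value < 0.05
        rate = rej / N
        assert rate <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / N)


class TestResultsObject:
    def test_summary_and_bse(self):
        data = [HkaLocusData(f"n{i}", S=8 + i, D=30 + i, L=500, n=6) for i in range(4)]
        res = fit_selection(data, "n0", seed=1)
        text = res.summary()
        assert "log-likelihood" in text and "k_n0" in text
        se = res.bse()
        assert "T" in se and np.isfinite(se["theta_n1"])

    def test_focal_must_exist(self):
        data = [HkaLocusData("a", S=5, D=10, L=100, n=2), HkaLocusData("b", S=5, D=10, L=100, n=2)]
        with pytest.raises(ValueError):
            MLHKA(data, focal="zzz")


def test_count_table_roundtrip(tmp_path):
    counts, _ = simulate_counts(SimConfig(seed=4, n_neutral=2, n_dom=1, n_imp=1))
    path = tmp_path / "counts.tsv"
    write_count_table(counts, path)
    back = read_count_table(path)
    assert len(back) == len(counts)
    data = locus_data_from_frame(back, "wild")
    assert {d.locus_id for d in data} == set(counts[counts.pool == "wild"]["locus"])
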