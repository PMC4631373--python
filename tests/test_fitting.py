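import numpy as np
import pytest

from twopac import (
    DiscreteConfig,
    FitError,
    LifeTable,
    ModelParams,
    evaluate_trajectory,
    evolve,
    fit_2pac,
    fit_gompertz,
    fit_k,
    fit_shared_k,
    fit_weibull,
    nonsmurf_survival,
    smurf_survival_table,
    survivorship_curve,
)


def table_from_fractions(ages, fractions):
    return LifeTable.from_counts(ages=ages, n_alive=fractions, p0=1.0)


class TestFitK:
    def test_noiseless_recovery(self):
        t = np.arange(0.0, 15.0)
        table = table_from_fractions(t, np.exp(-0.1911 * t))
        fit = fit_k(table)
        assert fit.params["k"] == pytest.approx(0.1911, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_cohort_recovery_with_bootstrap_ci(self, ref_cohort):
        table = smurf_survival_table(ref_cohort)
        fit = fit_k(table, lifetimes=ref_cohort.smurf_lifetimes(), n_boot=300, seed=11)
        assert 0.17 <= fit.params["k"] <= 0.21
        lo, hi = fit.ci["k"]
        assert lo <= fit.params["k"] <= hi
        assert lo <= 0.1911 <= hi  # true generator value covered

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError, match=">= 3"):
            fit_k(table_from_fractions([0.0, 1.0], [1.0, 0.8]))

    def test_constant_data_rejected(self):
        with pytest.raises(FitError, match="constant"):
            fit_k(table_from_fractions([0.0, 1.0, 2.0], [1.0, 1.0, 1.0]))


class TestFit2pac:
    def test_discrete_round_trip(self, ref_params):
        # daily iterative output refit with the matching forward model
        traj = evolve(ref_params, DiscreteConfig(dt=1.0, t_max=120.0))
        table = survivorship_curve(traj, np.arange(0.0, 90.0))
        fit = fit_2pac(table, k_fixed=0.1911, forward_dt=1.0)
        assert fit.params["a"] == pytest.approx(0.0039, rel=0.02)
        assert fit.params["b"] == pytest.approx(-0.019, rel=0.02)

    def test_continuous_round_trip(self, ref_params, daily_ages):
        traj = evaluate_trajectory(ref_params, daily_ages)
        table = table_from_fractions(daily_ages, traj.n_alive)
        fit = fit_2pac(table, k_fixed=0.1911)
        assert fit.params["a"] == pytest.approx(0.0039, rel=1e-4)
        assert fit.params["t0"] == pytest.approx(ref_params.t0, rel=1e-4)
        assert fit.r_squared >= 0.9999

    def test_subsampling_stability(self, ref_params, daily_ages):
        traj = evaluate_trajectory(ref_params, daily_ages)
        full = fit_2pac(table_from_fractions(daily_ages, traj.n_alive), k_fixed=0.1911)
        half = fit_2pac(
            table_from_fractions(daily_ages[::2], traj.n_alive[::2]), k_fixed=0.1911
        )
        assert half.params["a"] == pytest.approx(full.params["a"], rel=0.05)
        assert half.params["t0"] == pytest.approx(full.params["t0"], rel=0.05)

    def test_instant_death_k_reduces_to_phase1_fit(self, ref_params):
        # with k_fixed huge, only the phase-1 survival matters
        ages = np.arange(0.0, 60.0)
        frac = nonsmurf_survival(ages, ref_params)
        fit = fit_2pac(table_from_fractions(ages, frac), k_fixed=1e6)
        assert fit.params["a"] == pytest.approx(0.0039, rel=0.01)
        assert fit.params["t0"] == pytest.approx(ref_params.t0, rel=0.01)

    def test_shallow_curve_rejected(self):
        ages = np.arange(0.0, 10.0)
        with pytest.raises(FitError, match="50%"):
            fit_2pac(table_from_fractions(ages, 1.0 - 0.01 * ages), k_fixed=0.2)


class TestFastQuadrature:
    def test_gauss_legendre_matches_adaptive(self, ref_params):
        """The fixed-order quadrature used in the fitting hot loop agrees
        with the adaptive path across the fitting parameter regime."""
        from twopac.fitting import _smurf_fraction_batch
        from twopac.model import smurf_count

        for a, k in [(0.001, 0.05), (0.0039, 0.1911), (0.02, 1.0)]:
            p = ModelParams(a=a, t0=5.0, k=k)
            ages = np.array([6.0, 15.0, 30.0, 60.0])
            fast = _smurf_fraction_batch(ages - p.t0, a, k)
            slow = np.array([smurf_count(t, p) for t in ages])
            assert np.allclose(fast, slow, atol=1e-9)


class TestClassicFits:
    def test_gompertz_noiseless_recovery(self):
        ages = np.arange(1.0, 80.0)
        frac = np.exp(-(0.0053 / 0.0942) * (np.exp(0.0942 * ages) - 1.0))
        fit = fit_gompertz(table_from_fractions(ages, frac))
        assert fit.scale == pytest.approx(0.0053, rel=1e-4)
        assert fit.shape == pytest.approx(0.0942, rel=1e-4)
        assert fit.r_squared > 0.999999

    def test_weibull_noiseless_recovery(self):
        ages = np.arange(1.0, 80.0)
        frac = np.exp(-0.000485 * ages**2.4746)
        fit = fit_weibull(table_from_fractions(ages, frac))
        assert fit.scale == pytest.approx(0.000485, rel=1e-4)
        assert fit.shape == pytest.approx(2.4746, rel=1e-4)

    def test_weibull_nested_exponential(self):
        # pure exponential decay is Weibull with shape 1
        ages = np.arange(1.0, 40.0)
        fit = fit_weibull(table_from_fractions(ages, np.exp(-0.05 * ages)))
        assert fit.shape == pytest.approx(1.0, rel=1e-4)


@pytest.fixture(scope="module")
def two_genotypes():
    k = 0.1911
    short = ModelParams(a=0.012, t0=3.0, k=k)
    long_ = ModelParams(a=0.002, t0=9.0, k=k)
    tables = []
    for p in (short, long_):
        ages = np.arange(0.0, 90.0)
        traj = evaluate_trajectory(p, ages)
        tables.append(LifeTable.from_counts(ages=ages, n_alive=traj.n_alive, p0=1.0))
    return (short, long_), tables


class TestFitSharedK:
    def test_distinct_hazards_shared_k(self, two_genotypes):
        (short, long_), tables = two_genotypes
        fits = fit_shared_k(tables, k_fixed=0.1911)
        assert fits[0].params["a"] == pytest.approx(short.a, rel=0.02)
        assert fits[1].params["a"] == pytest.approx(long_.a, rel=0.02)
        assert all(f.r_squared > 0.99 for f in fits)
        assert fits[0].extras["sir_slope"] > fits[1].extras["sir_slope"]

    def test_single_curve_matches_fit_2pac(self, two_genotypes):
        _, tables = two_genotypes
        batch = fit_shared_k(tables[:1], k_fixed=0.1911)[0]
        single = fit_2pac(tables[0], k_fixed=0.1911)
        assert batch.params == pytest.approx(single.params)

    def test_mismatched_k_fits_worse(self, two_genotypes):
        _, tables = two_genotypes
        matched = fit_shared_k(tables, k_fixed=0.1911)
        wrong = fit_shared_k(tables, k_fixed=0.6)
        for m, w in zip(matched, wrong):
            assert w.r_squared < m.r_squared

    def test_per_curve_failure_does_not_abort(self, two_genotypes):
        _, tables = two_genotypes
        bad = LifeTable.from_counts(ages=[0.0, 1.0, 2.0, 3.0], n_alive=[1.0, 1.0, 1.0, 1.0], p0=1.0)
        fits = fit_shared_k([tables[0], bad], k_fixed=0.1911)
        assert fits[0].converged and not fits[1].converged
        assert "error" in fits[1].extras


class TestStochasticRecovery:
    def test_median_errors_across_seeds(self, ref_params):
        """Cohorts at the reference size: median relative error on the
        hazard slope and onset age stays within 10%."""
        from twopac import AssayDesign, sample_cohort, to_life_table

        errs_a, errs_t0, ks = [], [], []
        for seed in range(20):
            ev = sample_cohort(ref_params, AssayDesign(n_individuals=1146, n_vials=4, seed=seed))
            ks.append(fit_k(smurf_survival_table(ev)).params["k"])
            table = to_life_table(ev, np.arange(0.0, 70.0))
            fit = fit_2pac(table, k_fixed=0.1911)
            errs_a.append(abs(fit.params["a"] - ref_params.a) / ref_params.a)
            errs_t0.append(abs(fit.params["t0"] - ref_params.t0) / ref_params.t0)
        assert 0.17 <= np.median(ks) <= 0.21
        assert np.median(errs_a) <= 0.10
        assert np.median(errs_t0) <= 0.10
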