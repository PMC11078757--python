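"""Global mixture fitting, model selection, bootstrap, correlation, Tikhonov."""

import numpy as np
import pytest

from deerfret import (
    GaussianComponent,
    GlobalFitSpec,
    MixtureModel,
    bootstrap_ci,
    compare_conditions,
    default_distance_axis,
    default_time_axis,
    forward_signal,
    global_fit,
    population_correlation,
    select_model,
    tikhonov_fit,
)
from deerfret.deer.fit import BootstrapReport, disjunct_intervals
from deerfret.deer.forward import DipolarSignal


def make_model(specs, pops, lam=0.5, conc=50.0):
    """specs: list of (center, width); pops: dict cond -> weights."""
    return MixtureModel(
        components=[GaussianComponent(c, w) for c, w in specs],
        populations={k: np.asarray(v, float) for k, v in pops.items()},
        modulation_depths={k: lam for k in pops},
        concentrations={"g": conc},
        condition_groups={k: "g" for k in pops},
    )


def simulate(model, conds=None, noise=0.0, seed=0):
    t, r = default_time_axis(), default_distance_axis()
    rng = np.random.default_rng(seed)
    out = []
    for c in conds or model.conditions:
        sig = forward_signal(model, c, t, r)
        amp = sig.amplitude + (rng.normal(0, noise, len(t)) if noise else 0.0)
        out.append(DipolarSignal(time=t, amplitude=amp, condition=c,
                                 group="g", noise_sd=noise))
    return out


@pytest.fixture(scope="module")
def noiseless_single():
    model = make_model([(33.0, 3.0)], {"c": [1.0]})
    return simulate(model)


class TestGlobalFit:
    def test_noiseless_single_component_recovery(self, noiseless_single):
        fit = global_fit(noiseless_single,
                         GlobalFitSpec(n_components=1, n_starts=3))
        comp = fit.model.components[0]
        assert comp.center == pytest.approx(33.0, abs=0.01)
        assert comp.width == pytest.approx(3.0, abs=0.01)
        assert fit.model.modulation_depths["c"] == pytest.approx(0.5, abs=0.01)

    def test_populations_sum_to_one(self):
        model = make_model([(30.0, 3.0), (45.0, 3.0)],
                           {"a": [0.3, 0.7], "b": [0.6, 0.4]})
        fit = global_fit(simulate(model, noise=0.003, seed=1),
                         GlobalFitSpec(n_components=2, n_starts=4))
        for c in ("a", "b"):
            assert fit.model.populations[c].sum() == pytest.approx(1.0, abs=1e-9)

    def test_recovery_at_study_noise(self):
        """Centers/widths within 0.5 A, populations within 0.03 at sd 0.003."""
        model = make_model([(30.0, 3.0), (45.0, 4.0)],
                           {"a": [0.35, 0.65], "b": [0.7, 0.3]})
        fit = global_fit(simulate(model, noise=0.003, seed=2),
                         GlobalFitSpec(n_components=2, n_starts=6))
        centers = [c.center for c in fit.model.components]
        widths = [c.width for c in fit.model.components]
        assert centers == pytest.approx([30.0, 45.0], abs=0.5)
        assert widths == pytest.approx([3.0, 4.0], abs=0.5)
        assert fit.model.populations["a"] == pytest.approx([0.35, 0.65],
                                                           abs=0.03)

    def test_deterministic_given_seed(self):
        model = make_model([(35.0, 3.0)], {"c": [1.0]})
        data = simulate(model, noise=0.005, seed=3)
        spec = GlobalFitSpec(n_components=1, n_starts=4, seed=11)
        f1 = global_fit(data, spec)
        f2 = global_fit(data, spec)
        assert f1.rss == f2.rss
        assert f1.model.components[0].center == f2.model.components[0].center
        assert np.array_equal(f1.per_dataset_fit["c"], f2.per_dataset_fit["c"])

    def test_adjacent_unequal_width_components_resolved(self):
        """The per-component-width advantage: 39 A (sigma 3.8) next to
        43 A (sigma 2) are separated by the mixture fit."""
        model = MixtureModel(
            components=[GaussianComponent(39.0, 3.8), GaussianComponent(43.0, 2.0)],
            populations={f"c{i}": np.array([p, 1 - p])
                         for i, p in enumerate((0.25, 0.5, 0.75, 0.35, 0.65))},
            modulation_depths={f"c{i}": 0.5 for i in range(5)},
            concentrations={"g": 50.0},
            condition_groups={f"c{i}": "g" for i in range(5)},
        )
        data = simulate(model, noise=0.003, seed=4)
        fit = global_fit(data, GlobalFitSpec(n_components=2, n_starts=8))
        centers = [c.center for c in fit.model.components]
        assert centers == pytest.approx([39.0, 43.0], abs=0.7)


class TestSelectModel:
    def test_single_component_when_range_allows(self, noiseless_single):
        k, table, _ = select_model(noiseless_single, 1, 3,
                                   GlobalFitSpec(n_components=1, n_starts=3))
        assert k == 1

    def test_two_component_fixture(self):
        model = make_model([(30.0, 3.0), (45.0, 3.5)],
                           {"a": [0.4, 0.6], "b": [0.7, 0.3]})
        data = simulate(model, noise=0.003, seed=5)
        k, table, _ = select_model(data, 1, 4,
                                   GlobalFitSpec(n_components=1, n_starts=4))
        assert k == 2
        assert set(table.columns) >= {"k", "rss", "aicc", "bic"}

    def test_selection_never_overshoots_by_more_than_one(self):
        """Across seeded replicates of the 2-component fixture, the AICc
        choice stays within true k + 1."""
        model = make_model([(30.0, 3.0), (45.0, 3.5)], {"a": [0.4, 0.6]})
        for seed in range(10):
            data = simulate(model, noise=0.003, seed=100 + seed)
            k, _, _ = select_model(data, 1, 4,
                                   GlobalFitSpec(n_components=1, n_starts=3))
            assert k <= 3

    def test_invalid_range_rejected(self, noiseless_single):
        with pytest.raises(ValueError):
            select_model(noiseless_single, 5, 2)


class TestBootstrap:
    def test_vanishing_noise_gives_tight_cis(self):
        model = make_model([(33.0, 3.0)], {"c": [1.0]})
        data = simulate(model, noise=1e-6, seed=6)
        fit = global_fit(data, GlobalFitSpec(n_components=1, n_starts=2))
        boot = bootstrap_ci(data, fit, n_iter=50, seed=0)
        width = boot.centers_ci[0, 1] - boot.centers_ci[0, 0]
        assert width < 0.05

    def test_reproducible_given_seed(self):
        model = make_model([(33.0, 3.0)], {"c": [1.0]})
        data = simulate(model, noise=0.005, seed=7)
        fit = global_fit(data, GlobalFitSpec(n_components=1, n_starts=2))
        b1 = bootstrap_ci(data, fit, n_iter=25, seed=3)
        b2 = bootstrap_ci(data, fit, n_iter=25, seed=3)
        assert np.array_equal(b1.centers_ci, b2.centers_ci)

    def test_needs_two_iterations(self):
        model = make_model([(33.0, 3.0)], {"c": [1.0]})
        data = simulate(model)
        fit = global_fit(data, GlobalFitSpec(n_components=1, n_starts=1))
        with pytest.raises(ValueError):
            bootstrap_ci(data, fit, n_iter=1)

    def test_default_iteration_count_is_thousand(self):
        import inspect
        sig = inspect.signature(bootstrap_ci)
        assert sig.parameters["n_iter"].default == 1000


def _report(ci_low, ci_high, cond="c"):
    ci = np.array([[ci_low, ci_high]])
    return BootstrapReport(n_iter=10, centers_ci=ci, widths_ci=ci,
                           populations_ci={cond: ci},
                           lambda_ci={cond: (0.4, 0.6)},
                           concentration_ci={"g": (40, 60)},
                           centers_median=np.array([33.0]),
                           populations_median={cond: np.array([0.5])},
                           point=None)


class TestCompareConditions:
    def test_disjunct_intervals_significant(self):
        assert compare_conditions(_report(0.10, 0.20), _report(0.25, 0.35), 0)

    def test_overlapping_intervals_not_significant(self):
        assert not compare_conditions(_report(0.10, 0.30), _report(0.25, 0.45), 0)

    def test_missing_component_rejected(self):
        with pytest.raises(IndexError):
            compare_conditions(_report(0.1, 0.2), _report(0.3, 0.4), 5)

    def test_interval_helper(self):
        assert disjunct_intervals((0.0, 0.1), (0.2, 0.3))
        assert not disjunct_intervals((0.0, 0.25), (0.2, 0.3))


class TestPopulationCorrelation:
    def test_identical_vectors_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, 30)
        pops = np.column_stack([v, v, 1 - 2 * v / 3])
        rep = population_correlation(pops / pops.sum(1, keepdims=True))
        assert rep.r[0, 1] == pytest.approx(1.0)

    def test_two_component_closure_anticorrelation(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.2, 0.8, 20)
        rep = population_correlation(np.column_stack([w, 1 - w]))
        assert rep.r[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_reported_missing(self):
        w = np.column_stack([np.full(10, 0.5), np.full(10, 0.5)])
        rep = population_correlation(w)
        assert np.isnan(rep.r[0, 1])

    def test_null_distribution_of_pearson_r(self):
        """|r| > 0.36 in about 5% of independent draws at n = 30.

        0.36 is the two-sided 5% critical value of Pearson r at n = 30;
        1000 replicates of independent uniforms must land near it.
        """
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            a, b = rng.uniform(size=(2, 30))
            r = np.corrcoef(a, b)[0, 1]
            hits += abs(r) > 0.36
        assert hits / n_rep == pytest.approx(0.05, abs=0.02)

    def test_uncorrelated_block_listed_for_exclusion(self):
        from deerfret import reference_ensemble
        fix = reference_ensemble()
        rep = population_correlation(fix.population_matrix(),
                                     centers=fix.centers)
        assert rep.excluded == [4, 5]          # the 45 and 57 A components
        assert rep.p[0, 1] < 0.05              # 26-33 correlated
        assert rep.p[2, 3] < 0.05              # 39-43 correlated

    def test_needs_three_conditions(self):
        with pytest.raises(ValueError):
            population_correlation(np.ones((2, 3)) / 3)


class TestTikhonov:
    def test_noiseless_single_gaussian_mode(self):
        model = make_model([(40.0, 3.0)], {"c": [1.0]})
        sig = simulate(model)[0]
        dist = default_distance_axis()
        res = tikhonov_fit(sig, dist, lam=0.5, concentration=50.0)
        assert np.all(res.distribution >= 0)
        mode = dist.r[np.argmax(res.distribution)]
        assert mode == pytest.approx(40.0, abs=0.5)

    def test_rejects_all_zero_signal(self):
        t = default_time_axis()
        sig = DipolarSignal(time=t, amplitude=np.zeros(len(t)), condition="z")
        with pytest.raises(ValueError):
            tikhonov_fit(sig, default_distance_axis(), lam=0.5,
                         concentration=50.0)

    def test_matches_mixture_distribution(self):
        """Model-free inversion reproduces the mixture distribution:
        mean absolute difference below 10% of the peak height."""
        from deerfret import evaluate_mixture
        model = make_model([(33.0, 4.0), (43.0, 2.5)], {"c": [0.55, 0.45]})
        sig = simulate(model, noise=0.002, seed=8)[0]
        dist = default_distance_axis()
        res = tikhonov_fit(sig, dist, lam=0.5, concentration=50.0)
        p_true = evaluate_mixture(model, "c", dist)
        mad = np.mean(np.abs(res.distribution - p_true))
        assert mad < 0.1 * p_true.max()
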