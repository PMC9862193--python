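"""Estimation machinery with fast stub simulators.

The stubs map parameter sets to observables through cheap analytic
functions, so objective structure, screening and sweep logic can be tested
without ODE integration (the full-pipeline behaviour is covered by the
acceptance suite).
"""
import numpy as np
import pandas as pd
import pytest

from yeastff import ObservationBundle, load_calibrated_parameters, load_table1
from yeastff.estimation import (
    EstimationConfig,
    build_residuals,
    combinatorial_screen,
    fit_subset,
    fold_change_report,
    objective_parts,
    regularization_sweep,
)
from yeastff.params import TREHALOSE_CYCLE_REACTIONS


class StubSimulator:
    """Observables are direct (or product) reads of parameter values."""

    def __init__(self, mapping, times=np.array([0.0, 100.0, 300.0])):
        #: mapping (table, series) -> callable(params) -> scalar level
        self.mapping = mapping
        self.observables = {k: times for k in mapping}

    def __call__(self, params):
        return {k: np.full(len(t), self.mapping[k](params))
                for k, t in self.observables.items()}


def bundle_for(levels, times=np.array([0.0, 100.0, 300.0])):
    rows = []
    for (tab, key), level in levels.items():
        rows.append(pd.DataFrame({"series": key, "time_s": times,
                                  "value": level, "sd": 0.05 * abs(level) + 1e-3,
                                  "table": tab}))
    df = pd.concat(rows, ignore_index=True)
    return ObservationBundle(
        conc=df[df.table == "conc"][["series", "time_s", "value", "sd"]],
        flux=df[df.table == "flux"][["series", "time_s", "value", "sd"]])


@pytest.fixture(scope="module")
def reference():
    return load_calibrated_parameters()


@pytest.fixture()
def two_param_problem(reference):
    """Independent 2-parameter toy with its optimum at known values."""
    truth = {"HXT.Vmax": 1.7, "HXT.Km": 0.9}
    sim = StubSimulator({
        ("conc", "A"): lambda p: p["HXT.Vmax"],
        ("conc", "B"): lambda p: p["HXT.Km"],
    })
    data = bundle_for({("conc", "A"): truth["HXT.Vmax"],
                       ("conc", "B"): truth["HXT.Km"]})
    start = reference.replace({"HXT.Vmax": 5.0, "HXT.Km": 2.0})
    config = EstimationConfig(subset=("HXT",),
                              free_names=("HXT.Vmax", "HXT.Km"),
                              reference=start)
    return sim, data, config, truth


class TestResiduals:
    def test_perfect_fit_zero_residuals(self, reference):
        sim = StubSimulator({("conc", "A"): lambda p: p["HXT.Vmax"]})
        data = bundle_for({("conc", "A"): reference["HXT.Vmax"]})
        config = EstimationConfig(subset=("HXT",), free_names=("HXT.Vmax",),
                                  reference=reference)
        r = build_residuals(np.log10([reference["HXT.Vmax"]]), config, data, sim)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_lambda_zero_has_no_penalty_block(self, two_param_problem):
        sim, data, config, _ = two_param_problem
        r0 = build_residuals(np.array([0.0, 0.0]), config, data, sim)
        n_data = sum(len(t) for t in sim.observables.values())
        assert len(r0) == n_data
        config_pen = EstimationConfig(subset=config.subset,
                                      free_names=config.free_names,
                                      reference=config.reference, lam=0.5)
        r1 = build_residuals(np.array([0.0, 0.0]), config_pen, data, sim)
        assert len(r1) == n_data + len(config.free_names)

    def test_objective_decomposition_identity(self, two_param_problem, rng):
        sim, data, config, _ = two_param_problem
        config = EstimationConfig(subset=config.subset,
                                  free_names=config.free_names,
                                  reference=config.reference, lam=0.7)
        for _ in range(10):
            theta = rng.uniform(-1, 1, 2)
            r = build_residuals(theta, config, data, sim)
            data_err, param_err = objective_parts(theta, config, data, sim)
            ref = np.log10([config.reference[k] for k in config.free_names])
            assert float(r @ r) == pytest.approx(data_err + param_err, rel=1e-12)
            assert param_err == pytest.approx(
                0.7 * np.sum(np.abs(ref - theta)), rel=1e-12)

    def test_simulation_failure_becomes_finite_penalty(self, reference):
        def boom(params):
            raise RuntimeError("no steady state")

        sim = StubSimulator({("conc", "A"): boom})
        data = bundle_for({("conc", "A"): 1.0})
        config = EstimationConfig(subset=("HXT",), free_names=("HXT.Vmax",),
                                  reference=reference)
        r = build_residuals(np.array([0.0]), config, data, sim)
        assert np.all(np.isfinite(r)) and np.all(r > 100.0)

    def test_weights_scale_residual_blocks(self, reference):
        sim = StubSimulator({("flux", "HXT"): lambda p: p["HXT.Vmax"]})
        data = bundle_for({("flux", "HXT"): 2.0})
        kw = dict(subset=("HXT",), free_names=("HXT.Vmax",),
                  reference=reference)
        r1 = build_residuals(np.array([0.0]),
                             EstimationConfig(**kw), data, sim)
        r3 = build_residuals(np.array([0.0]),
                             EstimationConfig(weights={"flux": 3.0}, **kw),
                             data, sim)
        np.testing.assert_allclose(r3, 3.0 * r1, rtol=1e-12)


class TestFit:
    def test_empty_free_set_returns_reference(self, reference):
        sim = StubSimulator({("conc", "A"): lambda p: p["HXT.Vmax"]})
        data = bundle_for({("conc", "A"): 3.0})
        config = EstimationConfig(subset=("HXT",), free_names=(),
                                  reference=reference)
        fit = fit_subset(config, data, simulator=sim)
        assert fit.success
        assert fit.param_deviation == 0.0
        assert fit.estimate["HXT.Vmax"] == reference["HXT.Vmax"]
        assert fit.data_error > 0

    def test_two_param_optimum_matches_grid_oracle(self, two_param_problem):
        sim, data, config, truth = two_param_problem
        fit = fit_subset(config, data, simulator=sim)
        # independent brute-force grid over log10 space
        grid = np.linspace(-1.0, 1.0, 81)
        best = np.inf
        for a in grid:
            for b in grid:
                theta = np.array([np.log10(5.0) + a, np.log10(2.0) + b])
                r = build_residuals(theta, config, data, sim)
                best = min(best, float(r @ r))
        assert fit.cost <= best + 1e-6
        assert fit.estimate["HXT.Vmax"] == pytest.approx(truth["HXT.Vmax"],
                                                         rel=1e-5)
        assert fit.estimate["HXT.Km"] == pytest.approx(truth["HXT.Km"],
                                                       rel=1e-5)

    def test_free_parameter_must_belong_to_subset(self, reference):
        with pytest.raises(ValueError, match="outside subset"):
            EstimationConfig(subset=("HXT",), free_names=("GLK.Vmax",),
                             reference=reference)


def make_screen_fixture(reference):
    """Data generated at adapted HXT/GLK values; only subsets freeing both
    can reach zero misfit."""
    truth = {"HXT.Vmax": 1.7, "GLK.Vmax": 15.75}
    sim = StubSimulator({
        ("flux", "HXT"): lambda p: p["HXT.Vmax"],
        ("flux", "GLK"): lambda p: p["GLK.Vmax"],
    })
    data = bundle_for({("flux", "HXT"): truth["HXT.Vmax"],
                       ("flux", "GLK"): truth["GLK.Vmax"]})
    start = reference.replace({"HXT.Vmax": 8.13, "GLK.Vmax": 6.25})
    estimable = {"HXT": ("Vmax",), "GLK": ("Vmax",),
                 **{r: () for r in TREHALOSE_CYCLE_REACTIONS}}
    tre = TREHALOSE_CYCLE_REACTIONS
    subsets = [tre, tre + ("HXT",), tre + ("GLK",), tre + ("HXT", "GLK")]
    return sim, data, start, estimable, subsets


class TestScreen:
    def test_single_subset_single_weight_equals_fit_subset(self, reference):
        sim, data, start, estimable, subsets = make_screen_fixture(reference)
        table = combinatorial_screen([subsets[-1]], [{}], data, start,
                                     simulator=sim, estimable=estimable)
        config = EstimationConfig(subset=subsets[-1],
                                  free_names=("HXT.Vmax", "GLK.Vmax"),
                                  reference=start)
        fit = fit_subset(config, data, simulator=sim)
        assert table.iloc[0]["cost"] == pytest.approx(fit.cost, abs=1e-10)

    def test_subsets_with_both_adapted_enzymes_rank_first(self, reference):
        sim, data, start, estimable, subsets = make_screen_fixture(reference)
        table = combinatorial_screen(subsets, [{}], data, start,
                                     simulator=sim, estimable=estimable)
        assert table.iloc[0]["subset_id"].endswith("HXT+GLK")

    def test_uniform_weight_scaling_preserves_ranking(self, reference):
        sim, data, start, estimable, subsets = make_screen_fixture(reference)
        t1 = combinatorial_screen(subsets, [{"flux": 1.0}], data, start,
                                  simulator=sim, estimable=estimable)
        t5 = combinatorial_screen(subsets, [{"flux": 5.0}], data, start,
                                  simulator=sim, estimable=estimable)
        assert list(t1["subset_id"]) == list(t5["subset_id"])

    def test_missing_trehalose_cycle_rejected(self, reference):
        sim, data, start, estimable, _ = make_screen_fixture(reference)
        with pytest.raises(ValueError, match="trehalose"):
            combinatorial_screen([("HXT", "GLK")], [{}], data, start,
                                 simulator=sim, estimable=estimable)

    def test_ranking_invariant_to_observable_order(self, reference):
        sim, data, start, estimable, subsets = make_screen_fixture(reference)
        shuffled = ObservationBundle(
            conc=data.conc.sample(frac=1.0, random_state=5),
            flux=data.flux.sample(frac=1.0, random_state=6))
        t1 = combinatorial_screen(subsets, [{}], data, start,
                                  simulator=sim, estimable=estimable)
        t2 = combinatorial_screen(subsets, [{}], shuffled, start,
                                  simulator=sim, estimable=estimable)
        assert list(t1["subset_id"]) == list(t2["subset_id"])


class TestSweep:
    def _problem(self, reference):
        sim = StubSimulator({("flux", "HXT"): lambda p: p["HXT.Vmax"]})
        data = bundle_for({("flux", "HXT"): 1.7})
        start = reference.replace({"HXT.Vmax": 8.13})
        estimable = {"HXT": ("Vmax",)}
        return sim, data, start, estimable

    def test_lambda_zero_equals_unregularized(self, reference):
        sim, data, start, estimable = self._problem(reference)
        res = regularization_sweep(("HXT",), [0.0, 1.0], data, start,
                                   simulator=sim, estimable=estimable)
        config = EstimationConfig(subset=("HXT",), free_names=("HXT.Vmax",),
                                  reference=start)
        fit0 = fit_subset(config, data, simulator=sim)
        row0 = res["curve"][res["curve"].lam == 0.0].iloc[0]
        assert row0["data_error"] == pytest.approx(fit0.data_error, abs=1e-12)

    def test_large_lambda_pins_to_reference(self, reference):
        sim, data, start, estimable = self._problem(reference)
        res = regularization_sweep(("HXT",), [0.0, 1e4], data, start,
                                   simulator=sim, estimable=estimable)
        est = res["fits"][1e4].estimate["HXT.Vmax"]
        assert abs(np.log10(est) - np.log10(8.13)) < 1e-2

    def test_data_error_nondecreasing(self, reference):
        sim, data, start, estimable = self._problem(reference)
        res = regularization_sweep(("HXT",), [0.0, 0.1, 10.0, 1e4], data,
                                   start, simulator=sim, estimable=estimable)
        err = res["curve"]["data_error"].to_numpy()
        assert np.all(np.diff(err) >= -0.01 * (err[:-1] + 1e-12))

    def test_knee_rule_picks_largest_acceptable(self, reference):
        sim, data, start, estimable = self._problem(reference)
        res = regularization_sweep(("HXT",), [0.0, 1e-6, 1e4], data, start,
                                   simulator=sim, estimable=estimable)
        assert res["lambda"] == pytest.approx(1e-6)

    def test_grid_must_include_zero(self, reference):
        sim, data, start, estimable = self._problem(reference)
        with pytest.raises(ValueError, match="include 0"):
            regularization_sweep(("HXT",), [0.1, 1.0], data, start,
                                 simulator=sim, estimable=estimable)

    def test_collinear_pair_resolved_toward_reference(self, reference):
        """Two perfectly correlated parameters (only their product is
        observed): regularization breaks the dependency by keeping at least
        one of them at its reference value."""
        sim = StubSimulator({("flux", "HXT"):
                             lambda p: p["HXT.Vmax"] / p["HXT.Km"]})
        target = 4.0
        data = bundle_for({("flux", "HXT"): target})
        start = reference.replace({"HXT.Vmax": 2.0, "HXT.Km": 1.0})
        config = EstimationConfig(subset=("HXT",),
                                  free_names=("HXT.Vmax", "HXT.Km"),
                                  reference=start, lam=0.05, max_nfev=200)
        fit = fit_subset(config, data, simulator=sim)
        est_v, est_k = fit.estimate["HXT.Vmax"], fit.estimate["HXT.Km"]
        assert est_v / est_k == pytest.approx(target, rel=2e-2)
        dev_v = abs(np.log10(est_v / 2.0))
        dev_k = abs(np.log10(est_k / 1.0))
        assert min(dev_v, dev_k) < 0.05  # one stays pinned at its reference


class TestFoldChange:
    def test_table1_fold_changes(self):
        t1 = load_table1()
        ref = {k: v["reference"] for k, v in t1.items()}
        est = {k: v["estimated"] for k, v in t1.items()}
        table = fold_change_report(ref, est).set_index(
            ["enzyme", "parameter"])
        assert table.loc[("GLK", "Vmax"), "fold_change"] == 2.52
        assert table.loc[("GLK", "Ki_T6P"), "fold_change"] == 2.51
        assert table.loc[("GLK", "Km_GLC"), "fold_change"] == 0.31
        assert table.loc[("HXT", "Vmax"), "fold_change"] == 0.21

    def test_unchanged_parameters_omitted(self):
        table = fold_change_report({"HXT.Vmax": 2.0, "HXT.Km": 1.0},
                                   {"HXT.Vmax": 2.0, "HXT.Km": 3.0})
        assert list(table["parameter"]) == ["Km"]

    def test_missing_key_reported_as_gap(self):
        table = fold_change_report({"HXT.Vmax": 2.0},
                                   {"HXT.Vmax": 4.0, "HXT.Km": 1.0})
        gap = table[table.parameter == "Km"].iloc[0]
        assert np.isnan(gap["fold_change"]) and pd.isna(gap["reference"])
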