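"""Fitting, chain-length selection, composite decomposition, bootstrap, bleach removal."""

import math
from dataclasses import replace

import numpy as np
import pytest

import crckinetics as ck
from crckinetics.fitting import initial_template

from conftest import noise_free_curve


@pytest.fixture(scope="module")
def delayed_truth():
    return ck.CompositeModel.single(
        ck.CRCParameters(rates=(0.1, 0.02, 0.01), detachment_delay=50.0,
                         amplitude=1000.0, has_removal=True))


@pytest.fixture(scope="module")
def delayed_curve(delayed_truth):
    return noise_free_curve(delayed_truth, interval=2.0, duration=600.0)


class TestFitFixedStructure:
    def test_noise_free_recovery_is_exact(self, delayed_truth, delayed_curve):
        res = ck.fit_fixed_structure(delayed_curve, delayed_truth, options=ck.FitOptions(seed=1))
        fitted = res.model.components[0][0]
        truth = delayed_truth.components[0][0]
        np.testing.assert_allclose(fitted.rates, truth.rates, rtol=1e-4)
        assert fitted.detachment_delay == pytest.approx(truth.detachment_delay, rel=1e-4)
        assert fitted.amplitude == pytest.approx(truth.amplitude, rel=1e-4)
        assert res.converged

    def test_recovery_from_heuristic_start(self, delayed_truth, delayed_curve):
        # same structure but data-driven starting values: must find the optimum too
        tmpl = initial_template(delayed_curve, 3, removal=True)
        res = ck.fit_fixed_structure(delayed_curve, tmpl, options=ck.FitOptions(seed=2))
        pred = res.predict()
        truth_vals = ck.evaluate_model(delayed_truth, delayed_curve.timepoints)
        peak = np.max(truth_vals)
        assert np.max(np.abs(pred - truth_vals)) / peak <= 1e-4

    def test_sse_self_consistency(self, delayed_truth, delayed_curve):
        res = ck.fit_fixed_structure(delayed_curve, delayed_truth, options=ck.FitOptions(seed=1))
        assert res.recompute_sse() == pytest.approx(res.sse, rel=1e-12, abs=1e-300)

    def test_positivity_of_fitted_parameters(self, delayed_curve):
        tmpl = initial_template(delayed_curve, 3, removal=True)
        res = ck.fit_fixed_structure(delayed_curve, tmpl, options=ck.FitOptions(seed=3))
        p = res.model.components[0][0]
        assert all(k > 0 for k in p.rates)
        assert p.amplitude > 0 and p.detachment_delay >= 0

    def test_seeded_determinism(self, delayed_curve):
        tmpl = initial_template(delayed_curve, 3, removal=True)
        r1 = ck.fit_fixed_structure(delayed_curve, tmpl, options=ck.FitOptions(seed=7))
        r2 = ck.fit_fixed_structure(delayed_curve, tmpl, options=ck.FitOptions(seed=7))
        assert r1.sse == r2.sse
        assert r1.model == r2.model

    def test_zero_curve_never_crashes(self):
        t = np.arange(0.0, 100.0, 2.0)
        curve = ck.KineticCurve(timepoints=t, intensity_mean=np.zeros(t.size),
                                intensity_sd=np.zeros(t.size), n_cells=5)
        tmpl = ck.CompositeModel.single(ck.CRCParameters(rates=(0.1,), amplitude=1.0))
        try:
            res = ck.fit_fixed_structure(curve, tmpl, options=ck.FitOptions(seed=0, n_starts=3))
        except ck.NonConvergenceError:
            return  # acceptable contract outcome
        # amplitude driven to its lower rail on an all-zero curve
        assert res.model.components[0][0].amplitude <= 1e-3

    def test_insufficient_data_is_input_error(self, delayed_truth):
        t = np.array([0.0, 2.0, 4.0, 6.0])
        curve = ck.KineticCurve(timepoints=t, intensity_mean=np.array([0.0, 1.0, 2.0, 3.0]),
                                intensity_sd=np.zeros(4), n_cells=3)
        with pytest.raises(ck.InputError):
            ck.fit_fixed_structure(curve, delayed_truth)

    def test_inverse_variance_weighting(self, delayed_truth):
        design = ck.SimulationDesign(n_cells=12, sampling_interval=2.0, duration=600.0,
                                     noise_sd_fraction=0.05, cell_scale_sd=0.1, seed=4)
        curve = ck.simulate_curve(delayed_truth, design)
        # SD can be ~0 at t=0 for baseline-subtracted sims: nudge
        curve = ck.KineticCurve(timepoints=curve.timepoints, intensity_mean=curve.intensity_mean,
                                intensity_sd=np.maximum(curve.intensity_sd, 1e-3),
                                n_cells=curve.n_cells, metadata=curve.metadata)
        res = ck.fit_fixed_structure(curve, delayed_truth,
                                     options=ck.FitOptions(seed=4, weighting="inverse-variance"))
        assert res.converged
        assert res.recompute_sse() == pytest.approx(res.sse, rel=1e-10)

    def test_fixed_parameters_stay_fixed(self, delayed_truth, delayed_curve):
        res = ck.fit_fixed_structure(delayed_curve, delayed_truth,
                                     options=ck.FitOptions(seed=1), fixed=("c0.tau",))
        assert res.model.components[0][0].detachment_delay == 50.0
        assert "c0.tau" not in res.parameter_standard_errors


class TestSelectChainLength:
    def test_recovers_generating_n_with_removal(self, delayed_curve):
        res = ck.select_chain_length(delayed_curve, removal=True, options=ck.FitOptions(seed=5))
        assert res.n_selected == 3
        ns = [n for n, _, _ in res.selection_trace]
        assert ns == sorted(ns) and len(set(ns)) == len(ns)

    def test_single_exponential_selects_one(self):
        truth = ck.CompositeModel.single(ck.CRCParameters(rates=(0.05,), amplitude=500.0))
        curve = noise_free_curve(truth, interval=1.0, duration=200.0)
        res = ck.select_chain_length(curve, removal=False, options=ck.FitOptions(seed=6))
        assert res.n_selected == 1

    def test_selection_trace_minimality(self, delayed_curve):
        # the returned n is the last strictly-improving one: its successor failed the criterion
        res = ck.select_chain_length(delayed_curve, removal=True, options=ck.FitOptions(seed=5))
        trace = res.selection_trace
        assert trace[-1][0] == res.n_selected + 1  # one more n was tried and rejected
        assert trace[-2][1] - trace[-1][1] <= res.options.aicc_threshold

    def test_sse_criterion_also_works(self):
        truth = ck.CompositeModel.single(ck.CRCParameters(rates=(0.1, 0.03), amplitude=800.0))
        curve = noise_free_curve(truth, interval=1.0, duration=300.0)
        res = ck.select_chain_length(curve, removal=False,
                                     options=ck.FitOptions(seed=8, selection_criterion="sse"))
        assert res.n_selected == 2

    def test_no_plateau_flag_at_cap(self):
        truth = ck.CompositeModel.single(
            ck.CRCParameters(rates=(0.4, 0.2, 0.1, 0.05), amplitude=900.0))
        curve = noise_free_curve(truth, interval=1.0, duration=400.0)
        res = ck.select_chain_length(curve, removal=False,
                                     options=ck.FitOptions(seed=9, n_max=2))
        assert res.n_selected == 2
        assert res.no_plateau


class TestFitComposite:
    def test_two_phase_recovery_sorted(self):
        truth = ck.CompositeModel(components=(
            (ck.CRCParameters(rates=(math.log(2) / 5,), amplitude=400.0), "phase"),
            (ck.CRCParameters(rates=(math.log(2) / 120,), amplitude=600.0), "phase")))
        curve = noise_free_curve(truth, interval=1.0, duration=720.0)
        tmpl = ck.CompositeModel(components=(
            (ck.CRCParameters(rates=(0.01,), amplitude=500.0), "phase"),
            (ck.CRCParameters(rates=(0.3,), amplitude=500.0), "phase")))
        res = ck.fit_composite(curve, tmpl, options=ck.FitOptions(seed=10))
        halftimes = [ck.recruitment_halftime(ck.CompositeModel.single(p))
                     for p, _ in res.model.components]
        assert halftimes == sorted(halftimes)
        assert halftimes[0] == pytest.approx(5.0, rel=0.05)
        assert halftimes[1] == pytest.approx(120.0, rel=0.05)

    def test_nonremovable_share_recovered(self):
        truth = ck.CompositeModel(components=(
            (ck.CRCParameters(rates=(0.1, 0.01), detachment_delay=20.0,
                              amplitude=700.0, has_removal=True), "removable"),
            (ck.CRCParameters(rates=(0.08,), amplitude=300.0), "non-removable")))
        design = ck.SimulationDesign(n_cells=12, sampling_interval=2.0, duration=600.0,
                                     noise_sd_fraction=0.05, cell_scale_sd=0.0, seed=7)
        curve = ck.simulate_curve(truth, design)
        tmpl = ck.CompositeModel(components=(
            (ck.CRCParameters(rates=(0.2, 0.02), detachment_delay=10.0,
                              amplitude=500.0, has_removal=True), "removable"),
            (ck.CRCParameters(rates=(0.05,), amplitude=500.0), "non-removable")))
        res = ck.fit_composite(curve, tmpl, options=ck.FitOptions(seed=7))
        amps = {role: p.amplitude for p, role in res.model.components}
        share = amps["non-removable"] / (amps["non-removable"] + amps["removable"])
        assert share == pytest.approx(0.3, abs=0.05)
        # non-removable component stays plateau-type
        assert not [p for p, r in res.model.components if r == "non-removable"][0].has_removal

    def test_single_component_template_equals_fixed_fit(self, delayed_truth, delayed_curve):
        r1 = ck.fit_composite(delayed_curve, delayed_truth, options=ck.FitOptions(seed=1))
        r2 = ck.fit_fixed_structure(delayed_curve, delayed_truth, options=ck.FitOptions(seed=1))
        assert r1.model == r2.model

    def test_identifiability_guard(self):
        t = np.arange(0.0, 20.0, 2.0)
        curve = ck.KineticCurve(timepoints=t, intensity_mean=np.linspace(0, 9, t.size),
                                intensity_sd=np.zeros(t.size), n_cells=3)
        big = ck.CompositeModel(components=tuple(
            (ck.CRCParameters(rates=(0.1 * (i + 1), 0.05 / (i + 1)), amplitude=1.0), "phase")
            for i in range(2)))
        with pytest.raises(ck.InputError):
            ck.fit_composite(curve, big)


@pytest.fixture(scope="module")
def simple_fit():
    truth = ck.CompositeModel.single(ck.CRCParameters(rates=(0.05,), amplitude=500.0))
    design = ck.SimulationDesign(n_cells=12, sampling_interval=2.0, duration=200.0,
                                 noise_sd_fraction=0.05, cell_scale_sd=0.0, seed=20)
    curve = ck.simulate_curve(truth, design)
    fit = ck.fit_fixed_structure(curve, truth, options=ck.FitOptions(seed=20, n_starts=3))
    return curve, fit


class TestBootstrap:
    def test_same_seed_identical_intervals(self, simple_fit):
        curve, fit = simple_fit
        ci1 = ck.bootstrap_uncertainty(curve, fit, n_boot=60, seed=3)
        ci2 = ck.bootstrap_uncertainty(curve, fit, n_boot=60, seed=3)
        assert ci1 == ci2

    def test_intervals_contain_point_estimate(self, simple_fit):
        curve, fit = simple_fit
        ci = ck.bootstrap_uncertainty(curve, fit, n_boot=60, seed=3)
        params = fit.params
        for name, (lo, hi) in ci.items():
            assert lo <= params[name] <= hi

    def test_noise_free_intervals_collapse(self):
        truth = ck.CompositeModel.single(ck.CRCParameters(rates=(0.05,), amplitude=500.0))
        curve = noise_free_curve(truth, interval=2.0, duration=200.0)
        fit = ck.fit_fixed_structure(curve, truth, options=ck.FitOptions(seed=0, n_starts=1))
        ci = ck.bootstrap_uncertainty(curve, fit, n_boot=40, seed=1)
        lo, hi = ci["c0.k1"]
        assert hi - lo <= 1e-6 * 0.05

    def test_coverage_of_true_rate(self):
        # nominal 95% residual-bootstrap intervals across seeded replicates
        truth = ck.CompositeModel.single(ck.CRCParameters(rates=(0.05,), amplitude=500.0))
        start = ck.CompositeModel.single(ck.CRCParameters(rates=(0.1,), amplitude=400.0))
        cover = 0
        n_rep = 50
        for r in range(n_rep):
            design = ck.SimulationDesign(n_cells=12, sampling_interval=2.0, duration=200.0,
                                         noise_sd_fraction=0.05, cell_scale_sd=0.0, seed=3000 + r)
            curve = ck.simulate_curve(truth, design)
            fit = ck.fit_fixed_structure(curve, start, options=ck.FitOptions(seed=r, n_starts=3))
            lo, hi = ck.bootstrap_uncertainty(curve, fit, n_boot=200, seed=r)["c0.k1"]
            cover += lo <= 0.05 <= hi
        assert 0.85 * n_rep <= cover <= 0.99 * n_rep


class TestRemoveBleach:
    def test_round_trip_within_noise_envelope(self):
        clean = ck.CompositeModel.single(ck.CRCParameters(rates=(0.05,), amplitude=500.0))
        contaminated = ck.CompositeModel.single(
            ck.CRCParameters(rates=(0.05,), amplitude=500.0),
            bleach=ck.BleachComponent(depth=150.0, recovery_rate=0.15))
        design = ck.SimulationDesign(n_cells=12, sampling_interval=1.0, duration=300.0,
                                     noise_sd_fraction=0.02, cell_scale_sd=0.0, seed=11)
        curve = ck.simulate_curve(contaminated, design)
        tmpl = ck.CompositeModel.single(
            ck.CRCParameters(rates=(0.1,), amplitude=400.0),
            bleach=ck.BleachComponent(depth=100.0, recovery_rate=0.3))
        fit = ck.fit_composite(curve, tmpl, options=ck.FitOptions(seed=11))
        corrected = ck.remove_bleach(curve, fit)
        clean_vals = ck.evaluate_model(clean, curve.timepoints)
        sd = np.maximum(curve.intensity_sd, 1e-9)
        assert np.max(np.abs(corrected.intensity_mean - clean_vals) / sd) <= 3.0
        # SD passes through unchanged; correction restores +depth at t=0
        np.testing.assert_array_equal(corrected.intensity_sd, curve.intensity_sd)
        assert corrected.intensity_mean[0] == pytest.approx(
            curve.intensity_mean[0] + fit.model.bleach.depth)

    def test_missing_bleach_component_rejected(self, delayed_truth, delayed_curve):
        fit = ck.fit_fixed_structure(delayed_curve, delayed_truth, options=ck.FitOptions(seed=1))
        with pytest.raises(ck.InputError):
            ck.remove_bleach(delayed_curve, fit)


def test_summary_renders(delayed_truth, delayed_curve):
    res = ck.fit_fixed_structure(delayed_curve, delayed_truth, options=ck.FitOptions(seed=1))
    text = res.summary()
    assert "c0.k1" in text and "reduced chi^2" in text
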