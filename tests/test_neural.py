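import numpy as np
import pandas as pd
import pytest

from zfmf.model import ModelParams, NODE_TYPES
from zfmf.stimulus import IMAGING_LABELS, imaging_sides
from zfmf.neural import (
    ClassifierThresholds, default_rules, dff0, summarize_windows,
    classify_logical, classify_regression, build_regressors,
    reference_trace, node_activity_concat, fit_exponential,
    condition_distance, WINDOWS, snr_benchmark,
)
from zfmf.synth import CalciumSimSpec, simulate_calcium, convolve_gcamp, minmax

N_BINS = 120  # 60 s at 0.5 s


def split_stimuli(trace):
    return {lab: trace[i * N_BINS:(i + 1) * N_BINS]
            for i, lab in enumerate(IMAGING_LABELS)}


@pytest.fixture(scope="module")
def regressors(default_params):
    regs, flagged = build_regressors(default_params)
    assert not flagged
    return regs


class TestDff0:
    def test_constant_trace_maps_to_zero(self):
        assert np.allclose(dff0(np.full(N_BINS, 3.0)), 0.0)

    def test_doubling_gives_one(self):
        raw = np.full(N_BINS, 2.0)
        raw[40:80] = 4.0
        out = dff0(raw)
        assert np.allclose(out[40:80], 1.0)

    def test_nonpositive_baseline_flagged(self):
        with pytest.raises(ValueError):
            dff0(np.zeros(N_BINS))


class TestWindows:
    def test_constant_trace_fills_all_windows(self):
        summ = summarize_windows({"a": np.full(N_BINS, 0.7)})
        assert np.allclose(summ.loc["a"], 0.7)

    def test_boxcar_on_stimulus_window_only_hits_C(self):
        tr = np.zeros(N_BINS)
        tr[40:80] = 1.0  # 20-40 s
        summ = summarize_windows({"a": tr})
        assert summ.loc["a", "C"] == 1.0
        assert np.allclose(summ.loc["a", ["A", "B", "D", "E"]], 0.0)

    def test_motion_node_stimulus_window_dominates(self, default_params):
        tr = reference_trace(default_params, "motion_integrator", "left")
        summ = summarize_windows(split_stimuli(tr))
        # stimulus c = motion left, luminance off
        row = summ.loc["c"]
        assert row["C"] > row["A"]
        assert row["C"] > row["B"]
        assert row["C"] > row["E"]


class TestLogicalClassifier:
    def test_all_zero_summaries_label_nothing(self):
        summ = pd.DataFrame(0.0, index=list(IMAGING_LABELS),
                            columns=list("ABCDE"))
        assert classify_logical(summ) == set()

    def test_each_node_recovers_its_own_label(self, default_params):
        for node_type in NODE_TYPES:
            for side in ("left", "right"):
                tr = reference_trace(default_params, node_type, side)
                labels = classify_logical(summarize_windows(split_stimuli(tr)))
                assert (node_type, side) in labels, (node_type, side, labels)

    def test_change_node_is_not_an_increase_detector(self, default_params):
        tr = reference_trace(default_params, "luminance_change", "left")
        labels = classify_logical(summarize_windows(split_stimuli(tr)))
        assert ("luminance_increase", "left") not in labels
        assert ("luminance_decrease", "left") not in labels

    def test_hemispheric_duality_under_mirrored_stimuli(self, default_params):
        tr = reference_trace(default_params, "motion_integrator", "left")
        per = split_stimuli(tr)
        # relabel each stimulus by its mirror image: a<->e etc.
        sides = imaging_sides()
        flip = {"left": "right", "right": "left", "off": "off"}
        mirror_of = {}
        for lab, (m, l) in sides.items():
            target = (flip[m], flip[l])
            mirror_of[lab] = next(k for k, v in sides.items() if v == target)
        mirrored = {mirror_of[lab]: v for lab, v in per.items()}
        labels = classify_logical(summarize_windows(mirrored))
        assert ("motion_integrator", "right") in labels
        assert ("motion_integrator", "left") not in labels

    def test_missing_stimulus_rejected(self, default_params):
        tr = reference_trace(default_params, "motion_integrator", "left")
        summ = summarize_windows(split_stimuli(tr)).drop(index="i")
        with pytest.raises(ValueError):
            classify_logical(summ)

    def test_rule_table_is_pure_configuration(self, default_params):
        # dropping a type from the table removes only that type's labels
        rules = default_rules()
        del rules["motion_integrator"]
        tr = reference_trace(default_params, "motion_integrator", "left")
        labels = classify_logical(summarize_windows(split_stimuli(tr)),
                                  rules=rules)
        assert not any(t == "motion_integrator" for t, _ in labels)


class TestRegressionClassifier:
    def test_trace_equal_to_regressor_is_labeled(self, regressors):
        key = ("luminance_integrator", "left")
        labels = classify_regression(regressors[key], regressors)
        assert key in labels

    def test_integrator_agreement_between_classifiers(self, default_params,
                                                      regressors):
        for node_type in ("motion_integrator", "luminance_integrator",
                          "multifeature_integrator"):
            tr = reference_trace(default_params, node_type, "left")
            logical = classify_logical(summarize_windows(split_stimuli(tr)))
            regression = classify_regression(tr, regressors)
            assert (node_type, "left") in logical
            assert (node_type, "left") in regression

    def test_white_noise_unlabeled(self, regressors, rng):
        noise = rng.normal(size=9 * N_BINS)
        assert classify_regression(noise, regressors) == set()

    def test_anticorrelated_trace_unlabeled(self, regressors):
        key = ("motion_integrator", "left")
        labels = classify_regression(1.0 - regressors[key], regressors)
        assert key not in labels

    def test_zero_variance_trace_unclassified(self, regressors):
        assert classify_regression(np.zeros(9 * N_BINS), regressors) == set()


class TestExponentialFit:
    def test_noiseless_recovery(self):
        t = np.arange(0, 30, 0.5)
        y = 2.0 * (1 - np.exp(-t / 3.0)) + 0.1
        fit = fit_exponential(t, y)
        assert fit.converged
        assert fit.a == pytest.approx(2.0, abs=1e-3)
        assert fit.tau == pytest.approx(3.0, abs=1e-3)
        assert fit.b == pytest.approx(0.1, abs=1e-3)

    def test_constant_data_gives_zero_amplitude(self):
        t = np.arange(0, 30, 0.5)
        fit = fit_exponential(t, np.full_like(t, 0.4))
        assert fit.a == pytest.approx(0.0, abs=1e-3)
        assert fit.b == pytest.approx(0.4, abs=1e-3)

    def test_rise_time_scale_invariant_but_slowed_by_saturation(self, default_params):
        # a linear integrator rises with the same time constant at every
        # contrast; an apparent slower rise at low contrast emerges once a
        # saturating response ceiling compresses the high-contrast trace
        from zfmf.model import leaky_convolve
        dt = 0.5

        def fitted_tau(contrast, saturate):
            drive = np.concatenate([np.zeros(20), np.full(80, contrast)])
            node = leaky_convolve(drive, default_params.tau_ll, dt)
            if saturate:
                node = np.tanh(3.0 * node)
            trace = convolve_gcamp(node, dt=dt)[20:]
            t = np.arange(len(trace)) * dt
            return fit_exponential(t, trace).tau

        assert fitted_tau(1.0, False) == pytest.approx(
            fitted_tau(0.3, False), rel=1e-3)
        assert fitted_tau(0.3, True) > fitted_tau(1.0, True)


class TestConditionDistance:
    def _population(self, rng, separation):
        # 30 neurons, 3 trials; left and right trials separated along a
        # random population axis with strength `separation`
        n, trials, T = 30, 3, 40
        axis = rng.normal(size=n)
        axis /= np.linalg.norm(axis)
        t_prof = np.concatenate([np.zeros(10), np.ones(30)])
        data = {}
        for lab, sign in (("c", +1), ("f", -1), ("g", +0.5), ("h", -0.5)):
            base = sign * separation * np.outer(axis, t_prof)
            data[lab] = np.stack([
                base + 0.1 * rng.normal(size=(n, T)) for _ in range(trials)
            ], axis=1)
        return data

    def test_identical_trials_give_zero_distance(self, rng):
        arr = rng.normal(size=(20, 1, 30))
        data = {lab: np.repeat(arr, 2, axis=1) for lab in ("c", "f")}
        data["f"] = data["c"].copy()
        out = condition_distance(data)
        motion = out[out["type"] == "motion"]
        assert np.allclose(motion["distance_lr"], 0.0, atol=1e-9)

    def test_stronger_separation_gives_larger_distance(self, rng):
        data = self._population(rng, separation=2.0)
        out = condition_distance(data)
        motion = out[out["type"] == "motion"]
        lum = out[out["type"] == "luminance"]
        late = slice(20, 40)
        assert (motion["distance_lr"].to_numpy()[late].mean()
                > lum["distance_lr"].to_numpy()[late].mean())

    def test_control_distance_below_opposite_distance(self, rng):
        data = self._population(rng, separation=2.0)
        out = condition_distance(data)
        motion = out[out["type"] == "motion"]
        assert (motion["distance_lr"].to_numpy()[10:].mean()
                > motion["distance_control"].to_numpy()[10:].mean())

    def test_single_trial_rejected(self, rng):
        data = {"c": rng.normal(size=(10, 1, 20)),
                "f": rng.normal(size=(10, 2, 20))}
        with pytest.raises(ValueError):
            condition_distance(data)


class TestBenchmark:
    def test_noiseless_benchmark_is_perfect(self):
        spec = CalciumSimSpec(spike_rate=0.0, noise_scales=(0.0,),
                              n_neurons=4, n_repeats=2)
        df = snr_benchmark(sim_spec=spec, n_rounds=1, seed=0)
        assert np.all(df["accuracy"] == 100.0)

    def test_benchmark_design_shape(self):
        spec = CalciumSimSpec(noise_scales=(0.3, 2.0), n_neurons=3,
                              n_repeats=2)
        df = snr_benchmark(sim_spec=spec, n_rounds=2, seed=1)
        assert len(df) == 2 * 2 * 2 * 2  # method x type x noise x round
        assert set(df["method"]) == {"logical", "regression"}
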