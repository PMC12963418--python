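import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from zfmf.model import (
    ModelParams, decay_kernel, leaky_convolve, change_pathway, simulate,
    silence_pathway, swims_left_batch, trailing_mean,
)
from zfmf.stimulus import StimulusSpec, render_timeseries


class TestDecayKernel:
    def test_zero_before_the_15s_midpoint(self):
        k = decay_kernel(tau=2.0, dt=0.1)
        t = np.arange(len(k)) * 0.1
        assert np.all(k[t <= 15.0] == 0.0)
        assert len(k) == 301

    def test_discrete_integral_matches_closed_form(self):
        # integral of (1/tau) e^{-(t-15)/tau} over (15, 30] is 1 - e^{-15/tau}
        k = decay_kernel(tau=1.0, dt=0.01)
        assert k.sum() * 0.01 == pytest.approx(1.0 - np.exp(-15.0), abs=1e-2)

    def test_height_just_past_the_midpoint_is_one_over_tau(self):
        tau = 3.0
        k = decay_kernel(tau, dt=0.01)
        i = int(round(15.0 / 0.01)) + 1
        assert k[i] == pytest.approx(1.0 / tau, rel=1e-2)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            decay_kernel(0.0, 0.1)
        with pytest.raises(ValueError):
            decay_kernel(-1.0, 0.1)


class TestLeakyConvolve:
    def test_zero_input_gives_zero_output(self):
        out = leaky_convolve(np.zeros(100), tau=2.0, dt=0.1)
        assert np.all(out == 0.0)

    def test_step_response_matches_closed_form(self):
        dt, tau = 0.01, 2.0
        sig = np.zeros(3000)
        sig[1000:] = 1.0
        out = leaky_convolve(sig, tau, dt)
        t = (np.arange(3000) - 1000) * dt
        ref = np.where(t > 0, 1.0 - np.exp(-t / tau), 0.0)
        mask = (t > 0) & (t < 14.0)  # inside the kernel memory
        assert np.abs(out - ref)[mask].max() < 5e-3

    def test_impulse_response_is_a_decaying_exponential(self):
        dt, tau = 0.01, 1.5
        sig = np.zeros(2000)
        sig[100] = 1.0 / dt  # unit mass
        out = leaky_convolve(sig, tau, dt)
        assert out[101] == pytest.approx(1.0 / tau, rel=0.05)
        assert out[101 + 150] == pytest.approx(np.exp(-1.0) / tau, rel=0.05)

    def test_causality(self):
        sig = np.zeros(200)
        sig[100:] = 1.0
        out = leaky_convolve(sig, 2.0, 0.1)
        assert np.all(out[:100] == 0.0)

    def test_causal_form_equals_centered_convolution(self):
        # the kernel's zero first half makes a centered "same" convolution
        # strictly causal; both constructions must agree
        rng = np.random.default_rng(3)
        sig = rng.random(400)
        dt, tau = 0.1, 2.5
        k = decay_kernel(tau, dt)
        centered = np.convolve(sig, k, mode="full")[len(k) // 2:
                                                    len(k) // 2 + len(sig)] * dt
        # leaky_convolve additionally rescales the sampled kernel to the
        # exact continuous integral; apply the same factor
        scale = (1 - np.exp(-15.0 / tau)) / (k.sum() * dt)
        assert np.allclose(leaky_convolve(sig, tau, dt), centered * scale,
                           atol=1e-12)


class TestChangePathway:
    def test_constant_channel_transients_vanish(self):
        dt, tau = 0.1, 1.0
        lum = np.full(400, 0.7)
        li, ld, lc = change_pathway(lum, tau, dt)
        assert li[-1] < 1e-3 and ld[-1] < 1e-3
        assert np.all(li >= 0) and np.all(ld >= 0)
        assert np.allclose(lc, li + ld)

    def test_step_up_drives_increase_only(self):
        lum = np.concatenate([np.zeros(300), np.ones(300)])
        li, ld, lc = change_pathway(lum, tau_lc=1.0, dt=0.1)
        assert np.all(ld[300:] == 0.0)
        assert li[301] > 0.9
        assert li[-1] < 0.01  # decays back

    def test_step_down_mirrors_step_up(self):
        up = np.concatenate([np.zeros(300), np.ones(300)])
        li_u, ld_u, _ = change_pathway(up, 1.0, 0.1)
        li_d, ld_d, _ = change_pathway(1.0 - up, 1.0, 0.1)
        # after the initial settling the two cases are exact mirrors
        assert np.allclose(ld_d[300:], li_u[300:], atol=1e-6)
        assert np.all(li_d[300:] == 0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_rectification_on_random_channels(self, seed):
        rng = np.random.default_rng(seed)
        lum = rng.random(200)
        li, ld, lc = change_pathway(lum, tau_lc=2.0, dt=0.1)
        assert np.all(li >= 0) and np.all(ld >= 0)
        assert np.allclose(lc, li + ld)


class TestSimulate:
    def test_zero_stimulus_gives_chance_everywhere(self, default_params):
        spec = StimulusSpec(background_level=0.0)
        act = simulate(render_timeseries(spec, 0.1), default_params)
        assert np.all(act.swims_left == 0.5)

    def test_mirror_equivariance(self, default_params):
        spec = StimulusSpec(motion_side="left", coherence=0.6,
                            lum_side="right", background_level=0.5)
        ts = render_timeseries(spec, 0.1)
        a = simulate(ts, default_params)
        b = simulate(ts.mirrored(), default_params)
        assert np.allclose(a.swims_left, 1.0 - b.swims_left, atol=1e-12)

    def test_motion_left_biases_late_window_leftward(self, default_params):
        spec = StimulusSpec(motion_side="left", coherence=0.5,
                            background_level=0.5)
        act = simulate(render_timeseries(spec, 0.1), default_params)
        late = (act.t >= 30.0) & (act.t < 40.0)
        assert np.all(act.swims_left[late] > 0.5)

    def test_rectification_and_change_sum_invariants(self, default_params):
        spec = StimulusSpec(lum_side="left", background_level=0.5)
        act = simulate(render_timeseries(spec, 0.1), default_params)
        for arr in (act.li_left, act.li_right, act.ld_left, act.ld_right):
            assert np.all(arr >= 0.0)
        assert np.allclose(act.lc_left, act.li_left + act.ld_left)
        assert np.allclose(act.lc_right, act.li_right + act.ld_right)

    def test_additivity_signature_of_late_window(self, default_params):
        # congruent >= motion-only >= conflicting when all weights > 0
        def late_mean(motion, lum):
            spec = StimulusSpec(motion_side=motion, coherence=0.25,
                                lum_side=lum, background_level=0.5)
            act = simulate(render_timeseries(spec, 0.1), default_params)
            sel = (act.t >= 30.0) & (act.t < 40.0)
            return act.swims_left[sel].mean()

        congruent = late_mean("left", "left")
        motion_only = late_mean("left", "off")
        conflict = late_mean("left", "right")
        assert congruent >= motion_only >= conflict

    def test_halving_dt_changes_little(self, default_params):
        spec = StimulusSpec(motion_side="left", coherence=0.5,
                            lum_side="right", background_level=0.5)
        a = simulate(render_timeseries(spec, 0.1), default_params).swims_left
        b = simulate(render_timeseries(spec, 0.05), default_params).swims_left[::2]
        assert np.abs(a - b[:len(a)]).max() < 1e-2

    def test_batch_path_matches_reference_simulation(self, default_params):
        spec = StimulusSpec(motion_side="right", coherence=0.3,
                            lum_side="left", background_level=0.5)
        ts = render_timeseries(spec, 0.1)
        act = simulate(ts, default_params)
        ch = ts.channels()
        sw = swims_left_batch(ch["motion_left"], ch["motion_right"],
                              ch["luminance_left"], ch["luminance_right"],
                              0.1, default_params)
        assert np.allclose(sw[0], act.swims_left, atol=1e-9)

    def test_nan_channel_rejected(self, default_params):
        ts = render_timeseries(StimulusSpec(), 0.1)
        ts.motion_left[5] = np.nan
        with pytest.raises(ValueError):
            simulate(ts, default_params)


class TestSilencing:
    def test_silenced_motion_cannot_respond_to_motion(self, default_params):
        p = silence_pathway(default_params, "motion")
        spec = StimulusSpec(motion_side="left", coherence=1.0,
                            background_level=0.0)
        act = simulate(render_timeseries(spec, 0.1), p)
        assert np.all(act.swims_left == 0.5)

    def test_silencing_lum_change_removes_transients(self, default_params):
        spec = StimulusSpec(lum_side="left", background_level=0.5)
        full = simulate(render_timeseries(spec, 0.1), default_params)
        p = silence_pathway(default_params, "lum_change")
        part = simulate(render_timeseries(spec, 0.1), p)
        onset = (full.t >= 10.0) & (full.t < 14.0)
        # the change pathway is repulsive: with it the onset dips, without
        # it the luminance-level attraction acts immediately
        assert part.swims_left[onset].min() > full.swims_left[onset].min()
        assert np.all(part.lc_left * 0 == 0)  # still computed, just unweighted

    def test_silencing_is_idempotent_and_drops_tau_from_free_set(self, default_params):
        p1 = silence_pathway(default_params, "lum_level")
        p2 = silence_pathway(p1, "lum_level")
        assert p1 == p2
        assert "tau_ll" not in p1.free_names()
        assert "w_ll" not in p1.free_names()
        assert len(default_params.free_names()) == 7
        assert len(p1.free_names()) == 5

    def test_unknown_pathway_rejected(self, default_params):
        with pytest.raises(ValueError):
            silence_pathway(default_params, "smell")


def test_trailing_mean_uses_only_the_past():
    x = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
    out = trailing_mean(x, 3)
    assert out[1] == 0.0          # partial window
    assert out[2] == pytest.approx(1 / 3)
    assert out[4] == pytest.approx(1.0)


def test_params_validation():
    with pytest.raises(ValueError):
        ModelParams(w_m=-0.1)
    with pytest.raises(ValueError):
        ModelParams(tau_m=0.0)
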