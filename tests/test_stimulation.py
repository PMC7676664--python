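"""Pulse trains, stimulation of the full model, and the single-block study."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmburst import (
    BURSTING_OPERATING_POINT,
    ModelParams,
    NMBlockParams,
    PulseTrain,
    SimConfig,
    StimCoupling,
    nm_block_response,
    pulse_waveform,
    stimulate,
    sweep_energy_map,
)
from nmburst.simulate import background_state, integrate, lfp, signal_energy


def _sampled_integral(train, dt=1e-5, T=None):
    T = T or (train.onset + 3.0 / train.frequency)
    t = np.arange(0.0, T, dt)
    w = np.array([pulse_waveform(s, train) for s in t])
    return w, t


class TestPulseTrain:
    def test_anodic_first_values(self):
        tr = PulseTrain(frequency=10.0, amplitude=2.0, onset=1.0)
        assert pulse_waveform(1.0 + 1e-5, tr) == 2.0      # anodic phase
        assert pulse_waveform(1.0 + 7e-4, tr) == -2.0     # cathodic phase
        assert pulse_waveform(1.0 + 5e-3, tr) == 0.0      # inter-pulse
        assert pulse_waveform(0.5, tr) == 0.0             # before onset

    def test_charge_balance_per_period(self):
        tr = PulseTrain(frequency=20.0, amplitude=5.0, onset=0.0)
        w, t = _sampled_integral(tr)
        period = int(round(1.0 / tr.frequency / 1e-5))
        for k in range(3):
            q = np.sum(w[k * period:(k + 1) * period]) * 1e-5
            assert abs(q) < 1e-12 * tr.amplitude * period

    @given(st.floats(min_value=1.0, max_value=100.0),
           st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=50, deadline=None)
    def test_charge_balance_property(self, freq, amp):
        tr = PulseTrain(frequency=freq, amplitude=amp, onset=0.0)
        # exact integral over one period: amp*pw - amp*pw = 0 by symmetry
        n = 1000
        tt = np.linspace(0.0, 1.0 / freq, n, endpoint=False)
        q = sum(pulse_waveform(s, tr) for s in tt) / n
        assert abs(q) <= amp * 2.0 / n   # discretisation-level residual

    def test_pulse_count(self):
        tr = PulseTrain(frequency=13.0, amplitude=1.0, onset=2.0, offset=5.0)
        assert tr.n_pulses() == math.floor(13.0 * 3.0)
        # counting oracle on the sampled waveform: count anodic onsets
        w, t = _sampled_integral(tr, dt=1e-5, T=5.0)
        onsets = np.sum((w[1:] > 0) & (w[:-1] <= 0))
        assert onsets == tr.n_pulses()

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PulseTrain(frequency=2000.0, amplitude=1.0)

    def test_phase_exceeding_duration_rejected(self):
        with pytest.raises(ValueError):
            PulseTrain(frequency=10.0, amplitude=1.0, phase_width=1e-3,
                       total_pulse_duration=1e-3)


@pytest.fixture(scope="module")
def op_params():
    return ModelParams(**BURSTING_OPERATING_POINT)


@pytest.fixture(scope="module")
def op_x0(op_params):
    return background_state(op_params)


class TestStimulate:
    def test_zero_amplitude_matches_unstimulated(self, op_params, op_x0):
        cfg = SimConfig(dt=1e-4, duration=2.0)
        tr = PulseTrain(frequency=15.0, amplitude=0.0, onset=0.5)
        stim = integrate("full", op_x0, cfg, op_params, i_ext=tr,
                         coupling=StimCoupling(1.0, 1.0, 1.0))
        plain = integrate("full", op_x0, cfg, op_params)
        np.testing.assert_array_equal(stim.states, plain.states)

    def test_som_abort_and_homogeneous_contrast(self, op_params, op_x0):
        """SOM+-only 15 Hz / amplitude-10 stimulation aborts bursting;
        the same train applied homogeneously does not, but 25 Hz does."""
        cfg = SimConfig(dt=1e-4, duration=13.0)
        som = stimulate(op_params, StimCoupling(kSOM=1.0),
                        PulseTrain(frequency=15.0, amplitude=10.0), cfg,
                        x0=op_x0)
        assert som.aborted
        hom15 = stimulate(op_params, StimCoupling(1.0, 1.0, 1.0),
                          PulseTrain(frequency=15.0, amplitude=10.0), cfg,
                          x0=op_x0)
        assert not hom15.aborted
        hom25 = stimulate(op_params, StimCoupling(1.0, 1.0, 1.0),
                          PulseTrain(frequency=25.0, amplitude=10.0), cfg,
                          x0=op_x0)
        assert hom25.aborted

    def test_abort_invariant_to_settle_margin(self, op_params, op_x0):
        cfg = SimConfig(dt=1e-4, duration=13.0)
        tr = PulseTrain(frequency=15.0, amplitude=10.0)
        flags = [stimulate(op_params, StimCoupling(kSOM=1.0), tr, cfg,
                           x0=op_x0, settle_margin=m).aborted
                 for m in (0.5, 1.0, 2.0)]
        assert all(flags)


class TestEnergyMap:
    def test_amplitude_zero_row_is_baseline(self, op_params):
        cfg = SimConfig(dt=1e-4, duration=8.0)
        emap = sweep_energy_map(op_params, StimCoupling(kSOM=1.0),
                                [10.0, 20.0], [0.0], cfg)
        assert emap.energy[0, 0] == pytest.approx(emap.energy[1, 0],
                                                  rel=1e-12)
        assert not emap.aborted.any()

    def test_aborted_cell_has_lower_energy(self, op_params, op_x0):
        cfg = SimConfig(dt=1e-4, duration=13.0)
        emap = sweep_energy_map(op_params, StimCoupling(kSOM=1.0),
                                [5.0, 15.0], [10.0], cfg)
        assert not emap.aborted[0, 0] and emap.aborted[1, 0]
        assert emap.energy[1, 0] < emap.energy[0, 0]

    def test_reproducible(self, op_params):
        cfg = SimConfig(dt=1e-4, duration=6.5)
        a = sweep_energy_map(op_params, StimCoupling(kSOM=1.0),
                             [15.0], [10.0], cfg)
        b = sweep_energy_map(op_params, StimCoupling(kSOM=1.0),
                             [15.0], [10.0], cfg)
        np.testing.assert_array_equal(a.energy, b.energy)

    def test_empty_grid_rejected(self, op_params):
        with pytest.raises(ValueError):
            sweep_energy_map(op_params, StimCoupling(kSOM=1.0), [], [10.0],
                             SimConfig(duration=1.0))


class TestNMBlock:
    def test_baseline_without_input(self):
        """No input: the block settles at M tau S(0) = S(0) for M tau = 1."""
        cfg = SimConfig(dt=1e-4, duration=3.0)
        tr = PulseTrain(frequency=10.0, amplitude=0.0, onset=0.0)
        r = nm_block_response(NMBlockParams(tau=0.01), tr, cfg)
        want = 5.0 / (1.0 + math.exp(3.36))
        assert r.baseline == pytest.approx(want, rel=1e-12)
        assert r.envelope_min == pytest.approx(want, rel=1e-6)
        assert r.envelope_max == pytest.approx(want, rel=1e-6)
        assert not r.detached

    def test_slow_block_detaches_at_lower_frequency(self):
        """Monotone timescale-frequency law: the minimum detachment
        frequency is non-increasing in tau."""
        from nmburst.stimulation import min_detach_frequency

        cfg = SimConfig(dt=1e-4, duration=4.0)
        freqs = [2.0, 5.0, 10.0, 20.0, 40.0, 80.0]
        fmins = [min_detach_frequency(NMBlockParams(tau=tau), freqs, 10.0,
                                      cfg)
                 for tau in (0.05, 0.01, 0.003)]
        assert fmins[0] <= fmins[1] <= fmins[2]
        assert fmins[0] < fmins[2]

    def test_envelope_saturates_in_amplitude(self):
        """Beyond the sigmoid's saturation the envelope stops growing."""
        cfg = SimConfig(dt=1e-4, duration=4.0)
        env = {}
        for amp in (20.0, 40.0):
            tr = PulseTrain(frequency=10.0, amplitude=amp, onset=0.0)
            env[amp] = nm_block_response(NMBlockParams(tau=0.05), tr,
                                         cfg).envelope_max
        assert env[40.0] == pytest.approx(env[20.0], rel=1e-3)

    def test_non_settled_envelope_raises(self):
        cfg = SimConfig(dt=1e-4, duration=0.02)   # far too short for tau=0.05
        tr = PulseTrain(frequency=100.0, amplitude=10.0, onset=0.0)
        with pytest.raises(RuntimeError, match="steady"):
            nm_block_response(NMBlockParams(tau=0.05), tr, cfg)
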