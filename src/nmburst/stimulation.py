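"""Biphasic pulse-train stimulation and energy-map sweeps.

Deep-brain-stimulation-style trains of charge-balanced biphasic pulses
(anodic phase then cathodic phase, 0.5 ms each by default) are routed into
the sigmoid arguments of the model subpopulations by the coupling
coefficients (kP, kSOM, kPV).  Because each PSP block is a low-pass filter
with time constant tau, slow-kinetics populations (SOM+, tau_b = 50 ms)
integrate pulse trains at much lower frequencies than fast ones (PV+,
tau_g = 3 ms) — the design principle behind SOM+-targeted burst abortion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams, StimCoupling, sigmoid
from .simulate import (
    SimConfig,
    Trajectory,
    BurstSet,
    detect_spikes,
    segment_bursts,
    signal_energy,
    integrate,
    lfp,
    background_state,
)

__all__ = [
    "PulseTrain",
    "EnergyMap",
    "NMBlockParams",
    "StimulationResult",
    "pulse_waveform",
    "stimulate",
    "sweep_energy_map",
    "nm_block_response",
    "BURSTING_OPERATING_POINT",
]

# Deterministic pre-ictal bursting operating point used by the stimulation
# studies (SOM+ gain inside the sustained-bursting window, default PV+
# excitability).  Config-overridable.
BURSTING_OPERATING_POINT = dict(B=20.0, G=35.0, C5=450.0)


@dataclass(frozen=True)
class PulseTrain:
    """Charge-balanced biphasic pulse train.

    Anodic-first: +amplitude for ``phase_width`` seconds, -amplitude for the
    next ``phase_width``, zero until the next pulse.  Pulses start at
    ``onset`` and repeat at ``frequency`` until ``offset``.
    """

    frequency: float                 # Hz
    amplitude: float                 # arbitrary units
    phase_width: float = 5e-4        # s
    total_pulse_duration: float = 1e-3   # s
    onset: float = 5.0               # s
    offset: float = math.inf         # s
    polarity_order: str = "anodic-first"

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if 2 * self.phase_width > self.total_pulse_duration + 1e-15:
            raise ValueError("two phases exceed the total pulse duration")
        if self.frequency * self.total_pulse_duration > 1.0 + 1e-12:
            raise ValueError("overlapping pulses: frequency * total_pulse_duration > 1")
        if self.polarity_order != "anodic-first":
            raise ValueError("only anodic-first trains are supported")

    def __call__(self, t: float) -> float:
        return pulse_waveform(t, self)

    def n_pulses(self) -> int:
        """Complete pulses delivered in [onset, offset)."""
        if not math.isfinite(self.offset):
            raise ValueError("infinite train")
        return int(math.floor(self.frequency * (self.offset - self.onset)))


def pulse_waveform(t: float, train: PulseTrain) -> float:
    """Instantaneous value of the train at time t (s)."""
    if t < train.onset or t >= train.offset:
        return 0.0
    phase = (t - train.onset) % (1.0 / train.frequency)
    if phase < train.phase_width:
        return train.amplitude
    if phase < 2.0 * train.phase_width:
        return -train.amplitude
    return 0.0


@dataclass
class StimulationResult:
    trajectory: Trajectory
    lfp: np.ndarray
    bursts: BurstSet
    aborted: bool
    train: PulseTrain
    settle_margin: float


def stimulate(params: ModelParams, coupling: StimCoupling, train: PulseTrain,
              sim: SimConfig, x0=None, settle_margin: float = 1.0,
              max_intra_burst_gap: float = 0.3) -> StimulationResult:
    """Integrate the stimulated full model and flag burst abortion.

    The abort flag is true when no burst is detected between
    ``onset + settle_margin`` and the end of the evaluated window (bursts
    during the settle margin are stimulation-onset transients).  The spike
    threshold is derived from the pre-stimulation window so that abortion
    cannot redefine "spike" away.
    """
    if x0 is None:
        x0 = background_state(params)
    traj = integrate("full", x0, sim, params, i_ext=train, coupling=coupling)
    x = lfp(traj)
    dt = sim.dt
    # threshold from the pre-onset (bursting) window
    pre = x[: max(2, int(train.onset / dt))]
    threshold = 0.5 * (float(np.median(pre)) + float(np.max(pre)))
    t_eval = min(train.offset, sim.duration)
    i0 = int((train.onset + settle_margin) / dt)
    seg = x[i0: int(t_eval / dt) + 1]
    if seg.size and float(np.max(seg)) > threshold:
        spikes = detect_spikes(seg, dt, threshold=threshold,
                               t0=train.onset + settle_margin)
        bursts = segment_bursts(spikes, max_intra_burst_gap)
    else:
        bursts = BurstSet(bursts=[])
    return StimulationResult(trajectory=traj, lfp=x, bursts=bursts,
                             aborted=len(bursts) == 0, train=train,
                             settle_margin=settle_margin)


@dataclass
class EnergyMap:
    """Frequency x amplitude grid of post-onset LFP signal energy."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    energy: np.ndarray        # shape (n_freq, n_amp)
    aborted: np.ndarray       # bool, same shape
    coupling: StimCoupling
    seed: int

    def min_abort_frequency(self, amplitude: float) -> float:
        """Lowest frequency whose cell at ``amplitude`` aborts (inf if none)."""
        j = int(np.argmin(np.abs(self.amplitudes - amplitude)))
        for i, f in enumerate(self.frequencies):
            if self.aborted[i, j]:
                return float(f)
        return math.inf

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.energy, index=self.frequencies,
                          columns=self.amplitudes)
        df.index.name = "frequency_hz"
        df.columns.name = "amplitude"
        df.to_csv(path)


def sweep_energy_map(params: ModelParams, coupling: StimCoupling,
                     frequency_grid, amplitude_grid, sim: SimConfig,
                     onset: float = 5.0, settle_margin: float = 1.0) -> EnergyMap:
    """Run :func:`stimulate` per (frequency, amplitude) cell.

    Every cell reuses the same initial state and seed, so the map is
    reproducible; post-onset LFP energy is the Fig-of-merit E = sum |x|^2.
    """
    freqs = np.atleast_1d(np.asarray(frequency_grid, dtype=float))
    amps = np.atleast_1d(np.asarray(amplitude_grid, dtype=float))
    if freqs.size == 0 or amps.size == 0:
        raise ValueError("empty sweep grid")
    x0 = background_state(params)
    E = np.zeros((freqs.size, amps.size))
    A = np.zeros((freqs.size, amps.size), dtype=bool)
    i_on = int(onset / sim.dt)
    for i, f in enumerate(freqs):
        for j, a in enumerate(amps):
            train = PulseTrain(frequency=f, amplitude=a, onset=onset)
            res = stimulate(params, coupling, train, sim, x0=x0,
                            settle_margin=settle_margin)
            E[i, j] = signal_energy(res.lfp[i_on:])
            A[i, j] = res.aborted
    return EnergyMap(frequencies=freqs, amplitudes=amps, energy=E, aborted=A,
                     coupling=coupling, seed=sim.seed)


# ---------------------------------------------------------------------------
# Single neural-mass-block response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NMBlockParams:
    """A single second-order PSP block y'' = (M/tau) S(I(t)) - (2/tau) y' - y/tau^2.

    ``M`` defaults to 1/tau so that the product M*tau is one and the
    no-input baseline is M*tau*S(0) = S(0) for every tau.
    """

    tau: float
    M: float | None = None

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError("tau must be positive")
        if self.M is None:
            object.__setattr__(self, "M", 1.0 / self.tau)

    @property
    def baseline(self) -> float:
        return self.M * self.tau * sigmoid(0.0)


@dataclass
class BlockResponse:
    envelope_min: float
    envelope_max: float
    baseline: float
    detached: bool                 # steady envelope stays above the baseline
    trajectory: Trajectory = field(repr=False, default=None)


def nm_block_response(block: NMBlockParams, train: PulseTrain,
                      sim: SimConfig, detach_rtol: float = 0.02,
                      settle_fraction: float = 0.3) -> BlockResponse:
    """Steady-state oscillation envelope of a neural mass block under pulses.

    The block is integrated to steady state; the envelope is taken over the
    final ``settle_fraction`` of the run, and the block counts as
    "detached" when its minimum stays above the no-input baseline by more
    than ``detach_rtol`` relatively.  Raises if the envelope has not
    settled (drift between the last two windows).
    """
    tau, M = block.tau, block.M

    def rhs(x, t):
        y, dy = x
        I = pulse_waveform(t, train)
        return np.array([dy, (M / tau) * sigmoid(I) - (2.0 / tau) * dy
                         - y / (tau * tau)])

    x0 = np.array([block.baseline, 0.0])
    traj = integrate(rhs, x0, sim)
    y = traj.states[:, 0]
    n = y.size
    i0 = int((1.0 - settle_fraction) * n)
    half = (n - i0) // 2
    w1, w2 = y[i0: i0 + half], y[i0 + half:]
    drift = abs(float(np.mean(w2)) - float(np.mean(w1)))
    scale = max(float(np.ptp(y[i0:])), 1e-2 * abs(block.baseline), 1e-12)
    if drift > 0.05 * scale:
        raise RuntimeError("block response did not reach a steady envelope "
                           f"within {sim.duration} s (drift {drift:.3g})")
    env_min = float(np.min(y[i0:]))
    env_max = float(np.max(y[i0:]))
    detached = env_min > block.baseline * (1.0 + detach_rtol)
    return BlockResponse(envelope_min=env_min, envelope_max=env_max,
                         baseline=block.baseline, detached=detached,
                         trajectory=traj)


def min_detach_frequency(block: NMBlockParams, frequencies, amplitude: float,
                         sim: SimConfig) -> float:
    """Lowest pulse frequency at which the block's envelope detaches."""
    for f in sorted(np.atleast_1d(frequencies)):
        train = PulseTrain(frequency=float(f), amplitude=amplitude, onset=0.0)
        if nm_block_response(block, train, sim).detached:
            return float(f)
    return math.inf
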