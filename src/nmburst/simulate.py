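"""Fixed-step time integration, LFP extraction and spike/burst detection.

The integrator is Euler-Maruyama with a fixed step (default dt = 1e-4 s).
The stochastic external input enters the model only through the cortical
drive p(t) = p_mean + xi on the excitatory-input block (y1), with xi a
Gaussian increment of standard deviation sigma/sqrt(dt) per step, i.e. the
state receives (A/tau_a) * sigma * sqrt(dt) * N(0,1) per step.  With
sigma = 0 the scheme reduces exactly to forward Euler and a given seed
reproduces the trajectory bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams, StimCoupling, TimescaleParams, sigmoid
from . import model as _model

__all__ = [
    "SimConfig",
    "Trajectory",
    "SpikeTrain",
    "Burst",
    "BurstSet",
    "IntegrationError",
    "integrate",
    "lfp",
    "detect_spikes",
    "segment_bursts",
    "signal_energy",
    "background_state",
]

_NO_STIM = StimCoupling()


class IntegrationError(RuntimeError):
    """Raised when the state blows up; carries the offending step index."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"integration diverged (NaN/overflow) at step {step}")


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.

    dt : step size (s); duration : total simulated span (s); seed : RNG
    seed for the stochastic input; transient : initial span discarded by
    analysis helpers (s); sigma : noise standard deviation (Hz), 0 for a
    deterministic run.
    """

    dt: float = 1e-4
    duration: float = 10.0
    seed: int = 0
    transient: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        if not (self.duration >= self.transient >= 0):
            raise ValueError("need duration >= transient >= 0")


@dataclass
class Trajectory:
    """Uniformly sampled solution of one of the model systems.

    ``time_variable`` records which time the grid is expressed in
    ("t" seconds for the full system, "t_tilde" = t/tau_g for the rescaled
    system, "t_tilde_s", "t_tilde_ss" for the reduced problems).
    """

    time_variable: str
    times: np.ndarray
    states: np.ndarray
    system_tag: str

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def after(self, t0: float) -> "Trajectory":
        """Sub-trajectory with times >= t0 (used to discard transients)."""
        i = int(np.searchsorted(self.times, t0))
        return Trajectory(self.time_variable, self.times[i:], self.states[i:],
                          self.system_tag)

    def to_csv(self, path, labels=None) -> None:
        labels = labels or [f"x{i}" for i in range(self.states.shape[1])]
        df = pd.DataFrame(self.states, columns=list(labels))
        df.insert(0, f"time_{self.time_variable}", self.times)
        df.to_csv(path, index=False)


def _integrate_full(x0, config: SimConfig, params: ModelParams,
                    i_ext_fn, coupling: StimCoupling) -> np.ndarray:
    """Specialised Euler-Maruyama loop for the 10-dim full system."""
    pr = params
    sg = pr.sigmoid
    vmax, steep, thr = sg.vmax, sg.steepness, sg.threshold
    dt = config.dt
    n = int(round(config.duration / dt))
    A, B, G = pr.A, pr.B, pr.G
    C1, C2, C3, C4, C5, C6, C7 = pr.C1, pr.C2, pr.C3, pr.C4, pr.C5, pr.C6, pr.C7
    ita, itb, itg = 1.0 / pr.tau_a, 1.0 / pr.tau_b, 1.0 / pr.tau_g
    p = pr.p_mean
    kP, kS, kV = coupling.kP, coupling.kSOM, coupling.kPV
    exp = math.exp

    def S(v):
        z = steep * (thr - v)
        if z > 700.0:
            return vmax * exp(-z)
        return vmax / (1.0 + exp(z))

    noise = None
    if config.sigma > 0:
        rng = np.random.default_rng(config.seed)
        noise = A * ita * config.sigma * math.sqrt(dt) * rng.standard_normal(n)

    X = np.empty((n + 1, 10))
    y0, y1, y2, y3, y4, d0, d1, d2, d3, d4 = [float(v) for v in x0]
    X[0] = x0
    for k in range(n):
        if i_ext_fn is not None:
            I = i_ext_fn(k * dt)
            IP, IS, IV = kP * I, kS * I, kV * I
        else:
            IP = IS = IV = 0.0
        s2 = S(C3 * y0 + IS)
        dd0 = A * ita * S(y1 - y2 - y3 + IP) - 2.0 * ita * d0 - ita * ita * y0
        dd1 = A * ita * (p + C2 * S(C1 * y0 + IP)) - 2.0 * ita * d1 - ita * ita * y1
        dd2 = B * itb * C4 * s2 - 2.0 * itb * d2 - itb * itb * y2
        dd3 = G * itg * C7 * S(C5 * y0 - C6 * y4 + IV) - 2.0 * itg * d3 - itg * itg * y3
        dd4 = B * itb * s2 - 2.0 * itb * d4 - itb * itb * y4
        y0 += dt * d0
        y1 += dt * d1
        y2 += dt * d2
        y3 += dt * d3
        y4 += dt * d4
        d0 += dt * dd0
        d1 += dt * dd1 + (noise[k] * dt if noise is not None else 0.0)
        d2 += dt * dd2
        d3 += dt * dd3
        d4 += dt * dd4
        if not (math.isfinite(y0) and math.isfinite(y3)):
            raise IntegrationError(k + 1)
        X[k + 1] = (y0, y1, y2, y3, y4, d0, d1, d2, d3, d4)
    return X


def _integrate_generic(rhs, x0, config: SimConfig, noise_vec=None) -> np.ndarray:
    """Forward-Euler / Euler-Maruyama loop for an arbitrary callable rhs(x, t)."""
    dt = config.dt
    n = int(round(config.duration / dt))
    x = np.asarray(x0, dtype=float).copy()
    X = np.empty((n + 1, x.size))
    X[0] = x
    gain = None
    if config.sigma > 0 and noise_vec is not None:
        rng = np.random.default_rng(config.seed)
        gain = config.sigma * math.sqrt(dt) * rng.standard_normal(n)
    for k in range(n):
        x = x + dt * rhs(x, k * dt)
        if gain is not None:
            x = x + dt * gain[k] * noise_vec
        if not math.isfinite(x[0]):
            raise IntegrationError(k + 1)
        X[k + 1] = x
    return X


def integrate(system, x0, config: SimConfig, params: ModelParams | None = None,
              timescales: TimescaleParams | None = None,
              i_ext=None, coupling: StimCoupling = _NO_STIM) -> Trajectory:
    """Integrate one of the model systems (or any callable rhs) on a fixed grid.

    Parameters
    ----------
    system : {"full", "rescaled"} or callable
        Named systems use the model right-hand sides; a callable must have
        signature ``rhs(x, t) -> dx/dt`` and is integrated deterministically
        (per-channel noise is a model-level concept).
    i_ext : float or callable, optional
        External stimulation; a callable receives the time of the *physical*
        clock for the full system (t~ clock for the rescaled system).
    """
    if isinstance(i_ext, (int, float)) and i_ext != 0.0:
        value = float(i_ext)
        i_ext_fn = lambda t: value  # noqa: E731
    elif callable(i_ext):
        i_ext_fn = i_ext
    else:
        i_ext_fn = None

    if system == "full":
        if params is None:
            raise ValueError("params required for the full system")
        X = _integrate_full(x0, config, params, i_ext_fn, coupling)
        times = np.arange(X.shape[0]) * config.dt
        return Trajectory("t", times, X, "full")

    if system == "rescaled":
        if params is None:
            raise ValueError("params required for the rescaled system")
        pr, ts = params, timescales

        def rhs(x, t):
            I = i_ext_fn(t) if i_ext_fn is not None else 0.0
            return _model.rescaled_rhs(x, pr, ts, i_ext=I, coupling=coupling)

        cfg = SimConfig(dt=config.dt, duration=config.duration,
                        seed=config.seed, transient=config.transient, sigma=0.0)
        X = _integrate_generic(rhs, x0, cfg)
        times = np.arange(X.shape[0]) * config.dt
        return Trajectory("t_tilde", times, X, "rescaled")

    if callable(system):
        X = _integrate_generic(system, x0, config)
        times = np.arange(X.shape[0]) * config.dt
        return Trajectory("t", times, X, "custom")

    raise ValueError(f"unknown system {system!r}")


def lfp(traj: Trajectory, params: ModelParams | None = None) -> np.ndarray:
    """Simulated LFP: the summed PSP seen by the pyramidal population.

    Full system: y1 - y2 - y3.  Rescaled system: C2 ta v1 - C4 tb v2 -
    C7 tg v3, which equals the physical LFP minus the constant offset
    A ta p_mean absorbed by the variable conversion.
    """
    if traj.system_tag == "full":
        return traj.states[:, 1] - traj.states[:, 2] - traj.states[:, 3]
    if traj.system_tag == "rescaled":
        if params is None:
            raise ValueError("params required to form the rescaled LFP")
        pr = params
        v3, v1, v2 = traj.states[:, 0], traj.states[:, 4], traj.states[:, 6]
        return (pr.C2 * pr.tau_a * v1 - pr.C4 * pr.tau_b * v2
                - pr.C7 * pr.tau_g * v3)
    raise ValueError(f"no LFP convention for system {traj.system_tag!r}")


def background_state(params: ModelParams) -> np.ndarray:
    """Low-activity stable equilibrium (background) with zero velocities.

    Used as the default initial condition, matching the narrative of
    starting from background activity.  If the supplied parameters have no
    stable low-activity equilibrium (e.g. inside the bursting window), the
    state is taken from the background operating point (SOM+ gain at its
    default) instead — the physical scenario of background activity that
    drifted into the pathological regime.
    """
    from .continuation import find_equilibria  # local import avoids a cycle

    eqs = [e for e in find_equilibria(params) if e.stable]
    if not eqs:
        eqs = [e for e in find_equilibria(params.replace(B=ModelParams().B))
               if e.stable]
    if not eqs:
        raise RuntimeError("no stable background equilibrium found")
    return min(eqs, key=lambda e: e.state[0]).state.copy()


# ---------------------------------------------------------------------------
# Spike and burst detection
# ---------------------------------------------------------------------------


@dataclass
class SpikeTrain:
    spike_times: np.ndarray
    threshold: float


@dataclass
class Burst:
    start: float
    end: float
    spike_count: int


@dataclass
class BurstSet:
    bursts: list
    quiescent_gaps: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.bursts)

    def spike_counts(self) -> np.ndarray:
        return np.array([b.spike_count for b in self.bursts], dtype=int)

    def steady_counts(self, drop_first: int = 1, drop_last: int = 1) -> np.ndarray:
        """Spike counts excluding the leading/trailing (possibly partial) bursts."""
        sel = self.bursts[drop_first: len(self.bursts) - drop_last or None]
        return np.array([b.spike_count for b in sel], dtype=int)

    def period(self, drop_first: int = 1, drop_last: int = 1) -> float:
        """Mean inter-burst-onset interval over the steady portion."""
        sel = self.bursts[drop_first: len(self.bursts) - drop_last or None]
        if len(sel) < 2:
            raise ValueError("need at least two steady bursts for a period")
        starts = np.array([b.start for b in sel])
        return float(np.mean(np.diff(starts)))


def detect_spikes(x, dt: float, threshold: float | None = None,
                  min_separation: float = 0.01, t0: float = 0.0) -> SpikeTrain:
    """Find spikes as local maxima above a threshold.

    When ``threshold`` is None it defaults to the midpoint between the
    quiescent level (median of the window) and the global maximum.  Spikes
    closer than ``min_separation`` to the previous accepted spike are
    merged (the higher peak wins via scipy's distance rule).
    """
    from scipy.signal import find_peaks

    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if threshold is None:
        threshold = 0.5 * (float(np.median(x)) + float(np.max(x)))
    distance = max(1, int(round(min_separation / dt)))
    peaks, _ = find_peaks(x, height=threshold, distance=distance)
    return SpikeTrain(spike_times=t0 + peaks * dt, threshold=float(threshold))


def segment_bursts(spikes: SpikeTrain, max_intra_burst_gap: float = 0.3) -> BurstSet:
    """Group consecutive spikes separated by <= max_intra_burst_gap into bursts."""
    st = np.asarray(spikes.spike_times, dtype=float)
    if st.size == 0:
        return BurstSet(bursts=[], quiescent_gaps=np.empty(0))
    bursts = []
    start = st[0]
    prev = st[0]
    count = 1
    for s in st[1:]:
        if s - prev <= max_intra_burst_gap:
            count += 1
        else:
            bursts.append(Burst(start=start, end=prev, spike_count=count))
            start = s
            count = 1
        prev = s
    bursts.append(Burst(start=start, end=prev, spike_count=count))
    gaps = np.array([bursts[i + 1].start - bursts[i].end
                     for i in range(len(bursts) - 1)])
    return BurstSet(bursts=bursts, quiescent_gaps=gaps)


def signal_energy(x) -> float:
    """Energy of a discrete signal: sum of squared samples."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    return float(np.sum(np.square(x)))
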