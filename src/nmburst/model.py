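"""Right-hand sides of the neural mass model and its slow-fast reformulations.

Full system (10 first-order ODEs, state ``(y0..y4, dy0..dy4)``)
---------------------------------------------------------------
Five second-order PSP blocks::

    y0'' = (A/tau_a)  S(y1 - y2 - y3)            - (2/tau_a) y0' - y0/tau_a^2
    y1'' = (A/tau_a) (p(t) + C2 S(C1 y0))        - (2/tau_a) y1' - y1/tau_a^2
    y2'' = (B/tau_b)  C4 S(C3 y0)                - (2/tau_b) y2' - y2/tau_b^2
    y3'' = (G/tau_g)  C7 S(C5 y0 - C6 y4)        - (2/tau_g) y3' - y3/tau_g^2
    y4'' = (B/tau_b)  S(C3 y0)                   - (2/tau_b) y4' - y4/tau_b^2

where y0 is the pyramidal PSP, y1 the excitatory input on pyramidal cells,
y2 the SOM+ PSP, y3 the PV+ PSP and y4 the (un-lumped) inhibitory input on
PV+ interneurons.  The simulated LFP is y1 - y2 - y3.

Rescaled three-timescale system (8 ODEs, state ``(v3,y8,v0,y5,v1,y6,v2,y7)``)
-----------------------------------------------------------------------------
Using the time variable ``t~ = t / tau_g`` and the ratios
``delta = tau_g/tau_a``, ``epsilon = tau_a/tau_b``::

    dv3/dt~ = y8                                                       (fast)
    dy8/dt~ = G S(C5 ta v0 - C6 tb v2) - v3 - 2 y8                     (fast)
    dv0/dt~ = delta y5                                                 (slow)
    dy5/dt~ = delta (A S(A ta p + C2 ta v1 - C4 tb v2 - C7 tg v3) - v0 - 2 y5)
    dv1/dt~ = delta y6                                                 (slow)
    dy6/dt~ = delta (A S(C1 ta v0) - v1 - 2 y6)                        (slow)
    dv2/dt~ = delta epsilon y7                                         (superslow)
    dy7/dt~ = delta epsilon (B S(C3 ta v0) - v2 - 2 y7)                (superslow)

The variable conversion fixed by requiring algebraic equivalence of the two
systems is ``v0 = y0/ta``, ``v1 = (y1 - A ta p)/(C2 ta)``, ``v2 = y4/tb``,
``v3 = y3/(C7 tg)`` (the constant drive A ta p and the lumpings C2, C7, C4
are absorbed; note v2 maps to the un-lumped SOM PSP y4, with y2 = C4 tb v2).

An external stimulation value ``i_ext`` scaled by the coupling coefficients
(kP, kSOM, kPV) is added inside the sigmoid arguments: kP in the pyramidal
blocks (y0/y1 resp. F5/F6), kSOM in the SOM+ blocks (y2/y4 resp. F7), kPV
in the PV+ block (y3 resp. F8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    ModelParams,
    StimCoupling,
    TimescaleParams,
    sigmoid,
    sigmoid_deriv,
)

__all__ = [
    "FULL_STATE_LABELS",
    "RESCALED_STATE_LABELS",
    "full_rhs",
    "full_jacobian",
    "rescaled_rhs",
    "rescaled_jacobian",
    "subsystem_rhs",
    "fast_layer_equilibrium",
    "fast_layer_jacobian",
    "full_to_rescaled",
    "rescaled_to_full",
    "full_equilibrium_residual",
    "full_equilibrium_state",
    "subsystem_equilibrium_residual",
    "subsystem_equilibrium_state",
    "subsystem_jacobian",
]

_NO_STIM = StimCoupling()

FULL_STATE_LABELS = ("y0", "y1", "y2", "y3", "y4",
                     "dy0", "dy1", "dy2", "dy3", "dy4")
RESCALED_STATE_LABELS = ("v3", "y8", "v0", "y5", "v1", "y6", "v2", "y7")


def _check_state(state, dim: int) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (dim,):
        raise ValueError(f"state must have shape ({dim},), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite entries")
    return x


def full_rhs(state, params: ModelParams, p_inst: float | None = None,
             i_ext: float = 0.0, coupling: StimCoupling = _NO_STIM) -> np.ndarray:
    """Time derivative of the full 10-dimensional system.

    ``p_inst`` is the instantaneous external input (defaults to the mean
    p_mean); stimulation ``i_ext`` is routed by ``coupling`` inside the
    sigmoid arguments.
    """
    x = _check_state(state, 10)
    y0, y1, y2, y3, y4, d0, d1, d2, d3, d4 = x
    pr = params
    sg = pr.sigmoid
    p = pr.p_mean if p_inst is None else p_inst
    IP = coupling.kP * i_ext
    IS = coupling.kSOM * i_ext
    IV = coupling.kPV * i_ext
    ita, itb, itg = 1.0 / pr.tau_a, 1.0 / pr.tau_b, 1.0 / pr.tau_g
    S = sigmoid
    dd0 = pr.A * ita * S(y1 - y2 - y3 + IP, sg) - 2.0 * ita * d0 - ita * ita * y0
    dd1 = pr.A * ita * (p + pr.C2 * S(pr.C1 * y0 + IP, sg)) - 2.0 * ita * d1 - ita * ita * y1
    dd2 = pr.B * itb * pr.C4 * S(pr.C3 * y0 + IS, sg) - 2.0 * itb * d2 - itb * itb * y2
    dd3 = pr.G * itg * pr.C7 * S(pr.C5 * y0 - pr.C6 * y4 + IV, sg) - 2.0 * itg * d3 - itg * itg * y3
    dd4 = pr.B * itb * S(pr.C3 * y0 + IS, sg) - 2.0 * itb * d4 - itb * itb * y4
    return np.array([d0, d1, d2, d3, d4, dd0, dd1, dd2, dd3, dd4])


def full_jacobian(state, params: ModelParams, i_ext: float = 0.0,
                  coupling: StimCoupling = _NO_STIM) -> np.ndarray:
    """Analytic 10x10 Jacobian of :func:`full_rhs` (sigmoid derivative closed form)."""
    x = _check_state(state, 10)
    y0, y1, y2, y3, y4 = x[:5]
    pr = params
    sg = pr.sigmoid
    IP = coupling.kP * i_ext
    IS = coupling.kSOM * i_ext
    IV = coupling.kPV * i_ext
    ita, itb, itg = 1.0 / pr.tau_a, 1.0 / pr.tau_b, 1.0 / pr.tau_g
    J = np.zeros((10, 10))
    for i in range(5):
        J[i, 5 + i] = 1.0
    ds0 = sigmoid_deriv(y1 - y2 - y3 + IP, sg)
    J[5, 1] = pr.A * ita * ds0
    J[5, 2] = -pr.A * ita * ds0
    J[5, 3] = -pr.A * ita * ds0
    J[6, 0] = pr.A * ita * pr.C2 * sigmoid_deriv(pr.C1 * y0 + IP, sg) * pr.C1
    ds2 = sigmoid_deriv(pr.C3 * y0 + IS, sg)
    J[7, 0] = pr.B * itb * pr.C4 * ds2 * pr.C3
    ds3 = sigmoid_deriv(pr.C5 * y0 - pr.C6 * y4 + IV, sg)
    J[8, 0] = pr.G * itg * pr.C7 * ds3 * pr.C5
    J[8, 4] = -pr.G * itg * pr.C7 * ds3 * pr.C6
    J[9, 0] = pr.B * itb * ds2 * pr.C3
    for i, it in enumerate((ita, ita, itb, itg, itb)):
        J[5 + i, i] += -it * it
        J[5 + i, 5 + i] += -2.0 * it
    return J


def _rescaled_args(x, pr: ModelParams, p: float, IP: float, IS: float, IV: float):
    v3, y8, v0, y5, v1, y6, v2, y7 = x
    ta, tb, tg = pr.tau_a, pr.tau_b, pr.tau_g
    a8 = pr.C5 * ta * v0 - pr.C6 * tb * v2 + IV
    a5 = pr.A * ta * p + pr.C2 * ta * v1 - pr.C4 * tb * v2 - pr.C7 * tg * v3 + IP
    a6 = pr.C1 * ta * v0 + IP
    a7 = pr.C3 * ta * v0 + IS
    return a8, a5, a6, a7


def rescaled_rhs(state, params: ModelParams,
                 timescales: TimescaleParams | None = None,
                 p_inst: float | None = None,
                 i_ext: float = 0.0, coupling: StimCoupling = _NO_STIM) -> np.ndarray:
    """Derivative of the rescaled 8-dimensional system with respect to t~ = t/tau_g.

    Components are ordered fast -> slow -> superslow:
    (F3, F8, delta F0, delta F5, delta F1, delta F6,
    delta epsilon F2, delta epsilon F7).
    """
    x = _check_state(state, 8)
    pr = params
    ts = timescales or TimescaleParams.from_taus(pr)
    d, e = ts.delta, ts.epsilon
    p = pr.p_mean if p_inst is None else p_inst
    IP, IS, IV = coupling.kP * i_ext, coupling.kSOM * i_ext, coupling.kPV * i_ext
    v3, y8, v0, y5, v1, y6, v2, y7 = x
    sg = pr.sigmoid
    a8, a5, a6, a7 = _rescaled_args(x, pr, p, IP, IS, IV)
    S = sigmoid
    return np.array([
        y8,
        pr.G * S(a8, sg) - v3 - 2.0 * y8,
        d * y5,
        d * (pr.A * S(a5, sg) - v0 - 2.0 * y5),
        d * y6,
        d * (pr.A * S(a6, sg) - v1 - 2.0 * y6),
        d * e * y7,
        d * e * (pr.B * S(a7, sg) - v2 - 2.0 * y7),
    ])


def rescaled_jacobian(state, params: ModelParams,
                      timescales: TimescaleParams | None = None,
                      i_ext: float = 0.0,
                      coupling: StimCoupling = _NO_STIM) -> np.ndarray:
    """Analytic 8x8 Jacobian of :func:`rescaled_rhs` in the t~ time variable."""
    x = _check_state(state, 8)
    pr = params
    ts = timescales or TimescaleParams.from_taus(pr)
    d, e = ts.delta, ts.epsilon
    IP, IS, IV = coupling.kP * i_ext, coupling.kSOM * i_ext, coupling.kPV * i_ext
    sg = pr.sigmoid
    ta, tb, tg = pr.tau_a, pr.tau_b, pr.tau_g
    a8, a5, a6, a7 = _rescaled_args(x, pr, pr.p_mean, IP, IS, IV)
    ds8 = sigmoid_deriv(a8, sg)
    ds5 = sigmoid_deriv(a5, sg)
    ds6 = sigmoid_deriv(a6, sg)
    ds7 = sigmoid_deriv(a7, sg)
    # state order: v3, y8, v0, y5, v1, y6, v2, y7
    J = np.zeros((8, 8))
    J[0, 1] = 1.0
    J[1, 0] = -1.0
    J[1, 1] = -2.0
    J[1, 2] = pr.G * ds8 * pr.C5 * ta
    J[1, 6] = -pr.G * ds8 * pr.C6 * tb
    J[2, 3] = d
    J[3, 0] = d * pr.A * ds5 * (-pr.C7 * tg)
    J[3, 2] = -d
    J[3, 3] = -2.0 * d
    J[3, 4] = d * pr.A * ds5 * pr.C2 * ta
    J[3, 6] = d * pr.A * ds5 * (-pr.C4 * tb)
    J[4, 5] = d
    J[5, 2] = d * pr.A * ds6 * pr.C1 * ta
    J[5, 4] = -d
    J[5, 5] = -2.0 * d
    J[6, 7] = d * e
    J[7, 2] = d * e * pr.B * ds7 * pr.C3 * ta
    J[7, 6] = -d * e
    J[7, 7] = -2.0 * d * e
    return J


# ---------------------------------------------------------------------------
# Singular-limit subsystems
# ---------------------------------------------------------------------------

def fast_layer_equilibrium(v0: float, v2: float, params: ModelParams,
                           i_ext: float = 0.0,
                           coupling: StimCoupling = _NO_STIM) -> tuple[float, float]:
    """Unique equilibrium of the fast layer problem at frozen (v0, v2).

    The critical manifold S0 is the graph
    v3 = G S(C5 ta v0 - C6 tb v2), y8 = 0.
    """
    pr = params
    a = pr.C5 * pr.tau_a * v0 - pr.C6 * pr.tau_b * v2 + coupling.kPV * i_ext
    return pr.G * sigmoid(a, pr.sigmoid), 0.0


def fast_layer_jacobian(v0: float, v2: float, params: ModelParams) -> np.ndarray:
    """Jacobian of the fast layer problem with respect to (v3, y8).

    Independent of (v0, v2): [[0, 1], [-1, -2]], a defective matrix with the
    double eigenvalue -1, so S0 is uniformly attracting.
    """
    del v0, v2, params  # the fast-layer linearisation carries no dependence
    return np.array([[0.0, 1.0], [-1.0, -2.0]])


def subsystem_rhs(kind: str, frozen: dict, state, params: ModelParams,
                  timescales: TimescaleParams | None = None,
                  i_ext: float = 0.0,
                  coupling: StimCoupling = _NO_STIM) -> np.ndarray:
    """Derivative of one of the singular-limit reduced systems.

    ``kind`` selects the reduction; ``frozen`` supplies exactly the
    variables that the chosen limit treats as parameters:

    - ``fast_layer``: state (v3, y8), frozen {v0, v2}; time t~.
    - ``slow_layer``: state (v0, y5, v1, y6), frozen {v2}; time t~s.  The
      fast pair is slaved to S0 (v3 substituted algebraically).
    - ``slow_reduced``: state (v0, y5, v1, y6, v2, y7); nothing frozen; the
      superslow pair carries the factor epsilon; time t~s; on S0.
    - ``superslow_reduced``: state (v2, y7), frozen {v0}; time t~s; on L0
      (v0 held at its superslow-manifold value by the caller).
    """
    pr = params
    ts = timescales or TimescaleParams.from_taus(pr)
    sg = pr.sigmoid
    ta, tb, tg = pr.tau_a, pr.tau_b, pr.tau_g
    IP, IS, IV = coupling.kP * i_ext, coupling.kSOM * i_ext, coupling.kPV * i_ext
    S = sigmoid

    def need(*names):
        missing = [n for n in names if n not in frozen]
        extra = [n for n in frozen if n not in names]
        if missing or extra:
            raise ValueError(
                f"{kind}: frozen must supply exactly {names}, got {sorted(frozen)}")
        return [float(frozen[n]) for n in names]

    if kind == "fast_layer":
        v0, v2 = need("v0", "v2")
        x = _check_state(state, 2)
        v3, y8 = x
        a8 = pr.C5 * ta * v0 - pr.C6 * tb * v2 + IV
        return np.array([y8, pr.G * S(a8, sg) - v3 - 2.0 * y8])

    if kind == "slow_layer":
        (v2,) = need("v2")
        x = _check_state(state, 4)
        v0, y5, v1, y6 = x
        v3, _ = fast_layer_equilibrium(v0, v2, pr, i_ext, coupling)
        a5 = pr.A * ta * pr.p_mean + pr.C2 * ta * v1 - pr.C4 * tb * v2 - pr.C7 * tg * v3 + IP
        a6 = pr.C1 * ta * v0 + IP
        return np.array([
            y5,
            pr.A * S(a5, sg) - v0 - 2.0 * y5,
            y6,
            pr.A * S(a6, sg) - v1 - 2.0 * y6,
        ])

    if kind == "slow_reduced":
        need()
        x = _check_state(state, 6)
        v0, y5, v1, y6, v2, y7 = x
        v3, _ = fast_layer_equilibrium(v0, v2, pr, i_ext, coupling)
        a5 = pr.A * ta * pr.p_mean + pr.C2 * ta * v1 - pr.C4 * tb * v2 - pr.C7 * tg * v3 + IP
        a6 = pr.C1 * ta * v0 + IP
        a7 = pr.C3 * ta * v0 + IS
        e = ts.epsilon
        return np.array([
            y5,
            pr.A * S(a5, sg) - v0 - 2.0 * y5,
            y6,
            pr.A * S(a6, sg) - v1 - 2.0 * y6,
            e * y7,
            e * (pr.B * S(a7, sg) - v2 - 2.0 * y7),
        ])

    if kind == "superslow_reduced":
        (v0,) = need("v0")
        x = _check_state(state, 2)
        v2, y7 = x
        a7 = pr.C3 * ta * v0 + IS
        return np.array([y7, pr.B * S(a7, sg) - v2 - 2.0 * y7])

    raise ValueError(f"unknown subsystem kind: {kind!r}")


# ---------------------------------------------------------------------------
# Variable conversion between the full and rescaled systems
# ---------------------------------------------------------------------------

def full_to_rescaled(state, params: ModelParams) -> np.ndarray:
    """Map a full-system state to the rescaled (v, y) coordinates.

    v0 = y0/ta, v1 = (y1 - A ta p)/(C2 ta), v2 = y4/tb, v3 = y3/(C7 tg);
    the derivative partners follow from y5 = ta v0' etc. evaluated in t~.
    """
    x = _check_state(state, 10)
    pr = params
    ta, tb, tg = pr.tau_a, pr.tau_b, pr.tau_g
    y0, y1, y2, y3, y4, d0, d1, d2, d3, d4 = x
    return np.array([
        y3 / (pr.C7 * tg),          # v3
        d3 / pr.C7,                 # y8 = tg * dv3/dt
        y0 / ta,                    # v0
        d0,                         # y5 = ta * dv0/dt
        (y1 - pr.A * ta * pr.p_mean) / (pr.C2 * ta),  # v1
        d1 / pr.C2,                 # y6
        y4 / tb,                    # v2
        d4,                         # y7 = tb * dv2/dt
    ])


def rescaled_to_full(state, params: ModelParams) -> np.ndarray:
    """Inverse of :func:`full_to_rescaled` (y2 reconstructed as C4 tb v2)."""
    x = _check_state(state, 8)
    pr = params
    ta, tb, tg = pr.tau_a, pr.tau_b, pr.tau_g
    v3, y8, v0, y5, v1, y6, v2, y7 = x
    return np.array([
        ta * v0,
        pr.A * ta * pr.p_mean + pr.C2 * ta * v1,
        pr.C4 * tb * v2,
        pr.C7 * tg * v3,
        tb * v2,
        y5,
        pr.C2 * y6,
        pr.C4 * y7,
        pr.C7 * y8,
        y7,
    ])


# ---------------------------------------------------------------------------
# Scalar equilibrium reductions (used by the continuation machinery)
# ---------------------------------------------------------------------------

def _full_chain(y0, pr: ModelParams):
    """Equilibrium values of y1, y2, y3, y4 as functions of y0."""
    sg = pr.sigmoid
    y1 = pr.A * pr.tau_a * (pr.p_mean + pr.C2 * sigmoid(pr.C1 * y0, sg))
    y4 = pr.B * pr.tau_b * sigmoid(pr.C3 * y0, sg)
    y2 = pr.C4 * y4
    y3 = pr.G * pr.tau_g * pr.C7 * sigmoid(pr.C5 * y0 - pr.C6 * y4, sg)
    return y1, y2, y3, y4


def full_equilibrium_residual(y0, params: ModelParams):
    """Scalar fixed-point equation in y0: every block is gain*tau*S(.)."""
    y1, y2, y3, _ = _full_chain(y0, params)
    return params.A * params.tau_a * sigmoid(y1 - y2 - y3, params.sigmoid) - y0


def full_equilibrium_state(y0: float, params: ModelParams) -> np.ndarray:
    """Reconstruct the 10-dimensional equilibrium from its y0 value."""
    y1, y2, y3, y4 = _full_chain(y0, params)
    return np.array([y0, y1, y2, y3, y4, 0.0, 0.0, 0.0, 0.0, 0.0])


def subsystem_equilibrium_residual(v0, v2, params: ModelParams,
                                   i_ext: float = 0.0,
                                   coupling: StimCoupling = _NO_STIM):
    """Scalar equilibrium equation of the 6-dim (v3,y8,v0,y5,v1,y6)-subsystem.

    This is also the defining equation of the superslow manifold L0:
    A S(A ta p + C2 ta A S(C1 ta v0) - C4 tb v2 - C7 tg v3) - v0 = 0 with
    v3 on S0.
    """
    pr = params
    sg = pr.sigmoid
    ta, tb, tg = pr.tau_a, pr.tau_b, pr.tau_g
    IP, IV = coupling.kP * i_ext, coupling.kPV * i_ext
    v1 = pr.A * sigmoid(pr.C1 * ta * v0 + IP, sg)
    v3 = pr.G * sigmoid(pr.C5 * ta * v0 - pr.C6 * tb * v2 + IV, sg)
    a5 = pr.A * ta * pr.p_mean + pr.C2 * ta * v1 - pr.C4 * tb * v2 - pr.C7 * tg * v3 + IP
    return pr.A * sigmoid(a5, sg) - v0


def subsystem_equilibrium_state(v0: float, v2: float, params: ModelParams,
                                i_ext: float = 0.0,
                                coupling: StimCoupling = _NO_STIM) -> np.ndarray:
    """6-dim subsystem equilibrium (v3, y8, v0, y5, v1, y6) from its v0 value."""
    pr = params
    IP = coupling.kP * i_ext
    v1 = pr.A * sigmoid(pr.C1 * pr.tau_a * v0 + IP, pr.sigmoid)
    v3, _ = fast_layer_equilibrium(v0, v2, pr, i_ext, coupling)
    return np.array([v3, 0.0, v0, 0.0, v1, 0.0])


def subsystem_jacobian(v0: float, v2: float, params: ModelParams,
                       timescales: TimescaleParams | None = None,
                       i_ext: float = 0.0,
                       coupling: StimCoupling = _NO_STIM) -> np.ndarray:
    """Analytic 6x6 Jacobian of the fast subsystem at its equilibrium, in t~.

    Rows are ordered (v3, y8, v0, y5, v1, y6); v2 enters as a parameter.
    """
    pr = params
    ts = timescales or TimescaleParams.from_taus(pr)
    d = ts.delta
    sg = pr.sigmoid
    ta, tb, tg = pr.tau_a, pr.tau_b, pr.tau_g
    IP, IV = coupling.kP * i_ext, coupling.kPV * i_ext
    v1 = pr.A * sigmoid(pr.C1 * ta * v0 + IP, sg)
    a8 = pr.C5 * ta * v0 - pr.C6 * tb * v2 + IV
    v3 = pr.G * sigmoid(a8, sg)
    a5 = pr.A * ta * pr.p_mean + pr.C2 * ta * v1 - pr.C4 * tb * v2 - pr.C7 * tg * v3 + IP
    a6 = pr.C1 * ta * v0 + IP
    J = np.zeros((6, 6))
    J[0, 1] = 1.0
    J[1, 0] = -1.0
    J[1, 1] = -2.0
    J[1, 2] = pr.G * sigmoid_deriv(a8, sg) * pr.C5 * ta
    J[2, 3] = d
    J[3, 0] = d * pr.A * sigmoid_deriv(a5, sg) * (-pr.C7 * tg)
    J[3, 2] = -d
    J[3, 3] = -2.0 * d
    J[3, 4] = d * pr.A * sigmoid_deriv(a5, sg) * pr.C2 * ta
    J[4, 5] = d
    J[5, 2] = d * pr.A * sigmoid_deriv(a6, sg) * pr.C1 * ta
    J[5, 4] = -d
    J[5, 5] = -2.0 * d
    return J
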