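"""Geometric objects of the three-timescale analysis.

The rescaled model splits into a fast PV+ pair (v3, y8), a slow pyramidal
quadruple (v0, y5, v1, y6) and a superslow SOM+ pair (v2, y7).  Freezing
the superslow pair turns v2 into a parameter of the 6-dimensional fast
subsystem, whose equilibrium diagram versus v2 is Z-shaped with two folds
(LP1, LP2) and, on its upper branch, two Hopf points (H1, H2).  Bursting
arises from the fold/Hopf hysteresis: the quiescent phase tracks the lower
branch until LP1, jumps to the limit-cycle regime of the upper branch and
spikes until the supercritical Hopf H2, after which the active phase dies
and the orbit falls back to the lower branch near LP2.

The critical manifold S0 (equilibria of the fast layer problem) is the
graph v3 = G S(C5 ta v0 - C6 tb v2) with y8 = 0; its fast-layer Jacobian
is constant with the double eigenvalue -1, so S0 is uniformly attracting.
The superslow manifold L0 (equilibria of the slow layer problem, a curve
inside S0) satisfies the same scalar equation that the continuation module
uses for the fast subsystem, so its folds coincide with the ZCurve folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams, StimCoupling, TimescaleParams, sigmoid, sigmoid_deriv
from . import model as _model
from .continuation import (
    BifurcationPoint,
    EquilibriumBranch,
    FastSubsystemProblem,
    continue_branch,
    detect_bifurcations,
)

__all__ = [
    "CriticalManifold",
    "SuperslowManifold",
    "ZCurve",
    "z_diagram",
    "classify_burster",
    "spike_bound_distance",
    "superslow_manifold",
    "reduced_constant_input_analysis",
    "ReducedAnalysis",
]

_NO_STIM = StimCoupling()


# ---------------------------------------------------------------------------
# Critical manifold S0
# ---------------------------------------------------------------------------


@dataclass
class CriticalManifold:
    """Evaluator of S0 and certificate of its attractivity."""

    params: ModelParams

    def v3(self, v0, v2):
        """Height of S0: v3 = G S(C5 ta v0 - C6 tb v2)."""
        pr = self.params
        return pr.G * sigmoid(pr.C5 * pr.tau_a * np.asarray(v0)
                              - pr.C6 * pr.tau_b * np.asarray(v2), pr.sigmoid)

    def fast_layer_eigenvalues(self, v0: float, v2: float) -> np.ndarray:
        """Eigenvalues of the fast-layer Jacobian (both equal -1 everywhere)."""
        J = _model.fast_layer_jacobian(v0, v2, self.params)
        return np.linalg.eigvals(J)

    def fast_layer_charpoly(self, v0: float, v2: float) -> tuple[float, float]:
        """(trace, det) of the fast-layer Jacobian: (-2, 1) identically."""
        J = _model.fast_layer_jacobian(v0, v2, self.params)
        return float(np.trace(J)), float(np.linalg.det(J))


# ---------------------------------------------------------------------------
# Z-shaped fast-subsystem diagram versus v2
# ---------------------------------------------------------------------------


@dataclass
class ZCurve:
    """Fast-subsystem equilibrium diagram versus v2 with its folds and Hopfs."""

    branch: EquilibriumBranch
    folds: list          # BifurcationPoint, ascending v2
    hopfs: list          # BifurcationPoint, ascending v2

    @property
    def lp1(self) -> BifurcationPoint | None:
        return self.folds[0] if self.folds else None

    @property
    def lp2(self) -> BifurcationPoint | None:
        return self.folds[-1] if len(self.folds) >= 2 else None

    @property
    def h1(self) -> BifurcationPoint | None:
        return self.hopfs[0] if self.hopfs else None

    @property
    def h2(self) -> BifurcationPoint | None:
        return self.hopfs[-1] if len(self.hopfs) >= 2 else None


def z_diagram(params: ModelParams | None = None, v2_range=(0.02, 26.0),
              timescales: TimescaleParams | None = None,
              i_ext: float = 0.0, coupling: StimCoupling = _NO_STIM,
              ds: float = 0.02) -> ZCurve:
    """Equilibrium diagram of the 6-dim fast subsystem with v2 as parameter.

    The subsystem does not involve the SOM+ gain B (B enters only the
    superslow pair), so the diagram is structurally independent of B.
    Hopf frequencies are reported in Hz via the t = tau_g * t~ relation.
    """
    params = params or ModelParams()
    branch = continue_branch("v2", v2_range, params, system="fast_subsystem",
                             timescales=timescales, i_ext=i_ext,
                             coupling=coupling, ds=ds, ds_max=0.1)
    pts = detect_bifurcations(branch)
    folds = sorted([p for p in pts if p.kind == "fold"],
                   key=lambda p: p.parameter_value)
    hopfs = sorted([p for p in pts if p.kind == "hopf"],
                   key=lambda p: p.parameter_value)
    return ZCurve(branch=branch, folds=folds, hopfs=hopfs)


def classify_burster(z: ZCurve) -> str:
    """Izhikevich-style classification from the fast-subsystem diagram.

    "fold/Hopf" requires the active phase to start at the lower-branch fold
    LP1 and to terminate at a Hopf (H2) lying between LP1 and LP2 — the
    fold-initiated, Hopf-terminated hysteresis.
    """
    if not z.folds or not z.hopfs:
        return "unclassified"
    lp1 = z.folds[0].parameter_value
    lp2 = z.folds[-1].parameter_value if len(z.folds) >= 2 else math.inf
    h_candidates = [h for h in z.hopfs if h.parameter_value > lp1]
    if not h_candidates:
        return "unclassifiable as burster"
    h2 = max(h_candidates, key=lambda h: h.parameter_value)
    if lp1 < h2.parameter_value < lp2:
        return "fold/Hopf"
    return "fold/fold-like (not fold/Hopf)"


def spike_bound_distance(z: ZCurve) -> float:
    """Signed v2-distance v2(H2) - v2(LP1); positive means bursting possible.

    The further apart the spike-initiating fold and the spike-terminating
    Hopf are, the more spikes fit into the active phase.
    """
    if not z.folds:
        raise ValueError("ZCurve has no fold (LP1) to measure from")
    if not z.hopfs:
        raise ValueError("ZCurve has no Hopf (H2) to measure to")
    lp1 = z.folds[0].parameter_value
    h2 = max(h.parameter_value for h in z.hopfs)
    return float(h2 - lp1)


# ---------------------------------------------------------------------------
# Superslow manifold L0
# ---------------------------------------------------------------------------


def _slow_layer_jacobian_on_s0(v0, v2, params, i_ext=0.0, coupling=_NO_STIM):
    """4x4 Jacobian of the slow layer problem restricted to S0 (time t~s)."""
    pr = params
    sg = pr.sigmoid
    ta, tb, tg = pr.tau_a, pr.tau_b, pr.tau_g
    IP, IV = coupling.kP * i_ext, coupling.kPV * i_ext
    v1 = pr.A * sigmoid(pr.C1 * ta * v0 + IP, sg)
    a8 = pr.C5 * ta * v0 - pr.C6 * tb * v2 + IV
    v3 = pr.G * sigmoid(a8, sg)
    a5 = pr.A * ta * pr.p_mean + pr.C2 * ta * v1 - pr.C4 * tb * v2 - pr.C7 * tg * v3 + IP
    a6 = pr.C1 * ta * v0 + IP
    dv3_dv0 = pr.G * sigmoid_deriv(a8, sg) * pr.C5 * ta
    J = np.zeros((4, 4))
    J[0, 1] = 1.0
    J[1, 0] = pr.A * sigmoid_deriv(a5, sg) * (-pr.C7 * tg) * dv3_dv0 - 1.0
    J[1, 1] = -2.0
    J[1, 2] = pr.A * sigmoid_deriv(a5, sg) * pr.C2 * ta
    J[2, 3] = 1.0
    J[3, 0] = pr.A * sigmoid_deriv(a6, sg) * pr.C1 * ta
    J[3, 2] = -1.0
    J[3, 3] = -2.0
    return J


@dataclass
class SuperslowManifold:
    """Sampling of L0: v0 roots per v2, with stability and folds."""

    params: ModelParams
    v2_grid: np.ndarray
    roots: list                     # list per v2 of arrays of v0 roots
    stable: list                    # matching booleans
    folds: list = field(default_factory=list)   # (v0, v2) fold locations

    def fold_v2_values(self) -> np.ndarray:
        return np.array(sorted(f[1] for f in self.folds))

    def roots_at(self, v2: float, i_ext: float = 0.0,
                 coupling: StimCoupling = _NO_STIM) -> np.ndarray:
        return _v0_roots(self.params, v2, i_ext, coupling)


def _v0_roots(params, v2, i_ext=0.0, coupling=_NO_STIM, n=3000):
    hi = 1.05 * params.A * params.sigmoid.vmax
    grid = np.linspace(-0.5, hi, n)
    vals = np.array([_model.subsystem_equilibrium_residual(u, v2, params,
                                                           i_ext, coupling)
                     for u in grid])
    roots = []
    for i in range(n - 1):
        if vals[i] * vals[i + 1] < 0:
            roots.append(brentq(
                lambda u: _model.subsystem_equilibrium_residual(
                    u, v2, params, i_ext, coupling),
                grid[i], grid[i + 1], xtol=1e-14))
    return np.array(roots)


def superslow_manifold(params: ModelParams | None = None, v2_grid=None,
                       i_ext: float = 0.0,
                       coupling: StimCoupling = _NO_STIM) -> SuperslowManifold:
    """Sample the superslow manifold L0 over a v2 grid.

    For each v2 all v0 roots of the L0 equation are found by bracketing;
    stability comes from the slow-layer Jacobian on S0; folds are located
    where roots coalesce (refined on the same scalar equation used by the
    ZCurve continuation, so the two fold sets agree by construction of the
    model, not of the code paths: the refinements are run independently).
    """
    params = params or ModelParams()
    if v2_grid is None:
        v2_grid = np.linspace(0.05, 26.0, 400)
    v2_grid = np.asarray(v2_grid, dtype=float)
    roots, stab = [], []
    for v2 in v2_grid:
        rs = _v0_roots(params, v2, i_ext, coupling)
        roots.append(rs)
        stab.append([bool(np.linalg.eigvals(
            _slow_layer_jacobian_on_s0(r, v2, params, i_ext, coupling)
        ).real.max() < 0) for r in rs])

    # folds: root-count changes between consecutive grid points -> refine
    folds = []
    from scipy.optimize import fsolve

    def fold_system(z):
        v0, v2 = z
        h = 1e-7 * max(1.0, abs(v0))
        g0 = _model.subsystem_equilibrium_residual(v0, v2, params, i_ext, coupling)
        g1 = (_model.subsystem_equilibrium_residual(v0 + h, v2, params, i_ext, coupling)
              - _model.subsystem_equilibrium_residual(v0 - h, v2, params, i_ext, coupling)
              ) / (2 * h)
        return [g0, g1]

    for i in range(len(v2_grid) - 1):
        n0, n1 = len(roots[i]), len(roots[i + 1])
        if n0 == n1:
            continue
        # the coalescing pair is the mutually closest pair on the rich side
        rich = np.sort(roots[i] if n0 > n1 else roots[i + 1])
        if rich.size < 2:
            continue
        gaps = np.diff(rich)
        j = int(np.argmin(gaps))
        guess_v0 = float(0.5 * (rich[j] + rich[j + 1]))
        guess_v2 = 0.5 * (v2_grid[i] + v2_grid[i + 1])
        z, info, ier, _ = fsolve(fold_system, [guess_v0, guess_v2],
                                 full_output=True, xtol=1e-13)
        if ier == 1 and not any(abs(z[1] - f[1]) < 1e-6 for f in folds):
            folds.append((float(z[0]), float(z[1])))
    return SuperslowManifold(params=params, v2_grid=v2_grid, roots=roots,
                             stable=stab, folds=sorted(folds, key=lambda f: f[1]))


# ---------------------------------------------------------------------------
# Reduced constant-input (strong perturbation) analysis
# ---------------------------------------------------------------------------


@dataclass
class ReducedAnalysis:
    """Equilibria of the slow reduced problem under a constant input and the
    predicted regime of the burster."""

    regime: str                     # "trapped" | "oscillating"
    equilibria: list                # (state6, stable) of the slow reduced problem
    fold_v0: float                  # v0 of the left fold of the (perturbed) L0
    coupling: StimCoupling
    i_ext: float


def _slow_reduced_jacobian(v0, v2, params, timescales, i_ext, coupling):
    """6x6 Jacobian of the slow reduced problem (v0,y5,v1,y6,v2,y7 on S0)."""
    pr = params
    ts = timescales or TimescaleParams.from_taus(pr)
    e = ts.epsilon
    sg = pr.sigmoid
    ta, tb, tg = pr.tau_a, pr.tau_b, pr.tau_g
    IP, IS, IV = coupling.kP * i_ext, coupling.kSOM * i_ext, coupling.kPV * i_ext
    v1 = pr.A * sigmoid(pr.C1 * ta * v0 + IP, sg)
    a8 = pr.C5 * ta * v0 - pr.C6 * tb * v2 + IV
    v3 = pr.G * sigmoid(a8, sg)
    a5 = pr.A * ta * pr.p_mean + pr.C2 * ta * v1 - pr.C4 * tb * v2 - pr.C7 * tg * v3 + IP
    a6 = pr.C1 * ta * v0 + IP
    a7 = pr.C3 * ta * v0 + IS
    ds8 = sigmoid_deriv(a8, sg)
    ds5 = sigmoid_deriv(a5, sg)
    dv3_dv0 = pr.G * ds8 * pr.C5 * ta
    dv3_dv2 = -pr.G * ds8 * pr.C6 * tb
    J = np.zeros((6, 6))
    # order: v0, y5, v1, y6, v2, y7 (time t~s)
    J[0, 1] = 1.0
    J[1, 0] = pr.A * ds5 * (-pr.C7 * tg) * dv3_dv0 - 1.0
    J[1, 1] = -2.0
    J[1, 2] = pr.A * ds5 * pr.C2 * ta
    J[1, 4] = pr.A * ds5 * (-pr.C4 * tb - pr.C7 * tg * dv3_dv2)
    J[2, 3] = 1.0
    J[3, 0] = pr.A * sigmoid_deriv(a6, sg) * pr.C1 * ta
    J[3, 2] = -1.0
    J[3, 3] = -2.0
    J[4, 5] = e
    J[5, 0] = e * pr.B * sigmoid_deriv(a7, sg) * pr.C3 * ta
    J[5, 4] = -e
    J[5, 5] = -2.0 * e
    return J


def reduced_constant_input_analysis(
        params: ModelParams | None = None,
        coupling: StimCoupling = _NO_STIM, i_ext: float = 0.0,
        timescales: TimescaleParams | None = None) -> ReducedAnalysis:
    """Equilibria of the slow reduced problem under a constant routed input.

    The system is "trapped" (burst abortion) when a stable equilibrium
    exists on the quiescent lower-v0 sheet of the (perturbed) superslow
    manifold — the geometric mechanism by which depolarising SOM+ input
    halts bursting — and "oscillating" otherwise.
    """
    params = params or ModelParams()
    pr = params
    sg = pr.sigmoid

    # full-system equilibria under the constant input: v2 slaved to the
    # superslow nullcline Sigma, v0 solving the L0 equation
    def resid(v0):
        v2 = pr.B * sigmoid(pr.C3 * pr.tau_a * v0 + coupling.kSOM * i_ext, sg)
        return _model.subsystem_equilibrium_residual(v0, v2, pr, i_ext, coupling)

    hi = 1.05 * pr.A * sg.vmax
    grid = np.linspace(-0.5, hi, 4000)
    vals = np.array([resid(u) for u in grid])
    v0s = []
    for i in range(len(grid) - 1):
        if vals[i] * vals[i + 1] < 0:
            v0s.append(brentq(resid, grid[i], grid[i + 1], xtol=1e-14))

    equilibria = []
    for v0 in v0s:
        v2 = pr.B * sigmoid(pr.C3 * pr.tau_a * v0 + coupling.kSOM * i_ext, sg)
        state6 = np.array([v0, 0.0,
                           pr.A * sigmoid(pr.C1 * pr.tau_a * v0
                                          + coupling.kP * i_ext, sg),
                           0.0, v2, 0.0])
        J = _slow_reduced_jacobian(v0, v2, pr, timescales, i_ext, coupling)
        equilibria.append((state6, bool(np.linalg.eigvals(J).real.max() < 0)))

    # left fold of the perturbed L0 marks the edge of the quiescent sheet
    ssm = superslow_manifold(pr, np.linspace(0.05, 26.0, 200), i_ext, coupling)
    if ssm.folds:
        fold_v0 = min(f[0] for f in ssm.folds)
    else:
        fold_v0 = 1.0
    trapped = any(st and eq[0] <= fold_v0 + 1e-9 for eq, st in equilibria)
    return ReducedAnalysis(regime="trapped" if trapped else "oscillating",
                           equilibria=equilibria, fold_v0=fold_v0,
                           coupling=coupling, i_ext=i_ext)


def theta_surface(params: ModelParams, v0, v2, i_ext: float = 0.0,
                  coupling: StimCoupling = _NO_STIM):
    """y5 value on the Theta (y5-null) surface at (v0, v2): F5 = 0."""
    pr = params
    v1 = pr.A * sigmoid(pr.C1 * pr.tau_a * np.asarray(v0)
                        + coupling.kP * i_ext, pr.sigmoid)
    v3 = pr.G * sigmoid(pr.C5 * pr.tau_a * np.asarray(v0)
                        - pr.C6 * pr.tau_b * np.asarray(v2)
                        + coupling.kPV * i_ext, pr.sigmoid)
    a5 = (pr.A * pr.tau_a * pr.p_mean + pr.C2 * pr.tau_a * v1
          - pr.C4 * pr.tau_b * np.asarray(v2) - pr.C7 * pr.tau_g * v3
          + coupling.kP * i_ext)
    return 0.5 * (pr.A * sigmoid(a5, pr.sigmoid) - np.asarray(v0))


def sigma_surface(params: ModelParams, v0, i_ext: float = 0.0,
                  coupling: StimCoupling = _NO_STIM):
    """v2 value on the Sigma (y7-null, y7 = 0) surface at v0: F7 = 0."""
    pr = params
    return pr.B * sigmoid(pr.C3 * pr.tau_a * np.asarray(v0)
                          + coupling.kSOM * i_ext, pr.sigmoid)
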