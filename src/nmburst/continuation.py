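"""Equilibrium computation and bifurcation continuation.

Every equilibrium of the full model reduces to one scalar fixed-point
equation in the pyramidal PSP y0 (each block's steady state is
gain * tau * S(.), all expressible through y0); the 6-dimensional fast
subsystem reduces likewise to a scalar equation in v0 with v2 as the
bifurcation parameter.  Branches are therefore continued by a
pseudo-arclength predictor-corrector on the scalar reduced equation —
this traverses folded (Z-shaped) branches through their turning points —
while stability and bifurcation test functions are evaluated on the
analytic full-dimensional Jacobians (the sigmoid derivative is closed
form, so no finite-difference noise enters the eigenvalue tests).

Folds are detected as turning points of the branch parameter (sign change
of the determinant test function) and refined by a two-variable Newton
solve of {g = 0, dg/du = 0}; Hopf points as zero crossings of the real
part of a complex-conjugate eigenvalue pair with |Im| > 1e-3 (which keeps
fold and Hopf test functions cleanly apart), refined by bisection along
the branch.  Hopf points report their frequency Im(lambda)/2pi converted
to Hz with the time unit of the underlying system.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, fsolve

from .params import ModelParams, StimCoupling, TimescaleParams
from . import model as _model

__all__ = [
    "Equilibrium",
    "EquilibriumBranch",
    "BifurcationPoint",
    "Codim2Curve",
    "find_equilibria",
    "continue_branch",
    "detect_bifurcations",
    "codim2_trace",
]

_NO_STIM = StimCoupling()

_FULL_PARAM_NAMES = ("A", "B", "G", "C5", "C6", "p_mean")
_IM_MIN = 1e-3  # below this a "pair" is treated as (near-)real: fold territory


# ---------------------------------------------------------------------------
# Scalar-reduction problems
# ---------------------------------------------------------------------------


class FullSystemProblem:
    """Scalar reduction of the 10-dim model; continuation parameter is a
    ModelParams field.  Time unit: seconds."""

    def __init__(self, params: ModelParams, param_name: str):
        if param_name not in _FULL_PARAM_NAMES:
            raise ValueError(f"param_name must be one of {_FULL_PARAM_NAMES}")
        self.base = params
        self.param_name = param_name
        self.u_scale = 0.01      # y0 lives on ~1e-2 mV
        self.freq_factor = 1.0 / (2.0 * math.pi)
        self.u_range = (-0.5, 2.0)

    def with_par(self, par: float) -> ModelParams:
        # gains/contacts/input are non-negative; clamp so that finite
        # differences taken in a thin layer below zero stay evaluable
        return self.base.replace(**{self.param_name: max(float(par), 0.0)})

    def residual(self, u: float, par: float) -> float:
        return float(_model.full_equilibrium_residual(u, self.with_par(par)))

    def state(self, u: float, par: float) -> np.ndarray:
        return _model.full_equilibrium_state(u, self.with_par(par))

    def jacobian(self, u: float, par: float) -> np.ndarray:
        pr = self.with_par(par)
        return _model.full_jacobian(_model.full_equilibrium_state(u, pr), pr)


class FastSubsystemProblem:
    """Scalar reduction of the 6-dim (v3,y8,v0,y5,v1,y6)-subsystem with v2
    as the continuation parameter.  Time unit: t~ = t / tau_g."""

    param_name = "v2"

    def __init__(self, params: ModelParams,
                 timescales: TimescaleParams | None = None,
                 i_ext: float = 0.0, coupling: StimCoupling = _NO_STIM):
        self.base = params
        self.timescales = timescales or TimescaleParams.from_taus(params)
        self.i_ext = i_ext
        self.coupling = coupling
        self.u_scale = 1.0
        self.freq_factor = 1.0 / (2.0 * math.pi * params.tau_g)
        self.u_range = (-0.5, 1.05 * params.A * params.sigmoid.vmax)

    def residual(self, u: float, par: float) -> float:
        return float(_model.subsystem_equilibrium_residual(
            u, par, self.base, self.i_ext, self.coupling))

    def state(self, u: float, par: float) -> np.ndarray:
        return _model.subsystem_equilibrium_state(
            u, par, self.base, self.i_ext, self.coupling)

    def jacobian(self, u: float, par: float) -> np.ndarray:
        return _model.subsystem_jacobian(
            u, par, self.base, self.timescales, self.i_ext, self.coupling)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class Equilibrium:
    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool
    residual: float


@dataclass
class BifurcationPoint:
    kind: str                    # "fold" | "hopf"
    parameter_name: str
    parameter_value: float
    state: np.ndarray
    critical_eigenvalue: complex
    hopf_frequency: float | None = None   # Hz, Im(lambda)/2pi in physical time
    scalar: float = float("nan")          # reduced coordinate (y0 or v0)


@dataclass
class EquilibriumBranch:
    parameter_name: str
    parameter_values: np.ndarray
    states: np.ndarray
    eigenvalues: np.ndarray
    stability: np.ndarray
    scalars: np.ndarray
    termination_reason: str = "range_exhausted"
    problem: object = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.parameter_values)

    def to_csv(self, path, labels=None) -> None:
        labels = labels or [f"x{i}" for i in range(self.states.shape[1])]
        df = pd.DataFrame(self.states, columns=list(labels))
        df.insert(0, self.parameter_name, self.parameter_values)
        df["max_re_eigenvalue"] = self.eigenvalues.real.max(axis=1)
        df["stable"] = self.stability
        df.to_csv(path, index=False)


@dataclass
class Codim2Curve:
    point_label: str
    kind: str
    param1_name: str
    param2_name: str
    param1_values: np.ndarray
    param2_values: np.ndarray
    states: list
    termination_reason: str = "range_exhausted"

    def __len__(self) -> int:
        return len(self.param2_values)


# ---------------------------------------------------------------------------
# Equilibria
# ---------------------------------------------------------------------------


def find_equilibria(params: ModelParams, y0_range=(-0.5, 2.0),
                    n_grid: int = 4000) -> list[Equilibrium]:
    """All equilibria of the full model, with spectra and stability.

    The 10-dim fixed-point problem is reduced to the scalar equation in y0;
    all roots are found by sign-change bracketing on a fine grid followed
    by Brent refinement.
    """
    g = lambda u: float(_model.full_equilibrium_residual(u, params))  # noqa: E731
    grid = np.linspace(y0_range[0], y0_range[1], n_grid)
    vals = np.array([g(u) for u in grid])
    roots = []
    for i in range(n_grid - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-15, rtol=1e-15))
    out = []
    for r in roots:
        st = _model.full_equilibrium_state(r, params)
        ev = np.linalg.eigvals(_model.full_jacobian(st, params))
        out.append(Equilibrium(state=st, eigenvalues=ev,
                               stable=bool(ev.real.max() < 0),
                               residual=abs(g(r))))
    if not out:
        raise RuntimeError("no equilibria found: parameter pathology "
                           f"(searched y0 in {y0_range})")
    return out


# ---------------------------------------------------------------------------
# Pseudo-arclength continuation on the scalar reduced equation
# ---------------------------------------------------------------------------


def _grad(problem, u, par):
    hu = 1e-7 * max(problem.u_scale, abs(u))
    hp = 1e-7 * max(1.0, abs(par))
    gu = (problem.residual(u + hu, par) - problem.residual(u - hu, par)) / (2 * hu)
    gp = (problem.residual(u, par + hp) - problem.residual(u, par - hp)) / (2 * hp)
    return gu, gp


def _corrector(problem, u, par, tvec, ref, gtol, max_iter=12):
    """Newton solve of {g = 0, (x - ref) . t = 0} in scaled coordinates."""
    sc = problem.u_scale
    for _ in range(max_iter):
        g = problem.residual(u, par)
        ortho = (u - ref[0]) / sc * tvec[0] + (par - ref[1]) * tvec[1]
        if abs(g) < gtol and abs(ortho) < 1e-12:
            return u, par, True
        gu, gp = _grad(problem, u, par)
        # rows: [gu*sc, gp] in scaled coords; [t0, t1]
        a, b = gu * sc, gp
        c, d = tvec[0], tvec[1]
        det = a * d - b * c
        if det == 0 or not math.isfinite(det):
            return u, par, False
        dw = (-g * d + ortho * b) / det
        dq = (g * c - ortho * a) / det
        u += dw * sc
        par += dq
        if not (math.isfinite(u) and math.isfinite(par)):
            return u, par, False
    g = problem.residual(u, par)
    return u, par, abs(g) < gtol * 100


def _initial_roots(problem, par, n=2000):
    lo, hi = problem.u_range
    grid = np.linspace(lo, hi, n)
    vals = np.array([problem.residual(u, par) for u in grid])
    roots = []
    for i in range(n - 1):
        if vals[i] * vals[i + 1] < 0:
            roots.append(brentq(lambda u: problem.residual(u, par),
                                grid[i], grid[i + 1], xtol=1e-15))
    return roots


def continue_branch(param_name: str, prange, params: ModelParams | None = None,
                    system: str = "full",
                    timescales: TimescaleParams | None = None,
                    i_ext: float = 0.0, coupling: StimCoupling = _NO_STIM,
                    u_start: float | None = None, start_par: float | None = None,
                    ds: float = 0.05, ds_max: float = 0.25, ds_min: float = 1e-5,
                    max_steps: int = 50000, gtol: float = 1e-12) -> EquilibriumBranch:
    """Continue an equilibrium branch over ``prange`` by pseudo-arclength.

    By default the march starts from the upper end of the range (where the
    model has its background equilibrium for the B sweep) and proceeds
    downward, traversing folds until the parameter leaves the range or the
    corrector fails at the minimum step size.
    """
    params = params or ModelParams()
    if system == "full":
        problem = FullSystemProblem(params, param_name)
    elif system == "fast_subsystem":
        if param_name != "v2":
            raise ValueError("fast_subsystem continuation is parameterised by v2")
        problem = FastSubsystemProblem(params, timescales, i_ext, coupling)
    else:
        raise ValueError(f"unknown system {system!r}")

    lo, hi = float(min(prange)), float(max(prange))
    par = hi if start_par is None else float(start_par)
    if u_start is None:
        roots = _initial_roots(problem, par)
        if not roots:
            raise RuntimeError(f"no equilibrium at {param_name}={par}")
        u = roots[0]
    else:
        u = float(u_start)
        for _ in range(60):  # Newton polish onto the branch
            g = problem.residual(u, par)
            gu, _ = _grad(problem, u, par)
            if gu == 0.0:
                break
            du = g / gu
            u -= du
            if abs(du) < 1e-14:
                break

    sc = problem.u_scale
    gu, gp = _grad(problem, u, par)
    t = np.array([-gp, gu * sc])
    t = t / np.linalg.norm(t)
    # orient the initial tangent to march into the range
    direction = -1.0 if abs(par - hi) <= abs(par - lo) else 1.0
    if t[1] * direction < 0:
        t = -t

    us, pars = [u], [par]
    reason = "max_steps"
    step = ds
    k = 0
    while k < max_steps:
        k += 1
        pred = (u + step * t[0] * sc, par + step * t[1])
        if pred[1] < lo - 0.2 or pred[1] > hi + 0.2:
            reason = "range_exhausted"
            break
        un, pn, ok = _corrector(problem, pred[0], pred[1], t, pred, gtol)
        if ok:
            dnew = np.array([(un - u) / sc, (pn - par)])
            norm = np.linalg.norm(dnew)
            if norm == 0.0:
                ok = False
            else:
                tn = dnew / norm
                if np.dot(tn, t) < 0.2:   # sharp reversal: reject, shrink
                    ok = False
        if not ok:
            step *= 0.5
            if step < ds_min:
                reason = "corrector_failure"
                break
            continue
        u, par, t = un, pn, tn
        us.append(u)
        pars.append(par)
        if step < ds:
            step = min(step * 1.4, ds_max)
        if par < lo - 1e-9 or par > hi + 1e-9:
            reason = "range_exhausted"
            break

    us = np.array(us)
    pars = np.array(pars)
    states = np.array([problem.state(w, q) for w, q in zip(us, pars)])
    eig = np.array([np.linalg.eigvals(problem.jacobian(w, q))
                    for w, q in zip(us, pars)])
    stab = eig.real.max(axis=1) < 0
    return EquilibriumBranch(parameter_name=problem.param_name,
                             parameter_values=pars, states=states,
                             eigenvalues=eig, stability=stab, scalars=us,
                             termination_reason=reason, problem=problem)


# ---------------------------------------------------------------------------
# Bifurcation detection
# ---------------------------------------------------------------------------


def _refine_fold(problem, u0, par0):
    def F(z):
        u, par = z
        hu = 1e-7 * max(problem.u_scale, abs(u))
        gu = (problem.residual(u + hu, par)
              - problem.residual(u - hu, par)) / (2 * hu)
        return [problem.residual(u, par) / problem.u_scale, gu]

    z, info, ier, _ = fsolve(F, [u0, par0], full_output=True, xtol=1e-12)
    if np.linalg.norm(F(z)) > 1e-7:   # ier alone is too strict with FD noise
        return None
    return float(z[0]), float(z[1])


def _complex_pairs(eigs):
    """Upper-half-plane members of complex pairs with Im > _IM_MIN."""
    return [e for e in eigs if e.imag > _IM_MIN]


def _match_pair(pairs, ref):
    """The pair whose eigenvalue is closest to ``ref`` (or None)."""
    if not pairs:
        return None
    return min(pairs, key=lambda e: abs(e - ref))


def _refine_hopf(problem, u0, par0, u1, par1, ref_pair, iters=60):
    """Bisection along the chord between two branch samples for Re(pair)=0."""
    sc = problem.u_scale

    def eval_at(s):
        w = u0 + s * (u1 - u0)
        q = par0 + s * (par1 - par0)
        chord = np.array([(u1 - u0) / sc, par1 - par0])
        n = np.linalg.norm(chord)
        tvec = chord / n if n > 0 else np.array([0.0, 1.0])
        u, par, ok = _corrector(problem, w, q, tvec, (w, q), 1e-12)
        if not ok:
            return None
        ev = np.linalg.eigvals(problem.jacobian(u, par))
        pair = _match_pair(_complex_pairs(ev), ref_pair)
        if pair is None:
            return None
        return u, par, pair

    a, b = 0.0, 1.0
    ra = eval_at(a)
    rb = eval_at(b)
    if ra is None or rb is None or ra[2].real * rb[2].real > 0:
        return None
    for _ in range(iters):
        m = 0.5 * (a + b)
        rm = eval_at(m)
        if rm is None:
            return None
        if rm[2].real * ra[2].real <= 0:
            b, rb = m, rm
        else:
            a, ra = m, rm
    out = eval_at(0.5 * (a + b))
    if out is None or abs(out[2].real) > 1e-6:
        return None   # pair identity was lost during refinement
    return out


def detect_bifurcations(branch: EquilibriumBranch,
                        refine_tol: float = 1e-4) -> list[BifurcationPoint]:
    """Fold and Hopf points along a continued branch.

    Folds are turning points of the branch parameter refined by Newton on
    {g = 0, dg/du = 0}; Hopf points are real-part zero crossings of complex
    eigenvalue pairs (|Im| > 1e-3), matched between consecutive samples by
    spectral proximity and refined by bisection.
    """
    problem = branch.problem
    if problem is None:
        raise ValueError("branch does not carry its continuation problem")
    pars = branch.parameter_values
    us = branch.scalars
    points: list[BifurcationPoint] = []

    # --- folds ---
    dpar = np.diff(pars)
    for i in range(1, len(pars) - 1):
        if dpar[i - 1] * dpar[i] < 0:
            res = _refine_fold(problem, us[i], pars[i])
            if res is None:
                continue
            u, par = res
            ev = np.linalg.eigvals(problem.jacobian(u, par))
            crit = ev[np.argmin(np.abs(ev.real) + np.abs(ev.imag))]
            points.append(BifurcationPoint(
                kind="fold", parameter_name=problem.param_name,
                parameter_value=par, state=problem.state(u, par),
                critical_eigenvalue=complex(crit), scalar=u))

    # --- Hopf ---
    for i in range(len(pars) - 1):
        pairs0 = _complex_pairs(branch.eigenvalues[i])
        pairs1 = _complex_pairs(branch.eigenvalues[i + 1])
        for p0 in pairs0:
            p1 = _match_pair(pairs1, p0)
            if p1 is None or p0.real * p1.real >= 0:
                continue
            res = _refine_hopf(problem, us[i], pars[i], us[i + 1], pars[i + 1], p0)
            if res is None:
                continue
            u, par, pair = res
            points.append(BifurcationPoint(
                kind="hopf", parameter_name=problem.param_name,
                parameter_value=par, state=problem.state(u, par),
                critical_eigenvalue=complex(pair),
                hopf_frequency=float(pair.imag * problem.freq_factor),
                scalar=u))

    # de-duplicate (same kind, nearly same location)
    points.sort(key=lambda p: p.parameter_value)
    unique: list[BifurcationPoint] = []
    for pt in points:
        if any(pt.kind == q.kind
               and abs(pt.parameter_value - q.parameter_value) < 10 * refine_tol
               and abs(pt.scalar - q.scalar) < 10 * refine_tol * problem.u_scale * 100
               for q in unique):
            continue
        unique.append(pt)
    return unique


def bifurcations_to_json(points, path=None) -> str:
    recs = [{
        "kind": p.kind,
        "parameter_name": p.parameter_name,
        "parameter_value": p.parameter_value,
        "hopf_frequency_hz": p.hopf_frequency,
        "critical_eigenvalue": [p.critical_eigenvalue.real,
                                p.critical_eigenvalue.imag],
    } for p in points]
    text = json.dumps(recs, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Two-parameter (codim-2) tracing
# ---------------------------------------------------------------------------


def _problem_factory(system, params, param_name, param2_name, timescales,
                     i_ext, coupling):
    def make(par2_value):
        pr = params.replace(**{param2_name: float(par2_value)})
        if system == "full":
            return FullSystemProblem(pr, param_name)
        return FastSubsystemProblem(pr, timescales, i_ext, coupling)
    return make


def codim2_trace(point: BifurcationPoint, param2_name: str, param2_values,
                 params: ModelParams, system: str = "full",
                 timescales: TimescaleParams | None = None,
                 i_ext: float = 0.0, coupling: StimCoupling = _NO_STIM,
                 label: str | None = None,
                 jump_tol: float = 5.0) -> Codim2Curve:
    """Trace a fold/Hopf point through a second parameter by chained
    codim-1 re-detection.

    At each value of ``param2`` the codim-1 defining condition is re-solved
    starting from the previous location; the curve terminates (with a
    recorded reason) when the point is lost or jumps implausibly far.
    """
    make = _problem_factory(system, params, point.parameter_name, param2_name,
                            timescales, i_ext, coupling)
    p1s, p2s, states = [], [], []
    u, par = point.scalar, point.parameter_value
    ref_pair = point.critical_eigenvalue
    reason = "range_exhausted"
    for p2 in np.atleast_1d(np.asarray(param2_values, dtype=float)):
        problem = make(p2)
        if point.kind == "fold":
            res = _refine_fold(problem, u, par)
        else:
            res = _refine_hopf_at(problem, u, par, ref_pair)
        if res is None:
            reason = "point_lost"
            break
        un, pn = res[0], res[1]
        if p1s and (abs(pn - par) > jump_tol):
            reason = "point_lost"
            break
        u, par = un, pn
        if point.kind == "hopf":
            ref_pair = res[2]
        p1s.append(par)
        p2s.append(p2)
        states.append(problem.state(u, par))
    return Codim2Curve(
        point_label=label or f"{point.kind}@{point.parameter_value:.3g}",
        kind=point.kind, param1_name=point.parameter_name,
        param2_name=param2_name,
        param1_values=np.array(p1s), param2_values=np.array(p2s),
        states=states, termination_reason=reason)


def _refine_hopf_at(problem, u0, par0, ref_pair):
    """Newton/fsolve refinement of {g=0, Re(pair)=0} near (u0, par0)."""
    ref = [ref_pair]

    def F(z):
        u, par = z
        ev = np.linalg.eigvals(problem.jacobian(u, par))
        pair = _match_pair(_complex_pairs(ev), ref[0])
        re = pair.real if pair is not None else 1.0
        return [problem.residual(u, par) / problem.u_scale, re]

    z, info, ier, _ = fsolve(F, [u0, par0], full_output=True, xtol=1e-12)
    if ier != 1:
        return None
    u, par = float(z[0]), float(z[1])
    ev = np.linalg.eigvals(problem.jacobian(u, par))
    pair = _match_pair(_complex_pairs(ev), ref[0])
    if pair is None or abs(pair.real) > 1e-6:
        return None
    return u, par, pair
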