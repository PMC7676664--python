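# Methods

## Model equations and conventions

The full model is ten first-order ODEs for five second-order PSP blocks
(pyramidal y₀, excitatory input on pyramidal y₁, SOM+ y₂, PV+ y₃, and the
un-lumped inhibitory input on PV+ y₄), with the firing-rate sigmoid
S(v) = 5/(1+exp(0.56(6−v))) and background parameter defaults A=5, B=40,
G=35 mV, p̄=90 Hz, C₁…C₇ = 135, 108, 35, 25, 450, 121, 121, τ_a=10 ms,
τ_b=50 ms, τ_g=3 ms.  One damping/stiffness coefficient of the PV+ block
is written inconsistently across published forms of these equations
(τ_b² where the surrounding block uses τ_g); we use τ_g² throughout, which
is the only choice under which the full and time-rescaled systems are
algebraically equivalent.  That equivalence is enforced by a test that
integrates both systems from converted initial conditions and requires
identical spikes-per-burst and burst periods to within 1%.

The variable conversion between the two systems is fixed the same way
(the rescaled sigmoid arguments force it):

    v0 = y0/τ_a,  v1 = (y1 − A τ_a p̄)/(C2 τ_a),  v2 = y4/τ_b,
    v3 = y3/(C7 τ_g),   y5 = ẏ0,  y6 = ẏ1/C2,  y7 = ẏ4,  y8 = ẏ3/C7.

Note v₂ tracks the un-lumped SOM+ PSP y₄ (y₂ = C₄ τ_b v₂), and the
rescaled LFP C₂τ_a v₁ − C₄τ_b v₂ − C₇τ_g v₃ differs from the physical LFP
by the constant A τ_a p̄ absorbed into v₁ — irrelevant for spike or burst
statistics.

Stimulation is an additive perturbation inside the sigmoid arguments,
routed by (k_P, k_SOM, k_PV).  The published routing is printed only for
the rescaled system; the full-system routing mirrors it block by block
(k_P in the y₀/y₁ blocks, k_SOM in y₂/y₄, k_PV in y₃).

## Integration

Fixed-step Euler–Maruyama with dt = 1e-4 s.  The stochastic input enters
only through the cortical drive p(t) = p̄ + ξ on the y₁ block; ξ is
discretised as a per-step Gaussian increment of standard deviation
σ/√dt (state increment (A/τ_a)·σ·√dt·N(0,1)), the standard
Euler–Maruyama treatment of additive input noise.  With σ = 0 the scheme
is exactly forward Euler and runs are bit-reproducible regardless of seed.
All quantitative results in the package are computed at σ = 0.  The noise
level is never stated with the published model; for qualitative
demonstrations of sporadic bursting in the bistable window
(B between the two high-B folds) a demo value of σ = 30 Hz is a
reasonable choice (same order as the mean input's customary spread in
this model family), but nothing quantitative depends on it.

Burst-period convergence is checked by halving dt (1e-4 → 5e-5); the
deterministic period moves by less than 1%.

Default initial condition is the low-activity stable equilibrium
("background state").  When the operating point itself has no stable
equilibrium (inside the bursting window) the background state of the
default SOM+ gain is used instead, matching the physiological narrative of
background activity drifting into the pathological regime; the trajectory
then converges to the bursting attractor well within the 5 s transient
that all analyses discard.

## Spike and burst detection

Spikes are local maxima of the LFP above a threshold, separated by at
least 10 ms.  The default threshold is the midpoint between the quiescent
level (median of the analysed window) and the window maximum — robust for
this model's large-amplitude spikes riding on a flat quiescent phase.
Bursts group consecutive spikes with inter-spike gaps ≤ 0.3 s; the burst
period is the mean inter-burst-onset interval with the first and last
(possibly partial) bursts dropped.  In stimulation runs the threshold is
always derived from the pre-stimulation window, so that successful
abortion cannot redefine what counts as a spike.

## Continuation and bifurcation detection

Every equilibrium of the full model reduces to a scalar fixed-point
equation in y₀ (each block's steady state is gain·τ·S(·)); the
6-dimensional fast subsystem reduces likewise to a scalar equation in v₀
with v₂ as parameter.  Branches are continued by pseudo-arclength
predictor–corrector on the scalar reduced equation — one march traverses
the entire folded (Z-shaped) curve — with adaptive step control
(growth ×1.4, halving on corrector failure, floor 1e-5).  Stability and
test functions use the analytic full-dimensional Jacobians (the sigmoid
derivative is closed form); equilibrium residuals along branches are
below 1e-10.

Folds are turning points of the branch parameter, refined by Newton on
{g = 0, ∂g/∂u = 0}; at the refined point the Jacobian's critical
eigenvalue has |Re λ| < 1e-6.  Hopf points are zero crossings of the real
part of a complex-conjugate pair with |Im λ| > 1e-3 (keeping the fold and
Hopf test functions apart), matched between consecutive samples by
spectral proximity and refined by bisection along the branch; a refined
point is accepted only if the tracked pair lands on the imaginary axis to
1e-6.  Hopf frequencies are Im λ/2π, converted to Hz via t = τ_g·t̃ for
the rescaled subsystem.  Hopf criticality is not computed from normal
forms; where it matters (the burster classification) it is established
empirically by the simulated orbits.

Codim-2 curves are traced by chained codim-1 re-detection over a grid of
the second parameter (not a true two-parameter continuation): each step
re-solves the defining condition from the previous location and the curve
terminates with a recorded reason if the point is lost or jumps
implausibly.  This is accurate here because the traced curves are smooth
and well separated; it would not resolve curve crossings or sharp cusps
beyond grid resolution.

## Slow-fast geometry

The critical manifold S⁰ is the graph v₃ = G·S(C₅τ_a v₀ − C₆τ_b v₂) with
y₈ = 0; its fast-layer Jacobian is the constant matrix [[0, 1], [−1, −2]]
with the double eigenvalue −1, so S⁰ is uniformly attracting — asserted
exactly (trace −2, determinant 1) at random points.  The superslow
manifold L⁰ satisfies the same scalar equation as the fast-subsystem
equilibria; the package nevertheless computes its folds by an independent
route (dense root bracketing over a v₂ grid plus root-coalescence
refinement) and checks agreement with the continuation-derived ZCurve
folds to 1e-3.  L⁰ stability uses the 4-dimensional slow-layer Jacobian
on S⁰, which has no Hopf instabilities — only the fold-mediated stability
changes — consistent with the reduced system showing relaxation rather
than spiking.

The constant-input ("strong perturbation") analysis solves the slow
reduced problem's equilibria with the superslow nullcline Σ
(v₂ = B·S(C₃τ_a v₀ + k_SOM·I)) substituted, and classifies the regime as
**trapped** only when a stable equilibrium lies on the quiescent
lower-v₀ sheet of L⁰ (v₀ at or below the left fold), not merely when a
stable equilibrium exists — the geometric criterion for burst abortion.
At B = 15 and I = 1 this yields: k_SOM = +1 trapped, k_SOM = −1
oscillating (with a prolonged active phase), k_P = k_SOM = 1 oscillating,
k_SOM = 2 with k_P = 1 trapped; the full model confirms each regime by
direct simulation.

The singular-limit convergence of bursting orbits is demonstrated on the
rescaled system with (δ, ε) decoupled from the synaptic time constants:
at ε ∈ {0.05, 0.02, 0.01} (δ at its physical 0.3, B = 18) the
quiescent-phase distance to the ZCurve's lower branch decreases
monotonically.

## Stimulation studies

Pulse trains are anodic-first charge-balanced biphasic rectangles,
0.5 ms per phase (1 ms total), sampled exactly on the integration grid
(5 samples per phase at dt = 1e-4 s; no band-limiting).  Construction
rejects overlapping-pulse configurations (f · 1 ms > 1).

Operating point: the published stimulation experiments never print their
bursting parameter triple.  We use **B = 20, G = 35, C₅ = 450** — inside
the sustained-bursting window, close to its high-B edge — because at σ = 0
this point reproduces the full qualitative protocol pattern exactly:
SOM+-only 15 Hz / amplitude-10 stimulation aborts bursting, the same train
applied homogeneously to all populations does not, and homogeneous
stimulation aborts at 25 Hz.  Deeper in the bursting window (e.g. B = 10,
the many-spike point used for the spike-count analysis) the deterministic
abort boundary moves to ≈50 Hz for SOM+-only coupling; the qualitative
ordering (SOM+-only aborts at frequencies no higher than homogeneous)
holds throughout.  The abort flag means "no burst detected from 1 s after
stimulation onset to the end of the run" and is invariant to the settle
margin within 0.5–2 s.

Energy maps evaluate E = Σ|x(n)|² of the post-onset LFP per
(frequency, amplitude) cell with a fixed seed and initial state per map;
aborted cells have strictly lower energy than bursting cells at the same
amplitude.

The single neural-mass block study (ÿ = M/τ·S(I(t)) − 2/τ·ẏ − y/τ²,
M·τ = 1) quantifies the timescale–frequency law: the minimum pulse
frequency at which the steady envelope detaches from the baseline
M·τ·S(0) ≈ 0.168 is non-increasing in τ (at amplitude 10:
10 Hz for τ = 50 ms, 20 Hz for 10 ms, 80 Hz for 3 ms), and the envelope
saturates in amplitude once the sigmoid saturates (no change beyond
amplitude ≈ 20).

## Reference values: agreements and discrepancies

With the background parameter table, the package reproduces the published
bifurcation skeleton: the B-diagram folds at ≈4.55, 7.48, 21.34 and Hopfs
at ≈4.57, 7.74 (all within 0.7% of the printed values), the fast-subsystem
folds at v₂ = 4.778 / 20.66 to four digits, the ~30 Hz gamma Hopf
frequency, exactly 11 spikes per burst at B = 10, and the H₂–LP₁
alignment at C₅ ≈ 137.6 (printed: 139 ± 2).

Four printed values do not follow from the stated parameters under any
reading of the equations we tried, and the package reports its computed
values rather than the printed ones: the right fold of the high-B Z-curve
computes to B = 33.59 (printed ≈35.6; independent brute-force root
counting confirms three equilibria at B = 33.5 and one at B = 33.6), the
gamma Hopf to B = 1.46 (printed ≈1.51; direct simulation places the
oscillation onset between 1.46 and 1.48), and the fast-subsystem upper
branch Hopfs to v₂ = 0.286 and 16.40 at ≈29 Hz both (printed 0.27 and
14.27 at 30 and 10 Hz).  The simulated bursting orbit's intra-burst spike
rate stays ≈28 Hz through the end of the active phase, supporting the
29 Hz figure; and the H₂ branch that our Jacobian produces is the one
that passes through the published C₅ ≈ 139 alignment point, so we regard
these as inconsistencies in the printed values rather than in the model.

## Problem sizes

Default analyses use: continuation branches of 1.8k (B-sweep) and 4.1k
(v₂-sweep) points; 20 s simulations at dt = 1e-4 (200k steps) for burst
statistics; 13 s runs (5 s pre-stimulation) for each stimulation cell;
400-point v₂ grids for manifold samplings.  The full test suite runs in
under two minutes on one CPU.

## Known limitations

- Periodic orbits are not continued; limit-cycle extents (e.g. the
  saddle-node of periodics near B ≈ 6.6) are assessed only by direct
  simulation.
- Cusp and zero-Hopf codim-2 points are located only as merge loci of
  traced codim-1 curves, without normal-form coefficients.
- Canard solutions and spike-adding transitions near the folds are out of
  scope.
- The model is a single lumped mass: no spatial extent, network coupling,
  or electrode/volume-conduction modelling of the stimulation field.
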