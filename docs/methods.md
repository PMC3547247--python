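# Methods

This note documents the models implemented in `gcmotion`, the numerical
choices behind them, and what the tests do and do not establish.

## Chemokine fields

Each zone's chemokine profile is an unnormalized peak-height Gaussian
`f(x) = c·exp(-(x-μ)²/2w²)` of the cell displacement `x` along the
DZ–LZ axis, with the CXCL12 field centred at `-k` and the CXCL13 field at
`+k` (`k` = half-separation of the zone centroids, μm). `c` is the peak
concentration and `w` the width. The fields are static: chemokine
production, diffusion and absorption are assumed to equilibrate on time
scales shorter than the migration dynamics of interest.

The peak-height convention (rather than a normalized density, where the
peak would be `c/w√2π`) is a deliberate choice: with it, and with the
standard parameter sets shipped in `scenarios.py`, the toy model's upper
oscillation threshold lands at `k ≈ 39.5` and the three oscillatory
`(k, π1)` reference points all fall inside the computed oscillation
windows. Under the normalized convention the windows shift to `k ≈ 30–33`
and none of the reference points verify. The convention is isolated in
`fields.GaussianField1D` and can be swapped without touching any other
module.

## Receptor regulation

The mass-action trafficking scheme (module `models`, `mass_action_rhs`)
tracks unbound surface receptor `U`, ligand-bound receptor `B`, and
internalized receptor `I`:

    dU/dt = π − k⁺LU + k⁻B + βI − τU
    dB/dt = k⁺LU − k⁻B − μB
    dI/dt = μB − βI − δI

With ligand binding fast relative to trafficking, `B` equilibrates at
`B = κ f U` with `κ = k⁺/(k⁻+μ)`, and — neglecting the recycling
contribution of the internalized pool (valid when synthesis dominates,
π ≫ μB) — the surface receptor `r = U + B` obeys the single saturable
equation used everywhere else in the package:

    dr/dt = π − r·τκf/(1+κf) − δr

Here `κ` is a rescaled equilibrium association constant and `δ+τ` the
removal rate of bound receptor. The tests verify this reduction
numerically: in the fast-binding regime (`k⁺=100, k⁻=100, μ=10`) the
mass-action surface receptor tracks the reduced equation to within 5%
after the binding transient.

The toy model replaces the saturable loss with a linear one
(`dr/dt = π − rf − δr`), which keeps every analysis step closed-form:
the steady state is `r_ss = π/(δ+f)`, decreasing in local chemokine —
receptors are depleted exactly where their ligand is abundant, which is
the feedback that drives zone cycling.

## Chemotaxis

Velocity follows a damped, receptor-weighted drive. In the toy model the
drive is the bare receptor-weighted gradient `r1 f1′ + r2 f2′`. In the
phenomenological model it saturates in ligand:

    dv/dt = χ Σ_i S_i − γv,    S_i = ζ r_i f_i′(x) / (1 + ε_i f_i(x))²

`S_i` is the receptor density times the spatial gradient of the saturable
ligand signal `f/(1+εf)`; `ε` is kept distinct from the regulatory `κ` so
signal transduction and receptor trafficking can couple differently to
occupancy. Two design decisions here were genuinely open:

- **Form of S.** An alternative reading, `S_i ∝ r_i ε_i f_i′/(1+ε_i f_i)²`
  (the receptor-occupancy gradient), was rejected empirically: with the
  standard parameter sets it mislabels half of the six reference `(k, π1)`
  points (e.g. it makes the `(50, 0.15)` point a stable fixed point when
  it should oscillate), while the adopted form reproduces all six and puts
  the full model's upper threshold at `k ≈ 51.9`.
- **Placement of ζ.** `ζ` multiplies the signal (equivalently, rescales
  `χ`). Every shipped scenario has `ζ = 1`, so no reference behavior can
  distinguish placements; the choice is recorded here rather than tested.

## Equilibria, stability, and continuation

At a fixed point, `v = 0` and the receptors sit at their local steady
states, so equilibria reduce to roots of the scalar function
`F(x) = Σ_i S_i(r_i^ss(x), x)`. `find_equilibrium` polishes such a root
with Newton iteration on the full state (residual < 1e-10); stability
comes from the Jacobian eigenvalues (analytic for the toy model,
state-scaled central differences with step `1e-6·(1+|y|)` otherwise, the
two agreeing to 1e-5).

`continue_equilibrium` is natural-parameter continuation: sweep the
parameter (default step 0.25 in `k`), warm-start each root from the last,
detect Hopf points by a sign change of the largest real part over the
complex eigenvalue pairs (bisected to `param_tol = 1e-3`), and detect a
fold as the disappearance of the followed branch (also bisected).

`oscillatory_window` instead traces the *connected equilibrium curve*
through folds with pseudo-arclength continuation of `F(x; k) = 0` — a
secant predictor in `(k, x)` and a 1D Newton corrector along the chord
normal. This matters because the oscillation window's upper boundary does
not sit on the single-valued part of the branch: the connected curve is
S-shaped, and the point where a stable equilibrium reappears lies past two
folds. On the traced curve the window is read off the stability
transitions: the onset H1 is the first stable→unstable flip (a
supercritical Hopf), and the offset H2 is the last unstable→stable flip —
in these models a subcritical-Hopf/fold pair so close together that at
`param_tol` resolution they coincide (the complex pair of the newborn
stable branch grazes zero, |Re λ| ~ 1e-4). The reported H2 is the
parameter where the stable equilibrium is (re)born. For the standard toy
parameters this gives H1 = 38.84, H2 = 39.54; for the phenomenological
model at π1 = 0.15, H1 = 47.76, H2 = 51.89.

Sub/supercritical character is established empirically (simulating near
the Hopf and watching amplitude growth), not via normal-form
(first-Lyapunov-coefficient) computation — the tests only need the
window's location and the attraction/repulsion of the equilibrium.

Two-parameter boundaries (`trace_hopf_boundary`) run the one-parameter
detection per value of the second parameter and report the instability
interval of the followed branch — the dotted segment of a one-parameter
diagram. Note a subtlety found during development: for some `π1` the
stable equilibrium is reborn (hysteretically) at a `k` *below* the H1 of
the followed branch, so a stable fixed point and the limit cycle coexist;
classification of a parameter point as oscillatory/steady-state by "does
any stable equilibrium exist" (`classify_parameter_point`) and by
"does the followed branch oscillate" can legitimately differ there.

## Trajectory phenotyping

`classify_trajectory` discards the first 25% of the trace as transient and
applies, in order: fixed point (terminal spread < 1 μm); damped
(exponential peak-envelope fit with rate < −1e-4 *and* envelope at least
halved within the window); chaotic (inter-peak interval CV > 0.2 *and*
largest-Lyapunov estimate > 1e-3 per unit time); intrazonal (all extrema
on one side of the midline); nested (an interior extremum on the wrong
side of the midline — a loop that fails to cross between the zones —
with a both/one-zone subtype depending on where the small loops sit);
then symmetric vs asymmetric by cycle mean (<10% of amplitude) and
DZ/LZ residence balance (<10%), with the dead band defaulting to `k/4`.
All thresholds are config values (`ClassifySettings`); the reference
behaviors are qualitative, so the defaults are choices, recorded here.

The Lyapunov estimator is two-trajectory Benettin renormalization at
finite separation `d0 = 1e-5` (kept well above integrator noise),
renormalizing every 20 time units and discarding the first 20% of the
growth record. Two caveats are worth stating plainly:

- For the "apparently chaotic" showcase scenario the *infinitesimal*
  exponent is zero within resolution (unrenormalized separations from
  `d0 = 1e-8` stay flat over 12000 time units); what the estimator
  measures at `d0 = 1e-5` is finite-amplitude divergence near the
  trajectory's grazing zone-transitions. That finite-separation estimate
  is robust (λ = 1.04e-3 across 10 perturbation seeds, vs ≤ 2.2e-4 for
  the regular nested scenarios), so the chaotic label is an operational
  "sensitive at observable amplitudes" statement, not a proof of chaos.
- The one-zone showcase scenario is, asymptotically, a *very* weakly
  damped intrazonal oscillation (envelope rate ≈ −1.3e-4 per unit time;
  dozens of cycles per e-fold). On windows comparable to the published
  plots (t ≲ 6000) it classifies as sustained intrazonal; on much longer
  windows the damped branch triggers. The acceptance checks classify over
  t ∈ [0, 6000].

## Integration

Deterministic runs use scipy's adaptive LSODA with rtol 1e-8 / atol 1e-10
(halving tolerances moves endpoints by < 1e-6 relative). The Langevin
model uses fixed-step Euler–Maruyama (default dt 0.01 in 1D, 0.05 in the
IBM) with additive noise `σ√dt·N(0,1)` on velocity components only —
receptors and positions receive no direct noise, and with σ = 0 the
scheme reduces to plain Euler. The field-free velocity process is
Ornstein–Uhlenbeck with stationary variance σ²/2γ, which the tests verify
to within three standard errors.

## 3D individual-based model

The IBM advances N cells per fixed time step: trilinear interpolation of
the two chemokine grids (values and pre-computed central-difference
gradient fields at voxel centroids, one-sided at boundaries), saturable
receptor update (explicit Euler; stable for dt < 1/(δ+τ), orders of
magnitude above the default dt), Langevin velocity update along the 3D
interpolated gradients, reflective walls (position mirrored, normal
velocity negated), and optional linear soft-sphere repulsion
`F = k_rep·overlap` along the centre line (off by default; pair forces are
equal and opposite). Each cell owns a `numpy` generator seeded
`base_seed + cell_id`, so multi-cell runs are reproducible regardless of
update order. Grids are padded two voxels beyond the confinement volume so
interpolation queries never leave the centroid hull.

With σ = 0 and the field varying along one axis, a single cell reproduces
the 1D model up to spatial discretization error; the error is
second-order in the voxel size (halving 5 μm → 2.5 μm cuts the
pointwise error ≈ 5× on the reference oscillation). Two caveats:

- Pointwise trajectory error over many cycles is dominated by accumulated
  phase drift, so it looks large (tens of μm) even when the oscillation
  itself is faithful; comparisons are therefore made over the first
  transition (t ≤ 200) or at the level of qualitative classification.
- Parameter points whose equilibria are only marginally unstable
  (max Re λ ~ +0.005) can be over-damped by the 5 μm discretization and
  settle instead of oscillating; at 2.5 μm they recover the 1D amplitudes.
  A green IBM test at the default spacing establishes agreement for
  robustly oscillatory or robustly stable parameters only.

The IBM deliberately omits cell division, death, activation, and
cell–cell biology beyond the optional soft repulsion; chemokine grids are
static snapshots (no secretion/diffusion dynamics). The confinement
volume, cell radius (5 μm), and repulsion constant are config values with
no reference values to verify against.

## Units

Time is in abstract model units (the parameter sets produce oscillation
periods of hundreds of units, matching "hours" qualitatively); lengths
are in μm; receptor densities and concentrations are in arbitrary units.
No attempt is made to calibrate absolute rates.
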