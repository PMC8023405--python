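# Methods

This note records the model as implemented, the numerical choices, and what
the test phenomenology does and does not establish. SI units throughout;
human-readable units appear only at the config/CLI boundary.

## Rod kinematics and elastic equilibrium

The shoot is a Kirchhoff rod: unshearable, elastically inextensible, circular
cross section of radius `r`, clamped at the base with d3(0) vertical
(opposing gravity) and a fixed horizontal pair d1(0), d2(0). The
configuration is reconstructed from the strain components (u1, u2, u3) by a
rotation-group-preserving integrator: over each grid interval the strain is
frozen at the midpoint average and the exact rigid-motion (SE(3)) exponential
is applied. Consequences: director frames are orthonormal to machine
precision at every node (no drift over long runs), each segment's
displacement is exactly consistent with its arc length (inextensibility),
the scheme is exact for constant strain and second-order accurate otherwise.
The visible normal ν = κ⁻¹ ∂s d3 is flagged undefined where the curvature
κ = (u1² + u2²)^(1/2) falls below 1e-8 m⁻¹ (numerical floor of the straight
state).

Elastic equilibrium solves the fixed point

1. given the shape, integrate the contact couple from the tip,
   m(s) = −∫ₛ^ℓ q(ℓ−σ) ĝ × d3(σ) dσ (composite trapezoid from the tip, so
   m(ℓ) = 0 exactly);
2. u_j = u*_j + m_j/K_j in the local basis (per-node stiffnesses allow
   lignified rods);
3. reconstruct the rod,

with under-relaxation 0.5, warm start from the previous time step, and
convergence declared when the tip moves less than `tol_tip` = 1e-9 m between
iterations (cap 200). The map's contraction degrades as ℓ → ℓc; a
non-converged solve is reported as an equilibrium failure and interpreted as
proximity to a fold (mechanical collapse), never silently accepted. During
threshold bisections an equilibrium failure under a *growing* perturbation
is counted as evidence for the unstable side of the bracket, which is the
only way the probe can fail there.

Stiffnesses: K1 = K2 = EI with I = πr⁴/4; K3 = μJ with J = 2I. The default
shear modulus is the standard isotropic μ = E/(2(1+ν)); a config switch
`shear_modulus_convention: as_printed` selects the alternative μ = 2E(1+ν)
found in parts of this literature. The choice is inert in the planar and
near-vertical regimes exercised here (torsion never couples at linear
order), but it is surfaced rather than hidden.

Self-buckling normalization: α₀ = qℓc³/(EI) of a clamped-free vertical
prismatic column is computed by a sparse finite-difference generalized
eigenvalue solve of −θ'' = λ(1−σ)θ, θ(0) = 0, θ'(1) = 0 (ghost-node Neumann,
second order, Richardson-extrapolated; n = 1600 by default), and
independently from the classical closed form α₀ = (9/4)j², j the first
positive zero of J₋₁⁄₃. The two routes agree to better than 1e-6 relative;
α₀ ≈ 7.8373. With the baseline parameters ℓc ≈ 7.93 cm.

## Growth and lignification

Material cross sections are labeled by initial arc length S ∈ [0, ℓ0]; the
map s(S, t) and stretch γ = ∂s/∂S evolve under a piecewise-constant REGR
(1/τ_g inside the apical zone of length ℓ_g, zero below). For ℓ0 ≤ ℓ_g the
closed form is used: uniform exponential elongation until ℓ = ℓ_g at
t₁ = τ_g ln(ℓ_g/ℓ0), then linear elongation at ℓ_g/τ_g with exit times
t\*(S) = t₁ + τ_g ln(ℓ0/(ℓ0−S)) and frozen positions s = ℓ_g ln(ℓ0/(ℓ0−S))
thereafter. The apex never exits. For ℓ0 > ℓ_g (not the regime of interest)
an RK4 fallback integrates the same system, with exit times located by
linear interpolation within a step. The Young modulus follows
E = E1 − (E1−E0) e^(−max(0, t−t*)/τ_ℓ) per material node.

The Lagrangian discretization keeps all fields on the fixed material grid;
the "current grid" is its image under s(S, t), so no resampling or
interpolation ever occurs and material points cannot cross. Accumulated
spontaneous strain is treated as a material property; no passive curvature
dilution is applied as fibers stretch (the evolution laws prescribe rates,
not dilution). A config switch `curvature_dilution` enables the alternative
(u* rescaled by the step's stretch increment) for sensitivity studies;
default off.

## Stimulus histories and delay kernels

Gravitropism and proprioception act through an exponential memory kernel
evaluated a reaction delay in the past:
I(t) = (1/τ_m) ∫^{t−τ_r} e^{−(t−τ_r−σ)/τ_m} x(σ) dσ. Histories of the
statolith components (h1, h2) and the visible strains (u1, u2) are kept in
per-node ring buffers on the simulation time grid. The integral is evaluated
by trapezoidal quadrature truncated at 12 memory times, plus an analytic
tail that assigns the remaining kernel mass to the oldest usable sample.
With the production step (memory time / 40) the quadrature error of the
kernel mass is ≈ 5e-5 and the truncation ≈ 6e-6 — comfortably inside the
1e-4 budget that the kernel-mass test enforces. A shorter truncation (10
memory times) or a coarser history step (memory/20) would individually
breach that budget, which is why both are set as they are. Before t = 0 the
buffers hold the initial state's values (or an explicitly installed
pre-history), making the primed upright state an exact equilibrium.

Reaction delays are honored discretely: the time step is chosen to divide
the smallest active delay; a delay that is not commensurate with the grid is
quantized to the nearest sample (at most half a step, documented rather than
hidden — all baseline delays are exact multiples).

The statolith normal h evolves corotationally: the component law
ḣ_j = (1/τ_a)[h×(h×g)]·d_j is integrated on the frame of the current step
(frozen within the step, RK4, renormalized; the continuous law preserves
|h| = 1 exactly). Components are not re-projected when frames rotate between
steps — the literal component-wise reading of the law. At t = 0 statoliths
start sedimented (h = −g on the initial frames).

## Time stepping

The spontaneous strains obey u̇* = F(t, history): the rate does not depend
on the instantaneous u*, and every reaction delay is at least one step, so
F is known at both endpoints of a step from recorded history alone. The
update is therefore trapezoidal (second order) at no extra cost. This
matters quantitatively: a forward-Euler update carries an O(Δt) phase error
around the loop that shifts Hopf thresholds by a few percent, breaking the
agreement between the two threshold routes; with the trapezoidal update the
discretization bias is O((ωΔt)²) ≈ 5e-4 relative.

Default steps: reduced model Δt = min(active memory times, τ_e)/40 (18 s at
baseline); full simulator Δt = min(τ_a, memories, τ_e)/20 (6 s at baseline,
where τ_a = 2 min is the fastest scale). Per step the full simulator
advances, in order: growth map (closed form), stiffness field
(lignification), statoliths, spontaneous strains, elastic equilibrium,
histories and outputs.

## Reduced model and stability probes

The reduced model freezes ℓ ≤ ℓ_g (so ε̇ = 1/τ_g everywhere), E = E0, and
takes h = −g instantaneously. Scenarios zero parameters consistently:
graviceptive (α = η = 0), microgravity (α = β = 0, q = 0),
proprio-graviceptive (α = 0), with_endogenous (all active).

**Microgravity linearization.** With q = 0 the dynamics is pointwise in arc
length and linear: λ(1 + λτ̄_m) = −(η/τ_g) e^{−λτ̄_r}. On the imaginary
axis the phase condition arctan(1/(ωτ̄_m)) = ωτ̄_r fixes the frequency
(ω ≈ 1.195e-3 rad/s at the baseline times, period ≈ 87.6 min) and the
magnitude condition gives τ_g^crit = η/(ω√(1+(ωτ̄_m)²)) ≈ 3.52 h. The
threshold scales linearly in η and is length-independent. A closed-form
linearization of the *elastic* scenarios is not attempted; stability there
is probed in the time domain, and the microgravity case is where the two
routes (linear relation vs nonlinear simulation) are cross-validated —
they agree to ≈ 0.1%.

**Time-domain probe.** A trial configuration is kicked with a uniform
intrinsic-curvature perturbation of relative amplitude 1e-4 (curvature
1e-4/ℓ) whose history is primed as a rotating wave: the t = 0 fields with
their bending plane back-rotated at the estimated natural frequency. This
seeds a chirality reproducibly and suppresses the counter-rotating
(pendular) component, so the tip deflection magnitude is a clean
exponential. The leading rate is the slope of log |tip_xy| over the trailing
40% of a 30-period horizon; the frequency comes from the unwrapped phase.
Bisection on the rate's sign locates ℓ\* to 0.01 cm (or τ_g^crit to 1%).
Brackets are kept near the threshold so the fit window is not contaminated
by saturation onto the nonlinear limit cycle; a no-sign-change bracket is an
explicit error with the endpoint rates attached.

At baseline (τ_g = 20 h): proprio-graviceptive ℓ\* ≈ 6.56 cm
(ℓ\*/ℓc ≈ 0.83); graviceptive ℓ\* ≈ 7.4 cm — proprioception lowers the
threshold at these delay/memory values. With q = 0 the graviceptive
scenario has no threshold at all (ℓc → ∞), reported as a bracket error
stating the shoot is always stable.

## Trajectory analysis

Tip tracks are analyzed as the complex signal x + iy (rotation sign =
frequency sign). Tones: Hann-windowed periodogram, up to two peaks with
parabolic interpolation on log power (the vertex also descallops the
amplitude, accurate to a few percent; good enough for the 10%-of-dominant
significance decisions). Peaks below 20x the median power, or below 1% of
the dominant tone (the leakage floor), are not tones; pure noise yields an
empty list. Ellipticity is the singular-value ratio of the centered planar
samples over the trailing half of the track (robust to slow drift).
Labels: two significant tones whose frequency magnitudes differ by more
than 20% make the pattern trochoid-like (epi- if co-rotating, hypo- if
counter-rotating); otherwise ellipticity < 0.2 is pendular, > 0.8 circular,
elliptic between. The 0.2/0.8 cut-offs are this package's
operationalization of qualitative labels and are exposed in `Thresholds`.

The synthetic two-tone generator (x = A cos ω₁t + B cos(±ω₂t), and sines
for y, plus optional Gaussian noise) is the classifier's ground truth for
round-trip tests. It emulates the phenomenology of simulated and measured
tracks — two circular motions superposed — but not their slow amplitude
drift, frequency jitter, or measurement artifacts; classifier tests passing
on it demonstrate correct tone/chirality logic, not robustness to raw
experimental tracking data.

## Baseline parameters

| parameter | value | meaning |
|---|---|---|
| α | 0–1 (free) | endogenous sensitivity |
| β | 0.8 | gravitropic sensitivity |
| η | 20 | proprioceptive sensitivity |
| τ_a | 2 min | statolith avalanche time |
| τ_e | 20 min | endogenous period |
| τ_m, τ_r, τ̄_m, τ̄_r | 12 min | tropic memory and reaction times |
| τ_g | 20–40 h (free) | growth time |
| τ_ℓ | 6 d | lignification time |
| r | 0.5 mm | cross-section radius |
| ℓ_g | 4–7 cm | growth-zone length |
| ν | 0.5 | Poisson ratio |
| ρ | 10³ kg/m³ | tissue density |
| E0, E1/E0 | 10 MPa, 200 | initial modulus, stiffening ratio |

The `baseline` preset carries these values with ℓ_g defaulting to 5 cm. The
shipped transition experiment (`examples/transition.yaml`) uses τ_g = 20 h,
α = 0.2, ℓ0 = 2 cm and ℓ_g = 7 cm: the upper end of the growth-zone range
keeps the shoot unlignified while it crosses ℓ\*, so the
endogenous→exogenous hand-over happens cleanly within 36 h of simulated
growth. With a shorter growth zone (5 cm) lignification stiffens the base
faster than the shoot lengthens and the exogenous tone, while present and
growing, does not overtake the endogenous one in that window — the
transition is a qualitative reproduction whose exact timing depends on
these choices.

## Problem sizes

Defaults used by the test suite and analysis entry points, chosen as the
coarsest sizes whose discretization bias is far below the tolerances they
are tested against: 100 rod nodes for reduced-model stability work (the
leading rate moves by only a few percent between 50 and 100 nodes, and the
bisection answer by far less than the 0.01 cm bracket), 80 nodes for the
growing-shoot transition run, 30-period horizons for rate fits, 40-period
horizons for limit-cycle characterization. The self-buckling eigenvalue
uses 1600 intervals plus Richardson extrapolation.

## Known limitations

- Torsional growth is absent (u*₃ ≡ 0) and tropism cross-talk is not
  modeled; phototropism and hormone transport are out of scope.
- The exponential memory kernel is a parsimony choice, not a fitted
  response function.
- Near and beyond the self-buckling length the under-relaxed fixed point
  stops converging; the solver reports this as a physical signal rather
  than switching to continuation/arc-length methods, so post-fold states
  are not computable.
- The endogenous oscillator's phase and chirality at t = 0, and the
  perturbation that seeds the exogenous cycle's rotation direction, are
  conventions (exposed in config), not predictions.
- Limit-cycle tests assert persistence and shape of the orbit near onset,
  not full convergence to the asymptotic cycle, whose approach rate
  vanishes at threshold.
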