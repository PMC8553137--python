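# Methods

## Model

The cone outer segment is modeled as a tapered (frustum) stack of
`n_discs = 400` discs, base radius `R_b = 0.6 μm`, tip radius `R_t = 0.4 μm`,
length `H = 13.4 μm`.  The continuum approximation gives a total disc surface
area S_disc = 2·n·π·(R_b² + R_b·R_t + R_t²)/3 ≈ 637 μm² (two faces per disc,
linearly tapering radius) and a cytosolic volume
V_cyto = ν/(1+ν)·π·H·(R_b² + R_b·R_t + R_t²)/3 ≈ 4.2 μm³, the interdiscal
fraction of the frustum volume.  The volume-to-surface factor
η = ½·ν·ε₀ = 5.46 nm converts volumic concentrations in the thin
interdiscal space to surface densities on a bounding disc face and back;
every such conversion routes through the single constant
1 μM = 602.214 molecules·μm⁻³.

**Activation cascade (disc surface).**  A uniform flash of Φ
photoisomerizations seeds R\*(0) = Φ/S_disc.  With E_tot = 2·[PDE]_σ the
activated-subunit capacity,

    dR*/dt = −k_R·R*
    dG*/dt = ν_RG·R*·(G_σ − G* − E*)/G_σ − k_GE·(E_tot − E*)·G*
    dE*/dt = k_GE·(E_tot − E*)·G* − k_E·E*

The state variable E\* counts activated catalytic subunits (two per
holoenzyme, activated independently); one G\* is consumed per activated
subunit, which makes the transducin depletion term (G − G\* − 2[PDE\*])
exact and renders the holoenzyme and subunit bookkeeping algebraically
identical in the association term.  Free G\* has no independent decay: it
decays with the complex at k_E.  The per-R\* normalization of ν_RG by G_σ
keeps ν_RG in s⁻¹ as "G\* formation rate per R\*".

**Second messengers (well-stirred).**

    d[cG]/dt  = α([Ca²⁺]) − (β_dark + β_light(E*))·[cG]
    d[Ca²⁺]/dt = (1/B_Ca)·( f_Ca·J_cG([cG])·c₂ − J_ex([Ca²⁺])·c₁ )

with α(Ca) the cyclase rate falling sigmoidally from α_max to α_min
(Hill coefficient m_cyc, half-saturation K_cyc), J_cG a Hill function of
[cG] saturating at J_cG^max, J_ex Michaelis–Menten in Ca²⁺, and
c_z = 10⁹/(z·F·V_cyto) converting pA to μM/s for ions of charge z (2 for
the Ca²⁺ fraction of the CNG current, 1 for the exchanger's net charge per
Ca²⁺).  The light-induced hydrolysis rate is
β_light = k\*_σ;hyd·(E\*/2)/η with k\*_σ;hyd = (k_cat/K_m)/(N_Av·10⁻²¹·B_cG):
cGMP buffering enters only through this per-dimer efficiency, not as a
divisor of synthesis or dark hydrolysis — the pattern that leaves the dark
current independent of B_cG while making the early current drop scale
inversely with it.  Coupling is one-way: the cascade forces the messengers,
with no retroaction.

**Well-stirred reduction.**  Uniform flashes make all fields spatially
uniform up to boundary layers, so membrane and cytosolic diffusion
coefficients (carried in the parameter set) enter no equation, and currents
are treated as whole-cell totals in pA, which removes the channel-bearing
lateral area and the sliver angle ω₀ from the steady state.  The global
sensitivity results themselves justify this: geometry and diffusion rows
are numerically dead for every functional (total indices below 0.02).  The
reduction's known cost is response amplitude: at the best-fit parameters
the 940-photoisomerization flash — half-maximal in the recording the
parameters were fitted to — removes 83% of the dark current rather than
half, i.e. the reduction compresses the intensity scale (its own
half-maximal point is near 380 photoisomerizations).  Shape quantities
(time-to-peak ≈ 42 ms, monotone intensity family, recovery within 1% by
0.5 s) are preserved, and variance-based rankings, which compare draws
under the same reduction, are insensitive to this bias.

## Dark steady state and the a_min transform

In darkness, synthesis balances hydrolysis and Ca²⁺ influx balances
extrusion.  For fixed Ca the first balance gives [cG] in closed form, and
the current-balance residual is strictly decreasing in Ca, so the solver is
an outer bracketed root find on Ca (relative tolerance 1e-10) with the
closed-form inner step.  The batch variant used by Monte Carlo pipelines
performs the same computation as a vectorized bisection (150 iterations on
[1e-9, 1e10] μM — the wide upper bracket covers draws whose a_min
approaches 1, where the dark Ca²⁺ diverges) and is validated row-for-row
against the scalar solver.

A dark state exists iff 1 + (α_min/(β_dark·K_cG))^m_cG stays below
(1 − 2·J_ex^sat/(J_cG^max·f_Ca))⁻¹ (and the current ratio itself is below
one).  The admissible α_min interval is [0, ξ], ξ = min(α_max, χ) with χ
the root of the equality; the package stores a_min = α_min/ξ, uniform on
[0, 1] for sensitivity sampling, so independent draws never lose the dark
state.  Parameter sets may be specified with either coordinate (or with
the α_max/α_min ratio, as fitting constraints are expressed); exactly one
is authoritative.

## Functionals

Nine scalars per response: I_act and E_act are least-squares coefficients A
of ½·A·t² fits to the current drop and total E\* on [0, 10 ms] (closed form
A = Σy·t²/(½Σt⁴)); I_drop is the peak drop relative to J_dark (grid argmax
with 3-point parabolic refinement, which also defines T_peak); E_peak is
the maximum of total E\*; E_rec is the log-linear decay rate of the current
drop on [0.135, 0.5] s (undefined, and excluded from Monte Carlo
statistics, when fewer than three positive samples remain); J_dark is the
dark current; J_over is the largest transient excess of the current above
J_dark, relative to J_dark (the overshoot, when the recovering current
exceeds its dark level); L2 is the rms misfit to a target trace at the
target's sample times, over the target's support.

## Sensitivity analysis

Local sensitivity is the elasticity Q_i = (∂y/∂x_i)/(y/x_i) by forward
difference with a relative 5% step, computed with deterministic solver
settings and a shared base evaluation.

Global analysis draws paired N×d matrices A, B independently and uniformly
over the uncertainty ranges; a target y (single column or pair of columns)
gets the hybrid AB_y.  Estimators: S_y = mean(f(B)·(f(AB_y) − f(A)))/V̂
(first-order, or closed for pairs) and S_y^tot = mean((f(A) − f(AB_y))²)/(2V̂),
with V̂ the pooled sample variance of f(A) and f(B).  Estimates are reported
unclamped — small negatives are an expected Monte Carlo artifact.  Failed
or undefined evaluations are excluded pairwise with their design rows and
counted.  Confidence intervals: 95% normal intervals for the numerator and
denominator means combine, by the order-preserving property of division,
into a (conservative) 90% interval for the index; an interval whose
denominator straddles zero is flagged unbounded.  A percentile bootstrap
(row resampling) is available as a cross-check.  Plain Monte Carlo (not
quasi-random) sampling is used throughout.

Evaluation paths: the dark-current functional needs no time integration
(vectorized dark-state solve; N = 100,000 per statistic runs in seconds);
peak E\* uses a vectorized fixed-step RK4 on the cascade subsystem
(dt = 0.5 ms, horizon 1.5 s — non-stiff over the sampled ranges, horizon
validated against 3 s, and the path validated against the adaptive
integrator); the full nine-functional screen integrates the coupled
response per row (LSODA, rtol 1e-6) and is meant for desk-scale N.

## MCMC fitting

The stationary density combines a hard constraint set K — interval bounds
on parameters *and* on the derived dark-state quantities [cG]_dark,
[Ca²⁺]_dark, J_dark — a soft penalty 2^(−γ·dist) per parameter, where dist
is the distance outside the expected interval normalized by the interval
width (making one γ meaningful across heterogeneous units), and the rms
error to the power −β.  Defaults γ = 5, β = 2, componentwise Gaussian
proposals with standard deviation 2% of each soft-interval width
(overridable per parameter), geometry and the Ca²⁺ diffusion coefficient
held fixed.  The chain is a biased exploration, not a posterior: no
stationarity is required and the deliverable is the lowest-error sample.
Note that the packaged best-fit point itself lies outside two of the
expected intervals (transducin and PDE surface densities), so it carries a
nonzero soft penalty — the penalties guide rather than confine.

The packaged recovery experiment fits a zero-noise synthetic target
generated at the best-fit parameters, freeing the cascade kinetics
(k_R, k_E, ν_RG) from a 20–25% off-truth start with 0.5%-width proposals;
800 steps drive the rms below 0.01 pA and recover ν_RG within a few
percent.  The dark-current parameters are held at truth in this experiment
because the hard J_dark window (1.25 pA wide) makes interval-width-scaled
proposals in β_dark almost always infeasible; fitting those parameters
requires proposal scales tuned well below the default, which the
configuration exposes.

## Synthetic recordings

`generate_experiment` simulates the flash family at a known parameter
vector and adds iid Gaussian noise on the current (default sd 0.3 pA,
chosen as a visually plausible recording jitter; configurable).  Defaults:
intensities {40, 235, 940, 6000} photoisomerizations, 0.5 s sweeps at 1 ms
sampling — the recordings' true time base is not published.  The generator
emulates neither photon/electrode noise physics nor cell-to-cell
variability, and its traces inherit the reduction's amplitude bias above;
recovery tests against it therefore demonstrate identifiability of the
kinetics under the model's own dynamics, not fidelity of the reduction to
real recordings.

## Numerical choices and limitations

- Integrators: LSODA with rtol 1e-8/atol 1e-12 (cascade) and 1e-10
  (response) on fixed output grids, dt = 0.1 ms for functional fitting;
  rtol 1e-6 and dt = 1 ms inside MCMC, where speed matters and the rms is
  noise-dominated anyway.  All functionals are stable to <0.5% under grid
  halving at the reference parameters.
- Problem sizes: acceptance reruns use N = 100,000 per Sobol statistic for
  the dark current and N = 50,000 for the cascade pair index; the
  nine-functional screen and chain lengths in the test suite run at smoke
  scale.
- K_cyc is stored in nM as conventionally tabulated and converted at use;
  all other quantities are μM/μm/s/pA internally.
- The tabulated η = 0.01 and νε₀ = 11 nm rows of the source parameter table
  are inconsistent with η = ½νε₀ = 5.46 nm from the same table's ν and ε₀;
  the formula value is used, since it reproduces the tabulated dark surface
  hydrolysis rate 4.1e-4 μm³/s.
- β_dark is sampled independently of ν and ε₀ in the sensitivity ranges
  (not co-varied through η), matching how the ranges are defined.
- No light adaptation or steady backgrounds: flashes from darkness only.
  No spatial model: single-photon responses and localized stimuli, where
  spatial asynchrony matters, are out of scope.
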