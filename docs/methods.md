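# Methods

This note records the model, the reductions, the numerical choices and the
limitations of `epitip`, at the level of detail a user needs to judge what
a passing test suite does and does not establish.

## Microscopic model

The state is an integer matrix `X_ij` with 12 species rows — methylated
(`M`), acetylated (`A`) and unmodified (`S`) H3K27 sites, plus free and
complexed forms of the four enzymes (EZH2, UTX, HAT, SIRT) and the
sequestered-SIRT pool `C_S_D` — and one column per chromatin sub-region
(`N_C` columns; enzyme pools are global and stored in column 1 by
convention).  Each region carries three reaction channels per enzyme
(bind, unbind, catalyse), hence `12·N_C` channels, plus two global
sequestration channels: `12·N_C + 2` in total.

Binding propensities carry the landscape feedback

    k1_i = k1 (α1 + Σ_j w_ij m_j)      EZH2  ← methylation
    k4_i = k4 (α4 + Σ_j w_ij a_j)      UTX   ← acetylation
    k7_i = k7 (α7 + Σ_j w_ij a_j)      HAT   ← acetylation
    k10_i = k10 (α10 + Σ_j w_ij m_j)   SIRT  ← methylation

with marks expressed as rescaled concentrations (`m_j = M_j/Ω_27`), so that
the mean-field limit of the jump process matches the coarse-grained closed
forms unit-for-unit.  Two system sizes set the multiscale structure:
substrate counts scale with `Ω_27`, enzyme counts with `Ω_E`, and
`ε = Ω_E/Ω_27 < 1` separates fast (enzyme) from slow (mark) dynamics.  All
times are in the rescaled convention (the rescaling constant is absorbed
into the rate constants); no wall-clock conversions are performed.

Conservation laws hold exactly along every simulated path: per-region site
totals `M + A + S + C_E + C_U + C_H + C_S = S_0`, and one total per enzyme
pool (for SIRT including `C_S_D`).

### Sequestration and the competition level B

Competition for the deacetylase (e.g. sirtuin capture at DNA double-strand
breaks) appears in the reduced layers as an additive term in the
deacetylation Michaelis–Menten denominator.  The exact simulator realises
it as a fast reversible capture/release pair with rates
`b_on·D_dsb = λB` and `b_off = λ(k11+k12)`, `λ` a fastness multiplier
(default 10× the largest catalytic constant).  Under quasi-equilibrium the
effective additive term is `(k11+k12)·b_on·D_dsb/b_off = B` exactly, so the
identification `B = b_on·D_dsb` is not an approximation here but a choice
of `b_off` units; users supplying explicit `(b_on, b_off, D_dsb)` get the
general mapping `B_eff = (k11+k12)·b_on·D_dsb/b_off`.

### Exact stochastic simulation

Direct-method SSA (single propensity sum) with incrementally maintained
contact-weighted mark sums; the inner loop is numba-jitted.  Trajectories
are resampled on a uniform time grid (the state is piecewise constant, so
grid sampling is distributionally exact at the grid times).  Typical
throughput is ~10⁶ events/s, which makes 10³-replica ensembles at
`Ω_27 = 10³` routine.

## Spectral reduction

For an irreducible non-negative contact matrix the Perron eigenpair of
`Wᵀ` is computed by power iteration (deterministic positive start,
tolerance 1e-12, at most 10⁵ iterations) and verified against the residual
bound `‖Wᵀu − λu‖/λ < 1e-10`.  `u` is normalised to unit Euclidean norm;
`Φ̂ = α_w Φ₁*/|u|₁` is normalisation-dependent (only combinations such as
`Φ̂·X` are invariant), and under this choice the uniform all-to-all matrix
with self-contact gives exactly `Φ̂ = w√N_C`.  Strong connectivity of the
non-zero-entry graph is required; the strictly tridiagonal ablated
first-neighbors pattern is refused outright (its reducible perturbation
theory does not guarantee a strictly positive dominant eigenvector), which
is precisely what makes it the long-range-ablation control: the
microscopic layer still accepts it.

The closure matrices `K` (in `Φ₁*`) and vector `v` (in `Γ₁*`) default to
`W` and `u` respectively — the self-consistent choice that reproduces the
homogeneous reduction — and are overridable arguments of
`spectral_quantities`.

## Coarse-grained model

The slow observables are collective methylation `X₁ = Σ u_j m_j` and
acetylation `X₂ = Σ u_j a_j`, with `X₃ = |u|₁ s_sites − X₁ − X₂` fixed by
site conservation.  The drift components are differences of two saturating
fluxes whose binding intensities carry `Φ̂`, and the deacetylation
denominator carries `|u|₁B/√N_C`; the noise intensities are sums of the
jump intensities of the binding/unbinding/catalysis legs.  The fast
enzyme observables entering both are evaluated at the root of the fast
drift (the evaluation point of the averaged operator in the large-`Ω_E`
limit); each pool's fast drift is affine in its complex observable, so the
root is closed-form and its residual is checked against 1e-12.  A switch
(`noise_enzymes="total_pools"`) substitutes the cruder total-pool levels in
the noise for comparison.

Two deliberate consequences of finite `ε`:

- the coarse-grained conservation law ignores substrate bound in enzyme
  complexes, an `O(ε)` effect; micro-vs-CG fixed-point agreement is exact
  (< 1e-6 relative) only in the `ε → 0` limit and ~1% at the default
  `ε = 0.05`;
- the system is **not** invariant under the region count even at fixed
  per-region densities, because shared enzyme pools change the saturation
  level of the Michaelis–Menten denominators.  The bistable window in `B`
  is ≈ (0.7, 27.8) at 10 regions and ≈ (5.0, 31.3) at 50.  Comparisons
  between layers are therefore always performed at matched `N_C`.

The Euler–Maruyama integrator uses noise amplitude `Ω_27^{-1/2}` and
reflects at the physical simplex boundary `{X₁, X₂ ≥ 0, X₁+X₂ ≤ |u|₁s}` —
a regularisation keeping counts physical that the continuum description
itself does not provide.  Seeds are mandatory for every stochastic entry
point.

## Reference kinetic regime (`default_bistable`)

No community-standard rate set exists for this reaction scheme at this
granularity, so the package ships a repository-calibrated regime chosen
once with the package's own calibration tools: unit rate constants
throughout, basal activities `α = 0.05`, one substrate unit per region,
per-region enzyme densities 0.3 (EZH2, UTX, HAT) and 0.9 (SIRT), total row
contact weight 1, `Ω_27 = 1000`, `Ω_E = 50`, and default `B = 10`.  The
asymmetric SIRT pool makes the system monostable-hypoacetylated at
`B = 0`, opens a bistable window at a lower fold, and destroys the
hypoacetylated landscape again at an upper fold — the qualitative
phenomenology the analysis targets (two saddle-node tipping points in the
competition level, plus a fold in the effective acetyl-CoA level
`â_c ≈ 0.15` at `B = 10`).

## Bifurcation analysis

Fixed points by a uniform grid of damped-Newton starts, deduplicated
within 1e-6 of the domain scale (ties kept by smaller residual), classified
by central-difference Jacobians (step 1e-6·scale; eigenvalue real parts
within 1e-6 of zero are flagged non-hyperbolic rather than classified).
Continuation is natural-parameter stepping seeded by the previous grid
point plus a global rescan; each root-count change is refined by bisection
to a requested bracket.  This is deliberately simple — for planar systems
with at most three equilibria it is robust and auditable, and pseudo-
arclength machinery would add nothing.

## Quasi-potential and sensitivity

The stationary WKB exponent solves `⟨H⟩(X, ∇S₀) = 0` with
`⟨H⟩ = Σ_i(−⟨D_i⟩P_i + ½⟨N_i⟩P_i²)`; characteristics follow
`dX/ds = −∂⟨H⟩/∂P`, `dP/ds = +∂⟨H⟩/∂X`, under which the `P = 0` flow is
the forward deterministic dynamics (the built-in self-consistency check).
The barrier `ΔS±` is the line integral `|∫P·dX|` along the instanton from
each node to the saddle.

One-dimensional models use the analytic fluctuational branch `P = 2D/N`.
In two dimensions the default solver minimises the discrete geometric
(Freidlin–Wentzell) action `Σ_seg(‖b‖_a‖ΔX‖_a − ⟨b, ΔX⟩_a)` with the
inverse-noise metric over polygonal paths with fixed endpoints (L-BFGS-B
with an analytic gradient; arclength reparametrisation between rounds;
150 points by default).  Momenta recovered segmentwise satisfy `⟨H⟩ = 0`
identically, endpoint momenta vanish exactly, and the minimised value
equals the discrete line integral.  A classical shooting solver (launch
from the unstable subspace of the linearised characteristic flow at
(node, 0), bisection on the launch angle) is retained as
`method="shooting"` for cross-checks, but is ill-conditioned whenever the
traversal time is long — the heteroclinic launch angle then falls below
double-precision resolution — which is the regime of the chromatin model;
the path-space route has no such limitation.

Parameter sensitivity `∇_Θ ΔS±` is computed two ways and both are
reported: central finite differences re-solving equilibria and instantons
at perturbed parameters (warm-started from the base solution so that
discretisation errors cancel; step `h·(1+|θ|)` with `h = 3e-3`, a value set
by a step-size study balancing truncation against the path-solver's
termination jitter — at much smaller steps the difference quotient is
jitter-dominated), and the frozen-path (envelope-theorem) derivative of the
geometric action, equivalent to `−∫(∂⟨H⟩/∂θ)ds` along the unperturbed
instanton.  The two agree to about three significant digits on the
reference model; the structural summary `Φ̂` is itself a differentiable
input (its override scales the noise-closure scalar proportionally).

Near a fold the vanishing branch's barrier follows the standard
saddle-node asymptotics `ΔS ∝ (B_c − B)^{3/2}`; the package's sweep
reproduces the exponent within [1.3, 1.7] and drives `ΔS` below 1e-3 at
the fold, consistent with the bifurcation module's critical value.

## Diagnostics and early-warning signals

The variance scan pools post-burn-in samples of the collective acetylation
observable across independently seeded replicates at each control value
(burn-in defaults to half the horizon — a heuristic).  Replicate failures
are recorded without aborting the scan.  On the reference system the
microscopic variance at `Ω_27 = 400` peaks within one grid step (0.02) of
the coarse-grained fold in `â_c` — the metabolic early-warning signature.
The micro-vs-CG harness relaxes the microscopic mean-field system from
hypo- and hyper-acetylated starts, projects onto the collective
observables and pairs each branch with its nearest coarse-grained stable
state; for reducible (ablated) contact matrices the coarse-grained columns
are absent and only the microscopic window is reported.  Bistability
probing by two initial conditions can under-detect when a basin shrinks
(both starts then relax to the same attractor), which is exactly the
behaviour used for fold bisection.

## Problem sizes used in tests and the acceptance script

Unit and property tests run a 10-region all-to-all system.  The end-to-end
checks use: 50 regions for the fold-location comparison (coarse-grained
continuation vs bisection on the microscopic mean-field, agreement within
5%); 10³ exact sample paths at `Ω_27 = 10³`, 20 regions, 10 checkpoints for
the law-of-large-numbers check (within 3 Monte-Carlo standard errors);
3×10⁵ Euler–Maruyama steps at `Ω_27 = 5·10³` against the Ornstein–Uhlenbeck
stationary covariance (Lyapunov equation, within 10%); an 8-replica,
9-point microscopic variance scan at `Ω_27 = 400` through the acetyl-CoA
fold; and a 12-region, 9-point window comparison for the long-range
ablation study.  These sizes were chosen as the smallest that leave the
statistical tolerances comfortably non-binding.

## What the synthetic data do and do not show

All inputs are generated: contact matrices from the three idealised
connectivity classes (plus jittered TAD-like blocks) and kinetics from the
reference regime.  Passing tests therefore demonstrate the internal
consistency and numerical correctness of the pipeline — reduction against
microscopic benchmark, simulation against closed forms, barriers against
bifurcation structure — under controlled conditions.  They do not
establish that real Hi-C contact maps (with their distance-decay,
compartment structure and experimental noise), real rate constants, or
chromatin features outside the model's scope behave quantitatively alike.
In particular the model excludes replication-coupled histone dilution
through the cell cycle (so it applies to post-mitotic or slowly cycling
cells), spatial enzyme diffusion, and modifiers beyond the four classes
represented.

## Known limitations

- The spectral closure drops `O(Δ²)` terms; accuracy degrades for strongly
  modular matrices with small spectral gap (the heterogeneous class is the
  practical boundary: ~5% steady-state error).
- The noise closure (`Γ₁*`, `v`) affects fluctuation magnitudes but not
  mean-field bifurcations; its default is a modelling choice.
- WKB barriers are leading-order: prefactors and finite-`Ω_27` corrections
  are ignored, so `ΔS` ratios, not absolute switching times, are the
  meaningful output.
- Tau-leaping/hybrid acceleration is deliberately absent; the exact
  simulator is the benchmark and is fast enough at desk scale.
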