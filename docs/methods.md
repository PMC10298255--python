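# Methods

## Model

The capsule shell is treated as a 1-D slab of thickness L = 0.0002 m. The
film starts uniformly wet at M0 = 8.44 g water per g dry matter; the inner
(pin-side) face is impermeable (zero flux) and the outer (air-side) face is
pinned at the equilibrium moisture M_e from t = 0+ — the surface is assumed
to equilibrate with the drying air instantaneously. Shrinkage, coupled heat
transfer, and 2-D/3-D capsule geometry (elbow, bottom) are outside the
model: transport is isothermal at the air temperature and strictly normal
to the film faces.

Moisture moves by Fickian diffusion with the effective diffusivity

    D_eff(M, T) = D0 · exp(−Ea/(R·T) + a·M − b·M²)        [m² s⁻¹]

- `D0` [m² s⁻¹] — Arrhenius pre-exponential; reference diffusivity at
  infinite temperature.
- `Ea` [J mol⁻¹] — activation energy; sets the temperature sensitivity
  (drying-literature values for polysaccharide films are a few 10⁴).
- `a` [(g/g)⁻¹], `b` [(g/g)⁻²] — moisture modulation. With a, b > 0 the
  law rises and then falls with moisture, peaking at M = a/(2b), the
  "irregular variation" seen in porous polysaccharide materials.

The printed form of this law is typographically ambiguous between keeping
the moisture terms inside the exponential and adding them outside. The
all-in-exponent form is the default because it is strictly positive for
any finite state and standard in the drying literature; the additive form
is available via `DeffParams(form="additive")` and is clamped at a small
positive floor (default 1e-14 m² s⁻¹) since it can cross zero.

Temperatures are accepted in °C at the interfaces and converted to Kelvin
internally; all computation is SI. The gas constant is fixed at
8.3145 J mol⁻¹ K⁻¹ and is not a parameter.

## Solver

Explicit forward-in-time finite differences on Z layers (Z + 1 nodes,
Δl = L/Z; the study's grid is Z = 4). Interior nodes use the conservative
planar stencil

    M_x ← M_x + Δt·[ D_x·(M_{x+1} − 2M_x + M_{x−1})/Δl²
                     + (D_{x+1} − D_{x−1})/(2Δl) · (M_{x+1} − M_{x−1})/(2Δl) ]

with nodal diffusivities evaluated at the current state. A `geometry`
option (`cylindrical`, `spherical`) adds the curvilinear g·D/r advective
term (g = 1, 2) for users who want the radial variant; planar is the
default, consistent with the thin-film assumption.

Two inner-boundary updates are implemented. The default (`paper`) drives
the inner node with coefficient 6, M₀ ← M₀ + 6·D₀·Δt/Δl²·(M₁ − M₀), whose
stability bound is Δt ≤ Δl²/(6D); the `ghost` variant is the textbook
ghost-node rule with coefficient 2. Both enforce zero flux in the fine-grid
limit, but the coefficient-6 rule carries an O(Δl) boundary error: against
the classical series solution for the slab its Z = 64 error in mean
moisture ratio is ≈ 2.4e-3, falling first-order to < 1e-3 only around
Z = 256, while the ghost rule is ≈ 9e-5 at Z = 64. Quantitative
PDE-verification tests therefore use the ghost variant; the default stays
`paper` for fidelity to the published discretization (both agree to well
under 1 % of the drying range on the working Z = 4 grid).

Time stepping uses Δt = safety·Δl²/(6·max_x D_eff), recomputed every step
(safety 0.9 by default), which also satisfies the interior bound Δl²/(2D).
Snapshots at requested times are linearly interpolated between the two
bracketing steps. The march stops early once the normalized mean moisture
ratio (M_avg − M_e)/(M0 − M_e) falls below 1e-3 (later snapshots repeat the
final state) and refuses pathologically stiff parameter sets via a step
budget (default 5,000,000 steps; the fitting path uses 100,000, roughly
250× a realistic run) instead of marching without bound — such trial
parameter sets receive a penalty value during optimization. The hot loop is
JIT-compiled (numba); the numpy single-step functions implement the same
stencils independently and the test suite asserts bit-identical agreement
between the two paths.

The average moisture is the trapezoid-weighted spatial mean. The
moisture-weighted mean diffusivity reported in the analysis tables is the
discrete reading Σ D_eff(M_x)·M_x / Σ M_x of the moisture-integral average
∫D dM / ∫dM; integrating over the spatial coordinate instead is the other
defensible reading of that average — the moisture-weighted sum was chosen
and is stated here rather than asserted as the only possibility.

A classical series oracle is built in for verification:
MR(t) = Σ 8/((2n+1)²π²)·exp(−(2n+1)²π²Dt/(4L²)), the slab insulated at
x = 0 and fixed at x = L (equivalent to a 2L slab).

### The t = 0 point

Pinning the outer node at M_e from t = 0+ makes the spatial average of the
first snapshot sit (M0 − M_e)/(2Z) below M0, while a film weighed at t = 0
is still uniform at M0. Predictions and the synthetic generator therefore
both report M0 itself at t = 0 and the marched average afterwards.

## Estimation

`VariableDiffusivityModel` (scikit-learn estimator; `fit_variable` is the
functional wrapper) minimizes the pooled sum of squared residuals between
simulated and observed average moisture over all supplied curves, within
bounds D0 ∈ [1e-12, 1e-2] m² s⁻¹, Ea ∈ [0, 1e5] J mol⁻¹, a ∈ [0, 5],
b ∈ [0, 2] (all configurable). Design choices that proved necessary:

- **Residual scale.** Observations span 8.44 → 0.1 g/g with multiplicative
  error (constant CV), so residuals are relative by default — the
  maximum-likelihood weighting for that noise model. With absolute
  residuals (available via `residual_scale="absolute"`) the optimum tracks
  the wet early points and can drift ~0.02 g/g at the near-equilibrium
  tail, i.e. tens of percent in relative terms.
- **Initial condition.** When a curve carries its nominal initial moisture
  (`m0_nominal`, set by the generator), the simulation starts there rather
  than at the noisy first observation; treating a noisy measurement as an
  exact initial condition propagates its error through the entire
  predicted curve.
- **Parameterization.** D0 and Ea are nearly collinear through
  D0·exp(−Ea/RT) over a 10 °C span, and the diffusivity scale spans many
  decades. The search runs in u = log10 of the Arrhenius factor at the mean
  condition temperature, together with (Ea, a, b); D0 is recovered from
  (u, Ea).
- **Optimizer.** Bounded, derivative-free and global: differential
  evolution with a Latin-hypercube initial population (seeded, hence
  deterministic), followed by a bounded Powell polish that is kept only if
  it improves the objective. Local multi-start alone (Powell from
  Latin-hypercube starts, with or without a profiled diffusivity scale)
  repeatedly stalled on the plateaus this objective has where trial films
  dry instantly or not at all; the evolution reliably finds the basin
  (noiseless three-temperature recovery is exact to ~1e-12 in SSE).

A joint fit across all curves is the default; `per_condition=True` fits an
independent parameter set per condition. A single-temperature fit cannot
separate D0 from Ea — only the lumped Arrhenius factor is identified, and
the tests assert exactly that. `ConstantDiffusivityModel` fits one scalar
diffusivity per condition by a half-decade grid scan over log10 D followed
by bounded refinement (the scan exists because the SSE is flat in the
instant-dry and no-dry regimes and a bare bounded search can stall there).

R² follows the form whose total sum of squares is taken about the mean of
the *predictions*; the conventional observed-mean form is available via
`r2_denominator="observed_mean"`. RMSE is reported in absolute g/g
regardless of the fitting scale.

## MRI quantification

The spin-echo signal model I = k·ρ_H·(1 − e^(−TR/T1))·e^(−TE/T2) with the
study's sequence settings (TR = 2000 ms, TE = 18.125 ms) and a strictly
linear signal–moisture relation; no relaxation-time drift with drying is
modeled. Moisture percentage normalizes the mean zone signal between the
initial frame (100 %) and the equilibrium frame (0 %); the quantity is
invariant under any global affine rescaling of the signal, so scanner gain
and offset cancel. Per-layer percentages apply the same normalization to
radial bands of the shell annulus; a band whose initial and final means
coincide (the outer face, at equilibrium throughout) yields NaN rather
than a division error. The analysis zone excludes one pixel at each radial
boundary of the annulus (configurable), mirroring the partial-volume
corruption of boundary pixels; the "middle layer" band is defined as the
middle third of the radial extent — with shells only a few pixels thick a
fractional definition is the only stable one, and it is an implementation
convention, not an imaging standard.

## Synthetic data

The generator reproduces the study design: five conditions (RH 40/50/60 %
at 35 °C; 35/40/45 °C at RH 60 %), air velocity 2 m s⁻¹ (metadata only),
M0 = 8.44 g/g, L = 0.0002 m, Z = 4, sampling every 20 min for 140 min,
multiplicative Gaussian noise truncated at ±3σ with CV 0.05 (the study
reports experimental error < 10 %), clamped at M_e, applied independently
to the average series and to every nodal series; one RNG stream per
condition derived from the config seed, so identical configs give
byte-identical data.

Equilibrium moisture is never reported per condition in the source study;
a single configurable M_e = 0.10 g/g is used for all conditions, which
makes the three same-temperature conditions statistically identical — the
humidity dependence of M_e would be the knob to differentiate them, and it
is deliberately not invented here.

The generating diffusivity law (D0 = 1e-6 m² s⁻¹, Ea = 3e4 J mol⁻¹,
a = 0.2, b = 0.05) was chosen so that (i) D_eff is of order
1e-12–1e-11 m² s⁻¹ along the trajectory, internally consistent with a
0.2 mm film drying over ~2 h (a slab dries on the scale L²/D), and (ii)
the mean moisture ratio is ≈ 0.045 at 80 min, the published curve shape.
Diffusivities of a few 1e-10 m² s⁻¹ — the magnitude the study reports —
would dry this film in about a minute; the two figures cannot both hold at
L = 0.0002 m, and the generator resolves the conflict in favor of the
time axis. The `GeneratorConfig.paper_scale()` preset makes the opposite
choice: diffusivities in the reported 3–7e-10 m² s⁻¹ range with a
50-fold-shorter time axis (the identical dimensionless problem).

The MRI phantom renders the nodal moisture of each snapshot onto a
64 × 64 annulus (radii 20/28 px, one hydrogen-density value per radial
layer band), applies the spin-echo law, and adds Gaussian background noise
with σ = 1 % of the initial mean shell signal.

What passing tests on these data do **not** show: robustness to
non-instantaneous surface equilibration, shrinkage, temperature
transients, per-condition equilibrium moisture, spatially correlated
measurement error, or MRI artifacts beyond additive background noise
(partial volume is only emulated through the erosion convention).

## Problem sizes and tolerances in the test suite

Heavy fits are session-scoped fixtures: the noisy five-condition
experiment and the noiseless three-temperature recovery are each fitted
once (~15–20 s each). The noise-robustness property runs five seeded
replicates at a reduced evolution budget (maxiter 80, popsize 10) and
evaluates diffusivity recovery on M ∈ [0.3, 4] — the moisture range the
sampled trajectory actually traverses after the first interval; at the
wet extreme M ≈ M0 only the single t = 0 instant carries information, so
D_eff there is weakly identified and its error is dominated by inherent
estimation variance, not optimizer budget. PDE verification uses Z = 64
against the series oracle (< 1e-3 in moisture ratio); maximum-principle
and monotone-drying checks draw 50 parameter sets from the physically
plausible box (log10 D0 ∈ [−7, −5], Ea ∈ [1e4, 5e4], a ∈ [0, 0.5],
b ∈ [0, 0.15]). Pipeline determinism compares manifest content hashes of
two full CLI runs at a reduced fit budget (determinism is independent of
the optimization budget).

## Known limitations

- The per-condition constant-diffusivity benchmark has one free parameter
  per condition (five in the study design) while the joint variable law
  has four in total; the variable model's dominance on these data is an
  empirical finding about moisture dependence, not a strict nested-model
  identity.
- The printed coefficient-6 boundary rule's O(Δl) error is visible in
  fine-grid verification (see Solver); on the working Z = 4 grid both
  rules are used as published and agree to well under the measurement
  noise.
- The estimator assumes the equilibrium moisture of each condition is
  known (it enters the boundary condition); it is not estimated.
- Curvilinear geometries reuse the planar inner-node rule at r = 0, where
  the zero-flux condition makes the radial term vanish only in the limit.
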