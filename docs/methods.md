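# Methods

## Model and assumptions

A unicyclic kinetic scheme is a single closed loop of N ≥ 2 enzyme
conformational states with every transition reversible and first-order.
States are numbered 1..N counterclockwise; edge i joins state i to
state i+1 (mod N); the forward rate constant of edge i is the
odd-indexed k_{2i−1}, the reverse the even-indexed k_{2i}. Ligand
binding (substrate on edge 1, product rebinding on the last edge) is
pseudo-first-order: the stored rate is the second-order constant
(M⁻¹s⁻¹) times the molar ligand concentration, and the pair is retained
so that saturating- and vanishing-ligand limits are well defined. The
package assumes a single productive cycle — no branches, no parallel
cycles, no irreversible steps, no time-dependent (pre-steady-state)
kinetics, and no light-driven transitions. Every rate constant must be
strictly positive and finite; schemes violating this are rejected at
construction, which also makes the rate graph strongly connected and
the stationary distribution unique.

## Steady state: King–Altman tree weights, not a linear solve

The stationary distribution is computed by the King–Altman / Hill
diagram method: the weight of state j is the sum over directed spanning
trees rooted at j of the product of their rate constants. For a single
cycle these trees are simply the cycle with one edge removed and the
remaining path directed toward the root, so every weight is a sum of
N positive products of N−1 rate constants. This was chosen over a dense
linear solve deliberately: with rate constants spanning ten decades the
LU-based solve loses up to eight significant digits to cancellation,
while positive-sum tree weights are accurate to a few ulps, and the
package's conservation identity (below) then holds at ~1e−15 relative
instead of ~1e−7. The dense solve is retained as the independent
brute-force oracle in the test suite, run there in exact rational
arithmetic (`fractions.Fraction` Gaussian elimination) so the oracle
itself carries no roundoff.

One-way cycle fluxes are J± = ∏k_fwd|rev / Σ with Σ the summed tree
weights; the net flux J = J₊ − J₋ is computed from this product form
(never as a difference of occupancy-weighted edge rates, which cancels
catastrophically on fast, nearly balanced edges).

## Entropy production and its decomposition

Force: X/RT = ln(∏k_fwd/∏k_rev), natural log, accumulated with
compensated summation of the individual log terms. Total dissipation
per enzyme is J·X/RT, reported in RT units (s⁻¹ per enzyme) throughout
— working per enzyme in RT units sidesteps the k_B-versus-R choice, and
matches how dissipation axes are conventionally labelled. The per-edge
partial entropy production is

σ_ij/RT = (k_ij p_i − k_ji p_j)·ln(k_ij p_i/(k_ji p_j)).

Numerically the difference in the first factor equals the cycle flux J
on every edge of a unicycle, so the implementation evaluates
σ = J·log1p(J/(k_ji p_j)): both factors then share J's sign, making
nonnegativity exact, and the formula stays smooth to machine precision
on nearly balanced edges where the subtraction form carries ~1e−4
relative noise. The sum of edge σ equals J·X/RT identically up to
~1e−15 relative.

Degenerate cases. A scheme within 1e−12 (relative to the summed
log-rate magnitude) of detailed balance is snapped to exact
equilibrium: J, X, dissipation, and every σ are returned as exactly
0.0, implementing the x·ln x → 0 limit; an edge whose one-way fluxes
agree within 1e−14 relative likewise returns σ = 0 exactly.

Sign convention: X ≥ 0 means net forward (substrate-consuming) drive,
so the mass-action form is X = RT·ln(K_eq/Γ) with Γ = c_p/c_s — chosen
so that positive force always accompanies J₊ ≥ J₋ and positive entropy
production.

## Catalytic parameters

k_cat is lim [S]→∞, [P]→0 of J; k_cat/K_M is lim [S]→0, [P]→0 of
J/[S]; K_M is their ratio. Closed forms are written out for 2–4 states
(the 4-state turnover, k_cat = k3k5k7/(k3k5+k3k6+k3k7+k4k6+k4k7+k5k7),
was derived from the saturating limit of the 4-state King–Altman flux
and is verified against the numeric limit oracle in the tests). The
numeric limits exploit that the King–Altman denominator is linear in
k1, D(k1) = d0 + d1·k1: both coefficients are computed explicitly and
[S] is pushed until the subdominant term is a 1e−4 perturbation, then a
two-point Richardson extrapolation (1×, 4×) removes the leading error,
giving ~1e−9 relative agreement with the algebra. The [P] = 0 condition
is imposed exactly (zero product-rebinding rate inside the raw flux
evaluator) rather than by a tiny concentration, which would reintroduce
cancellation. A scheme driven backwards (X < 0) at the working
concentrations is flagged, not rejected — its k_cat and K_M are still
well-defined forward-limit quantities.

Dissipation in the per-enzyme summary is evaluated at the declared
working concentrations; `catalytic_parameters(...,
product_concentration=...)` re-evaluates at any other positive [P]. An
exactly zero working [P] is not accepted there because the force, and
with it the dissipation, diverges logarithmically as [P] → 0.

## MPEP optimization

The partial entropy production of a chosen edge is maximized over that
edge's forward rate constant, everything else fixed. Unimodality is not
assumed: a 1000-point multiplicative grid across the search bounds
(default 1e−6..1e12 s⁻¹, the physically plausible elementary-step
range) locates the global bracket; golden-section search on the log
axis then refines it to 1e−6 in log10 k (σ tolerance 1e−8 relative).
The search is parametrized multiplicatively, k(t) = k_min·(k_max/k_min)^t,
which makes the whole procedure exactly covariant under a common
rescaling of all rates and bounds (doubling everything doubles k* and
σ* bit-for-bit). A maximum on a search bound is flagged, never silently
reported as interior. The optimizer is fully deterministic.

Two modes: by default only the forward constant varies, so the step
equilibrium constant and the cycle force change as a consequence — in
that mode σ(k) typically saturates monotonically (the edge force grows
with ln k while the flux saturates) and the supremum sits at the upper
bound. The optional `hold_step_equilibrium` mode co-varies the reverse
constant to keep K_step fixed; the cycle force is then invariant and
the flux–force trade-off produces a sharp interior maximum (σ → 0 at
both extremes). The two-edge variant alternates single-edge
maximizations until both optima move < 1e−6 relative between outer
iterations (cap 100; non-convergence is reported in the result, never
raised). Whether a simultaneous 2D search would differ is checkable by
brute force; on the schemes tested the alternating fixed point is
order-invariant and stable under ±1% perturbations.

A caveat discovered during validation: on some strongly driven random
schemes the default-mode objective is flat to the last floating-point
ulp across whole decades of k. There the *location* of the maximum is
numerically undefined (any two correct methods can disagree in k while
agreeing in σ to ~1e−16); the acceptance checks therefore require
location agreement only where the maximum is resolvable, and maximal-σ
agreement to 1e−12 otherwise.

## Scaling fits

Power laws are fit by OLS on decadic logs with dissipation/RT as the
response (slope SE and 95% CI from the t-distribution with n−2 df);
total-least-squares (orthogonal) regression is exposed as a sensitivity
mode because the choice of regression variant is not innocuous when
both axes carry error. Rows with nonpositive values on either log axis,
and rows driven backwards (X < 0), are excluded with a logged warning —
the scaling analysis targets forward-driven ensembles. The two slopes
(vs k_cat/K_M and vs k_cat) share their response variable, so their
difference is tested by a paired case-resampling bootstrap
(percentile 95% CI; seeded, reproducible; SE-based z-tests would be
invalid here). The dissipation plane is an OLS plane in
(log₁₀ k_cat, log₁₀ K_M, log₁₀ Φ/RT) with the residual SD (n−3 dof)
reported as the plane-thickness statistic; rank-deficient predictors
are rejected.

## Synthetic ensembles

The generator emulates the statistical features of curated rate-
constant collections for single-cycle enzymes: rate constants
log-uniform over 1e−2..1e8 s⁻¹ (constants spread over many orders of
magnitude are characteristic of such datasets), scheme sizes drawn from
{2, 3, 4} with weights (0.25, 0.5, 0.25), and a strictly positive
thermodynamic drive imposed by rescaling the single last reverse
constant so that X/RT hits a uniform draw from [1, 40] — touching one
marginal only, rejection-free. Working concentrations default to
[S] = 1 mM and [P] = 1 µM, typical forward-driven assay conditions;
binding second-order constants are back-computed from them. The
scaling-ensemble generator imposes log₁₀(Φ/RT) = a + b·log₁₀(k_cat/K_M) + ε,
ε ~ N(0, SD), with efficiency log-uniform over 1e2..1e9 M⁻¹s⁻¹,
k_cat log-uniform over 1e−1..1e6 s⁻¹ independently, and K_M their
ratio; defaults b = 0.72, SD = 0.5 decades.

What the generator does not emulate: enzyme-family structure,
correlations between class labels (specialist/generalist/mutant) and
kinetics, correlation between k_cat and efficiency, phylogenetic
relatedness, or measurement error in individual rate constants. Tests
passing on these ensembles therefore demonstrate the correctness and
calibration of the machinery (identities, limits, estimator coverage),
not any empirical claim about real enzyme collections; conclusions
about real ensembles require real rate-constant tables run through the
same pipeline.

All randomness flows from one integer seed through
`numpy.random.default_rng`; ensembles are byte-identical across runs
and platforms.

## Problem sizes and calibration checks

The ensemble-scale checks run 1000 random schemes for the conservation
and flux-oracle identities (tolerance 1e−9 relative; observed ~1e−15),
100 schemes per size for the kinetic-limit equivalences (tolerance
1e−6; observed ~1e−9), 50 schemes per mode for the MPEP-vs-grid
comparison (1e−4 relative in k where resolvable), and 100 seeded
replicates of the n = 75, b = 0.72, SD = 0.5 slope-recovery experiment,
requiring 95% CI coverage in at least 93 of 100. These sizes keep the
full suite around a minute while leaving the tolerances far from
marginal.

## Known limitations

* Single cycles only; multi-cycle diagrams and free-energy-transducing
  machines (pumps, motors, photocycles) are out of scope.
* Closed-form flux and catalytic expressions are written out for 2–4
  states; larger cycles use the general tree-weight solver and numeric
  limits.
* The CSV schema carries at most k1..k8; larger schemes are
  constructible through the API only.
* Orthogonal-regression fits report no analytic standard errors.
* The backward-flux diagnostic threshold (k_cat/J > 2) is a convention,
  exposed as a constant, not a fitted quantity.
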