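# Methods

## Model

Nine species — the dione **A**, hydroxyketones **B**–**E**, diols
**F**–**I** — connected by twelve irreversible apparent-first-order steps
in two layers: four parallel steps A→{B,C,D,E} and two steps from each
hydroxyketone into its pair of reachable diols. Assumptions: every surface
step is rate-determining, irreversible and first order in its single
substrate; hydrogen partial pressure, solvent, catalyst loading,
temperature and the chiral-modifier concentration are constant over a run
and are absorbed into the rate constants (units min⁻¹); adsorption and
desorption are not modelled; aromatic-ring hydrogenation does not occur, so
diols are terminal. Stoichiometry is 1:1 throughout, hence the generator
matrix `K` has zero column sums and total concentration is an invariant.

Concentrations are normalised (default initial state: A = 1, rest 0).
First-order constants are invariant under a global concentration rescaling,
so absolute units never enter the analysis; the SSR scales with the square
of the chosen units and is reported, not interpreted across datasets.

The k-index ↔ edge assignment is k1:A→E, k2:A→B, k3:A→D, k4:A→C, k5:B→I,
k6:B→F, k7:C→H, k8:E→I, k9:C→G, k10:E→H, k11:D→F, k12:D→G. The indices of
the four A-steps and the F/H-feeding steps are pinned by which constants
must dominate to explain the observed high F (k2, k6 vs k3, k11) and high H
(k4, k7 vs k1, k10), and by the two nil constants being the E→I and C→G
steps. The remaining pair {k5, k12} ↔ {B→I, D→G} is a declared convention;
swap it by editing the shipped `data/default_network.yaml` — no code change
is needed, and every result in this package is self-consistent under either
choice.

## Forward solution

The system is linear and time-invariant, so profiles are propagated exactly
by the matrix exponential, computed by SciPy's scaling-and-squaring `expm`
(robust to repeated eigenvalues, which genuinely occur: equal lumped rates
are admissible). Propagation walks the sampling grid incrementally and
caches one exponential per distinct time increment, so a uniform grid costs
a single 9×9 `expm`. Cross-checks: the Bateman closed form for each
intermediate (series limit `k_in·t·exp(−k_out·t)` engaged when the two
rates agree within a relative 1e−12 — a cancellation guard, not a model
choice) and an adaptive DOP853 integration at rtol 1e−12/atol 1e−14 kept
solely as a test oracle. The interior maximum of an intermediate sits at
`ln(k_tot/k_out)/(k_tot − k_out)`; for the reference constants the B
maximum falls at ≈233 min, which rationalises a 360-min observation window
for a process whose target product is that intermediate.

## Estimation

`fit` minimises the weighted sum of squared concentration residuals over
all species and times with `scipy.optimize.least_squares` (trf), uniform
initial guess 0.01 min⁻¹, lower bound 0, tolerances `ftol = xtol = gtol =
1e−14` (tight enough that noiseless self-generated data are recovered to
well below 0.1% relative). A constant driven to the bound (active-set flag,
or an estimate below 1e−9 min⁻¹ — about six orders below the typical
constants) is clipped to exactly zero and flagged `at_bound`; such
constants report no interval and are excluded from the covariance and
correlation matrices, because the local quadratic approximation is invalid
at an active bound.

Weighting options (diagonal observation covariance throughout):

- `uniform` (default) — every cell weighted equally; mirrors a pooled
  diagonal-covariance treatment of the data.
- `per_species` — residuals scaled by each species' RMS signal.
- `relative` — cell-wise inverse-observation weights floored at
  1e−3 × max(obs). This is the matched error model when measurement noise
  is proportional to the signal, and it is what the coverage test uses: HPD
  calibration is a statement about a correctly specified error model. Under
  `uniform` weighting with multiplicative noise, intervals for constants
  identified mainly by low-concentration species (k5 via diol I, k12 via
  diol G) are conservative — wide relative to the actual estimator scatter
  — because the pooled σ² is dominated by the large-signal species.

Uncertainty: the default Laplace path takes cov = σ²(JᵀJ)⁻¹ at the optimum
(SVD inverse; σ² = weighted SSR/(n − p) unless `obs_sigma` fixes it) and a
95% half-width of 1.959964·stderr. The MCMC path (emcee, flat prior on
k ≥ 0) starts walkers scattered at the Laplace scale around the optimum,
discards a burn-in (default 500 steps, 32 walkers), and reports the
narrowest window containing 95% of each marginal — one-sided in effect for
constants piled against zero. The sampler is explicitly seeded; identical
configurations reproduce identical chains. The Laplace path is the default
because it is ~10³× cheaper and agrees with the sampler for constants that
are well separated from the bound; the MCMC path exists to verify that and
to handle the truncated, non-Gaussian marginals of weakly identified
constants.

The initial state defaults to the dataset's first row (which then must be
at t = 0) and can be supplied explicitly — the right choice whenever the
initial charge is known by design rather than measured, as in the coverage
study, where reading a noisy t = 0 row would inject model error the test is
not about.

## Synthetic data

The generator emulates the sampled batch experiment: exact forward
simulation on a 10-point equally spaced grid over 0–360 min (the grid of
the emulated study is not published; equal spacing including t = 0 is this
package's choice), initial state pure A, reference fitted constants as the
generating truth, then per-cell noise. Default noise is multiplicative
Gaussian with σ = 2%, which puts visually realistic scatter on the major
species while leaving the minor diols (G, I) noisy relative to their small
signals; negative draws are clipped to zero, as measured concentrations
are. Seeds are mandatory in the metadata; identical seeds give bit-identical
datasets, and CSV round-trips are exact (`%.17g` on write, round-trip float
parsing on read).

What the generator does *not* emulate: chromatographic calibration error,
species-correlated noise, drift, missing samples, or any adsorption
saturation that would make real kinetics deviate from first order. Passing
the recovery and coverage suites therefore demonstrates the correctness and
calibration of the estimator under the model's own assumptions — an
inverse-crime design, chosen deliberately because the original raw profiles
are not deposited — not that the first-order model is adequate for any
particular real catalyst.

## Pathway classification

Routes are the eight two-step paths A–X–Y. A route is **negligible** when
either of its constants is ≤ `negligible_tol` (default 0, i.e. a constant
on the bound). Among the survivors, the `top_n` (default 2) ranked by
bottleneck rate min(k_first, k_second) are **preferential**, provided the
ranking is strict at the cut — a tie across the boundary promotes none of
the tied routes and reports them as ties; the rest are **intermediate**.
The bottleneck was chosen as the score because the slower step limits the
diol delivered through a route; on the reference constants this rule
reproduces the expected summary (negligible E–I and C–G; preferential
A–B–F and A–C–H; four intermediate routes). A consequence worth noting: a
single active edge does not make a route preferential — a route needs both
of its steps alive, so an isolated nonzero constant classifies all routes
as negligible.

Selectivity metrics are reporting conveniences: regioselectivity
(B+C)/(B+C+D+E), enantiomeric excesses (B−C)/(B+C) and (D−E)/(D+E),
undefined (NaN) where the denominator vanishes, e.g. at t = 0.

## Problem sizes and numerical checks in the test suite

- Forward-solver equivalence: 20 random nonnegative rate draws plus the
  reference set, 10-point grid, agreement ≤ 1e−8 max-abs.
- Mass conservation ≤ 1e−10; Bateman vs matrix solution ≤ 1e−10; the
  equal-rate limit continuous across the switching tolerance.
- Inverse-crime recovery: noiseless 10-point datasets, all nonzero
  constants within 0.1% relative (observed: ~1e−9), nil constants on the
  bound.
- HPD coverage: 200 replicates at 2% multiplicative noise, `relative`
  weighting, known initial state; each of the 10 identifiable constants
  must be covered in 88–99% of replicates, with an at-bound replicate
  counted as a miss.
- Correlation structure: 50 noisy replicates, default (`uniform`) fit; the
  parallel-route pairs (k10,k1) and (k10,k7) must rank in the top-3
  mean |correlation| among constants that are free in the fits.

These sizes keep the full suite under a minute of fitting time while
leaving the Monte-Carlo margins comfortably wider than the assertion bands.

## Limitations

- The inverse-crime acceptance surface validates the implementation, not
  the chemistry; fitting real profiles requires digitised or re-measured
  data this package does not ship.
- Reversible steps, adsorption/site-competition models (e.g. multi-site
  Langmuir–Hinshelwood treatments with modifier coverage) and
  temperature/pressure-dependent rate laws are out of scope.
- The Laplace covariance is a local approximation; for constants within a
  couple of standard errors of zero, prefer the MCMC intervals.
- With only 10 sampling times and 12 parameters, the design is close to
  minimal; constants on low-flux routes (k10, k11) carry wide intervals and
  noticeable pairwise correlation, which is faithfully reported rather than
  regularised away.
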