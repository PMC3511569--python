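# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator and the known limitations of `firekrige`.

## Sampling design

`generate_design` reconstructs an intensive nested design: rows of 9 cores
whose within-row spacings are drawn from {2, 4, 8} m, 9 rows 2 m apart, on a
50 m × 50 m plot, 81 cores in all. Nested spacings give comparable pair
counts at the 2, 4 and 8 m lags while keeping the field walk short; the
spacing order is reversed in the middle three rows as a crude anisotropy
check. Two reconstruction choices were genuinely open and are configurable:

- Row placement. Nine rows 2 m apart span only 16 m of a 50 m plot; the
  published description does not say where the rows sat. Default: rows at
  y = 0, 2, …, 16 m.
- Within-row spacing order. The exact 2/4/8 sequence is unpublished.
  Default: (2, 2, 4, 4, 8, 8, 4, 2), spanning 34 m, which guarantees pairs
  at all three target lags.

The true core coordinates of the original survey are not public; the default
design is a faithful-as-possible reconstruction, not the actual layout.

## Spatial model

One variable at a time is modelled as a three-level Gaussian hierarchy:
`Y(u) = Xβ + S(u) + ε(u)` with a linear coordinate trend (intercept-only
available via `trend="constant"`), a stationary Gaussian process `S` with
partial sill σ² and exponential correlation `R(h; φ) = exp(−h/φ)`, and
i.i.d. nugget noise with variance τ² = τ²ʳᵉˡ·σ² entering only the diagonal.
The reported "range" is 3φ (correlation ≈ 0.05). One source text phrase
describes the observations as "exponentially distributed"; the estimation
machinery it names is Gaussian with exponential *correlation*, and that is
what is implemented.

Priors: flat on β, reciprocal on σ², and uniform over a discrete grid of
(φ, τ²ʳᵉˡ) cells — uniform mass per cell, not uniform density on a
continuum, matching the predefined-grid construction. Defaults, both
configurable:

- φ grid: 100 log-spaced values from L/300 to L, where L is the largest
  coordinate span (≈0.11–34 m on the default design). This spans sub-grain
  to whole-plot ranges.
- τ²ʳᵉˡ grid: 100 linear values on [0, 4], 0 included.

Conditional on a cell, (β, σ²) are conjugate: with V = R(φ) + τ²ʳᵉˡ·I,

    p(φ, τ²ʳᵉˡ | y) ∝ |V|^(−1/2) |XᵀV⁻¹X|^(−1/2) (S²)^(−(n−p)/2),

where β̂ is the GLS estimate and S² the generalised residual sum of squares.
Per cell, σ² | y is scaled inverse-chi-squared with n − p degrees of freedom
and β | σ², y is Gaussian. This marginal is invariant to rescaling y (the
(φ, τ²ʳᵉˡ) posterior is scale-free; σ² summaries scale by c²) and to
V → cV, which is why a huge relative nugget reduces exactly to the i.i.d.
error model. Both facts are exercised as tests, and the grid posterior is
verified against brute-force 2-D quadrature over (β, σ²) on 3-point toys to
total-variation < 1e-4.

### Numerics

For each φ the correlation matrix is eigendecomposed once; V = R + τI shares
the eigenvectors, so all cells of a φ-slice reuse one O(n³) factorisation
and each cell costs O(np²). Eigenvalues are floored at 1e-12 (a warning
reports when the floor engages — numerically degenerate φ). Cells whose
trend cross-product is singular or whose residual sum is non-positive
receive zero mass with a warning; if every cell is degenerate the fit
aborts ("no admissible correlation parameters"). Log masses are normalised
after max-subtraction. The posterior mode breaks ties toward the smallest φ
(arbitrary, documented), and `mode_on_edge()` reports when the mode sits on
the φ-grid boundary — the published long-range/low-R² abundance fit suggests
such boundary-dominated posteriors occur in practice; no special handling
beyond reporting is attempted.

### Sampling, prediction, summaries

`sample_posterior` draws cells from the grid masses (default 100,000 draws),
then σ² from its inverse-chi-squared conditional and β from its Gaussian
conditional. Prediction is of the *signal* Xβ + S (the nugget is excluded):
per draw, the conditional mean is x_tᵀβ + rᵀV⁻¹(y − Xβ) and variance
σ²(1 − rᵀV⁻¹r); the surface reports the across-draw mean and variance.
Draws sharing a grid cell share all V-dependent algebra, and per-cell draw
moments are accumulated in closed form, so prediction cost is independent of
the draw count. Consequences used as tests: with τ²ʳᵉˡ = 0 the predictor
interpolates observed locations exactly with zero signal variance, and far
beyond the range it reverts to the GLS trend surface. Locations outside the
observed bounding box warn rather than fail. The default map spacing is
0.5 m (the source work does not state one).

Posterior summaries (mean, 5%, 95%) are computed per draw first — trend
intercept β₀, range 3φ, sill σ², nugget τ²ʳᵉˡσ², and nugget ratio
τ²ʳᵉˡ/(1 + τ²ʳᵉˡ) — never as ratios of summaries. Whether the published
"trend" column was the intercept or a plot mean is unstated; the intercept
is reported here, and with the default trend centred on the plot corner the
two differ.

### Leave-one-out cross-validation

Each point is predicted from the remaining n − 1 with the full posterior
refit per fold on a reduced grid (default 25 × 25; configurable up to the
full grid). Whether the original analysis re-estimated correlation
parameters per fold is unstated; refitting is the conservative choice. The
per-fold predictive mean and variance are computed analytically as the
mass-weighted mixture of the per-cell closed-form conditionals (per cell,
E[σ² | cell] = S²/(n − p − 2) scales the kriging and trend-uncertainty
variances), so LOO is deterministic; a `seed` argument is accepted for
interface stability. R² is the squared Pearson correlation of observed vs
predicted, adjusted as 1 − (1 − R²)(n − 1)/(n − p − 1); degenerate refits
flag and exclude the point with a warning.

A note on attainable R²: even predicting with the *true* parameters, the
LOO R² of a noiseless field on this design saturates near 0.95 and varies
substantially across realizations — with a very long range the linear trend
absorbs most of the field, leaving little residual signal variance. The test
suite therefore anchors the Bayesian LOO to the per-realization
exact-parameter oracle rather than to a fixed threshold alone.

## PLFA metrics

Lipid names follow `[i|a|cy]CHAIN:UNSATS[wN][c|t][2OH]`; the iso/anteiso
suffix spelling (`15:0iso`) and unicode `∶`/`ω` are canonicalised, and chain
length is the integer before the colon — needed to apply the chain-length
rule mechanically. Filtering: cores with no (or zero) 16:0 are removed and
listed; lipid columns with chain length ≥ 20 are dropped (the boundary
lipid 20:4ω6c is excluded); retained values pass through bit-identical.

Metrics per core, computed on mole fractions (all are invariant to positive
rescaling of a core's raw amounts): total abundance (nmol, sum of retained
amounts); fungi:bacteria = (18:1ω9c + 16:1ω5) / (a15:0 + i15:0 + 15:0 +
i16:0 + 15:1ω8c + 16:1ω7c + cy17:0 + a17:0 + 17:1ω7c); Gram+ = i15:0 +
a15:0 + i16:0 + a17:0 + i17:0; Gram− = 15:1ω8 + 16:1ω7 + 17:1ω7 + 19:1ω8t +
15:1ω9; stress ratio i15:0/a15:0. Marker spellings with and without the
cis/trans suffix are unified (exact match first, then suffix-tolerant);
absent markers contribute zero, a zero denominator yields NaN (flagged
undefined, not an exception), and a marker-coverage report accompanies every
filter run. 17:1ω8 appears in the published profile but in no stated marker
set and is assigned to none. Plot summaries are mean ± SE (sd/√n, sample
sd), with missing cores excluded from n.

Two summary modes exist because the published tables mix them: plot-level
ratios can be computed from per-core ratios (mean of ratios — what the
published community-metric table reports) or from plot-mean profiles (ratio
of means — what the published lipid table implies, e.g. fungi:bacteria 0.79
vs 0.93 for the same plot). Both are exposed; they are not interchangeable.
A further irreconcilable inconsistency: the published plot-mean profiles
imply Gram+ mole fractions near 0.10, while the published community-metric
table prints 0.010–0.016; the implementation follows the stated marker-sum
definition and does not attempt to reproduce the latter scale from the
former.

## Synthetic lipid tables

`simulate_lipid_table` emulates the survey's wide per-core tables: per-core
total abundance is a spatially autocorrelated field (standardised draw of
the spatial model, default φ = 3 m and τ²ʳᵉˡ = 0.5, scaled to a requested
mean/sd and floored just above zero), and per-core composition is Dirichlet
around a target mole-percent profile. The default concentration 135 was
chosen once to match survey-scale mole-percent standard errors at n = 81
(e.g. a 12% lipid with SE ≈ 0.3 over 81 cores); `None` gives exact profiles.
An option zeroes 16:0 in a chosen number of cores to exercise the filter.
What the generator does *not* emulate: cross-lipid correlation beyond the
Dirichlet's (negative) compositional constraint — real cores show positively
co-varying related lipids, so mean-of-ratio metrics (notably i15:0/a15:0)
are biased upward relative to the published per-core means; spatial
structure in composition (only total abundance is autocorrelated); and
detection/censoring of minor lipids. Published profile columns also do not
sum to 100 (93–110, being means of per-core percentages with per-core
missingness), so callers renormalise before simulating. Passing tests on
synthetic plots therefore demonstrate correctness of the estimators under
the stated model, not fidelity of every distributional feature of field
PLFA data.

## Net rates and plot comparison

Net rate = gross − consumption (the pool-dilution identity); negative values
are net immobilisation, and the operation is exactly linear. Published
plot-level values are ambiguous between mean-of-differences and
difference-of-means (they disagree by 0.01 in one published case:
0.38 − 0.61 = −0.23 printed as −0.24); `net_rates_table` computes per-row
nets so both summaries are available. Plot contrasts use Welch's
unequal-variance t test (the original test is unnamed; Welch is the safer
default) and its type-I calibration is verified by simulation.

## Stepwise selection

`StepwiseAIC` mirrors the conventional bidirectional stepAIC workflow:
start from the full model (configurable), evaluate all single-term
additions and deletions, apply the largest AIC decrease, stop when none
helps; ties break toward deletion, then alphabetically, making the search
deterministic. Fits are Gaussian OLS; AIC = −2·loglik + 2k with k counting
coefficients plus the error variance — the extra constant is shared by all
candidate models, so either counting convention selects identically.
Collinear candidates (e.g. vegetative and non-vegetative cover summing to
~100) are dropped greedily left-to-right with a warning, and incomplete
rows are dropped and reported before selection. "Fungi" and "Bacteria" as
candidate variables are the fungal and bacterial marker sums (the F:B
numerator and denominator) as mole fractions of the filtered profile.
The published selections report only signs and significance bands
(thresholds 0.05, 0.01, 0.001, and "p = 0" interpreted as p below double
precision, 1e-16); coefficients were never published, so only qualitative
reproduction on synthetic data is possible, and the published adjusted R²
span (0.11–0.29) likewise cannot be recomputed without the raw data.

## Pipeline

A YAML config (pydantic-validated before any computation; all defaults
echoed into the manifest) drives design → simulation or CSV ingest → PLFA
metrics → kriging per variable → LOO → selection. Every stochastic stage
has an explicit seed derived from the run seed; a manifest records the
config, its hash and per-stage row counts, and rerunning an identical
config reproduces outputs byte-for-byte. Coordinates are 0-based metres
from the plot's southwest corner throughout.

## Problem sizes used in tests and the acceptance script

Grid posteriors in tests use 8–40 points per axis and the recovery
experiment uses the 25 × 25 grid with 10,000 draws over 50 simulated
81-core plots at the reference truth (σ² = 1, φ = 2 m, τ²ʳᵉˡ = 0.7);
oracle-equivalence checks run on 3-point toys where quadrature is exact.
These sizes were chosen as the smallest at which each property is
informative. One caveat the recovery experiment quantifies honestly: at a
2 m grain the nugget is weakly identified against a φ = 2 m process, so the
posterior mean of the nugget ratio stays near its prior mean (≈0.58 under
the uniform [0, 4] relative-nugget grid) rather than the true 0.41 — the
same prior-dominance visible in the published posterior summaries, where
every nugget ratio is 0.72–0.83 with a 90% interval of roughly (0.16,
0.98) regardless of variable. Range-interval coverage (≥ 80% at 90%
credibility) holds.

## Known limitations

- Isotropy and Gaussianity are assumed; Matérn/spherical families, MCMC and
  anisotropic models are out of scope (the discrete-grid scheme *is* the
  method).
- The ¹⁵N mass-balance equations behind pool-dilution rates are upstream of
  this package; it consumes the resulting rates.
- The synthetic generator's compositional model understates cross-lipid
  correlation (see above).
- LOO refits on a reduced grid by default; full-grid refits are available
  but ~16× slower.
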