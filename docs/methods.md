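# Methods

## Scope and model assumptions

`mixsel` computes expected responses to **one** cycle of recurrent
truncation selection in two populations from different species improved for
their performance in mixture.  The analytical model is additive and
Gaussian: per progeny family a direct effect `v` (on the own species'
contribution), an associate effect `a` (on the partner's contribution), a
pair-specific direct × associate interaction `(va)`, and normal plot
errors.  Disomic inheritance and negligible epistasis are assumed, so the
cross-cycle change in population mean is entirely the selection response,
and with half-sib or topcross progeny families every parent–offspring
covariance is a constant multiple (`θφ`) of a between-family
variance/covariance.  Consequences built into the code:

- *After-recombination* responses contain only direct/associate
  (co)variances; interaction variances appear in the criterion variance
  `σI²` but never in the response covariances, because pairings are
  re-randomized each cycle and `(va)` is not transmitted.
- *Before-recombination* responses (selected pairs' own genetic values) use
  the full contribution components `σGx1² = σv1² + σa2² + σ(va)12²` etc.;
  under unit weights and `θφ = 1` the per-species transmission gap is
  `i·(σ(va)12² + Cov((va)12,(va)21))/σy`, and the total gap `i·σd²/σy`.
- Multi-cycle effects (drift, inbreeding, changing variances) are out of
  scope; responses are per-cycle expectations at the current parameter
  values.

All covariances are parameterized through correlations (`ρ·σx·σy`), since
that is how practitioners state them; a zero variance silently forces the
corresponding covariance to zero.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| `var_direct`, `var_associate` (per species) | between-family variances of v, a (trait²) | required |
| `rho_va` | corr(v, a) within a species | 0 |
| `var_va_12`, `var_va_21`, `rho_va12_va21` | interaction variances / correlation | 0 |
| `var_plot_error_mixture` | plot-error variance σε² of the mixture performance | 0 |
| `var_e1`, `var_e2`, `rho_e1_e2` | explicit split ε = e1 + e2 | see below |
| `eta`, `omega` | corr(p, v), corr(p, a) of the pure-stand effect | unset (required for pure-stand responses) |
| `pure_design_h2` | σp²/σyp.² of the pure-stand trial | 0.6 |
| `total_plots`, `replicates` | plot budget and observations per tested mixture (M) | 900, 3 |
| `selection_rate` | truncation fraction per species | scheme presets 0.10 / 0.20 |
| `theta_*`, `phi_*` | sexes under selection; progeny-type factor (1 half-sib, ½ topcross) | 1, 1 |

When only σε² is given, the error split defaults to
`σe1² = σe2² = σε²`, `ρ(e1,e2) = −0.5`, which reproduces σε² exactly and is
the standard index-selection setting; `consistent_error_split` generalizes
this to any `ρe > −1` via `σe² = σε²/(2+2ρe)` (used by the `s2`/`s3` grid
variants at `ρe = +0.5` so that ε = e1 + e2 stays consistent — the variant
source states only the changed correlation, and keeping the decomposition
consistent preserves the unit-weight criterion variance).

The equal-budget comparison fixes the design arithmetic: one pair-mixture
plot tests one candidate of *each* species, so the reciprocal scheme tests
`plots/M` candidates per species while the parallel schemes split the budget
over two processes (`plots/2M` each); with 900 plots and M = 3 that is 300
vs 150 tested, and rates 10% vs 20% select 30 candidates per species either
way (selected counts round half-up with a floor of one; the criterion is
continuous so ties are measure-zero, broken by candidate id in the
simulator).

## Selection intensity

`selection_intensity(rate)` is the infinite-population Gaussian value
`i = φ(z)/p` (1.755 at 10%, 1.400 at 20%).  `finite_sample_intensity(n, k)`
computes the exact expected mean of the top k of n standard-normal draws by
a single order-statistics quadrature,
`E = (n/k)∫ z φ(z) I_{Φ(z)}(n−k, k) dz`; at n = 300, k = 30 it is 1.7465
vs 1.7550.  Closed-form responses use the infinite-population value (the
convention of the underlying theory); Monte-Carlo comparisons evaluate the
closed forms at the finite-sample value, because at 500 replicates the
~0.5% order-statistics bias would otherwise be resolvable.

## Index tuning

**Reciprocal scheme.**  Weights meeting a before-recombination response
ratio `(k1, k2)` solve the linear system `G α = k` with `G` the 2×2 genetic
covariance matrix of the species contributions.  The system is rejected as
unsolvable when `|det G| ≤ 1e−12·σGx1²σGx2²` (perfectly correlated
contributions).  Weights are returned unnormalized — responses are invariant
under joint positive rescaling — and negative weights are legal (logged as a
warning).  The after-recombination ratio under a tuned index has no closed
target; it is reported, and equals `k1/k2` exactly only when the interaction
variances are symmetric.

**Parallel GMA scheme.**  Each process's responses are invariant under
positive rescaling of its own weight pair, so an index is one angle
`t ∈ (−π, π]`, `(α_own, α_comp) = (cos t, sin t)`, and the pair lives on a
2-torus.  Both the objective (cumulated mixture response) and the constraint
(product form `k2·ΔGx1 − k1·ΔGx2 = 0`, avoiding division near zero
responses) separate into single-angle terms `f1(t1)+f2(t2)` and
`h1(t1)+h2(t2)`.  The optimizer scans a 1°-step torus grid to locate every
branch of the constraint zero set (it can be disconnected), then polishes
the best branches derivative-free: `t2` is solved from `t1` by bracketed
Brent root-finding on the constraint (xtol 1e−13) and the objective is
maximized over `t1` by bounded scalar minimization (xatol 1e−10).  The
result must satisfy the constraint to 1e−6 relative to `|ΔGG|` (in practice
~1e−15) and is certified in the tests against a 721×721 interpolated grid
oracle with an allowed gap of 1e−4.  Both halves of the torus are searched;
a negative companion-species process response may be optimal.  Because the
per-angle constraint terms are antipodally antisymmetric, the product-form
constraint is never globally infeasible for valid parameters; the
infeasible-target error path is defensive.

Note that plain selection (equal weights) does not generally maximize the
cumulated response even for symmetric species: the error covariances enter
the index variance, so the constrained optimum at a symmetric 1:1 target is
a mirrored, slightly unequal weight pair with a response marginally above
the plain value.

## Monte-Carlo oracle

`simulate_cycle` realizes the model literally: per replicate it draws
`(v, a)` per candidate from the bivariate normal, interaction pairs and
correlated plot-mean errors where the scheme calls for them, forms the
index, selects exactly the top k, and measures gains as `θφ` times the mean
transmitted effects of the selected parents (before-recombination gains add
the selected pairs' interaction means).  Transmission is represented by the
`θφ` coefficient rather than explicit meiosis — the oracle tests the
covariance algebra, which already averages over Mendelian sampling.
Replicate r uses the stream seeded `(base_seed, r)`, so results are
reproducible and independent of execution order; swapping the seed moves
the draws but not the acceptance outcome of the 3-standard-error bands.
The test suite uses 500 replicates of the standard 300-pair (reciprocal) or
150-family (parallel) designs, and a single 50,000-pair draw for criterion
variances.

What the simulator does *not* emulate about real data: non-Gaussian or
heteroscedastic plot errors, spatial field structure, genotype × environment
interaction, estimation error in the variance components (which are inputs,
not estimates — the package performs no variance-component estimation), and
any multi-cycle dynamics.  Agreement of the closed forms with this oracle
therefore validates the algebra under the model's own assumptions, not the
model's fit to field data.

A caveat on the pure-stand module: the grid settings pair `η`, `ω` and
`ρ(v,a)` freely, and some textbook combinations (e.g. η = 0.75, ω = 0.5,
ρ = −0.75) are pairwise valid but make the joint (p, v, a) correlation
matrix indefinite.  The closed forms only ever use pairwise covariances and
remain well-defined; the simulator, which needs the joint distribution,
checks positive semidefiniteness and refuses such settings.  Its tests use
a jointly valid point (η = 0.5, ω = 0.3, ρ = −0.25).

## Numerical conventions

- Algebraic identities are tested at 1e−12 relative; solver round-trips at
  1e−9; Monte-Carlo bands at 3 standard errors.
- The correlation grid of the preset studies uses 17 points (−1 to 1, step
  0.125); the grid resolution is a package constant, not a claim about any
  external figure, and curve values are never asserted numerically — only
  signs, orderings and monotonicities.
- One ordering is asserted in relative rather than absolute form: the gap
  between the two species-contribution responses under parallel GMA
  selection, `i(σa1²−σv²)/σy1 + i(σv²−σa2²)/σy2`, is not monotone in ρ for
  every variance panel, while the gap divided by the total response is;
  the reciprocal-scheme gap `i(σa1²−σa2²)/σy` is monotone as-is.
- Degenerate inputs: a zero criterion variance raises (responses divide by
  `σI`); zero-variance effects force their covariances to zero; grid rows
  with unsolvable index targets are retained with a `status` column.

## Design choices

- Parameter containers are pydantic models with `extra="forbid"`, so a
  misspelled JSON key fails validation instead of silently dropping a
  correlation.
- The pure-stand criterion is parameterized by design heritability (with a
  `from_trial` constructor for the (σp², σεp², M′) triple), matching how
  such trials are usually summarized.
- Equal selection intensity in both species is built into the reciprocal
  scheme (a single rate; pairs are selected jointly), which is also the
  condition under which the before-recombination expectations hold.
- The library functions are the primary interface; the `mixsel` CLI is a
  thin layer for shell use (`srma`, `sgma`, `pure`, `validate`, `figures`).
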