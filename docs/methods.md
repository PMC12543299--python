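# Methods

## Model

`mlggm` estimates networks from nested time-series data: raw observations
(e.g. BOLD signals) nested in participants nested in a population.  The
joint posterior factorizes as

    p(G, S_1, …, S_N | data) ∝ ∏_n  p(data_n | S_n) · p(S_n | G) · p(G),

where `S_n = (Ω_n, γ_n)` is participant *n*'s network — a precision matrix
and its edge indicators — and `G = (μ, σ)` is the group-level network.
The group explains *all* commonalities between participants: conditional
on `G`, the `S_n` are independent.

**Individual level — Gaussian graphical model.**  The centered (optionally
standardized) series `x_t ~ N(0, Ω⁻¹)` i.i.d. over time points.  A zero
off-diagonal `ω_ij` means conditional independence of nodes i and j; the
partial correlation is `r_ij = −ω_ij / √(ω_ii ω_jj)`.  The prior is
spike-and-slab on off-diagonals — `ω_e | γ_e ~ N(0, v1²)` if the edge
indicator `γ_e = 1`, else `N(0, v0²)` with `v0 ≪ v1` — and exponential on
diagonals (`∝ exp(−λ ω_pp / 2)`; `λ` is the package's rate convention),
all truncated to the positive-definite cone.

**Group level — Curie-Weiss model.**  The edge indicators of every
participant share the exponential-family distribution

    p(γ | μ, σ) = Z(μ, σ)⁻¹ exp( Σ_e γ_e μ_e + (σ/E)·s² ),   s = Σ_e γ_e,

with per-edge main effects `μ_e` (log-odds scale) and a single average
pairwise interaction `σ ≥ 0` acting through the squared edge count.  The
interaction is divided by `E` so that `σ` is the *average* pairwise
coupling; an unscaled parameterization is recovered by passing `σ·E`.
At `σ = 0` the edges are independent Bernoulli(logistic(`μ_e`)).

All Curie-Weiss computations run through the Hubbard–Stratonovich
(latent-tilt) representation: `Z = E_t[ ∏_e (1 + exp(μ_e + t)) ]` with
`t ~ N(0, 2σ/E)`.  Conditional on `t` the edges are independent, which
yields one-dimensional quadrature for `Z` and the marginals, and an exact
i.i.d. sampler (draw `t` by inverse CDF on a dense grid, then independent
Bernoulli edges).  An exact `O(E²)` route via elementary symmetric
polynomials (`count_dp`) serves as the reference; the two agree to
~1e−12 relative in routine testing.

## Gibbs sampler

One cycle alternates:

1. **Participants (parallelizable).**  For each `n`: redraw all `γ_en`
   Bernoulli with log-odds = slab/spike density ratio at the current
   `ω_e` + the Curie-Weiss full-conditional prior log-odds
   `μ_e + (σ/E)(2·s_{n,−e} + 1)`; then one pass of column-wise block
   Gibbs over `Ω_n` (the stochastic-search construction: each column's
   off-diagonal block has a conjugate normal conditional, the Schur
   complement a gamma conditional — positive definiteness holds by
   construction and is asserted in tests).
2. **Group.**  Random-walk Metropolis sweeps over each `μ_e` and over
   `log σ` (priors: `N(0, 10²)` per `μ_e`, half-normal(1) on `σ`), with
   `log Z` evaluated on a trapezoid grid over the latent tilt.

Baselines re-use the same machinery: the *individual* analysis freezes
the group at `(μ, σ) = (0, 0)` (prior inclusion probability ½, no
pooling); the *aggregate* analysis inverts each participant's sample
covariance, averages the precision matrices, and fits one GGM to the
scatter implied by the averaged precision with `T_eff = round(mean T_n)`
pseudo-observations (ridge `10⁻³·tr(S)/P` only when `T ≤ P` or inversion
fails).

Retained indicator draws are stored bit-packed (1 bit per participant ×
edge × iteration).  Reported summaries: per-(participant, edge) inclusion
probabilities and posterior partial-correlation means; group-level edge
probabilities as the posterior mean of the model-implied Curie-Weiss
marginals over retained `(μ, σ)` draws (the posterior probability of
`μ_e > 0` is recoverable from the stored draws if preferred); inclusion
Bayes factors (posterior over prior inclusion odds; ≥ 3 include, ≤ 1/3
exclude); convergence via classic split-chain R̂ for all Curie-Weiss
parameters with the < 1.05 working criterion.

## Numerical choices

- **Quadrature.**  A Gauss–Hermite rule centered at `t = 0` cannot track
  the tilted density, whose mode sits up to `√(σE)` standardized units
  away; `cw_log_z`/`cw_marginal_probs` therefore use *mode-centered*
  adaptive Gauss–Hermite (64 nodes; mode by bracketed root-finding,
  width from the log-density curvature), still a pure deterministic
  function of `(μ, σ)`.  Inside the group update the grid must not move
  with `μ` (otherwise per-edge caching breaks detailed balance), so
  `log Z` there uses a trapezoid grid on `[−8τ, 2σ + 8τ]`,
  `τ = √(2σ/E)`, spacing `τ/4` (256–4097 points) — a pure function of
  `σ` alone; the tilt mode always lies in `[0, 2σ]` and the density
  width is ≥ ~τ, so the rule is accurate to well below 1e−10 relative.
  Exact sampling uses a 2049-point mode-centered grid (±12 widths) for
  the inverse CDF.
- **Proposal adaptation.**  Robbins–Monro on the log step sizes toward
  0.44 acceptance during burn-in, frozen afterwards so the post-burn-in
  kernel is fixed.  A group state entering the update with `σ = 0`
  restarts at `σ = 0.01`, since the log-scale walk cannot leave zero.
- **Determinism.**  Every participant update at (chain c, iteration i,
  participant n) draws from a stream seeded by the master seed and the
  key (c, i, n); the group update uses key (c, i, 0).  Results are
  therefore bitwise identical for any number of parallel workers and
  across reruns.
- **Update order.**  Indicators first, then columns 1..P ascending;
  chains are initialized at `Ω = I`, `γ = 0`, `μ = 0`, `σ = 0.05`.
- **Degenerate inputs.**  Constant columns fail standardization with the
  node named; participants with `T = 0` sample the prior; a singular
  averaged precision in the aggregate baseline raises with a ridge
  suggestion.

## Defaults and their rationale

| parameter | default | meaning |
|---|---|---|
| `v0`, `v1` | 0.02, 1.0 | spike/slab sds; 50× ratio, scale-meaningful with standardized data |
| `λ` | 1.0 | diagonal exponential rate (`exp(−λω/2)` convention) |
| `μ` prior sd | 10 | weakly informative |
| `σ` prior | half-normal(1) | ferromagnetic regime only (`σ ≥ 0`) |
| iterations / burn-in / chains | 2000 / 500 / 2 | desk scale; tests use smaller |

## Simulator

The generator mirrors the model: Erdős–Rényi group graph (edge
probability `density`, default 0.16); per-edge main effects from
sign-truncated normals — `N(+2.73·r, (2.33·r)²)` truncated positive at
group-present edges, `N(−3.16·r, (3.35·r)²)` truncated negative at
group-absent edges, `r = ρ/100` — so the homogeneity percentage ρ scales
location *and* spread linearly, `ρ = 0` gives `μ = 0` (independent
participants, every edge a coin flip) and `ρ = 100` matches cohesion as
estimated on a large resting-state fMRI cohort; Curie-Weiss `σ = 0.1`;
individual graphs by exact Curie-Weiss sampling; precision matrices from
a G-Wishart(3, I) restricted to each graph; series i.i.d.
`N(0, Ω⁻¹)`.  At `ρ = 30` the cohorts show the characteristic
discordance — individuals add ≈26% of the group-absent edges and miss
≈28% of the group-present ones (recomputed by `scripts/acceptance.py`).

G-Wishart draws use the direct scheme: unconstrained Wishart draw, then
cyclic per-node maximum-determinant completion of the implied covariance
over non-neighbor entries (tolerance 1e−9), then inversion; non-edge
entries are forced to exact zeros and positive definiteness re-verified.
Tests check the exact closed forms at the empty and complete graphs and
an independent Cholesky-construction sampler (valid for decomposable
graphs) on a path graph.

The mixture (misspecification) scenario flips `round(0.2·E)` edges of
the group graph to create a second group; at flipped edges `μ` is
redrawn with the sign matching the new state, elsewhere kept — isolating
the manipulated difference.  The homogeneous/heterogeneous pair used in
misfit illustrations is generated with `ρ = 100` vs `ρ = 30`.

**What the simulator does not emulate:** temporal autocorrelation within
a scan (time points are exchangeable), non-Gaussian margins, missing
data, scanner/site effects, and any spatial structure of real
parcellations.  Passing tests therefore demonstrate correctness of the
estimator under its own generative assumptions, not robustness to
violations of them.

## Known limitations and notable behavior

- The spike-and-slab prior is truncated to the positive-definite cone,
  which penalizes slab-heavy configurations: the *prior* edge-inclusion
  probability is slightly below ½ at the default `λ = 1` (≈0.42 at
  P = 2; confirmed against exact 2-D numerical integration).  The
  fair-coin reading of "prior inclusion probability ½" is exact only
  when diagonals are large relative to `v1` (small `λ`); tests verify
  the ½ limit at `λ = 0.1`.
- Prior-only spike/slab chains (no data) mix slowly between modes;
  with data this is immaterial.
- `σ < 0` (edge repulsion) is outside the supported regime — the
  integral representation requires `σ ≥ 0`.
- The aggregate baseline's `T_eff` is a convention (exposed as a flag);
  aggregation discards between-participant variance by design — that is
  the point of the comparison.
- The multimodality flag (largest adjacent gap in sorted per-participant
  AUCs > 5× the median gap) is a screening heuristic: sensitive to true
  subgroup structure but prone to firing on small cohorts; inspect the
  ROC bundles before concluding misfit.
- Test and example problem sizes (P ≤ 20, N ≤ 50, hundreds to a few
  thousand sweeps) are desk-scale choices; production analyses should
  use the defaults or larger and check R̂.
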