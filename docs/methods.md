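# Methods

This note documents the models implemented in `ammodiv`, the priors and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations. Ages are in Ma (before
present); durations in Myr; rates in events · lineage⁻¹ · Myr⁻¹.

## Occurrence cleaning

An occurrence is a dated (`max_ma > min_ma ≥ 0`), located, classified fossil
record. Cleaning applies three independent screens:

* **Age uncertainty.** Rows whose dating interval *exceeds* 10 Myr are
  removed; the boundary case is kept (strict inequality, so a
  10.0 Myr-resolved occurrence survives).
* **Reference ranges.** Each occurrence is compared with its genus'
  reference stratigraphic range. Only intervals lying *wholly* outside the
  range are flagged (`older_than_range` / `younger_than_range`); partial
  overlap is `straddles`, unknown genera are `no_reference`. The flags
  partition the table and never modify it.
* **Range tails.** Per genus, occurrence intervals are densified at 0.1 Myr
  into an age-frequency profile (histogram, or a Gaussian kernel with
  Silverman's bandwidth). The tails are the spans outside the profile's 5 %
  and 95 % quantiles; a genus whose tails occupy more than a chosen share
  (30–40 %) of its duration is flagged, along with the occurrences lying
  entirely inside a tail. The quantile reading means an isolated outlier
  separated from the core range by a long gap produces a long tail even
  though it carries little probability mass — which is exactly the
  misidentified-straggler pattern the screen exists to catch.

**Age randomisation.** Point ages are drawn uniformly within each
occurrence's interval, with all occurrences of one locality sharing a draw
from the *intersection* of their intervals; localities whose intervals are
inconsistent fall back to independent draws with a logged warning (the
choice is arbitrary — real data rarely hits it because locality members
share their dating). Replicate *k* uses seed `root_seed + k`, so any
replicate regenerates in isolation.

## Spatial standardisation

* **Grid.** The sphere is tessellated into the Voronoi cells of an
  icosahedron subdivided at frequency *f* (`10f² + 2` cells: 12 pentagons,
  the rest hexagons), so cell areas carry no latitudinal distortion. Points
  map to the nearest cell centroid by great-circle distance; ties break to
  the smallest cell id. The grid resolution is a free parameter (default
  *f* = 8, ≈ 642 cells, ~800 km spacing).
* **Extent.** Spatial extent of a stage/region sample is the summed
  great-circle length of the minimum spanning tree over occupied cell
  centroids (Earth radius 6371.0088 km, the IUGG mean). A single occupied
  cell has extent 0.
* **Pruning.** To standardise extent, the degree-1 (tip) cell with the
  fewest occurrences is removed (ties to the smallest id) and the MST
  recomputed, repeatedly; because the length is non-increasing along this
  path, |length − target| falls and then rises, and the first state at the
  minimal gap is returned. Recomputing the full MST each step (rather than
  subtracting the tip edge) is the contract: it stays correct if removal
  re-shapes the tree.
* **Windows.** Drifting bioprovinces are tracked by a fixed-size lon/lat
  window anchored on the oldest stage's occurrence centroid, drifting at a
  constant bearing and per-stage step; a coarse deterministic grid search
  (bearings every 15°, steps every 0.5°, small anchor offsets) maximises
  retained occurrences, with ties going to the smallest total displacement.
* **Coverage-standardised richness.** Sample coverage of the full sample is
  estimated with the Chao–Jost singleton/doubleton correction. The
  rarefaction curve (expected richness and expected within-sample coverage
  of all without-replacement subsamples, computed hypergeometrically) is
  rescaled to end at that estimate, and richness is linearly interpolated at
  the quorum (never below one individual). A quorum above the full-sample
  coverage triggers Chao-style extrapolation and is flagged. The
  within-sample expectation definition makes the estimator exactly
  verifiable against exhaustive subsample enumeration.
* **Correlations.** One-tailed Pearson and Spearman tests of
  "larger extent → larger diversity"; the Spearman p-value is an exact
  permutation fraction for n ≤ 8.

## Birth–death–sampling inference

Each lineage *i* has a latent origination age `ts_i` and extinction age
`te_i`. The log-likelihood has two factors:

* **Birth–death.** `Σ ln λ(ts_i) + Σ_extinct ln μ(te_i) − Σ ∫_[te,ts] (λ+μ)`,
  with λ(t), μ(t) piecewise constant and the integrals exact. Every lineage
  is an extinction event unless flagged extant (then `te = 0` is fixed and
  no μ term accrues). No tree topology is used: each origination is an
  independent λ event, appropriate when occurrence data carry no phylogeny.
* **Preservation.** Occurrences are a Poisson process with rate q(t) on
  `[te, ts]`, conditioned on at least one occurrence per observed lineage:
  `Σ_j ln q(a_j) − ∫_[te,ts] q − ln(1 − e^{−∫q})`. q is homogeneous (HPP) or
  piecewise constant per geological stage (TPP); the stage bins are extended
  beyond the study frame (to age 0 and to a 400 Ma ceiling) so sampled times
  outside the frame keep a defined rate. The distance-from-endpoints
  (NHPP) variant is deliberately not implemented and raises an explicit
  error: the TPP captures time-varying preservation including its total loss
  after a clade's true extinction, which the alternatives cannot.

A maximum-likelihood model test fixes durations at the observed first/last
point ages and compares HPP vs TPP by AIC (`2k − 2 lnL`); single-age
lineages carry no information under the conditioned likelihood and are
excluded, and bins without lineage time keep a floor rate and no free
parameter.

**Priors.** Frame rates λ, μ ~ Gamma(2, 1); number of shifts per rate ~
Poisson(1), shift positions uniform in the edge window (113.2–66 Ma by
default, which confines shift detection to the adequately sampled span);
q bins ~ Gamma(shape 1.5, rate β) with β ~ Exponential(mean 1), updated by
its conjugate Gibbs step.

**Sampler.** One move per iteration: a vectorised sliding-window update of
every lineage's `ts`/`te` (reflected at the stratigraphic bounds — a
lineage can never be younger than its oldest occurrence interval allows);
multiplier updates of single λ/μ frames and q bins; and reversible-jump
add/delete/move of rate shifts. Add draws the new frame rate from its
prior, so the Jacobian is 1 and the acceptance ratio reduces to
`ν/(k+1)` (add) and `k/ν` (delete) times the likelihood ratio; a
likelihood-free run therefore leaves the Poisson(ν) shift-count prior
invariant, which the test suite verifies by a χ² goodness-of-fit at 10⁴
thinned samples. Shift moves are confined between neighbouring shifts so
frames keep their identity and the proposal stays symmetric. Default
desk-scale run: 200 000 iterations sampled every 100; the cluster-scale
setting (10⁸ iterations) is a config value, not a code change.

**Summaries.** Chains from the age-randomised replicates are combined after
a 10 % burn-in each. Rates-through-time reports the posterior mean and 95 %
HPD (shortest interval holding ⌈0.95 n⌉ sorted samples) of the frame rate
active at each grid age; shift support per stage bin is
`2·ln[(p/(1−p)) / (p₀/(1−p₀))]` with p the posterior and p₀ the prior
probability of ≥ 1 shift in the bin (thresholds 2 and 6 on this scale).
Range-through diversity counts lineages with `ts ≥ t > te` per posterior
sample on a 0.5 Myr grid, summarised by central 75 % and 95 % intervals.
The likelihood ESS (autocorrelation-based, via `arviz`) is reported per
replicate chain, with a warning below 200.

## Driver model (multivariate birth–death)

Drivers are linearly interpolated onto a 0.1 Myr grid spanning
100.5–68 Ma (stopping short of the terminal mass extinction, whose pulse
would otherwise dominate any regression) and min–max rescaled to [0, 1].
The clade's own range-through diversity, computed from the input lineage
times and rescaled the same way, is appended as a diversity-dependence
driver. Rates follow either `r(t) = r₀ exp(Σ G_l x_l(t))` or
`r(t) = max(ε, r₀ (1 + Σ G_l x_l(t)))` with ε = 10⁻¹⁰ guarding the linear
link against negative rates.

Under the exponential link the log-rate is piecewise linear between grid
knots, so each segment's exposure integral has the closed form
`h (e^{g₂} − e^{g₁}) / (g₂ − g₁)`; under the linear link the trapezoid rule
is exact. Exact segment integration (rather than a trapezoid approximation
of the exponential) keeps the likelihood within 10⁻⁶ of brute-force
quadrature.

`G_l ~ Normal(0, τ²ψ_l²)` with local ψ_l and global τ scales half-Cauchy(0,1)
— the horseshoe — sampled through the inverse-gamma parameter expansion
(clamped to [10⁻¹⁰, 10¹⁰] for numerical safety). The shrinkage weight
`W_l = E[ψ_l²τ² / (1 + ψ_l²τ²)]` measures escape from the spike at zero;
`W > 0.5` flags a significant driver. Baselines carry Gamma(2, 1) priors.
Link functions are compared by AICM (`−2(mean lnL − var lnL)`) and the
harmonic-mean log marginal likelihood (stable log-sum-exp), declared
indistinguishable when |ΔAICM| < 2 and |logBF| < 2.

## Trait-dependent extinction

Within the same 100.5–68 Ma window, lineage *i*'s extinction rate is
`μ_i = μ̄ · Π_t δ_{t,cat_t(i)}` over *included* traits; the log-likelihood is
`Σ_i [extinct_i ln μ_i − μ_i d_i]` with `d_i` the within-window duration and
right-censoring for lineages outliving the window. Category multipliers are
parameterised as `δ_c = exp(z_c − z̄)` (geometric mean 1 per trait, which
makes them identifiable against μ̄) with `z_c ~ Normal(0, σ_t²)` and the
per-trait spread σ_t under a half-Cauchy(0, 0.2) prior truncated at 1.5 —
the truncation keeps the null-model Bayes factor of a no-effect trait near
1, so the posterior inclusion frequency of an effect-free trait sits near
its prior, while still admitting multipliers beyond e^±3. Per-trait
inclusion indicators carry a Bernoulli(0.05) prior (95 % prior mass on no
effect) and are flipped by Metropolis steps against the always-maintained
latent multipliers (Kuo–Mallick style); when a trait is off, its latent
spread and multipliers are refreshed from the same truncated prior, so both
branches target one joint distribution. μ̄ has a conjugate gamma update.
Significance requires a posterior inclusion frequency strictly above
51.4 % — the posterior probability matching logBF > 6 at the 5 % prior,
via `posterior odds = e^{logBF/2} · prior odds`. Traits with a single
category in the data are excluded (no contrast); categories absent from a
region's data are structurally missing, not multipliers of 1.

## Synthetic records

The generator composes: an exact event-driven birth–death simulation
(piecewise-constant or grid rates; survivors at the window end are flagged),
per-lineage Poisson preservation, substage dating (each stage split into
three equal dating intervals, emulating the mostly substage-level resolution
of well-curated records — mean interval ≈ 3.5 Myr), shared localities per
substage, half-normal great-circle scatter of localities around regional
centres, smoothed Gaussian-random-walk drivers rescaled to [0, 1], optional
exponential-link driver effects and per-suborder extinction multipliers, and
a suborder → superfamily → genus taxonomy. The truth (rates, effects, true
times, true occurrence ages, unsampled lineages) serialises to JSON and
round-trips exactly.

What it does **not** emulate: facies- or depth-structured preservation,
plate motion (regions are static), taxonomic error, synonymy, or
correlated dating errors between localities. Tests passing on these records
therefore demonstrate the *inference machinery* is correct and calibrated
under the stated model, not that real-data biases beyond temporal/spatial
sampling are handled.

## Validation experiments and problem sizes

All experiments are seeded and deterministic.

* **Constant-rate recovery**: λ = 0.25, μ = 0.15, q = 1.5 over a (42, 0) Ma
  window, ~150 lineages per run (survivors flagged extant), 20 runs of
  200 000 iterations; each rate's time-averaged 95 % HPD must cover the
  truth in ≥ 18 runs (per-parameter coverage, the standard calibration
  check).
* **Prior recovery**: a likelihood-free run; 10⁴ thinned samples of the
  shift count must match Poisson(1) in mean (±10 %) and by χ² fit.
* **Driver recovery**: one extinction driver at G = 1.5 plus two decoys,
  ~1 400 lineages (sized so the expected log-likelihood gain
  ≈ ½G²·D·Var(x) of the true effect is ~50, which a lone horseshoe effect
  needs to clear W = 0.5), 10 simulations: the true driver must reach
  W > 0.5 with the correct sign and the decoys stay below, in ≥ 8.
* **Trait recovery**: one suborder with a 3× extinction multiplier among
  five, ~400 lineages, 10 simulations: the trait must exceed the 51.4 %
  threshold in ≥ 8 while effect-free traits stay within [1 %, 15 %].
* **Pipeline**: the desk-scale default configuration (≈ 3 000 occurrences,
  2 age replicates, 20 000 iterations) runs end to end in well under a
  minute per stage.

## Known limitations

* **Unobserved lineages.** The likelihood conditions each *observed*
  lineage on ≥ 1 occurrence but cannot see lineages that left no fossils at
  all — a fraction μ/(μ+q) of extinct lineages (≈ 9 % at μ = 0.15,
  q = 1.5). Their missing birth and death events bias both rates slightly
  downward (measured ≈ −5 % on λ and −8 % on μ in the constant-rate
  experiment), so *joint* per-run HPD coverage of both rates sits below the
  product of the per-parameter coverages. This is a property of the model
  family, shared by standard fossil birth–death–sampling implementations;
  it shrinks as preservation improves.
* The MST-pruning target is user-supplied per region/stage; the package
  does not choose it.
* Preservation heterogeneity *between* lineages (gamma-distributed rate
  multipliers) is not modelled; neither are lagged or interacting drivers,
  trait-dependent origination, or time-varying trait effects.
* The harmonic-mean marginal likelihood is known to be high-variance; it is
  used only for the coarse link-function comparison, alongside AICM.
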