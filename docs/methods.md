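# Methods

This note documents the models, the synthetic data they are exercised
on, the numerical choices, and the limitations a user should know
before pointing the package at real data.

## Neutral community model

The fit follows the occupancy–abundance formulation: for each taxon,
its metacommunity abundance p is estimated as the mean relative
abundance across samples, its occurrence frequency as the fraction of
samples in which it is detected, and the single parameter Nm is chosen
to minimize the squared deviation between observed frequencies and the
model's detection curve. N is the mean sample read total (a `median`
option exists), the detection limit d = 1/N (one read), and taxa with
zero mean abundance or zero occurrence are excluded since their Beta
parameters are undefined.

**Detection model.** Two curves are available:

* `threshold` — the classical sharp cutoff, freq = 1 − BetaCDF(d; Nm·p,
  Nm·(1−p)), exposed as `predicted_frequency`;
* `betabinomial` (default) — the exact probability of observing at
  least one read when a latent Beta abundance is sampled to depth N,
  1 − B(Nm·p, Nm(1−p)+N) / B(Nm·p, Nm(1−p)).

The two agree as N grows, but at realistic read depths the detection
event is soft — P(detect | x) = 1 − (1−x)^N, not a step at x = d — and
fitting the sharp threshold to multinomially sampled counts
overestimates m by roughly 15–25%. With the Beta-binomial curve the
immigration rate is recovered essentially without bias (≤ 2% median
error across m ∈ {0.01, 0.05, 0.2} at N = 10⁴, 200 samples, 300 taxa,
measured by the test suite). The threshold form is retained both for
comparability with the classical formulation and for fitting frequency
points that do not come from counts (`fit_frequencies`).

**Optimizer.** The SSE is scanned on a dense grid of 281 points in
log(Nm) over [10⁻³, 10⁷] and the best bracket is refined by bounded
scalar minimization (xatol 10⁻⁸ in log space). The global scan removes
any dependence on starting values.

**Uncertainty.** Bootstrap resamples taxa — the points of the
occupancy–abundance plot — with replacement, 1000 replicates by
default, percentile 2.5/97.5 intervals for m and R². Because taxon
resampling is equivalent to multinomial reweighting of a fixed residual
grid, all replicates reduce to a single matrix product followed by
parabolic refinement of each replicate's grid minimum; resampling
samples instead is available (`bootstrap_unit="samples"`) but slower.
The above/neutral/below partition places a Wilson score band (95% by
default, n = number of samples) around the fitted curve; a 10⁻⁹
tolerance guards the saturated ends where the band collapses onto 0
or 1.

## Phylogenetic and Raup–Crick null models

βMNTD between two communities is the mean, over each community's
present taxa weighted by renormalized relative abundance (uniform
weights optional), of the cophenetic distance to the nearest taxon in
the other community, averaged over the two directions. Cophenetic
distances are tip-to-tip path lengths; every non-root branch must carry
a length.

The βNTI null shuffles taxon labels across the whole distance matrix —
one shared permutation per null round applied to all pairs (999 rounds
by default), which is the standard scheme and lets all pairs share the
permutation cost. βNTI is the z-score of the observed βMNTD against the
null sample (sd with n−1). Pairs with zero null spread (e.g.
compositionally identical samples) are reported as undefined rather
than failing the run. Because the z-score is scale-free, βNTI is
invariant to multiplying all branch lengths by a constant.

The RC null reassembles each community of a pair at its observed
richness and read total: taxa are drawn without replacement with
probability proportional to metacommunity occupancy (via the Gumbel
top-k trick, which vectorizes across null rounds), each drawn taxon is
seeded with one read, and the remaining reads are allocated
multinomially proportional to metacommunity relative abundance among
the drawn taxa — so realized richness always equals observed richness.
RC = 2·((#null BC below observed + ½·ties)/n_null − ½) ∈ [−1, 1]; ties
count half, so a degenerate all-tie comparison gives RC = 0 exactly.
The metacommunity weights default to the input matrix itself and can be
supplied explicitly, which is how the self-calibration experiment
judges null-assembled pairs against the metacommunity that generated
them.

Classification uses the conventional thresholds: βNTI > 2 variable
selection, βNTI < −2 homogeneous selection; otherwise RC > 0.95
dispersal limitation, RC < −0.95 homogenizing dispersal, else
undominated. Pairs are formed within declared groups (lake × fraction
by default); cross-group pairs are computed only on request.

## Compositional stability

Stability at time t is s_t = 1 − BrayCurtis(rel_{t−1}, rel_t) on
depth-aggregated (counts summed within lake × fraction × month)
relative abundances, bounded in [0, 1]; the average stability index of
a group is the arithmetic mean of its transitions. This
consecutive-pair convention is a declared choice — baseline-referenced
and window-averaged variants are reasonable alternatives — and two
other kernels are selectable for sensitivity analysis: presence/absence
Jaccard similarity and a Spearman rank-correlation variant (clipped to
[0, 1] to keep the index's range). Irregular sampling gaps are used
as-is; no interpolation. For per-sample alignment (needed by PLS-PM),
each sample receives the transition ending at its time point, and
samples at the first time point receive the first transition's value.

## PLS path modelling

All blocks are reflective (mode A). Manifests are standardized (sd with
n−1); latent scores are standardized weighted sums of their block.
Inner weights follow the chosen scheme — centroid (default; sign of the
score correlation), factor (the correlation), or path (regression
coefficients toward predecessors, correlations toward successors) — and
the mode-A update sets each outer weight to the covariance of its
manifest with the block's inner proxy. Convergence is declared when the
normalized outer weights change by less than 10⁻⁶ (300 iterations
maximum, then a fit error with the last delta). Each latent variable is
oriented so the sum of its loadings is positive; bootstrap replicates
are instead aligned to the full-data outer weights so replicate path
signs are comparable. Path coefficients are OLS of each endogenous
score on its predecessors' scores; GoF = √(mean communality × mean R²)
holds as an identity of the returned quantities. With single-indicator
blocks the machinery degenerates exactly to correlations/standardized
OLS, which the tests exploit as closed-form oracles.

Bootstrap p-values are two-sided percentile tests of zero (twice the
smaller tail fraction, capped at 1) rather than normal-theory t-tests,
because the bootstrap distributions of PLS paths are skewed at small n.
The significance flag uses α = 0.1, the conventional threshold in this
literature. Indirect effects sum the products of coefficients over all
simple directed paths of length ≥ 2 (the inner model is required to be
acyclic).

The shipped block template — salinity {salinity, conductivity},
nutrients {NO3, PO4, NH3, SO4, DOC}, physicochemical {temperature, DO,
pH, fDOM}, particles {turbidity}, richness {richness} → stability, with
the four driver blocks also acting through richness — is an editable
reconstruction of the conventional layout for environment→stability
questions, not a fixed contract.

## Synthetic data

* **Trees** are pure-birth (Yule, rate 1) with tips relabelled
  deterministically; the process is run past the n-th speciation by one
  exponential waiting time so all branch lengths are positive and the
  tree stays ultrametric.
* **Neutral communities** draw each taxon's latent relative abundance
  from the Sloan stationary Beta, renormalize across taxa, and sample N
  reads multinomially. The default metacommunity abundance distribution
  is lognormal(0, 1.5) normalized — a long right tail that exercises
  the rare-taxon regime the NCM fit is sensitive to; a Fisher
  log-series option exists.
* **Selection-structured communities** evolve niche optima by Brownian
  motion on the tree (so optima carry phylogenetic signal, which βNTI's
  interpretation requires) and weight a lognormal base abundance by a
  Gaussian fitness kernel of (trait − environment) with width σ; σ → ∞
  recovers environment-independent sampling.
* **Lake campaigns** produce one sample per (lake, month, depth,
  fraction). Composition per lake × fraction performs a latent
  log-abundance random walk whose innovation sd is the `turnover`
  parameter; in "gradient" lakes a salinity-selection increment (also
  scaled by turnover) pushes composition with a seasonal salinity
  sinusoid peaking in late summer, mimicking seawater intrusion, while
  "stable" lakes hold salinity near constant. Read sampling is
  multinomial, but the sampling RNG is seeded by a hash of the latent
  composition state, so identical composition yields identical reads —
  this makes `turnover = 0` give a stability index of exactly 1 at
  every step, a useful identity for testing, at the cost of read noise
  not being independent across repeated visits to the same state.
  Metadata (temperature, DO, pH, fDOM, turbidity, conductivity,
  nutrient and ion concentrations, DOC) carries seasonal and
  trophic-state structure with observation noise.

Default campaign sizes (two lakes × 8–12 months × 2 depths × 2
fractions, 120–150 taxa, a few thousand reads per sample) are chosen so
a full pipeline run completes in seconds; they are configuration, not
claims about any particular field campaign, which typically has more
taxa, deeper sequencing and gappier sampling.

**What passing tests do and do not show.** The generators satisfy
exactly the assumptions each method makes (Beta-multinomial neutrality,
Brownian niche conservatism, fixed-richness null exchangeability), so
calibration and recovery results here demonstrate internal correctness
of the implementations — not that real lake communities meet those
assumptions. Real data add compositional biases, sequencing error,
unmodelled temporal autocorrelation, and phylogenies with estimation
error, none of which the synthetic module emulates.

## Numerical conventions

* Samples are rows, taxa columns, everywhere; Bray–Curtis is computed
  on relative abundances by default (counts by flag); rarefaction is
  available but off by default.
* All generators and resampling procedures are pure functions of
  (configuration, seed); the pipeline fans one root seed out to
  per-stage seeds through a deterministic counter, and two runs from
  one config are byte-identical.
* Undefined statistics (zero null spread, empty groups) warn and are
  excluded from summaries with separate counts, rather than aborting a
  run.

## Known limitations

* No forward-time (Hubbell) neutral dynamics; the stationary form only.
* Mode-B (formative) blocks, higher-order constructs and multi-group
  comparisons are not implemented in the PLS-PM module.
* No clade-wise (per-bin) assembly partitioning or phylogenetic-signal
  diagnostics; βNTI is computed on the whole community.
* BIOM support covers the v1 (JSON) format, dense or sparse, without
  observation/sample metadata payloads.
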