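# lakeassembly

Community-assembly and stability analysis for lake microbial time
series (protists, fungi, or any marker-gene community), built around
four questions ecologists ask of ASV/OTU tables collected along
environmental gradients:

1. **How neutral is the metacommunity?** Fit of the Sloan neutral
   community model (NCM) to occupancy–abundance data, with bootstrap
   confidence intervals and a per-taxon above/neutral/below partition.
2. **Which assembly processes dominate?** Stegen-style null models:
   βMNTD/βNTI from a phylogeny, abundance-based Raup–Crick (RC), and a
   five-way classification of every sample pair into variable selection,
   homogeneous selection, dispersal limitation, homogenizing dispersal,
   or undominated assembly.
3. **How stable is the community through time?** A compositional
   stability index, s_t = 1 − BC(rel_{t−1}, rel_t), per lake × size
   fraction (particle-associated vs free-living), averaged into a
   campaign-level stability index.
4. **What drives stability?** PLS path modelling (PLS-PM) linking
   latent environmental blocks (salinity, nutrients, physicochemical,
   particles) and richness to stability, with bootstrap significance at
   α = 0.1, goodness of fit, and indirect effects.

A first-class synthetic-data module generates all the inputs these
stages assume — Yule phylogenies, Sloan-neutral metacommunities sampled
to finite read depth, selection-structured communities with
phylogenetically conserved niche optima, and monthly multi-depth
two-fraction lake campaigns — so the whole pipeline runs end-to-end
with no downloads.

## The models

**Sloan NCM.** A taxon with metacommunity mean relative abundance p in
a local community of size N coupled to the metacommunity by immigration
rate m has stationary relative abundance Beta(Nm·p, Nm·(1−p)). Its
predicted detection frequency across communities is

    freq(p) = 1 − I_d(Nm·p, Nm·(1−p)),   d = 1/N

with I the regularized incomplete Beta function. `fit_ncm` estimates the
single parameter Nm by least squares of observed occurrence frequencies
against this curve (by default using the exact finite-depth
Beta-binomial detection probability, which converges to the threshold
form above — see `docs/methods.md`), reports R² = 1 − SSE/SST, and
bootstraps taxa for 95% confidence intervals.

**βNTI.** βMNTD is the abundance-weighted mean distance from each taxon
to its nearest relative in the paired community; βNTI is its z-score
against a null that shuffles taxon labels across the cophenetic matrix.
|βNTI| > 2 indicates deterministic selection (variable if > 2,
homogeneous if < −2).

**RC(Bray).** Pairs within |βNTI| ≤ 2 are further split by an
abundance-based Raup–Crick index in [−1, 1], built by reassembling each
community at observed richness and read total with probabilities
proportional to metacommunity occupancy and abundance: RC > 0.95 →
dispersal limitation, RC < −0.95 → homogenizing dispersal, otherwise
undominated.

**PLS-PM.** Latent variable scores are estimated by the classic
Lohmöller iteration (mode A, centroid scheme by default), path
coefficients by OLS on the latent level, GoF = √(mean communality ×
mean R²), and path p-values by a sign-aligned bootstrap percentile test.

## Worked example

```python
import numpy as np
import lakeassembly as la

# a Sloan-neutral metacommunity sampled to 10,000 reads per sample
cfg = la.NeutralSimConfig(n_taxa=300, n_samples=100, community_size=10_000,
                          migration_rate=0.05, seed=1)
counts = la.simulate_neutral(cfg)
fit = la.fit_ncm(counts, n_bootstrap=1000, seed=1)
print(f"m = {fit.m:.4f}  (95% CI {fit.ci_m[0]:.4f}-{fit.ci_m[1]:.4f})")
print(f"R^2 = {fit.r_squared:.3f}")
print(fit.partition_counts().to_dict())

# selection along an environmental gradient raises bNTI
tree = la.simulate_tree(100, seed=3)
env = np.array([-2.5]*8 + [2.5]*8)
sel = la.simulate_selection(la.SelectionSimConfig(
    tree=tree, env_values=env, niche_breadth=0.4, community_size=5000, seed=9))
pairs = la.bnti_pairwise(sel, tree, n_null=199, seed=4)
print(f"mean bNTI = {pairs['bnti'].mean():.2f}")
```

prints

```
m = 0.0501  (95% CI 0.0482-0.0520)
R^2 = 0.979
{'above': 44, 'neutral': 245, 'below': 11}
mean bNTI = 1.61
```

The generating immigration rate (0.05) is recovered inside a tight
bootstrap interval with a near-perfect fit; most taxa sit inside the
neutral band. Under niche selection the mean βNTI rises well above the
neutral expectation of 0 (between-environment pairs exceed +2).

## Command line

```sh
lakeassembly simulate --seed 1 --output synthetic      # counts + tree + metadata
lakeassembly ncm --input synthetic/counts.tsv --seed 1
lakeassembly run --config examples/demo.yaml           # full pipeline
```

`run` executes simulate → NCM → null models → stability → PLS-PM into a
run directory with per-stage TSV/JSON outputs and a `manifest.json`
recording the config snapshot, per-stage seeds, input checksums and row
counts. Two runs from one config are byte-identical.

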