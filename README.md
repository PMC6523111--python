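# phyloniche

Phylogenetic community structure, parsimony trait mapping, and
stable-isotope statistics for plot-based community surveys — built for
ecologists asking *which processes assemble local communities from a
regional species pool*, in study systems like termite assemblages across
tropical-forest sites.

The reasoning chain the package implements:

1. **Are co-occurring species more or less related than chance?**
   For each plot, the mean pairwise patristic distance (MPD) among its
   species — optionally abundance-weighted — is standardized against an
   independent-swap null model (2×2 checkerboard swaps of the
   plot × species presence matrix that preserve all row and column
   totals):

       NRI = −(MPD_obs − mean MPD_null) / sd MPD_null

   Positive NRI = phylogenetic clustering, negative = overdispersion.
   Significance uses two-tailed ranks: with R = 9999 randomizations and
   α = 0.05, ranks ≥ 9750 or ≤ 250 are significant. Both regional and
   site-specific species pools are supported.

2. **Are the niche traits conserved on the phylogeny?**
   Categorical feeding groups (I dead wood … IV true soil) are mapped by
   minimum-change unordered parsimony (exact on polytomies, with MPR state
   sets and exact min/max transition counts over all most-parsimonious
   reconstructions); continuous δ15N/δ13C signatures by squared-change
   parsimony. A tip-permutation test quantifies conservatism:
   p = (1 + #{permuted score ≤ observed}) / (n_perm + 1).

3. **What do the niches look like?** δ-notation
   (δX = (R_sample/R_standard − 1)·10³ ‰), per-site/feeding-group/family
   summaries (n, mean, sample SD), one-way ANOVA with Tukey HSD compact
   letter displays, and Pearson correlations of NRI against rainfall,
   elevation and temperature (plus an OLS fit with a site factor).

Conserved traits + overdispersion ⇒ interspecific competition; conserved
traits + clustering ⇒ environmental filtering. A synthetic-data module
generates whole study systems (Yule tree, Brownian traits, Markov feeding
groups, three assembly modes, environment gradients, isotope tables) so the
entire pipeline is testable end to end, with every stage deterministic
given a seed.

## Worked example

```python
from phyloniche import (paper_like_config, simulate_study,
                        run_pool_analysis, results_to_frame,
                        conservatism_test, correlate_nri_environment)

data = simulate_study(paper_like_config(seed=42))   # 32 spp, 3 sites x 5 plots
frame = results_to_frame(run_pool_analysis(
    data.community, data.tree, mode="regional",
    n_randomizations=999, rng_seed=42))
print(frame.merge(data.environment, left_on="plot_id", right_on="plot")
      .groupby("site")["nri"].mean().round(3))
```

```
site
site1    0.791
site2   -0.358
site3   -1.293
```

Site 1 (wet, filtering in this profile) averages NRI +0.79 — co-occurring
species more related than its null; site 3 (dry, competitive) averages
−1.29 — overdispersed, and its plot `site3_p4` is individually significant
(rank 993 of 1000, direction `overdispersed`). The gradient shows up in
the plot-level correlations:

```python
corr = correlate_nri_environment(frame, data.environment)
# rainfall r = 0.784, elevation r = 0.796, temperature r = -0.311
```

and the traits driving it are conserved:

```python
vals = data.traits.set_index("species")["d15N"].to_dict()
obs, p = conservatism_test(data.tree, vals, n_perm=999, rng_seed=42)
# observed squared-change score 32.12, p = 0.001
```

so the overdispersion at the dry site reads as interspecific competition
among ecologically similar relatives. The isotope leg closes the loop —
litter δ13C differs at the dry site (`F_2,42 = 20.31, p < 0.001`, Tukey
letters a/a/b).

A CLI mirrors the library:

```
phyloniche simulate --seed 42 --out study/
phyloniche nri --tree study/tree.nwk --community study/community.csv \
    --pool regional --nrand 9999 --seed 1
phyloniche asr --tree study/tree.nwk --traits study/traits.csv \
    --character feeding_group --nperm 999 --seed 1
phyloniche isotopes compare --table study/isotopes.csv --by site \
    --element d15N
```

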