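# Methods

## The problem

Communities assemble from a regional species pool by processes that leave a
phylogenetic fingerprint. If a niche trait is phylogenetically conserved
(close relatives share it), then environmental filtering concentrates
relatives in the plots where their shared niche works — co-occurring species
are *more* related than chance (phylogenetic clustering) — while
interspecific competition excludes similar species and spaces co-occurring
species *further* apart on the tree than chance (overdispersion). The
package implements the three legs of that argument for a plot-based survey
of a ~32-species pool: (1) the Net Relatedness Index with an
independent-swap null model, (2) parsimony mapping of niche traits (ordinal
feeding groups, continuous δ15N/δ13C signatures) onto the phylogeny with a
permutation test of conservatism, and (3) the stable-isotope summaries and
one-way ANOVA/Tukey comparisons that characterize the niches themselves.

## NRI and the independent-swap null

For a plot with species set S and patristic distance matrix d, the mean
pairwise distance is

    MPD = mean_{i<j in S} d(i, j)                        (unweighted)
    MPD = Σ_{i<j} a_i a_j d(i,j) / Σ_{i<j} a_i a_j       (abundance-weighted)

and the Net Relatedness Index standardizes it against a null distribution:

    NRI = −(MPD_obs − mean(MPD_null)) / sd(MPD_null).

Positive NRI = clustering, negative = overdispersion. The null fixes both
margins of the plot × species presence matrix: each null matrix is reached
by 2×2 checkerboard swaps ([[1,0],[0,1]] ↔ [[0,1],[1,0]]) that preserve
every row (plot richness) and column (species occurrence) total. We sample
by a symmetric Metropolis chain — draw two rows and two columns uniformly,
swap when the 2×2 block is a checkerboard — whose stationary distribution
is uniform over the margin-fixed set. Between successive samples the chain
performs 10 × (number of 1-cells) successful swaps, plus a random extra
0/1 swap; the extra swap matters because in some matrices (e.g. 3×3
complements of permutation matrices) every swap flips a parity class, and
a deterministic even swap count would confine the chain to half the state
space. One full schedule of burn-in precedes the first sample, and the
attempt budget is 100× the swap target so an unswappable matrix returns
unchanged (with a warning) rather than hanging.

Significance uses Webb-style two-tailed ranks: the observed MPD's rank
among nulls-plus-observation is 1 + #{null < obs} + ½·#{null = obs}
(rounded half up; half-counting ties keeps the two-sided rank unbiased
under discrete nulls); with R randomizations, ranks ≥ ⌈(1−α/2)(R+1)⌉ or
≤ ⌊(α/2)(R+1)⌋ are significant — at R = 9999 and α = 0.05, 9750 and 250.

**Pools.** The regional analysis randomizes all plots within the pool of
every species observed anywhere; the site-specific analysis randomizes each
site's plots within only that site's recorded species. A plot with fewer
than two species is reported as a flagged NA row. When the weighted MPD is
requested, swaps still act on presence/absence; each species' observed
positive abundances are then permuted uniformly across its occurrence cells
in the null matrix (column totals are preserved, so counts match).

**Degeneracy.** If the null distribution is constant (null SD ≤ 1e-12
relative), NRI is undefined and the row is flagged degenerate rather than
reporting a 0/0 artifact.

## Parsimony trait mapping

*Categorical (feeding groups I–IV).* Minimum-change unordered parsimony on
the rooted tree. The downpass applies Hartigan's majority rule at each
node — keep the states present in the most child sets, add
(children − majority count) changes — which equals Fitch's
intersection-else-union on binary nodes and remains exact (equal to the
unit-cost Sankoff minimum) on polytomies, where a naive pairwise fold can
undercount. The uppass produces MPR-union state sets. Because "evolved
only once" claims depend on which most-parsimonious resolution one adopts,
transition counts are reported three ways: for one canonical resolution
(top-down, prefer-parent tie-break, alphabetical otherwise) and as the
exact minimum and maximum over all MPRs from a bi-criteria dynamic program
(cost first, transition count second).

*Continuous (δ15N, δ13C).* Squared-change parsimony: internal values
minimizing Σ_edges (parent − child)², unit edge weights by default (the
convention of classic ASR software; a branch-length-weighted variant
divides each term by branch length and is off by default). The optimum is
the solution of the sparse linear system in which each internal node equals
the (weighted) mean of its tree neighbors; the minimized score is also a
quadratic form v'Qv in the tip values v, with Q the Schur complement of the
tree's graph Laplacian onto the tips — precomputing Q makes the
permutation test below cheap.

*Conservatism test.* Shuffle tip assignments uniformly n_perm times and
recompute the score; p = (1 + #{permuted ≤ observed}) / (n_perm + 1) (the
+1 avoids zero p). Low p = conserved. Applies to either character type;
n_perm ≥ 99 is enforced.

## Isotope statistics

δX = (R_sample/R_standard − 1)·10³ in ‰. Summaries report n, mean and
sample SD (n−1 denominator; a singleton's SD is NA, not 0) per site,
feeding group or family (the latter two join the species trait table).
Between-group tests are one-way fixed-effects ANOVA plus Tukey HSD
(studentized range, Tukey–Kramer correction for unequal n), rendered as a
compact letter display built by insert-and-absorb: start from one set of
all groups, split every set containing a significantly different pair,
drop nested sets; groups sharing a letter are not significantly different.
Groups with n < 2 are excluded from the omnibus with a warning.

NRI–environment relationships are Pearson correlations (two-sided t,
df = n − 2) per covariate, plus an OLS fit of NRI on the three standardized
covariates with a site fixed factor. The site term is deliberately fixed,
not random: in the motivating design the site random-effect SD is
negligible relative to the residual, and the OLS stand-in is flagged in the
output (`ols_site_factor`) so downstream users see the modeling choice.
Instrument precision (0.1‰ C, 0.2‰ N) is carried as metadata only.

## The synthetic study generator

The generator emulates a three-site, five-plots-per-site survey of a
32-species pool:

- **Tree** — Yule pure-birth, default rate 1.0, ultrametric, grown forward
  in time with exponential waiting times.
- **Traits** — δ15N and δ13C evolve by Brownian motion (defaults σ = 2.0
  and 1.0 ‰ per √branch-unit, roots 6.0 and −27.0 ‰, near the centers
  typical of forest termite assemblages); the feeding group evolves by a
  Markov jump process (default 0.4 jumps per branch-length unit, root
  state II) so clades share groups.
- **Communities** — per-plot richness ~ truncated Poisson(mean 8, min 2).
  Random mode samples species uniformly; filtering samples ∝
  exp(−strength·|δ15N − site optimum|), site optima spread across the
  trait range; competition admits species sequentially only if their
  minimum patristic distance to residents exceeds 0.5 × strength × the
  median pairwise distance (truncating richness with a warning when the
  pool is exhausted). Abundances are i.i.d. geometric(0.25); the analyses
  must not depend on the abundance shape.
- **Environment** — per-plot values are site means (defaults 1500/1100/700
  mm rainfall, 300/180/50 m elevation, 26.5/27.0/27.7 °C) + 3% Gaussian
  noise; the default mode tuple (filtering, random, competition) makes the
  driest, warmest site the competitive one.
- **Isotope table** — termite rows are species trait means + N(0, 0.8‰),
  three replicates per species per occupied site; litter 15 rows/site with
  optional per-site offsets (default +1.5‰ at the dry site on both
  elements); soil 5 rows/site with no site effect.

Everything is reproducible from the config seed. What the generator does
*not* emulate: spatial autocorrelation between plots, colony demography,
abundance–environment interactions, or measurement error structure beyond
i.i.d. Gaussians — so green tests show the estimators and their
calibration are correct under the assumed model, not that any particular
field system satisfies that model.

## Problem sizes and numerical choices

- Exhaustive-null validation enumerates every margin-preserving matrix for
  fixtures up to 5 plots × 6 species and checks the sampled NRI (R = 9999)
  against the enumerated standardized effect size.
- Null calibration uses 67 independent study-sized draws (15 plots each,
  1005 plots) with R = 499 nulls, unweighted MPD; 499 gives the two-tailed
  rank test an exact nominal size of 25/500 = 0.05.
- Direction recovery uses 14 draws (210 plots) per assembly mode at
  R = 199; trait-signal power uses 100 replicate 32-tip trees with 999
  permutations each.
- Squared-change systems are solved with a sparse direct solver;
  branch-weighted weights are clipped at 1/1e-12 for zero-length branches.
- The Newick writer emits 6 significant digits, so round-trips preserve
  distances to ~1e-5 relative.

## Known limitations

- Uppass MPR-union sets use Hartigan's rule; on polytomies the *score* is
  exact but the canonical single resolution is one arbitrary choice among
  possibly many (the MPR min/max bracket is exact).
- The independent-swap chain is uniform over the margin-fixed set it can
  reach; pathological margins with very few checkerboards mix slowly, and
  the attempt budget then returns under-mixed samples with a warning.
- The site-specific pool analysis treats sites independently; species
  observed only at other sites never enter a site's null, by design.
- Weighted-null abundance permutation assumes abundances are exchangeable
  across a species' occurrences, which is the natural extension of the
  occurrence-swap null but is still a modeling choice.
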