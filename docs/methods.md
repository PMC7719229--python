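# Methods

`nhejevo` reimplements, as a tested pipeline over synthetic data, a
comparative-genomics and phylogenetics analysis of bacterial nonhomologous
end joining (NHEJ): classifying genomes into NHEJ states from protein-domain
evidence, reconstructing the trait's history on a species tree with
gain/loss accounting, and testing its association with genome size and
growth rate in phylogenetically controlled ways.  This note records the
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic data do and do not establish.

## NHEJ state model

Bacterial NHEJ requires Ku (end binding) and LigD, a three-domain protein
with ligase (LIG), polymerase (POL) and phosphoesterase (PE) activities.
Genomes are classified from domain-hit tables (HMMER-style, E-value
reporting threshold 1e-4) into five states:

* `conventional_plus`: Ku present and at least one protein carries LIG, POL
  and PE together.  The conventional definition is existential: extra
  fragmented LigD copies never demote a genome.
* `nonconventional_plus`: Ku and LIG present but no single three-domain
  protein (fragmented/partial LigD architectures).
* `Ku_only`: Ku without LIG.  POL/PE fragments without LIG never count as a
  ligase; LIG is the diagnostic domain throughout.
* `LigD_only`: LIG without Ku.
* `NHEJ_minus`: neither Ku nor LIG.

The classification is a total deterministic function of the hit table; on
generated data it recovers the generating state for 100% of genomes, which
is the generator's core contract and the classifier's acceptance-level
check.

The ku–ligD neighborhood of conventional genomes is called from gene ranks
(annotation order), not base pairs: `operonic` when the closest (ku, ligD)
pair sits within a 10-gene window (inclusive) on the same strand,
`proximal_opposite_strand` within the window on opposite strands, `distant`
otherwise.  With multiple copies the minimum-rank-distance pair decides and
ties prefer a same-strand pair.  When a replicon's gene count is supplied,
rank distance is computed on the circle (bacterial chromosomes are
circular); otherwise linearly.  Per-phylum enrichment of a focal state uses
the two-sided Fisher exact test against an all-genomes background by
default (a `nhej_plus` background is available), reporting the raw odds
ratio ad/bc and a Haldane-corrected version when a cell is zero.

## Discrete-trait machinery

For reconstruction the five states collapse to four: `NHEJ_minus`,
`Ku_only`, `LigD_only`, `NHEJ_plus`.  A continuous-time Markov (Mk) model
with generator Q governs the trait; rate structures ER (1 free rate), SYM
(k(k−1)/2) and ARD (k(k−1); 12 transition types for k = 4) are compared by
AIC weight.

**Likelihood.** Felsenstein pruning with per-node rescaling; transition
matrices exp(Qt) for all branches at once via eigendecomposition when the
eigenvector matrix is well conditioned (cheap norm-product bound < 1e8),
otherwise scaling-and-squaring per unique branch length.  Branch lengths
are floored at 1e-12 so the 1e-6 branches introduced by polytomy resolution
are safe.  The root prior defaults to the normalized root conditional
likelihoods ("estimated at the root"); flat and stationary priors and
explicit vectors are also supported.  The pruning likelihood is verified
against brute-force summation over internal-node states on 5-tip trees
(max |Δ| < 1e-10) and against the 2-state closed form
p00(t) = 1/2 + exp(−2qt)/2 at 1e-12.

**Fitting.** Box-constrained L-BFGS-B on log rates, rates in [1e-8, 1e3]
per unit branch length.  A 1-D scan over a common rate multiplier seeds the
multistart (default 5 seeded starts); the scan also avoids a real failure
mode where the first quasi-Newton line search overshoots onto the
saturated-rate plateau, where the likelihood is numerically flat and the
optimizer reports convergence at the bound.  `fit_mk_models` warm-starts
SYM from the ER optimum and ARD from the SYM optimum, making the nested
log-likelihood ordering a structural property of the fit rather than an
optimizer accident.

**Posterior over Q.** Metropolis sampling on log rates (joint Gaussian
random-walk proposals), independent exponential priors with mean at the
MLE, burn-in 10% of the chain with step adaptation toward ~30% acceptance,
thinning (default 2) to the requested number of draws; a warning fires if
the post-burn-in acceptance rate leaves [0.05, 0.8].  The chain is byte
reproducible given a seed.

**Stochastic mapping.** Node states are drawn from their joint posterior by
a pre-order sweep over conditional likelihoods; branch paths are drawn
exactly by uniformization, with the jump-count series summed to convergence
and used as its own normalizer (robust on the 1e-6 branches, where
rejection sampling would stall).  One map is simulated per posterior Q draw.
Map summaries report mean transition counts (12 ordered pairs for k = 4),
relative transition frequencies, expected time in state (conserving total
tree length to 1e-6 relative), and per-node state frequencies.  Sampler
correctness is established two ways: node-state frequencies against
marginal posteriors computed by an independent up-pass (and, during
development, against clamped-likelihood enumeration), and per-branch jump
counts against the analytic endpoint-conditioned expectation computed by
numerical integration.  Because the per-cell "within 3 Monte-Carlo SEs"
band is miscalibrated for the many cells with posterior mass near 0/1 and
for ~80 simultaneous comparisons, the acceptance check applies the exact
binomial tail at the 3-sigma confidence level with Bonferroni control
across cells — same strictness, correct familywise behavior.

**Node calls and primary gains.** A node is called when its posterior state
frequency strictly exceeds 0.7 (display convention); a *primary gain* is an
internal node where (1) every node from the root down to its parent is
called `NHEJ_minus`, (2) the posterior probability of `NHEJ_plus`,
`LigD_only` or `Ku_only` is at least 0.7 (gain criterion, inclusive —
deliberately different from the strict display threshold), (3) a partial
gain (`Ku_only`/`LigD_only`) is completed by a called `NHEJ_plus` node or
tip somewhere below, and (4) at least three tips descend from it.

**Continuous ancestral states.** Genome size (log10) is reconstructed under
single-rate Brownian motion by solving the GLS normal equations on the tree
(each internal value the inverse-branch-length-weighted average of its
neighbors); the root estimate equals the GLS mean, and variances are the
conditional variances scaled by the ML Brownian rate.

## Comparative statistics

All continuous analyses use log10 genome size and log10 rRNA copy number
(the growth-rate proxy).  The Brownian covariance C has entries equal to
root-to-LCA depths.

* **Pagel's λ**: ML over the covariance with off-diagonal scaled by λ
  (mean and rate profiled analytically), λ bounded by positive
  definiteness; LR test against λ = 0 (χ², df 1).  A flat likelihood (star
  tree) triggers an unidentifiability warning.
* **Blomberg's K**: observed MSE0/MSE around the GLS mean divided by its
  Brownian expectation; significance by tip permutation with the
  (1 + exceedances)/(1 + permutations) estimator.
* **Phylogenetic ANOVA**: observed one-way F; null from Brownian
  simulations on the tree at the ML rate (1,000 by default); pairwise
  post-hoc t statistics against their own simulated nulls with
  Holm–Bonferroni correction.  The method assumes normality of the trait;
  that caveat is inherited knowingly.
* **Correlated evolution (Pagel's discrete test)**: both binary traits on
  the product space {00, 01, 10, 11}; independent model with 4 free rates
  (each trait's gain/loss shared across the other's background), dependent
  model with 8; double transitions excluded in both, so the models nest
  with df = 4.  ML LRT with a χ² tail.  The dependent fit is warm-started
  at the independent MLE, guaranteeing the nesting inequality.  Binarization
  rules: continuous traits split at the mean (values below the mean are 0);
  growth rate split at the median with "slow" = at-or-below.  Calibration
  under the study conditions (500-tip Yule trees scaled to height 3,
  moderate switching rates): type-I error at α = 0.05 within [0.02, 0.09]
  over 200 null replicates, power ≥ 0.8 against a strongly coupled
  generator.
* **Phylogenetic logistic regression**: y ~ Bernoulli(logit⁻¹(Xβ)) with a
  working correlation from a stationary two-state Markov switching process
  run along the tree and conditioned on the root, with switching intensity
  α (higher α = less phylogenetic signal):
  R_ij = (e^{−α d_ij} − e^{−α(t_i+t_j)}) / √((1−e^{−2αt_i})(1−e^{−2αt_j})),
  d the patristic distance, t the root-to-tip depths.  Tips sharing no
  history are exactly uncorrelated, so on star trees the estimator *is*
  ordinary logistic regression (verified to 1e-4, achieved at machine
  precision).  β solves the GEE score equations by damped Fisher scoring
  (step halving on the score norm); α maximizes a Gaussian working
  likelihood of the standardized residuals on [0.01/T, 50/T] (T = tree
  height), grid-then-refine.  Model comparison uses the independence
  quasi-likelihood at the GEE solution (the quantity behind QIC-type
  criteria) with AIC = −2·loglik + 2(p+1); the Gaussian correlation term is
  deliberately excluded from cross-model comparison because its
  residual-dependent value is not comparable across mean models.  Perfect
  separation is detected at the independence limit and reported as an
  error; collinearity is screened by VIF = 1/(1−R²) before fitting.
* **Mantel test**: Pearson r of lower-triangle patristic distances over the
  shared label set; one-tailed null by jointly permuting rows and columns,
  p = (1 + exceedances)/(1 + permutations), 10,000 permutations by default;
  exact enumeration whenever n! does not exceed the permutation budget.
* **Gene-pool genome-size randomization**: genes drawn uniformly from the
  pooled gene set (genomes enter with probability proportional to their
  gene count), the source genome's gene count recorded per draw, the median
  kept per iteration (100 iterations); the null medians are compared with
  the observed focal-group sizes by the two-sided Wilcoxon rank-sum test.
* **Wilcoxon rank-sum**: exact when the smaller sample has ≤ 10
  observations and the pooled values are tie-free, otherwise the normal
  approximation with tie and continuity correction (scipy).

## Trees

Newick parsing/writing goes through dendropy with underscores preserved,
quoted labels supported and internal labels (bootstrap/SH-aLRT values) kept
as plain strings; the writer emits 10 significant digits and round-trips.
Midpoint rooting finds the tree diameter, breaking ties by the
lexicographically smallest tip pair, and conserves total length.  Polytomy
resolution repeatedly groups the first two children (deterministic, no
seed) and sets every zero-length branch to 1e-6.  Pruning preserves
tip-to-tip path lengths exactly.  Patristic and shared-depth matrices come
from one LCA sweep and are checked against brute-force path sums.

## Synthetic data: what it emulates, what it does not

The generator produces Yule trees (pure birth; the analyses never use
extinction) rescaled to height 4, NHEJ histories under a default 4-state
generator whose rates encode the motivating biology — losses outpace gains,
the LigD-first route dominates sequential acquisition, direct whole-machinery
gains/losses occur, and Ku-only is rarely entered — at an overall flux that
leaves deep nodes genuinely uncertain.  NHEJ+ tips split 70/30 into
conventional/nonconventional.  Domain-hit tables are strictly consistent
with each state (multi-copy Ku at 16% with 2–8 copies, extra LIG/POL/PE
fragments at 66/37/8%), with decoy hits generated strictly above the
E-value threshold to exercise the filter.  Gene tables place ku/ligD at
controlled rank offsets (60% operonic, 15% proximal-opposite, rest distant)
on a circular replicon sized by the genome's gene count.  Trait tables draw
log10 genome size per state (NHEJ− mean 6.46 ≈ 2.9 Mb, conventional 6.73 ≈
5.4 Mb, sd 0.15), rRNA copies (means 4 vs 3), and G–C content with a
positive NHEJ+ shift; phylum labels are categorical with conventional NHEJ
tilted toward one phylum so enrichment has signal.  Default scale is
200–1,000 tips (400 in the analysis scripts); heavier calibration loops use
500-tip trees and the acceptance script uses 300-tip trees, sizes chosen to
keep a laptop-class run comfortable while leaving the asymptotics
recognizable.

Synthetic data cannot establish: real HMMER score distributions (only the
pass/fail filter is emulated), plasmid-vs-chromosome placement, genuine
horizontal transfer (the Mantel arm emulates incongruence by label
shuffling), taxonomic structure beyond categorical labels, or any
sequence-level effect.  Passing tests show the machinery is correct and
calibrated under the generating model, not that the biological conclusions
transfer to real assemblies.

## Known limitations

* The Bayesian RJMCMC/stepping-stone arm of the correlated-evolution
  comparison and Bayes factors are out of scope; only the ML/LRT arm is
  implemented.
* Multi-rate Brownian comparisons (stable-distribution models) are not
  implemented; continuous reconstruction is single-rate BM.
* The phylogenetic logistic regression is a GEE estimator with a documented
  working correlation, not a reimplementation of any specific R package's
  algorithm; its α is comparable across our own models only.
* `phylo_anova` simulates at the ML Brownian rate of the observed data,
  which ignores rate uncertainty; with 1,000 simulations the p-value floor
  is 1/1001.
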