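# Methods

## The setting

A supplementation program takes up to `max_broodstock_pairs` (default 40)
pairs of natural-origin (NOR) adults per year at a weir, spawns them in a
hatchery, and direct-releases the juveniles; all other returns spawn
naturally. Hatchery-origin (HOR) returns are identifiable, return to the
same river at ages 3–5, and spawn in nature. Two questions drive the
analyses: the *demographic boost* (how many more returning adults a
broodstock fish produces than a natural spawner, over one and two
generations) and *relative reproductive success* (whether HOR fish spawning
naturally produce fewer returning adults than NOR fish, overall and within
cross types).

## Synthetic population generator

`simulate.simulate_population` builds the truth-level population year by
year from a single seeded generator stream (rerunning with the same
`SimConfig` is bit-identical).

**Demography.** Founders are injected over the first five return years
(the span of brood years feeding any later return). Each spawn year, NOR
adults of age ≥ 4 are paired at random into up to 40 broodstock pairs; the
rest spawn naturally. Offspring counts per natural female are negative
binomial with dispersion θ (`nb_dispersion`, default 0.7 — strongly
overdispersed, most spawners producing zero returning adults, as observed
in salmonid RS distributions) and log mean

```
log mu = log(r_max · dd) + year_effect + β_origin·1[NOR] + β_len·z_len + β_day·z_day
```

where `dd = 1/(1 + n_females/carrying_k)` is a Beverton–Holt density
factor shared by all matings of the year (so it cancels from every
within-year ratio), `year_effect ~ N(0, β_year_sd²)` is a brood-year
quality shock, `z_len` is body length standardized within age class and
`z_day` return day standardized by its mixture moments. Fathers are drawn
per female (one mate each, giving full-sib families) with probability
proportional to the male's own log-linear predictor — the marginal counts
stay negative binomial, which is all the downstream analyses assume.
Broodstock pairs produce `NB(r_max·dd·year_effect·multiplier, θ)`
offspring with no individual covariate terms (artificial spawning), so
with covariate effects off the expected first-generation boost equals
`hatchery_survival_multiplier` (default 4.5, emulating a strong juvenile
survival advantage). Offspring are sexed 1:1; return ages are drawn from
sex-specific distributions (males 3/4/5 = 0.25/0.55/0.20; females
0/0.60/0.40 — age-3 females are effectively absent); offspring that would
return after the simulated horizon are never observed, exactly like a
real study window.

**Phenotypes.** Body length is normal within age class (means 560/780/870
mm at ages 3/4/5, SD 45), which induces the strong age–length correlation
(r ≈ 0.7) that motivates never fitting age and length together. Return
day is a two-component normal mixture ((190, 8), (215, 8), weight 0.45) —
a bimodal run.

**Genotypes.** Per-locus reference-allele frequencies are uniform on
`allele_freq_range` (default (0.2, 0.8), typical of a parentage panel
selected for informativeness); loci are unlinked; founders are
Hardy–Weinberg draws and offspring strictly Mendelian.

**Observation model.** Each fish is sampled with probability 0.93
(weir plus carcass surveys); each observed allele flips with the
*realized* error rate (default 0.001 — the QC-concordance scale of error,
an order of magnitude below the 1% the parentage likelihood conservatively
assumes); calls go missing with probability 0.02. At a 1% *realized*
per-allele error a 290-locus true trio would show ~4.4 Mendelian
mismatches on average and the standard >2-mismatch filter would reject
most true families — the assumed-vs-realized distinction is therefore
essential, not cosmetic.

**What the generator does not emulate.** Strays (removed at the weir),
harvest, ocean/temperature covariates, redd-count expansion, weir
efficiency, linkage between loci, sex-ratio or fecundity trends, and any
difference in genotyping failure between origins. Passing tests therefore
show the statistical machinery is correct under the stated model, not
that any particular wild population satisfies that model.

**Initialization transient.** The founder ramp distorts the age structure
for roughly the first six years (e.g., jacks from the first large brood
arrive a year before their sisters, skewing the natural pool male).
Calibration analyses and the acceptance script evaluate post-burn-in
brood years only; this is a burn-in choice made once, like discarding
MCMC warm-up.

## Genotype QC

Loci with call rate < 90% are removed first; individuals with ≥ 10%
missing calls on the retained loci second. The boundary is asymmetric on
purpose: a locus at exactly 90% coverage is retained while an individual
at exactly 10% missing is removed, matching the two stated rules, which
disagree only exactly at the boundary. Duplicate samples are flagged at
≥ 0.95 pairwise shared-call identity (full sibs sit near 0.59 at
informative frequencies — enumeration gives 19/32 at f = 0.5 — so the
threshold cleanly separates re-sampled fish from close kin); pairs with
no jointly called locus are reported as indeterminate, never as
duplicates.

## Trio parentage

The likelihood machinery precomputes, per locus, the joint probability of
the three *observed* genotypes under four hypotheses — both parents true,
either single parent true, all unrelated — by summing over the 3×3×3 true
genotype grid with HWE priors, Mendelian transmission, and the per-allele
error confusion matrix

```
C = [[(1-ε)², 2ε(1-ε), ε²],
     [ε(1-ε), (1-ε)²+ε², ε(1-ε)],
     [ε², 2ε(1-ε), (1-ε)²]]
```

(each observed allele independently miscalled with probability ε; default
assumed ε = 0.01). Loci with any missing member or frequency exactly 0 or
1 contribute nothing. With ε = 0, impossible loci contribute log10 of a
1e-300 floor instead of −∞ so ranking stays total.

**Candidate structure.** For an offspring returning in year Y, candidates
are spawners of years Y−3, Y−4, Y−5; a pair must share a spawn year and a
spawning pool (two broodstock fish or two natural spawners — hatchery and
natural matings never mix). Parent sex is not used in the likelihood.

**Pruning.** Evaluating all pairs is quadratic in cohort size; instead,
single-parent LODs rank all candidates and pairs are evaluated
exhaustively among the top K = 30. At ≥ 150 informative loci the
true-parent single LOD separation is so large (ROC AUC > 0.99) that the
true pair is effectively never pruned away.

**Confidence and filters.** The null distribution is `n_null` (default
10,000) unrelated pseudo-trios drawn from the observed-genotype marginal;
the per-offspring p-value is the null exceedance fraction of the top LOD
(with a +1 correction), converted to q-values by Benjamini–Hochberg. This
approximates the reference implementation's Monte-Carlo FDR machinery; it
ignores the max-over-pairs selection on both the observed and null sides,
so published LOD/FDR averages are distribution-level references, not bit
targets. Assignments are then filtered, in precedence order: > 2 trio
Mendelian mismatches; q-value > 0.05; same-sex pair; broodstock rules
(HOR offspring must assign to two broodstock parents; mixed
broodstock/non-broodstock pairs, and broodstock pairs for NOR offspring,
are spurious); and a category-posterior check that the both-parents
hypothesis is the MAP category among {both, single, unrelated} with equal
priors. Ties in top-LOD pairs break by fewer mismatches, then
lexicographic pair id, so results are reproducible given the seed.

## Pedigree fitness

RS is the number of accepted offspring edges per parent; candidates with
no assignments count as zeros (they remain in the all-candidates
estimand). Grand-RS cuts F1 broodstock out of the path entirely — their
hatchery progeny are not credited to the F0 grandparents — the
conservative (lower) accounting. An F1 broodstock fish still counts
toward its parents' first-generation RS (it is a returning adult); only
the grand-offspring path is cut. Cross types are labelled female-first
from pedigree-informed sex; when field sex conflicts with pedigree
position, the pedigree wins (logged). Age-2, age-6 and age-3-female
returns (< 1% classes) are excluded everywhere; jacks stay in RRS and the
demographic boost but never in cross analyses.

## Ratio statistics

RRS divides the mean RS of the focal group by the mean RS of the
reference group, per return year × sex class (females 4–5, males 4–5,
jacks), under two estimands: all candidates, and successful-only (zeros
dropped from both groups — the two estimands coincide exactly when no
zeros exist). Across-year summaries are unweighted means of yearly
ratios, not pooled ratios: pooling mixes years with different mean RS and
different origin composition and is confounded (Simpson-style), which the
per-year estimator avoids. The delta-method 95% CI uses
`Var(R) ≈ Var(x̄_n)/x̄_d² + x̄_n²Var(x̄_d)/x̄_d⁴` with `Var(x̄) = s²/n`
on the linear scale, floored at 0, so intervals can span zero like
published error bars; at n ≥ 200 per group it agrees with a
nonparametric bootstrap percentile interval to within a few percent of
width and covers at ~94%. Significance against 1.0 is read off the CI,
alongside a per-year two-group ANOVA (identical to the pooled-variance
t-test). Undefined strata (empty groups, zero denominator mean, years
without broodstock) are flagged, never silently dropped.

Cross-type RRS restricts the per-parent counts to offspring of the focal
cross type, among parents that actually participated in that cross type
(a successful-cross framing; with one mate per female in the simulator
these are full-family counts). F0DB is the broodstock/natural-spawner RS
ratio with sexes and jacks combined; F1DB multiplies it by the HOR/NOR
RRS of the brood year's F1 natural spawners after broodstock removal, and
its CI combines the two ratios' delta variances as an independent
product.

## Negative-binomial fitness models

`fit_nb_glm` wraps full maximum-likelihood NB regression (dispersion
estimated jointly with the coefficients; Poisson-fit starting values,
BFGS with a Nelder–Mead fallback; non-convergence is reported, never
silent). AIC is −2·loglik + 2(k+1), counting the dispersion parameter.
Reference levels are the earliest return year and HOR origin, so the
origin coefficient reads as the NOR effect. Sexes are fit separately and
the male stratum includes jacks. "MAD transformation" is implemented as
within-year centering *and* scaling by the year's mean absolute
deviation (division is the default; a centering-only mode is available
via `mad_scale=False`, since the phrase admits both readings; centering
alone leaves slopes on the raw covariate scale). The eight candidate
models are the subsets of {return year, origin, body length | age,
return day} that always contain return year, never contain body length
and age together, and span 2–4 predictors — the two 4-predictor models
are the stated full models. All candidates are fit on the identical
observation set (rows with any missing covariate removed first).

## Numerical and testing choices

- Zero-likelihood guard 1e-300 (log10 ≈ −300); oracle-equivalence tests
  compare the table-driven likelihood against an explicit 27-cell loop to
  1e-10.
- Monte-Carlo problem sizes were chosen once for a desk-scale run: the
  assignment check uses a fully sampled 3-cohort run at 290 loci
  (~1,700 trios); calibration uses 20 replicate populations (~400
  founders/year, 17 years) evaluated on post-burn-in years; CI coverage
  uses 1,000 draws at n = 200/group; GLM recovery uses 100 replicates at
  n = 2,000, θ = 1.5 (covariates centred within year so the generating
  slopes are the estimands), and AIC-selection consistency 21
  replicates.
- The acceptance script (`scripts/acceptance.py`) runs the *observed*
  pipeline (not the truth pedigree) end to end on one seeded simulated
  program of 17 years × 250 founders/year × 290 loci and reports what it
  computes.

## Known limitations

- The FDR null ignores the max-over-candidate-pairs selection (see
  above); in practice accepted-trio q-values are ≪ 0.05 and the realized
  false-assignment rate in simulations is far below the bound.
- Single-parent assignment is out of scope; offspring with one unsampled
  parent are (correctly) rejected rather than half-assigned, so
  assignment success is bounded near the square of the sampling rate.
- The mean-of-yearly-ratios estimator is slightly biased upward when
  yearly group sizes are small (Jensen effect in the denominator);
  jack strata show this most.
- Hatchery pair output uses the same dispersion θ as natural matings;
  real hatcheries standardize egg takes and are probably less variable.
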