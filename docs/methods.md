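# Methods

## Scientific question and overall design

Risk alleles of common diseases are expected to be slightly deleterious
and therefore under negative (purifying) selection, which pushes their
population frequencies down. If, however, a disease is driven largely by
recent changes in environment or lifestyle, many of its risk alleles
were selectively neutral until a few generations ago; selection has not
had time to act, and their frequency spectrum should still look neutral.
The package tests this contrast with four linked analyses:

1. a literature co-occurrence index (ELI) that scores how
   environment/lifestyle-dependent each disease is;
2. minor-risk-allele (MiRA) statistics and binned risk-allele frequency
   spectra as estimators of the negative-selection left-shift;
3. the overlap between SNP sets (genotyping platforms, GWAS-reported
   SNPs) and a catalog of SNPs with signatures of recent positive
   selection, as a negative control for ascertainment effects;
4. a forward Wright-Fisher simulator of the "recently neutral, currently
   deleterious" model that generates the predicted dynamics.

## Environment/Lifestyle Index

For a disease with `n_disease` PubMed abstracts, of which `n_env`
co-mention "environment" and `n_lifestyle` co-mention "lifestyle",

    ELI = (n_env + n_lifestyle) / n_disease * 1000      [per 1,000 abstracts]

The extended index adds an `n_exposure` term to the numerator. Counts
are term-level, so an abstract matching two terms contributes to both
terms; the extended formula is taken as the same ratio with three
numerator terms (the natural extension of the two-term definition).
Values are kept unrounded internally and rounded to 1 decimal only in
output tables, so rank correlations downstream never compound rounding.

Tertiles: diseases are sorted ascending by ELI (ties broken by
case-folded name) and cut into three groups as equal as possible, the
remainder going to the lower-numbered groups; tertile 1 = lowest ELI =
environment/lifestyle-independent. The remainder and tie-break rules are
this package's own determinism choices; with the bundled 44-disease
table they give tertile sizes 15/15/14 and place rheumatoid arthritis,
systemic lupus erythematosus and pathological myopia in tertile 1 and
type 2 diabetes, coronary heart disease and obesity in tertile 3,
matching the published stratification.

## MiRA and binned spectra

A risk allele with control-population frequency F is *minor* when
F < 0.5 (exactly 0.5 is scored non-minor, following the "< 50%"
definition of minority; the event is logged). The MiRA proportion of a
SNP group is p = #minor / n with binomial SE sqrt(p(1-p)/n). Under
frequency-independent risk assignment the expectation is 0.5; negative
selection raises it.

The published per-disease SE column is reproduced by the
sample-variance convention sqrt(p(1-p)/(n-1)) — what a statistics
package reports when averaging a 0/1 indicator — and `binomial_se`
exposes this via `ddof=1`; the default `ddof=0` is the plain binomial
SE, which is what the platform-level SE column follows (at platform
sample sizes the two are indistinguishable).

Spectra bin F into 0<F<0.2, 0.2<=F<0.4, 0.4<=F<0.6, 0.6<=F<0.8,
0.8<F<1 (lower edge closed from the second bin on). The
frequency-independence null is built empirically, not from a parametric
neutral SFS: each SNP's two alleles get weight 1/2 at F and 1/2 at 1-F.
This matches the null's definition exactly and sidesteps platform
ascertainment, which makes the GWAS frequency spectrum bell-shaped
rather than U-shaped. The left-shift score is the observed-minus-null
mass in the two lowest bins; positive values indicate negative
selection. Rarity uses MAF = min(F, 1-F) with the closed threshold
MAF <= 0.05.

## Selection overlap

For a SNP set and the positively-selected catalog the statistic is the
intersection percentage 100*|A ∩ S|/|A| with binomial SE. Pairwise
comparisons use the 2x2 Pearson chi-square without continuity
correction (at the relevant sample sizes the correction is negligible);
the platform-versus-GWAS family is adjusted by Bonferroni
(p_adj = min(1, p*k)), the strictest standard adjustment. The pooled
platform summary is the unweighted mean of platform percentages with
its SD.

## Test statistics

Spearman, chi-square and one-way ANOVA are implemented from their
defining formulas (mid-ranks then Pearson; sum (O-E)^2/E; explicit
between/within sums of squares on the 0/1 minor-risk indicator), with
tail probabilities from the t, chi-square and F distributions. The
Spearman p-value uses the t approximation
t = rho*sqrt((n-2)/(1-rho^2)); an exact permutation p is available for
n <= 10. ANOVA on the SNP-level binary indicator is the only reading
consistent with between-group df = number of diseases minus one;
results report both df components. Degenerate inputs (constant vectors,
zero margins) return a flagged "not computable" result instead of
raising, so pipeline report tables stay complete.

## Wright-Fisher simulator

State: per-locus risk-allele frequency f in a diploid population of
constant size N; loci are unlinked and independent (the underlying
argument is per-locus). Each generation applies the deterministic genic
selection update f* = f(1-s)/(1-sf) — equivalent to additive diploid
selection to first order; no dominance parameter, since none is implied
by the model — followed by binomial drift f' = B(2N, f*)/(2N). Fixed
loci are absorbing. s > 0 means the risk allele is deleterious; signed
samplers allow advantageous variants.

The environment change is represented by the initial condition rather
than simulated history: `folded_neutral` initialization draws MAF from
the 1/f folded neutral density on (1/(2N), 0.5] by inverse CDF
(MAF = a*(0.5/a)^u, a = 1/(2N)) and assigns the risk label to the minor
or major allele with probability 1/2 each, so MiRA at t = 0 is 0.5 in
expectation. A `uniform` mode exists for diagnostics. MiRA trajectories
are computed over segregating loci only.

Default run size — 5,000 loci, N = 10,000, 500 generations — is large
enough that the directional predictions (MiRA rises above 0.5 and the
spectrum left-shifts for s > 0; both effects increase with s; neutral
runs drift without systematic shift) are resolved well above drift
noise, while a single run completes in well under a second. The model's
timescale claim ("tens to hundreds of generations, depending on s") is
checked as sign/ordering properties, not numeric targets, because no
quantitative distribution of selection coefficients is specified by the
hypothesis.

## Synthetic-data generator

The generator emulates the structure the analyses assume, with the
estimable quantities as explicit parameters:

* **MAF ascertainment**: Beta(2,2) rescaled to (0.05, 0.5) — bell-shaped,
  like the spectrum of GWAS-detected SNPs on commercial platforms; the
  shape and range are configurable.
* **Left shift**: the risk allele is minor with probability
  1/2 + delta/2, delta in [0,1], so E[MiRA] = 0.5 + delta/2 and delta is
  recoverable as 2*(MiRA - 0.5). In preset scenarios delta decreases
  linearly in the disease's true ELI (delta_max = 0.4 at the lowest ELI,
  0 at the highest), reproducing the tertile gradient qualitatively.
* **Literature counts**: env+lifestyle co-mentions are
  Poisson(true_eli * n_pubs/1000), split Binomial(1/2) between the two
  terms, so the estimated ELI is unbiased with variance shrinking in
  publication volume.
* **Selection overlap**: a SNP universe with selected fraction q
  (default 0.0075, the empirical platform-level rate); platforms are
  uniform draws, the GWAS subset uniform (null) or weighted by
  enrichment e. Because subsets are drawn without replacement, the
  realized GWAS proportion approaches q*e only when q and the sampling
  fraction are small; the bundled power check sizes the GWAS subset at
  4,000 of a 50,000-SNP universe, where the e = 2 design has >95%
  analytic power for the 2x2 chi-square at alpha = 0.05.
* **Sample-size coupling**: optional `rare_coupling` makes larger studies
  likelier to carry rare (MAF <= 0.05) SNPs without touching the
  risk-direction assignment, reproducing the observed pattern of a
  positive sample-size-rarity correlation alongside a null
  sample-size-direction correlation.

What the generator does **not** emulate: linkage disequilibrium between
reported SNPs, genotyping error, study heterogeneity beyond sample
size, winner's-curse effect-size inflation, or secular trends in the
literature counts. Passing tests on generated data therefore validate
the estimators and the pipeline plumbing under the stated model, not
the robustness of the published conclusions to those real-data
complications.

## Pipeline conventions and degenerate inputs

Association records are filtered at the genome-wide threshold
p <= 5e-8 (records with no reported p-value are kept and logged);
duplicated (disease, SNP) pairs keep the smallest-p record, ties by
input order. Disease labels join case-insensitively after trimming; no
fuzzy matching. MiRA tables require >= 20 SNPs per disease and spectra
>= 50 (the published eligibility thresholds). Diseases are indexed for
ELI whenever they appear in the counts table; a study-count eligibility
filter ("at least 3 independent GWASs") is not recomputable from these
inputs and is deliberately not guessed at. Every filter logs
input = kept + dropped, and all outputs are sorted deterministically
(descending ELI; descending SNP count), so reruns are byte-identical.

## Reproduction scope and known limitations

From the bundled published count tables the package reproduces
exactly: all 44 ELI values; the platform percentages for the 8
internally consistent platform rows; the platform SE column from the
printed (percentage, count) pairs; and 24 of 25 per-disease SE values
under the ddof=1 convention. Known irreproducible cells, excluded and
documented rather than forced: two platform rows whose printed
percentage does not follow from their printed counts (evidently a mix
of nominal and actual SNP totals), and one disease row (pathological
myopia) whose printed SE is unattainable from its printed (p, n) under
any denominator convention — its SNP count also breaks the table's
descending-count ordering, suggesting a typo. The published
dataset-level statistics (ANOVA F across 25 diseases, the
ELI-frequency Spearman of 0.1-0.12, the ELI/extended-ELI correlation
of 0.92) depend on a 2014 database extraction and an unpublished
supplementary table and are not desk-reproducible; they are replaced by
parameter-recovery and end-to-end null/gradient properties on the
synthetic presets, with the tertile-gradient and positive
ELI-frequency-correlation checks mirroring the published direction.
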