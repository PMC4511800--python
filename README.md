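# riskspectra

Do risk alleles of common human diseases carry the footprint of negative
selection — and is that footprint weaker for diseases driven by recent
changes in environment and lifestyle? `riskspectra` is an analysis
package for GWAS-reported disease-SNP associations that answers this
with four linked components:

* **ELI** — an Environment/Lifestyle Index per disease from PubMed
  abstract co-occurrence counts:
  `ELI = (n_env + n_lifestyle) / n_disease × 1000`, with tertile
  stratification (tertile 1 = environment-independent diseases).
* **MiRA and spectra** — the Minor-Risk-Allele proportion
  (`p = #{F < 0.5}/n`, expected 0.5 when risk assignment is
  frequency-independent, > 0.5 under negative selection) and 5-bin
  risk-allele frequency spectra compared against an empirical
  frequency-independence null (each SNP's frequency mirrored with
  weight ½).
* **Selection overlap** — the percentage of SNPs with signatures of
  recent positive selection on genotyping platforms versus among
  GWAS-reported SNPs, with 2×2 chi-square comparisons and Bonferroni
  adjustment.
* **Wright–Fisher simulator** — forward simulation of the "recently
  neutral, currently deleterious" model: standing folded-neutral
  variation acquires selection coefficients at an environment change,
  then evolves by `f* = f(1−s)/(1−sf)` plus binomial drift,
  demonstrating the predicted MiRA rise and spectrum left-shift.

All inferential numbers flow through first-principles implementations of
Spearman rank correlation, chi-square tests and one-way ANOVA on a
binary indicator (`riskspectra.stats`), so every statistic is auditable.
A synthetic-data generator produces all pipeline inputs with known
parameters (left-shift strength δ, true ELI, selected fraction q) for
parameter-recovery testing. The published summary tables this analysis
rests on ship with the package (`riskspectra.reference`).

It is aimed at population and statistical geneticists who want to audit
or extend allelic-spectrum analyses of GWAS catalog data.

## Worked example

```python
>>> from riskspectra import LiteratureCounts, compute_eli
>>> ra = LiteratureCounts("Rheumatoid arthritis", n_disease=120346, n_env=1578, n_lifestyle=393)
>>> round(compute_eli(ra), 1)
16.4
```

16.4 abstracts per 1,000 rheumatoid-arthritis abstracts co-mention
environment or lifestyle — a low value, placing the disease in tertile 1
(environment-independent). Obesity scores 112.8, the highest.

The full analysis is a sequence of numbered drivers (each writes TSVs
under `results/`):

```bash
python analysis/01_published_tables.py   # ELI table + platform overlap from published counts
python analysis/02_synthetic_bundle.py   # preset synthetic inputs (δ decreasing in ELI)
python analysis/03_pipeline_run.py       # full pipeline on the bundle
python analysis/04_wf_simulation.py      # Wright-Fisher runs across s
```

`03_pipeline_run.py` prints the study's central pattern on the preset
scenario — the MiRA proportion falls from the environment-independent to
the environment-dependent tertile:

```
MiRA by ELI tertile (1 = environment-independent):
 tertile  mira  n_snps   se
       1  0.67     680 0.02
       2  0.59     612 0.02
       3  0.52     503 0.02
  anova_mira_by_tertile: stat=13.242 df=(2, 1792) p=1.96e-06
  spearman_eli_vs_risk_freq: stat=0.102 df=1793 p=1.63e-05
```

and `04_wf_simulation.py` shows the simulator's dose response — stronger
selection against risk alleles raises the MiRA proportion over 500
generations and left-shifts the endpoint spectrum:

```
s=0.0:   MiRA 0.485 -> 0.464, left-shift -0.038
s=0.005: MiRA 0.485 -> 0.569, left-shift +0.069
s=0.01:  MiRA 0.485 -> 0.781, left-shift +0.278
s=0.02:  MiRA 0.485 -> 0.994, left-shift +0.493
```

There is also a CLI mirroring the library
(`riskspectra synth|eli|mira|spectra|overlap|simulate|run`); see
`riskspectra --help`.

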