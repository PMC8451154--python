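# tandem5hmc

Analysis of 5-hydroxymethylcytosine (5hmC) from tandem bisulfite /
oxidative-bisulfite methylation arrays, with a synthetic-data generator for
end-to-end validation.

## The problem

Standard bisulfite (BS) conversion cannot distinguish 5-methylcytosine
(5mC) from its oxidised form 5hmC: a BS beta value reads their **sum**.
Oxidative bisulfite (OxBS) treatment of a second aliquot converts 5hmC
before readout, so its beta reads 5mC alone. Profiling both treatments on
the same samples lets the two marks be separated — which matters most in
brain tissue, where 5hmC is abundant, and in CNS tumors, where its loss is
a candidate prognostic marker and a hidden confounder of methylation-based
tumor classifiers.

`tandem5hmc` implements the full downstream workflow for paired BS/OxBS
beta matrices:

1. **Deconvolution** — per CpG and sample, estimate (pC, p5mC, p5hmC) on
   the probability simplex, by constrained subtraction
   (p̂5hmC = max(βBS − βOxBS, 0)) or by per-cell maximum likelihood under a
   beta noise model βBS ~ Beta(μ₁φ, (1−μ₁)φ), βOxBS ~ Beta(μ₂φ, (1−μ₂)φ)
   with μ₁ = p5mC + p5hmC, μ₂ = p5mC.
2. **Locus selection** — rank loci by median tumor 5hmC and keep the top
   fraction (floor(frac·N); 5% of 743,461 loci is exactly 37,173),
   plus per-sample medians with Welch tests, per-CpG Spearman 5mC–5hmC
   correlations, and TSS-distance profiles.
3. **Enrichment** — Fisher exact 2×2 tests of the high-5hmC set in CpG
   island/shore/shelf/open-sea contexts, Cochran–Mantel–Haenszel tests
   stratified by Infinium probe type for regulatory flags, interval-overlap
   enrichment against BED region collections (e.g. super-enhancer
   catalogues) with BH q-values, and gene-level high-5hmC scores.
4. **Differential hydroxymethylation** — per-CpG OLS of 5hmC betas on
   group + age + sex (optional limma-style variance moderation),
   Benjamini–Hochberg FDR, and extraction of differentially
   hypohydroxymethylated CpGs ("DHMRs": q < 0.1, negative effect).
5. **Clustering and survival** — a recursively partitioned beta-mixture
   model (RPMM) over the most variable 5hmC loci: recursive two-class
   beta-mixture EM splits accepted by BIC; leaves labelled high/low 5hmC;
   class membership related to death and recurrence through multivariable
   Cox proportional hazards (Efron ties, Harrell concordance) and
   Kaplan–Meier / log-rank comparisons.

A configurable synthetic-data generator plants all of these signals — high-
5hmC loci concentrated in open-sea/enhancer contexts, global tumor
hypohydroxymethylation with locus-specific 5mC gain at DHMRs, a low-5hmC
tumor class with elevated hazard — so that every stage can be tested
against known truth. See `docs/methods.md` for the models, defaults and
numerical choices.

## Worked example

```python
from tandem5hmc import SimConfig, simulate_dataset, deconvolve_naive
from tandem5hmc.locus_selection import sample_medians, select_high_5hmc
from tandem5hmc.enrichment import fisher_context_enrichment
from tandem5hmc.cluster_survival import (
    top_variable_loci, cluster_tumors, label_clusters, cox_fit,
)

cfg = SimConfig(n_cpg=20_000, n_genes=800, seed=11)   # 27 tumors, 3 controls
paired, ann, samples, truth = simulate_dataset(cfg)
props = deconvolve_naive(paired)

med, tests = sample_medians(props, samples)
summary = select_high_5hmc(props, samples.tumor_ids, frac=0.05)
high = summary.index[summary.is_high_5hmc]
island = fisher_context_enrichment(high, props.locus_ids, ann, "island")
open_sea = fisher_context_enrichment(high, props.locus_ids, ann, "open_sea")

top = top_variable_loci(props, samples.tumor_ids, 4_000)
tree = cluster_tumors(props, samples.tumor_ids, top)
labels, diag = label_clusters(tree, props, samples)
fit = cox_fit(samples, outcome="death", cluster_labels=labels)
```

Output of this script (printing the quantities above):

```
median 5hmC: tumor 0.0075, non-tumor 0.0251 (Welch p = 1.42e-16)
high-5hmC loci: 1000 (threshold median 0.034)
island: OR 0.20 (95% CI 0.15-0.26), p = 2.96e-45
open_sea: OR 3.04 (95% CI 2.62-3.54), p = 1.85e-54
clusters: 14 low / 13 high (Kruskal-Wallis p = 1.01e-05)
low-5hmC death HR 6.09 (95% CI 1.91-19.40), p = 0.002, concordance 0.71
```

Reading the numbers: tumors are globally depleted of 5hmC relative to
non-tumor brain (per-sample medians ~3x lower); the top-5% high-5hmC loci
are strongly depleted in CpG islands (OR < 1) and enriched in open-sea
regions (OR > 1); the beta-mixture clustering splits the 27 tumors into a
low- and a high-5hmC class whose mean 5hmC levels differ (Kruskal–Wallis),
and the low-5hmC class carries a substantially higher hazard of death in
the covariate-adjusted Cox model — the planted prognostic signal, recovered
end to end from the noisy paired betas.

The same pipeline runs from the shell:

```sh
tandem5hmc simulate --outdir data/ --seed 11
tandem5hmc run --config run.yaml            # simulate/ingest → ... → survival
tandem5hmc deconvolve --bs beta_bs.tsv --oxbs beta_oxbs.tsv --method naive --out props/
```

`run.yaml` holds a `RunConfig`: an output directory, either a `simulate:`
block (SimConfig fields) or paths to BS/OxBS/annotation/metadata TSVs,
plus the stage parameters (`frac_high5hmc`, `fdr`, `top_n_variable`,
`min_high`). Every run writes TSV/BED outputs and a `manifest.json` with
the seed, a parameter hash and row counts; identical configurations
reproduce identical outputs.

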