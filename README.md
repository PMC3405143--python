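# bloodmeth

Cell-type differential DNA methylation analysis for whole blood.

Whole blood is not a tissue but a mixture: neutrophils, lymphocyte subsets,
monocytes and eosinophils each carry their own methylome, and the bulk
methylation signal of a blood draw is the cell-fraction-weighted average of
those profiles. A case–control difference measured in whole blood can
therefore reflect a shift in the differential cell count rather than any
change in methylation state. `bloodmeth` implements the complete analysis
used to characterize this problem on two-channel methylation arrays —
purified leukocyte populations and their composite fractions (whole blood,
PBMC, granulocytes) compared probe by probe — together with a synthetic
cell-mixture generator so every stage is testable end to end without any
download.

## The model and statistics

**M-values.** Each probe yields methylated and unmethylated channel
intensities; the analysis works on `M = log2((meth + c)/(unmeth + c))`
(offset `c = 100`), with `beta = 2^M / (2^M + 1)` the methylated fraction.
`M = 0` means a half-methylated CpG. Preprocessing: per-sample background
subtraction at a low quantile, quantile mapping of red-channel probes onto
the green distribution, then quantile normalization of the stacked
intensity matrix.

**Moderated t.** Probe-wise one-way fit of M on population; the residual
variance s² (df `d = N − G`) is shrunk toward an ensemble prior (d₀, s₀²)
estimated by the method of moments on log s²:

    s²_post = (d₀ s₀² + d s²) / (d₀ + d),
    t = (mean_A − mean_B) / sqrt(s²_post (1/n_A + 1/n_B)),  df = d₀ + d.

Pairwise contrasts of every population against whole blood are BH-adjusted
per contrast; q < 0.01 is significant.

**Gamma-mixture calls.** Per sample, the M distribution is fit with a
two-component mixture of reflected gammas anchored just outside the data
range:

    f(m) = π_u Γ(a_u − m; k_u, θ_u) + (1 − π_u) Γ(m − a_m; k_m, θ_m),

fit by EM (weighted gamma MLE in the M-step). The posterior probability of
the methylated component, thresholded at τ = 0.9, gives three calls:
unmethylated / marginal / methylated. Population calls are the majority
consensus over donors (ties → marginal). The **call-discordance filter**
keeps a significant probe only when the two compared populations carry
different calls — the paper-style definition of the final DM probe set.

**Downstream.** Genomic-region classification (TSS / 5′ region / gene body /
3′ region / intergenic, with CpG island–shore–shelf context), candidate-gene
probe subsetting, and DAVID-style hypergeometric term enrichment of the
genes unmethylated in a cell type but methylated in whole blood.

**Synthetic mixtures.** The generator draws per-probe base betas from three
archetypes, plants population-specific effects (Δβ ∈ [0.45, 0.75],
hypomethylation-biased in myeloid populations) and a shared myeloid-vs-
lymphoid lineage block, mixes composites *linearly in beta space*
(whole blood ≈ 60% neutrophils), adds logit-scale donor effects shared
within donor, M-scale measurement noise, gamma-distributed total intensity,
red-channel bias and additive background — and records the full ground
truth. See `docs/methods.md` for every default and its rationale.

## Worked example

```python
from bloodmeth import synthetic, pipeline

truth = synthetic.make_truth(synthetic.GeneratorConfig(), seed=1)
dataset = synthetic.simulate_samples(truth, seed=2)      # 20,000 x 60
result = pipeline.run_reference_analysis(dataset)         # vs whole blood
print(result.summary.loc[["Granulocytes", "CD4T"]].round(1))
print(pipeline.recovery_metrics(result, truth))
```

prints (seed-exact):

```
              significant  call_filtered  abs_dm_min  abs_dm_max  pct_unmethylated  pct_marginal  pct_methylated
population
Granulocytes         1506            659         0.3         3.6              17.0          80.1             2.9
CD4T                 1500            445         0.4         7.1              18.4          22.5            59.1
{'sensitivity': 0.9651..., 'fdr': 0.0, 'n_planted': 1750, ...}
```

The granulocyte fraction, which dominates whole blood, shows the smallest
effect sizes against it (|ΔM| up to 3.6 vs 7.1 for CD4⁺ T cells) and an
unmethylated/marginal-skewed call distribution, while the lymphoid CD4⁺
T cells skew methylated — the mixture-dilution mechanism the package exists
to demonstrate. Of 1,750 planted effects, 96.5% survive the q < 0.01 +
call-discordance filter with no false recoveries.

The same analysis is available as numbered scripts (`analysis/01_simulate.py`
… `analysis/07_recovery.py`, writing tables under `results/`) and as a CLI
(`bloodmeth simulate|preprocess|diffmeth|call|structure|annotate|enrich|report`).
`analysis/08_validate_full_scale.py` optionally reruns the pairwise analysis
on the real 60-sample purified blood-cell dataset (GEO accession GSE35069,
user-downloaded series matrix) and scores rank agreement against the
published pairwise counts.

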